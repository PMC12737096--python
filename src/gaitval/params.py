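"""Canonical vocabulary for the seven spatiotemporal gait parameters."""

#: Parameter names, in the conventional reporting order.
PARAMETERS = (
    "stance_pct",
    "swing_pct",
    "single_support_pct",
    "stride_length",
    "step_length",
    "velocity",
    "cadence",
)

#: Measurement units per parameter.
UNITS = {
    "stance_pct": "%GCT",
    "swing_pct": "%GCT",
    "single_support_pct": "%GCT",
    "stride_length": "m",
    "step_length": "m",
    "velocity": "m/s",
    "cadence": "steps/min",
}

#: Human-readable labels used in report tables.
LABELS = {
    "stance_pct": "Stance phase [%GCT]",
    "swing_pct": "Swing phase [%GCT]",
    "single_support_pct": "Single support phase [%GCT]",
    "stride_length": "Stride length [m]",
    "step_length": "Step length [m]",
    "velocity": "Velocity [m/s]",
    "cadence": "Cadence [steps/min]",
}
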