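"""Study-shaped synthetic gait data with known ground truth.

Emulates the structure of a two-system, two-rater validation study on a
walkway cohort: per-subject true spatiotemporal parameters, per-trial event
streams, and long-format measurement tables in which each walking trial is
recorded simultaneously by both measurement systems.

Subject-level truths are drawn as independent normals for cadence, stride
length, step length and stance phase; the remaining parameters follow from
deterministic consistency constraints:

* ``velocity = stride_length * cadence / 120``  (two steps per stride)
* ``swing = 100 - stance``  (the phases partition the cycle)
* ``single_support = swing - ds_asymmetry``  (equal double-support halves by
  default, so single support equals the contralateral swing)

Trial-to-trial variation perturbs the independent quantities and the derived
ones are recomputed, so measured stance and swing stay complementary within a
trial, as a real event-based system would report them.  Measurement-system
error is injected per parameter as ``a + b * value + noise`` — the constant
(a) and proportional (b) error taxonomy that the validity battery is designed
to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import DomainError
from .gait_events import GaitEventSeries
from .params import PARAMETERS

#: Reference-system population moments (healthy adults, self-selected speed).
DEFAULT_MEANS = {
    "stance_pct": 61.76,
    "swing_pct": 38.24,
    "single_support_pct": 38.26,
    "stride_length": 1.38,
    "step_length": 0.69,
    "velocity": 1.38,
    "cadence": 120.13,
}
DEFAULT_SDS = {
    "stance_pct": 2.58,
    "swing_pct": 2.58,
    "single_support_pct": 2.56,
    "stride_length": 0.13,
    "step_length": 0.06,
    "velocity": 0.18,
    "cadence": 10.13,
}

#: Parameters drawn independently per subject; the rest are derived.
INDEPENDENT = ("cadence", "stride_length", "step_length", "stance_pct")
#: Parameters receiving independent trial-to-trial noise.
TRIAL_NOISE_KEYS = ("cadence", "stride_length", "step_length", "stance_pct",
                    "single_support_pct")


def _default_within_sd() -> dict[str, float]:
    # Half the between-subject SD, i.e. a true test-retest ICC of 0.80 —
    # the reliability level such validation studies are typically powered for.
    return {k: DEFAULT_SDS[k] / 2.0 for k in TRIAL_NOISE_KEYS}


@dataclass
class CohortConfig:
    """Configuration of the synthetic study cohort."""

    n_subjects: int = 30
    n_raters: int = 2
    n_sessions_per_rater: int = 2
    walkway_length: float = 8.0
    subject_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MEANS))
    subject_sds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SDS))
    within_subject_sd: dict[str, float] = field(default_factory=_default_within_sd)
    rater_shift: dict[str, float] = field(default_factory=dict)
    ds_asymmetry: float = 0.0
    systems: tuple[str, ...] = ("mocap", "imu")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise DomainError("n_subjects must be at least 2")
        if any(sd < 0 for sd in list(self.subject_sds.values())
               + list(self.within_subject_sd.values())):
            raise DomainError("standard deviations must be non-negative")
        for key in INDEPENDENT:
            if self.subject_means.get(key, 0) <= 0:
                raise DomainError(f"mean of {key} must be positive")
        if not 50 < self.subject_means["stance_pct"] < 100:
            raise DomainError("stance mean must lie in (50, 100) %GCT")


@dataclass(frozen=True)
class SystemModel:
    """Linear measurement-system error: value -> a + b * value + N(0, noise_sd^2)."""

    a: float = 0.0
    b: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")


IDENTITY_MODEL = SystemModel()


def _derive(values: Mapping[str, float | np.ndarray],
            ds_asymmetry: float) -> dict:
    """Fill in velocity, swing and single support from the independent values."""
    out = dict(values)
    out["velocity"] = out["stride_length"] * out["cadence"] / 120.0
    out["swing_pct"] = 100.0 - out["stance_pct"]
    if "single_support_pct" not in out:
        out["single_support_pct"] = out["swing_pct"] - ds_asymmetry
    return out


def sample_subjects(config: CohortConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-subject true parameters; one row per subject, one column each.

    Non-physiological draws (negative lengths, stance outside (0, 100)) are
    redrawn, up to 100 attempts per subject.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rows = []
    for i in range(config.n_subjects):
        for attempt in range(100):
            draw = {k: rng.normal(config.subject_means[k], config.subject_sds[k])
                    for k in INDEPENDENT}
            ok = (draw["cadence"] > 0 and draw["stride_length"] > 0
                  and 0 < draw["step_length"] < draw["stride_length"]
                  and 0 < draw["stance_pct"] < 100)
            if ok:
                break
        else:
            raise DomainError(f"subject {i}: no physiological draw in 100 attempts")
        truth = _derive(draw, config.ds_asymmetry)
        truth["subject"] = f"S{i + 1:02d}"
        rows.append(truth)
    return pd.DataFrame(rows).set_index("subject")[list(PARAMETERS)]


def events_from_parameters(
    truth: Mapping[str, float],
    n_strides: int,
    subject_id: str = "S01",
    rater_id: str = "A",
    system_id: str = "truth",
    session_id: str = "1",
    jitter_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> GaitEventSeries:
    """Build a strictly interleaved event stream realising a truth vector.

    The stream is periodic and symmetric: left heel strikes fall half a cycle
    after right ones, double support is split equally, and heel-strike
    positions advance by the stride length.  Right-side cycles carry exactly
    the requested stance, single-support, stride and step values; the
    side-averaged trial summary therefore recovers the truth exactly whenever
    the truth satisfies the geometric identities of symmetric gait
    (``single_support = 100 - stance`` and ``step = stride / 2``), which the
    cohort defaults do.  ``walk_duration`` is set to ``60 * step_count /
    cadence`` so cadence also round-trips exactly.

    Optional ``jitter_sd`` adds independent Gaussian jitter to the within-
    cycle events (toe-offs and left heel strikes), emulating event-detection
    noise; the jittered stream is re-validated and must keep its interleaving.
    """
    if n_strides < 2:
        raise DomainError("n_strides must be at least 2")
    cadence = truth["cadence"]
    stride = truth["stride_length"]
    step = truth["step_length"]
    stance = truth["stance_pct"]
    ss = truth.get("single_support_pct", 100.0 - stance)
    if cadence <= 0:
        raise DomainError("cadence must be positive")
    if not 50.0 < stance < 100.0:
        raise DomainError(
            f"stance {stance:.2f}%GCT infeasible: symmetric gait requires "
            "50 < stance < 100 (otherwise double support would be negative)")
    if not 0.0 < ss < 50.0:
        raise DomainError(
            f"single support {ss:.2f}%GCT infeasible: must lie in (0, 50)")
    if not 0.0 < step < stride:
        raise DomainError("step length must lie strictly between 0 and stride length")

    gct = 120.0 / cadence
    k = np.arange(n_strides + 1, dtype=float)
    hs_right = k * gct
    kk = np.arange(n_strides, dtype=float)
    to_right = kk * gct + stance / 100.0 * gct
    hs_left = kk * gct + gct / 2.0
    to_left = hs_left - ss / 100.0 * gct
    x_hs_right = k * stride
    x_hs_left = (kk + 1) * stride - step

    if jitter_sd > 0:
        rng = np.random.default_rng() if rng is None else rng
        to_right = to_right + rng.normal(0, jitter_sd, to_right.shape)
        hs_left = hs_left + rng.normal(0, jitter_sd, hs_left.shape)
        to_left = to_left + rng.normal(0, jitter_sd, to_left.shape)

    step_count = len(hs_right) + len(hs_left)
    return GaitEventSeries(
        subject_id=subject_id, rater_id=rater_id, system_id=system_id,
        session_id=session_id,
        hs_right=hs_right, hs_left=hs_left, to_right=to_right, to_left=to_left,
        x_hs_right=x_hs_right, x_hs_left=x_hs_left,
        walk_duration=60.0 * step_count / cadence, step_count=step_count)


def representable_truth(truth: Mapping[str, float]) -> dict[str, float]:
    """Project a truth vector onto values a symmetric event stream can carry.

    Side-averaging over a periodic stream forces ``step = stride / 2`` and
    ``stance + single_support = 100``; this returns the projected vector that
    :func:`events_from_parameters` recovers exactly.
    """
    t = _derive({k: truth[k] for k in INDEPENDENT}, 0.0)
    t["single_support_pct"] = truth.get("single_support_pct", t["swing_pct"])
    stance_p = (t["stance_pct"] + 100.0 - t["single_support_pct"]) / 2.0
    ss_p = 100.0 - stance_p
    return {
        "cadence": t["cadence"],
        "stride_length": t["stride_length"],
        "step_length": t["stride_length"] / 2.0,
        "velocity": t["velocity"],
        "stance_pct": stance_p,
        "swing_pct": 100.0 - stance_p,
        "single_support_pct": ss_p,
    }


def apply_system_model(values, model: SystemModel,
                       rng: np.random.Generator | None = None):
    """Measure true values through a linear error model, ``a + b x + noise``."""
    values = np.asarray(values, dtype=float)
    out = model.a + model.b * values
    if model.noise_sd > 0:
        rng = np.random.default_rng() if rng is None else rng
        out = out + rng.normal(0.0, model.noise_sd, size=values.shape)
    return out if out.shape else float(out)


def _normalize_models(
    config: CohortConfig,
    system_models: Mapping[str, SystemModel | Mapping[str, SystemModel]] | None,
) -> dict[tuple[str, str], SystemModel]:
    models: dict[tuple[str, str], SystemModel] = {}
    system_models = system_models or {}
    for system in config.systems:
        entry = system_models.get(system, IDENTITY_MODEL)
        for p in PARAMETERS:
            if isinstance(entry, SystemModel):
                models[(system, p)] = entry
            else:
                models[(system, p)] = entry.get(p, IDENTITY_MODEL)
    return models


def generate_study(
    config: CohortConfig,
    system_models: Mapping[str, SystemModel | Mapping[str, SystemModel]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full study and return (measurements, truth).

    The measurement table is long-format with columns
    ``subject, rater, system, session, parameter, value`` covering every
    subject x rater x session x system x parameter combination.  Each trial
    (subject, rater, session) is realised once — trial-to-trial noise and any
    rater shift perturb the true values — and then recorded by every system
    through its error model, mirroring simultaneous acquisition.

    ``system_models`` maps system id to either a single :class:`SystemModel`
    (applied to all parameters) or a per-parameter mapping; unlisted systems
    and parameters are measured identically (identity model, no noise).
    """
    rng = np.random.default_rng(config.seed)
    truth = sample_subjects(config, rng)
    models = _normalize_models(config, system_models)
    raters = [chr(ord("A") + i) for i in range(config.n_raters)]
    records = []
    for subject, t in truth.iterrows():
        for ri, rater in enumerate(raters):
            for session in range(1, config.n_sessions_per_rater + 1):
                trial = {k: t[k] + rng.normal(0.0, self_sd)
                         for k, self_sd in
                         ((k, config.within_subject_sd.get(k, 0.0))
                          for k in INDEPENDENT)}
                trial = _derive(trial, config.ds_asymmetry)
                trial["single_support_pct"] += rng.normal(
                    0.0, config.within_subject_sd.get("single_support_pct", 0.0))
                for p in PARAMETERS:
                    trial[p] = trial[p] + ri * config.rater_shift.get(p, 0.0)
                for system in config.systems:
                    for p in PARAMETERS:
                        value = apply_system_model(trial[p], models[(system, p)], rng)
                        records.append({
                            "subject": subject, "rater": rater, "system": system,
                            "session": str(session), "parameter": p,
                            "value": float(value)})
    return pd.DataFrame(records), truth


# ---------------------------------------------------------------------------
# Config (de)serialization — nested key-value YAML.

def config_to_yaml(config: CohortConfig, path) -> None:
    doc = {
        "design": {
            "n_subjects": config.n_subjects,
            "n_raters": config.n_raters,
            "n_sessions_per_rater": config.n_sessions_per_rater,
            "walkway_length": config.walkway_length,
            "systems": list(config.systems),
            "seed": config.seed,
        },
        "population": {
            "means": dict(config.subject_means),
            "sds": dict(config.subject_sds),
            "ds_asymmetry": config.ds_asymmetry,
        },
        "noise": {
            "within_subject_sd": dict(config.within_subject_sd),
            "rater_shift": dict(config.rater_shift),
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def config_from_yaml(path) -> CohortConfig:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    design = doc.get("design", {})
    pop = doc.get("population", {})
    noise = doc.get("noise", {})
    kwargs = {}
    for key in ("n_subjects", "n_raters", "n_sessions_per_rater",
                "walkway_length", "seed"):
        if key in design:
            kwargs[key] = design[key]
    if "systems" in design:
        kwargs["systems"] = tuple(design["systems"])
    if "means" in pop:
        kwargs["subject_means"] = {**DEFAULT_MEANS, **pop["means"]}
    if "sds" in pop:
        kwargs["subject_sds"] = {**DEFAULT_SDS, **pop["sds"]}
    if "ds_asymmetry" in pop:
        kwargs["ds_asymmetry"] = pop["ds_asymmetry"]
    if "within_subject_sd" in noise:
        kwargs["within_subject_sd"] = {**_default_within_sd(),
                                       **noise["within_subject_sd"]}
    if "rater_shift" in noise:
        kwargs["rater_shift"] = dict(noise["rater_shift"])
    return CohortConfig(**kwargs)
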