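"""Event-stream representation and per-cycle parameter extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitval import gait_events as ge
from gaitval import synthetic_cohort as sc
from gaitval.exceptions import DomainError, ParseError, ValidationError


def one_cycle_series(**overrides):
    kw = dict(subject_id="s1", rater_id="A", system_id="imu", session_id="1",
              hs_right=[0.0, 1.0], hs_left=[0.5], to_right=[0.6],
              to_left=[0.1], x_hs_right=[0.0, 1.5], x_hs_left=[0.75])
    kw.update(overrides)
    return ge.GaitEventSeries(**kw)


class TestSeriesValidation:
    def test_minimal_series_valid(self):
        s = one_cycle_series()
        assert s.step_count == 3
        assert s.walk_duration == pytest.approx(1.0)

    def test_contralateral_toe_off_after_heel_strike_rejected(self):
        # TO-left must precede HS-left within the cycle
        with pytest.raises(ValidationError, match="cycle 0"):
            one_cycle_series(to_left=[0.55])

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValidationError, match="strictly increasing"):
            one_cycle_series(hs_right=[0.0, 0.0])

    def test_position_length_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="x_hs_right"):
            one_cycle_series(x_hs_right=[0.0])

    def test_backward_walk_positions_reoriented(self):
        s = one_cycle_series(x_hs_right=[0.0, -1.5], x_hs_left=[-0.75])
        assert s.x_hs_right[1] == pytest.approx(1.5)
        [c] = ge.extract_cycles(s)
        assert c.stride_length == pytest.approx(1.5)


class TestCadence:
    @pytest.mark.parametrize("steps,duration,expected",
                             [(10, 5.0, 120.0), (2, 1.0, 120.0)])
    def test_direct_arithmetic(self, steps, duration, expected):
        s = one_cycle_series(walk_duration=duration, step_count=steps)
        assert ge.compute_cadence(s) == pytest.approx(expected)

    def test_nonpositive_duration_rejected(self):
        s = one_cycle_series()
        s.walk_duration = 0.0
        with pytest.raises(DomainError):
            ge.compute_cadence(s)

    def test_generator_cadence_recovered(self):
        truth = dict(cadence=117.4, stride_length=1.5, step_length=0.75,
                     stance_pct=60.0, single_support_pct=40.0)
        s = sc.events_from_parameters(truth, n_strides=8)
        assert ge.compute_cadence(s) == pytest.approx(117.4, rel=1e-12)


class TestExtractCycles:
    def test_single_cycle_values(self):
        [c] = ge.extract_cycles(one_cycle_series())
        assert c.side == "right" and c.cycle_index == 0
        assert c.gct == pytest.approx(1.0)
        assert c.stride_length == pytest.approx(1.5)
        assert c.step_length == pytest.approx(0.75)
        assert c.velocity == pytest.approx(1.5)
        assert c.stance_pct == pytest.approx(60.0)
        assert c.swing_pct == pytest.approx(40.0)
        assert c.single_support_pct == pytest.approx(40.0)

    def test_printed_single_support_formula_is_negative(self):
        # The as-printed operand order yields a negative duration under the
        # canonical interleaving; kept only for auditing.
        [c] = ge.extract_cycles(one_cycle_series(), ss_formula="printed")
        assert c.single_support_pct == pytest.approx(-10.0)

    def test_fewer_than_two_heel_strikes_yields_empty(self):
        s = one_cycle_series()
        s.hs_right = s.hs_right[:1]
        s.x_hs_right = s.x_hs_right[:1]
        assert ge.extract_cycles(s, sides=("right",)) == []

    def test_cycle_missing_contralateral_events_skipped(self, caplog):
        s = one_cycle_series(to_left=[], hs_left=[], x_hs_left=[])
        with caplog.at_level("WARNING"):
            assert ge.extract_cycles(s, sides=("right",)) == []
        assert "missing paired events" in caplog.text

    def test_stance_swing_partition_exact(self):
        truth = dict(cadence=113.0, stride_length=1.41, step_length=0.705,
                     stance_pct=61.3, single_support_pct=38.7)
        s = sc.events_from_parameters(truth, n_strides=12, jitter_sd=2e-3,
                                      rng=np.random.default_rng(5))
        cycles = ge.extract_cycles(s)
        assert len(cycles) > 10
        for c in cycles:
            assert c.stance_pct + c.swing_pct == 100.0  # exact, by construction

    def test_synthetic_stream_cycle_means_equal_truth(self):
        truth = dict(cadence=120.0, stride_length=1.49, step_length=0.745,
                     stance_pct=60.3, single_support_pct=39.7)
        s = sc.events_from_parameters(truth, n_strides=20)
        right = [c for c in ge.extract_cycles(s) if c.side == "right"]
        assert len(right) == 20
        assert np.mean([c.stride_length for c in right]) == pytest.approx(1.49)
        assert np.mean([c.stance_pct for c in right]) == pytest.approx(60.3)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(shift=st.floats(-50, 50), xshift=st.floats(-20, 20))
def test_translation_invariance(shift, xshift):
    """Shifting all times/positions by constants leaves parameters unchanged."""
    base = one_cycle_series()
    shifted = one_cycle_series(
        hs_right=base.hs_right + shift, hs_left=base.hs_left + shift,
        to_right=base.to_right + shift, to_left=base.to_left + shift,
        x_hs_right=base.x_hs_right + xshift, x_hs_left=base.x_hs_left + xshift)
    [c0], [c1] = ge.extract_cycles(base), ge.extract_cycles(shifted)
    for attr in ("gct", "stride_length", "step_length", "velocity",
                 "stance_pct", "swing_pct", "single_support_pct"):
        assert getattr(c1, attr) == pytest.approx(getattr(c0, attr), rel=1e-9)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(c=st.floats(0.25, 4.0))
def test_time_scaling(c):
    """Scaling times by c divides velocity and cadence by c; %GCT unchanged."""
    base = one_cycle_series(walk_duration=1.0, step_count=3)
    scaled = one_cycle_series(
        hs_right=base.hs_right * c, hs_left=base.hs_left * c,
        to_right=base.to_right * c, to_left=base.to_left * c,
        walk_duration=1.0 * c, step_count=3)
    [c0], [c1] = ge.extract_cycles(base), ge.extract_cycles(scaled)
    assert c1.velocity == pytest.approx(c0.velocity / c)
    assert ge.compute_cadence(scaled) == pytest.approx(ge.compute_cadence(base) / c)
    assert c1.stance_pct == pytest.approx(c0.stance_pct)
    assert c1.single_support_pct == pytest.approx(c0.single_support_pct)


class TestSummarizeTrial:
    def test_sides_averaged_with_equal_weight(self):
        # Oracle: recompute side means directly from the cycle list.
        truth = dict(cadence=118.0, stride_length=1.45, step_length=0.725,
                     stance_pct=60.0, single_support_pct=40.0)
        s = sc.events_from_parameters(truth, n_strides=10, jitter_sd=3e-3,
                                      rng=np.random.default_rng(9))
        cycles = ge.extract_cycles(s)
        summ = ge.summarize_trial(s)
        for attr in ("stance_pct", "single_support_pct", "stride_length"):
            side_means = [np.mean([getattr(c, attr) for c in cycles if c.side == sd])
                          for sd in ("right", "left")]
            assert getattr(summ, attr) == pytest.approx(np.mean(side_means))

    def test_symmetric_gait_sides_agree(self):
        truth = dict(cadence=120.0, stride_length=1.5, step_length=0.75,
                     stance_pct=60.0, single_support_pct=40.0)
        s = sc.events_from_parameters(truth, n_strides=10)
        cycles = ge.extract_cycles(s)
        r = np.mean([c.stance_pct for c in cycles if c.side == "right"])
        l = np.mean([c.stance_pct for c in cycles if c.side == "left"])
        assert r == pytest.approx(l)
        assert ge.summarize_trial(s).stance_pct == pytest.approx(60.0)

    def test_one_side_empty_falls_back_with_warning(self, caplog):
        s = one_cycle_series()  # only a right cycle exists
        with caplog.at_level("WARNING"):
            summ = ge.summarize_trial(s)
        assert summ.n_cycles_left == 0 and summ.n_cycles_right == 1
        assert summ.stance_pct == pytest.approx(60.0)
        assert "other side" in caplog.text


class TestEventsCsv:
    def test_round_trip_identity(self, tmp_path):
        truth = dict(cadence=115.0, stride_length=1.4, step_length=0.7,
                     stance_pct=61.0, single_support_pct=39.0)
        orig = [sc.events_from_parameters(truth, n_strides=6, subject_id=f"S{i}")
                for i in (1, 2)]
        path = tmp_path / "events.csv"
        ge.write_events_csv(orig, path)
        back = ge.read_events_csv(path)
        assert len(back) == 2
        for a, b in zip(sorted(orig, key=lambda s: s.subject_id), back):
            for field in ("hs_right", "hs_left", "to_right", "to_left",
                          "x_hs_right", "x_hs_left"):
                np.testing.assert_allclose(getattr(b, field), getattr(a, field))

    def test_minimal_csv_one_right_cycle(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text(
            "subject,rater,system,session,event_type,side,time_s,position_m\n"
            "s1,A,imu,1,HS,R,0.0,0.0\n"
            "s1,A,imu,1,HS,R,1.0,1.5\n"
            "s1,A,imu,1,HS,L,0.5,0.75\n"
            "s1,A,imu,1,TO,L,0.1,\n")
        [s] = ge.read_events_csv(path)
        assert len(s.hs_right) == 2

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text(
            "subject,rater,system,session,event_type,side,time_s,position_m\n"
            "s1,A,imu,1,HS,R,0.0,0.0\n"
            "s1,A,imu,1,XX,R,1.0,1.5\n")
        with pytest.raises(ParseError, match="line 3"):
            ge.read_events_csv(path)

    def test_interleaving_violation_in_file_rejected(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text(
            "subject,rater,system,session,event_type,side,time_s,position_m\n"
            "s1,A,imu,1,HS,R,0.0,0.0\n"
            "s1,A,imu,1,HS,R,1.0,1.5\n"
            "s1,A,imu,1,HS,L,0.5,0.75\n"
            "s1,A,imu,1,TO,L,0.55,\n")
        with pytest.raises(ValidationError, match="cycle 0"):
            ge.read_events_csv(path)
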