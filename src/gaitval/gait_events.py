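"""Foot-contact event streams and per-cycle spatiotemporal gait parameters.

A walking trial is represented by the times of right and left heel strikes
(HS) and toe-offs (TO), plus the forward position of each heel strike along
the walkway.  A *gait cycle* runs from one heel strike to the next heel
strike of the same foot; within a complete right cycle the events interleave
as

    HSr(k) < TOL(k) < HSL(k) < TOr(k) < HSr(k+1)

(and mirrored for left cycles).  From the event stream this module computes,
per cycle, the seven parameters conventionally reported in clinical gait
analysis:

* cadence [steps/min] — stepping rate, ``60 * steps / walk time`` (trial level)
* stride length [m] — displacement between consecutive ipsilateral heel strikes
* step length [m] — displacement between a contralateral heel strike and the
  following ipsilateral heel strike
* velocity [m/s] — stride length over gait cycle time
* stance / swing phase [%GCT] — fraction of the cycle with the reference foot
  on / off the ground; they partition the cycle so stance + swing = 100 exactly
* single-support phase [%GCT] — fraction of the cycle with only the reference
  foot on the ground, i.e. the contralateral foot's swing interval
  (contralateral toe-off to contralateral heel strike)

Cycle-level values are averaged per side and the two side means averaged with
equal weight to give the trial summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, ParseError, ValidationError
from .params import PARAMETERS

logger = logging.getLogger(__name__)

_EVENT_ARRAYS = ("hs_right", "hs_left", "to_right", "to_left")


@dataclass
class GaitEventSeries:
    """Timestamped, position-stamped foot-contact events for one trial.

    Positions are one-dimensional along the walking direction; on
    construction they are re-oriented (negated) if the net displacement is
    negative, so that forward progress is always positive.

    ``walk_duration`` and ``step_count`` default to the span and count of the
    heel-strike events when not supplied (e.g. when read from the event CSV,
    which carries neither).
    """

    subject_id: str
    rater_id: str
    system_id: str
    session_id: str
    hs_right: np.ndarray
    hs_left: np.ndarray
    to_right: np.ndarray
    to_left: np.ndarray
    x_hs_right: np.ndarray
    x_hs_left: np.ndarray
    walk_duration: float | None = None
    step_count: int | None = None

    def __post_init__(self) -> None:
        for name in (*_EVENT_ARRAYS, "x_hs_right", "x_hs_left"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self._orient_positions()
        if self.step_count is None:
            self.step_count = len(self.hs_right) + len(self.hs_left)
        if self.walk_duration is None:
            hs_all = np.concatenate([self.hs_right, self.hs_left])
            if hs_all.size >= 2:
                self.walk_duration = float(hs_all.max() - hs_all.min())
        self.validate()

    def _orient_positions(self) -> None:
        # Walking direction = sign of net heel-strike displacement.
        if (len(self.x_hs_right) != len(self.hs_right)
                or len(self.x_hs_left) != len(self.hs_left)):
            return  # length mismatch; validate() reports it
        xs = np.concatenate([self.x_hs_right, self.x_hs_left])
        ts = np.concatenate([self.hs_right, self.hs_left])
        if xs.size >= 2:
            order = np.argsort(ts)
            if xs[order][-1] < xs[order][0]:
                self.x_hs_right = -self.x_hs_right
                self.x_hs_left = -self.x_hs_left

    def validate(self) -> None:
        """Check structural invariants; raise :class:`ValidationError` on failure."""
        who = f"{self.subject_id}/{self.rater_id}/{self.system_id}/{self.session_id}"
        for name in _EVENT_ARRAYS:
            arr = getattr(self, name)
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValidationError(f"{who}: {name} times are not strictly increasing")
        if len(self.x_hs_right) != len(self.hs_right):
            raise ValidationError(f"{who}: x_hs_right length differs from hs_right")
        if len(self.x_hs_left) != len(self.hs_left):
            raise ValidationError(f"{who}: x_hs_left length differs from hs_left")
        for name in ("x_hs_right", "x_hs_left"):
            arr = getattr(self, name)
            if arr.size > 1 and np.any(np.diff(arr) < 0):
                raise ValidationError(f"{who}: {name} positions decrease along walking direction")
        if self.walk_duration is not None and self.walk_duration <= 0:
            raise ValidationError(f"{who}: walk_duration must be positive")
        self._check_interleaving("right", who)
        self._check_interleaving("left", who)

    def _sides(self, side: str):
        """(ref_hs, ref_x, ref_to, con_hs, con_x, con_to) for a reference side."""
        if side == "right":
            return (self.hs_right, self.x_hs_right, self.to_right,
                    self.hs_left, self.x_hs_left, self.to_left)
        if side == "left":
            return (self.hs_left, self.x_hs_left, self.to_left,
                    self.hs_right, self.x_hs_right, self.to_right)
        raise DomainError(f"unknown side {side!r}")

    def _check_interleaving(self, side: str, who: str) -> None:
        ref_hs, _, ref_to, con_hs, _, con_to = self._sides(side)
        for k in range(len(ref_hs) - 1):
            t0, t1 = ref_hs[k], ref_hs[k + 1]
            events = []
            for label, times in (("contralateral TO", con_to),
                                 ("contralateral HS", con_hs),
                                 ("reference TO", ref_to)):
                inside = times[(times > t0) & (times < t1)]
                if inside.size > 1:
                    raise ValidationError(
                        f"{who}: {side} cycle {k} contains {inside.size} {label} events")
                if inside.size == 1:
                    events.append((label, float(inside[0])))
            # Events that are present must appear in canonical order.
            observed = [t for _, t in events]
            if observed != sorted(observed):
                raise ValidationError(
                    f"{who}: {side} cycle {k} violates event interleaving "
                    f"(expected TO-contra < HS-contra < TO-ref within the cycle)")


@dataclass(frozen=True)
class CycleParameters:
    """Spatiotemporal parameters of one complete gait cycle."""

    side: str
    cycle_index: int
    gct: float
    stride_length: float
    step_length: float
    velocity: float
    stance_pct: float
    swing_pct: float
    single_support_pct: float


@dataclass(frozen=True)
class TrialSummary:
    """Per-trial parameter means (sides averaged with equal weight)."""

    subject_id: str
    rater_id: str
    system_id: str
    session_id: str
    cadence: float
    velocity: float
    stride_length: float
    step_length: float
    stance_pct: float
    swing_pct: float
    single_support_pct: float
    n_cycles_right: int
    n_cycles_left: int

    def parameter_values(self) -> dict[str, float]:
        return {p: getattr(self, p) for p in PARAMETERS}


def compute_cadence(series: GaitEventSeries) -> float:
    """Cadence in steps/min: ``60 * step_count / walk_duration``."""
    if series.walk_duration is None or series.walk_duration <= 0:
        raise DomainError("cadence requires a positive walk duration")
    if series.step_count is None or series.step_count < 2:
        raise DomainError("cadence requires at least 2 steps")
    return 60.0 * series.step_count / series.walk_duration


def extract_cycles(
    series: GaitEventSeries,
    sides: Sequence[str] = ("right", "left"),
    ss_formula: str = "corrected",
) -> list[CycleParameters]:
    """Compute per-cycle parameters for each complete cycle on each side.

    A cycle is half-open between consecutive same-side heel strikes
    (0-based index); incomplete terminal cycles are discarded.  Cycles
    missing a paired contralateral event are skipped with a warning.

    Parameters
    ----------
    ss_formula:
        ``"corrected"`` (default) computes single support as the
        contralateral swing interval, (HS_contra − TO_contra)/GCT.
        ``"printed"`` uses (HS_ref(k) − TO_contra(k))/GCT, which is negative
        under the canonical interleaving; retained for auditing only.
    """
    if ss_formula not in ("corrected", "printed"):
        raise DomainError(f"unknown ss_formula {ss_formula!r}")
    out: list[CycleParameters] = []
    for side in sides:
        ref_hs, ref_x, ref_to, con_hs, con_x, con_to = series._sides(side)
        if len(ref_hs) < 2:
            continue  # empty-result signal for this side
        for k in range(len(ref_hs) - 1):
            t0, t1 = ref_hs[k], ref_hs[k + 1]
            gct = t1 - t0

            def _inside(times):
                idx = np.nonzero((times > t0) & (times < t1))[0]
                return int(idx[0]) if idx.size else None

            i_ref_to = _inside(ref_to)
            i_con_to = _inside(con_to)
            i_con_hs = _inside(con_hs)
            if i_ref_to is None or i_con_to is None or i_con_hs is None:
                logger.warning("skipping %s cycle %d: missing paired events", side, k)
                continue
            stride = ref_x[k + 1] - ref_x[k]
            step = ref_x[k + 1] - con_x[i_con_hs]
            stance = (ref_to[i_ref_to] - t0) / gct * 100.0
            swing = 100.0 - stance  # exact partition of the cycle
            if ss_formula == "corrected":
                ss = (con_hs[i_con_hs] - con_to[i_con_to]) / gct * 100.0
            else:
                ss = (t0 - con_to[i_con_to]) / gct * 100.0
            if gct <= 0 or stride <= 0 or step <= 0:
                logger.warning("skipping %s cycle %d: non-positive length/time", side, k)
                continue
            out.append(CycleParameters(
                side=side, cycle_index=k, gct=float(gct),
                stride_length=float(stride), step_length=float(step),
                velocity=float(stride / gct), stance_pct=float(stance),
                swing_pct=float(swing), single_support_pct=float(ss)))
    return out


def summarize_trial(series: GaitEventSeries, ss_formula: str = "corrected") -> TrialSummary:
    """Average per-cycle parameters per side, then across sides with equal weight."""
    cycles = extract_cycles(series, ss_formula=ss_formula)
    by_side = {"right": [c for c in cycles if c.side == "right"],
               "left": [c for c in cycles if c.side == "left"]}
    if not by_side["right"] and not by_side["left"]:
        raise DomainError("no complete gait cycle on either side")
    for side, cyc in by_side.items():
        if not cyc:
            logger.warning("no complete %s cycles; summary uses the other side only", side)

    def _side_mean(cyc: list[CycleParameters], attr: str) -> float:
        return float(np.mean([getattr(c, attr) for c in cyc]))

    means = {}
    for attr in ("velocity", "stride_length", "step_length",
                 "stance_pct", "swing_pct", "single_support_pct"):
        side_means = [_side_mean(cyc, attr) for cyc in by_side.values() if cyc]
        means[attr] = float(np.mean(side_means))
    return TrialSummary(
        subject_id=series.subject_id, rater_id=series.rater_id,
        system_id=series.system_id, session_id=series.session_id,
        cadence=compute_cadence(series), **means,
        n_cycles_right=len(by_side["right"]), n_cycles_left=len(by_side["left"]))


def summaries_to_frame(summaries: Iterable[TrialSummary]) -> pd.DataFrame:
    """Tabulate trial summaries, one row per (subject, rater, system, session)."""
    rows = []
    for s in summaries:
        rows.append({
            "subject": s.subject_id, "rater": s.rater_id,
            "system": s.system_id, "session": s.session_id,
            "cadence_steps_min": s.cadence, "velocity_m_s": s.velocity,
            "stride_length_m": s.stride_length, "step_length_m": s.step_length,
            "stance_pct": s.stance_pct, "swing_pct": s.swing_pct,
            "single_support_pct": s.single_support_pct,
            "n_cycles_right": s.n_cycles_right, "n_cycles_left": s.n_cycles_left,
        })
    return pd.DataFrame(rows)


_CSV_COLUMNS = ["subject", "rater", "system", "session",
                "event_type", "side", "time_s", "position_m"]


def read_events_csv(path) -> list[GaitEventSeries]:
    """Read an event CSV into one :class:`GaitEventSeries` per trial.

    Expected columns: subject, rater, system, session, event_type (HS|TO),
    side (R|L), time_s, position_m (required for HS rows, ignored for TO).
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface as a parse error
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in _CSV_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if "position_m" not in df.columns:
        df["position_m"] = np.nan
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        if row["event_type"] not in ("HS", "TO"):
            raise ParseError(f"{path} line {line}: event_type must be HS or TO")
        if row["side"] not in ("R", "L"):
            raise ParseError(f"{path} line {line}: side must be R or L")
        if not np.isfinite(row["time_s"]):
            raise ParseError(f"{path} line {line}: non-numeric time_s")
        if row["event_type"] == "HS" and not np.isfinite(row["position_m"]):
            raise ParseError(f"{path} line {line}: HS row requires position_m")

    series = []
    for (subj, rater, system, session), grp in df.groupby(
            ["subject", "rater", "system", "session"], sort=True):
        grp = grp.sort_values("time_s")

        def _sel(ev, side, col):
            m = (grp["event_type"] == ev) & (grp["side"] == side)
            return grp.loc[m, col].to_numpy(dtype=float)

        series.append(GaitEventSeries(
            subject_id=str(subj), rater_id=str(rater),
            system_id=str(system), session_id=str(session),
            hs_right=_sel("HS", "R", "time_s"), hs_left=_sel("HS", "L", "time_s"),
            to_right=_sel("TO", "R", "time_s"), to_left=_sel("TO", "L", "time_s"),
            x_hs_right=_sel("HS", "R", "position_m"),
            x_hs_left=_sel("HS", "L", "position_m")))
    return series


def write_events_csv(series: Iterable[GaitEventSeries], path) -> None:
    """Write event series in the dialect read by :func:`read_events_csv`."""
    rows = []
    for s in series:
        ids = dict(subject=s.subject_id, rater=s.rater_id,
                   system=s.system_id, session=s.session_id)
        for t, x in zip(s.hs_right, s.x_hs_right):
            rows.append({**ids, "event_type": "HS", "side": "R", "time_s": t, "position_m": x})
        for t, x in zip(s.hs_left, s.x_hs_left):
            rows.append({**ids, "event_type": "HS", "side": "L", "time_s": t, "position_m": x})
        for t in s.to_right:
            rows.append({**ids, "event_type": "TO", "side": "R", "time_s": t, "position_m": np.nan})
        for t in s.to_left:
            rows.append({**ids, "event_type": "TO", "side": "L", "time_s": t, "position_m": np.nan})
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
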