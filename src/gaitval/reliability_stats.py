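"""Intra- and inter-rater reliability: ICC, SEM and MDC from ANOVA mean squares.

Single-measure, absolute-agreement intraclass correlations are computed from
the classical mean-square decompositions:

* ICC(1,1), one-way random effects (same rater, repeated sessions):
  ``(MSB - MSW) / (MSB + (k1 - 1) MSW)``
* ICC(2,1), two-way random effects (raters as a random sample):
  ``(MSB - MSE) / (MSB + (k2 - 1) MSE + k2 (MSR - MSE) / n)``

where MSB, MSW, MSR, MSE are the between-subject, within-subject,
between-rater and residual mean squares.

The standard error of measurement is ``SEM = spread * sqrt(1 - ICC)`` with a
configurable definition of the spread (pooled SD by default), and the minimal
detectable change at 90% confidence uses the fixed constant
``MDC = SEM * 1.65 * sqrt(2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import DomainError, UndefinedResultError, ValidationError

#: 90%-confidence two-measurement multiplier, kept as the literal constant.
MDC_FACTOR = 1.65 * math.sqrt(2.0)

SPREAD_MODES = ("pooled_sd", "rms_of_values", "rms_of_differences")


@dataclass(frozen=True)
class AnovaSummary:
    """Mean squares of a balanced repeated-measures decomposition.

    One-way summaries carry ``msw``; two-way (subject x rater, no
    replication) summaries carry ``msr`` and ``mse``.
    """

    model: str  # "one_way" | "two_way"
    msb: float
    n_subjects: int
    k: int
    msw: float | None = None
    msr: float | None = None
    mse: float | None = None


@dataclass(frozen=True)
class ReliabilityResult:
    """ICC with band, SEM and MDC for one parameter.

    ``icc_ci`` uses the standard F-distribution constructions; the interval
    convention is flagged in ``icc_ci_note`` because no published reference
    values were available to verify it against.
    """

    parameter: str
    model: str
    icc: float
    icc_ci: tuple[float, float]
    sem: float
    mdc: float
    band: str
    n_subjects: int
    n_dropped: int = 0
    icc_ci_note: str = "F-based CI; convention unverified against source tables"


def _as_balanced_table(values, expected_k: int | None = None) -> np.ndarray:
    rows = [np.asarray(r, dtype=float) for r in values]
    if len(rows) < 2:
        raise DomainError("at least 2 subjects are required")
    k = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != k:
            raise ValidationError(f"unbalanced design: subject index {i} has {len(r)} "
                                  f"measurements, expected {k}")
    if k < 2:
        raise DomainError("at least 2 measurements per subject are required")
    if expected_k is not None and k != expected_k:
        raise ValidationError(f"expected {expected_k} measurements per subject, got {k}")
    return np.vstack(rows)


def anova_one_way(values: Sequence[Sequence[float]]) -> AnovaSummary:
    """One-way decomposition of a balanced subjects-by-measurements table.

    ``values`` is an n-subject sequence of k repeated measurements each.
    """
    tab = _as_balanced_table(values)
    if not np.all(np.isfinite(tab)):
        raise ValidationError("non-finite measurement in one-way table")
    n, k = tab.shape
    grand = tab.mean()
    subj_means = tab.mean(axis=1)
    ssb = k * np.sum((subj_means - grand) ** 2)
    ssw = np.sum((tab - subj_means[:, None]) ** 2)
    return AnovaSummary(model="one_way", msb=ssb / (n - 1),
                        msw=ssw / (n * (k - 1)), n_subjects=n, k=k)


def anova_two_way(values: Sequence[Sequence[float]]) -> AnovaSummary:
    """Two-way (subject x rater, no replication) decomposition of an n x k table."""
    tab = _as_balanced_table(values)
    n, k = tab.shape
    if not np.all(np.isfinite(tab)):
        bad = np.argwhere(~np.isfinite(tab))[0]
        raise ValidationError(f"missing cell at (subject index {bad[0]}, rater index {bad[1]})")
    grand = tab.mean()
    subj_means = tab.mean(axis=1)
    rater_means = tab.mean(axis=0)
    ssb = k * np.sum((subj_means - grand) ** 2)
    ssr = n * np.sum((rater_means - grand) ** 2)
    sse = np.sum((tab - subj_means[:, None] - rater_means[None, :] + grand) ** 2)
    return AnovaSummary(model="two_way", msb=ssb / (n - 1), msr=ssr / (k - 1),
                        mse=sse / ((n - 1) * (k - 1)), n_subjects=n, k=k)


def icc_1_1(a: AnovaSummary) -> float:
    """Single-measure one-way random-effects ICC."""
    if a.model != "one_way" or a.msw is None:
        raise DomainError("icc_1_1 requires a one-way ANOVA summary")
    denom = a.msb + (a.k - 1) * a.msw
    if denom == 0:
        raise UndefinedResultError("ICC(1,1) undefined: zero total variance")
    return (a.msb - a.msw) / denom


def icc_2_1(a: AnovaSummary) -> float:
    """Single-measure two-way random-effects ICC (absolute agreement)."""
    if a.model != "two_way" or a.mse is None or a.msr is None:
        raise DomainError("icc_2_1 requires a two-way ANOVA summary")
    denom = a.msb + (a.k - 1) * a.mse + a.k * (a.msr - a.mse) / a.n_subjects
    if denom == 0:
        raise UndefinedResultError("ICC(2,1) undefined: zero denominator")
    return (a.msb - a.mse) / denom


def icc_ci(a: AnovaSummary, alpha: float = 0.05) -> tuple[float, float]:
    """F-based confidence interval for the single-measure ICC.

    One-way uses the exact F pivot; two-way uses the Satterthwaite
    approximation standard for absolute-agreement single measures.  The
    interval is clipped to [-1, 1].
    """
    n, k = a.n_subjects, a.k
    if a.model == "one_way":
        if a.msw == 0:
            return (1.0, 1.0)
        f_obs = a.msb / a.msw
        df1, df2 = n - 1, n * (k - 1)
        f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (f_l - 1) / (f_l + k - 1)
        hi = (f_u - 1) / (f_u + k - 1)
    else:
        icc = icc_2_1(a)
        msr, mse, msb = a.msr, a.mse, a.msb
        if mse == 0 and msr == 0:
            return (1.0, 1.0)
        a_coef = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
        b_coef = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
        if not np.isfinite(a_coef):
            return (1.0, 1.0)
        num = (a_coef * msr + b_coef * mse) ** 2
        den = ((a_coef * msr) ** 2 / (k - 1)
               + (b_coef * mse) ** 2 / ((n - 1) * (k - 1)))
        v = num / den if den > 0 else 1.0
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = (n * (msb - f_l * mse)
              / (f_l * (k * msr + (k * n - k - n) * mse) + n * msb))
        hi = (n * (f_u * msb - mse)
              / (k * msr + (k * n - k - n) * mse + n * f_u * msb))
    return (float(np.clip(lo, -1.0, 1.0)), float(np.clip(hi, -1.0, 1.0)))


def spread_measure(session_values: Sequence[Sequence[float]],
                   mode: str = "pooled_sd") -> float:
    """Measurement spread feeding the SEM, per the configured convention.

    ``session_values`` is the same n x k table the ANOVA sees.

    * ``pooled_sd`` — square root of the mean per-session sample variance
      (the conventional SEM spread).
    * ``rms_of_values`` — root mean square of all raw values.
    * ``rms_of_differences`` — RMS of session-2 minus session-1 differences
      (k = 2 only).
    """
    tab = _as_balanced_table(session_values)
    if mode == "pooled_sd":
        return float(np.sqrt(np.mean(np.var(tab, axis=0, ddof=1))))
    if mode == "rms_of_values":
        return float(np.sqrt(np.mean(tab ** 2)))
    if mode == "rms_of_differences":
        if tab.shape[1] != 2:
            raise DomainError("rms_of_differences requires exactly 2 sessions")
        d = tab[:, 1] - tab[:, 0]
        return float(np.sqrt(np.mean(d ** 2)))
    raise DomainError(f"unknown spread mode {mode!r}; choose from {SPREAD_MODES}")


def sem(spread: float, icc: float) -> float:
    """Standard error of measurement, ``spread * sqrt(1 - ICC)``."""
    if spread < 0:
        raise DomainError("spread must be non-negative")
    if icc > 1:
        raise DomainError("ICC cannot exceed 1")
    return spread * math.sqrt(1.0 - icc)


def mdc(sem_value: float) -> float:
    """Minimal detectable change at 90% confidence, ``SEM * 1.65 * sqrt(2)``."""
    if sem_value < 0:
        raise DomainError("SEM must be non-negative")
    return sem_value * MDC_FACTOR


def classify_icc(icc: float) -> str:
    """Qualitative ICC band: poor / moderate / good / excellent.

    Boundaries: < 0.40 poor; [0.40, 0.75] moderate; (0.75, 0.90) good;
    >= 0.90 excellent.
    """
    if icc > 1:
        raise DomainError("ICC cannot exceed 1")
    if icc < 0.40:
        return "poor"
    if icc <= 0.75:
        return "moderate"
    if icc < 0.90:
        return "good"
    return "excellent"
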