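"""Concurrent-validity battery for two-system method comparison.

For each gait parameter the test system (y) is compared against the
reference system (x) on paired per-subject values with:

* a normality-gated paired test — Shapiro-Wilk on the differences decides
  between the paired t-test and the Wilcoxon signed-rank test;
* Spearman rank correlation with a qualitative band;
* Passing-Bablok regression in its simplified form: the slope is the median
  of all pairwise slopes ``m_ij = (y_j - y_i) / (x_j - x_i)`` (x_i != x_j),
  with the 95% CI taken from rank indices
  ``L = round((N - C_alpha)/2)``, ``U = round((N + C_alpha)/2)`` into the
  ascending slopes, ``C_alpha = 1.96 * sqrt(n (n-1) (2n-5) / 18)``; the
  intercept is ``q = median(y_i - m x_i)`` with CI endpoints computed from
  the slope CI endpoints.  The classical variant (offset K for slopes below
  -1, slopes equal to -1 excluded) is available via ``variant="classical"``;
* Bland-Altman analysis: bias = mean(y - x), limits of agreement
  ``bias +/- 1.96 SD``, bias CI ``bias +/- 1.96 SD / sqrt(n)`` (normal
  quantile as a fixed constant, sample SD with n-1 denominator);
* a systematic-error verdict: constant error when 0 lies outside the bias CI
  or outside the intercept CI; proportional error when 1 lies outside the
  slope CI; "agreement" iff neither fires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import DomainError, UndefinedResultError

ALPHA = 0.05  # fixed study-wide uncertainty level
Z95 = 1.96    # fixed normal quantile, used as a literal constant throughout


@dataclass(frozen=True)
class PBResult:
    """Passing-Bablok slope/intercept with rank-based 95% CIs."""

    m: float
    m_ci: tuple[float, float]
    q: float
    q_ci: tuple[float, float]
    n_pairs: int
    n_valid_slopes: int
    c_alpha: float
    proportional_error: bool
    constant_error: bool


@dataclass(frozen=True)
class BAResult:
    """Bland-Altman bias, bias CI and limits of agreement."""

    bias: float
    sd_bias: float
    bias_ci: tuple[float, float]
    loa: tuple[float, float]
    n: int


@dataclass(frozen=True)
class PairedTestResult:
    test_name: str  # "paired_t" | "wilcoxon" | "degenerate"
    p_value: float
    shapiro_p: float | None
    degenerate: bool = False


@dataclass(frozen=True)
class ValidityReport:
    """Full concurrent-validity result for one parameter."""

    parameter: str
    test: PairedTestResult
    spearman_r: float
    correlation_band: str
    pb: PBResult
    ba: BAResult
    agreement: str  # "agreement" | "no_agreement"
    error_type: str  # "none" | "constant" | "proportional" | "constant+proportional"
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    n: int


def _paired(x, y, min_n: int = 2) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-D arrays of equal length")
    if len(x) < min_n:
        raise DomainError(f"at least {min_n} pairs are required")
    return x, y


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman correlation: Pearson correlation of average-ranked values."""
    x, y = _paired(x, y, min_n=3)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedResultError("Spearman undefined: zero rank variance")
    r = stats.spearmanr(x, y).statistic
    return float(r)


def classify_correlation(r: float) -> str:
    """Qualitative band of |r|: weak / moderate / strong / very strong.

    Cut points 0.25 / 0.55 / 0.75 (band gaps in the conventional scale are
    closed at their midpoints).
    """
    a = abs(r)
    if a > 1:
        raise DomainError("|r| cannot exceed 1")
    if a <= 0.25:
        return "weak"
    if a <= 0.55:
        return "moderate"
    if a <= 0.75:
        return "strong"
    return "very strong"


def paired_test(x: Sequence[float], y: Sequence[float],
                alpha: float = ALPHA) -> PairedTestResult:
    """Two-tailed paired comparison with a Shapiro-Wilk normality gate.

    Normal differences -> paired t-test; non-normal -> Wilcoxon signed-rank.
    All-zero differences short-circuit to p = 1 with a degenerate flag.
    """
    x, y = _paired(x, y, min_n=3)
    d = y - x
    if np.all(d == 0):
        return PairedTestResult("degenerate", 1.0, None, degenerate=True)
    if np.ptp(d) == 0:
        # Constant non-zero shift: Shapiro is undefined; treat as non-normal.
        p = float(stats.wilcoxon(d, zero_method="wilcox").pvalue)
        return PairedTestResult("wilcoxon", p, None)
    shapiro_p = float(stats.shapiro(d).pvalue)
    if shapiro_p >= alpha:
        p = float(stats.ttest_rel(y, x).pvalue)
        return PairedTestResult("paired_t", p, shapiro_p)
    p = float(stats.wilcoxon(d, zero_method="wilcox").pvalue)
    return PairedTestResult("wilcoxon", p, shapiro_p)


def _round_half_away(v: float) -> int:
    return int(math.floor(v + 0.5))


def pb_fit(x: Sequence[float], y: Sequence[float],
           variant: str = "simplified") -> PBResult:
    """Passing-Bablok regression of test values y on reference values x.

    ``variant="simplified"`` implements the plain pairwise-slope-median form
    described in the module docstring; ``"classical"`` applies the original
    offset correction K (slopes below -1 shift the median and CI ranks;
    slopes equal to -1 are excluded).
    """
    if variant not in ("simplified", "classical"):
        raise DomainError(f"unknown variant {variant!r}")
    x, y = _paired(x, y, min_n=5)
    if np.ptp(x) == 0:
        raise DomainError("Passing-Bablok requires non-identical x values")
    n = len(x)
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    iu = np.triu_indices(n, k=1)
    dx, dy = dx[iu], dy[iu]
    valid = dx != 0
    slopes = dy[valid] / dx[valid]
    if variant == "classical":
        slopes = slopes[slopes != -1.0]
    n_valid = len(slopes)
    if n_valid == 0:
        raise DomainError("no valid pairwise slopes")
    slopes = np.sort(slopes)
    c_alpha = Z95 * math.sqrt(n * (n - 1) * (2 * n - 5) / 18.0)

    if variant == "classical":
        k_off = int(np.sum(slopes < -1.0))
        # Offset median over the valid slopes.
        mid = n_valid + 2 * k_off
        if mid % 2:
            m = slopes[np.clip((mid - 1) // 2, 0, n_valid - 1)]
        else:
            i1 = np.clip(mid // 2 - 1, 0, n_valid - 1)
            i2 = np.clip(mid // 2, 0, n_valid - 1)
            m = 0.5 * (slopes[i1] + slopes[i2])
        lo_rank = _round_half_away((n_valid - c_alpha) / 2.0) + k_off
        hi_rank = n_valid - _round_half_away((n_valid - c_alpha) / 2.0) + 1 + k_off
    else:
        m = float(np.median(slopes))
        lo_rank = _round_half_away((n_valid - c_alpha) / 2.0)
        hi_rank = _round_half_away((n_valid + c_alpha) / 2.0)

    lo_rank = int(np.clip(lo_rank, 1, n_valid))
    hi_rank = int(np.clip(hi_rank, 1, n_valid))
    m_lo = float(slopes[lo_rank - 1])
    m_hi = float(slopes[hi_rank - 1])

    q = float(np.median(y - m * x))
    q_lo = float(np.median(y - m_lo * x))
    q_hi = float(np.median(y - m_hi * x))
    q_ci = tuple(sorted((q_lo, q_hi)))

    proportional = not (m_lo <= 1.0 <= m_hi)
    constant = not (q_ci[0] <= 0.0 <= q_ci[1])
    return PBResult(m=float(m), m_ci=(m_lo, m_hi), q=q, q_ci=q_ci,
                    n_pairs=n, n_valid_slopes=n_valid, c_alpha=c_alpha,
                    proportional_error=proportional, constant_error=constant)


def ba_fit(x: Sequence[float], y: Sequence[float]) -> BAResult:
    """Bland-Altman analysis of the differences y - x."""
    x, y = _paired(x, y, min_n=2)
    d = y - x
    n = len(d)
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    half_loa = Z95 * sd
    half_ci = Z95 * sd / math.sqrt(n)
    return BAResult(bias=bias, sd_bias=sd,
                    bias_ci=(bias - half_ci, bias + half_ci),
                    loa=(bias - half_loa, bias + half_loa), n=n)


def ba_coordinates(x: Sequence[float], y: Sequence[float]) -> np.ndarray:
    """Difference-vs-mean pairs for an external Bland-Altman plot (n x 2)."""
    x, y = _paired(x, y, min_n=2)
    return np.column_stack([(x + y) / 2.0, y - x])


def agreement_verdict(pb: PBResult, ba: BAResult) -> tuple[str, str]:
    """Combine PB and BA evidence into (agreement, error_type).

    Constant systematic error: 0 outside the BA bias CI or outside the PB
    intercept CI.  Proportional systematic error: 1 outside the PB slope CI.
    """
    constant = pb.constant_error or not (ba.bias_ci[0] <= 0.0 <= ba.bias_ci[1])
    proportional = pb.proportional_error
    kinds = [k for k, flag in (("constant", constant),
                               ("proportional", proportional)) if flag]
    if kinds:
        return "no_agreement", "+".join(kinds)
    return "agreement", "none"


def validity_report(parameter: str, x: Sequence[float], y: Sequence[float],
                    alpha: float = ALPHA,
                    pb_variant: str = "simplified") -> ValidityReport:
    """Run the full validity battery for one parameter (x = reference, y = test)."""
    x, y = _paired(x, y, min_n=5)
    test = paired_test(x, y, alpha=alpha)
    try:
        r = spearman(x, y)
    except UndefinedResultError:
        r = float("nan")
    band = classify_correlation(r) if np.isfinite(r) else "undefined"
    pb = pb_fit(x, y, variant=pb_variant)
    ba = ba_fit(x, y)
    agreement, error_type = agreement_verdict(pb, ba)
    return ValidityReport(
        parameter=parameter, test=test, spearman_r=r, correlation_band=band,
        pb=pb, ba=ba, agreement=agreement, error_type=error_type,
        mean_x=float(np.mean(x)), sd_x=float(np.std(x, ddof=1)),
        mean_y=float(np.mean(y)), sd_y=float(np.std(y, ddof=1)), n=len(x))
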