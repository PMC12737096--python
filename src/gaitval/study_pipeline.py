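"""Orchestration of the full validation analysis from a measurement table.

The measurement table is long-format — one row per (subject, rater, system,
session, parameter) — and feeds three analyses:

* intra-rater reliability: per system and rater, ICC(1,1) over the repeated
  sessions, SEM, MDC, and Bland-Altman of session 1 vs session 2;
* inter-rater reliability: per system, sessions averaged within rater, then
  ICC(2,1) across raters with SEM, MDC and rater-A-vs-rater-B Bland-Altman;
* concurrent validity: per parameter, subject-level means per system
  (all raters and sessions averaged), then the paired test, Spearman
  correlation, Passing-Bablok regression, Bland-Altman analysis and the
  systematic-error verdict.

Subjects with incomplete required cells are dropped per analysis and counted,
so every reported n is the number of complete subjects actually used.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import agreement_stats as ag
from . import reliability_stats as rel
from .exceptions import DomainError, ValidationError
from .params import LABELS, PARAMETERS

logger = logging.getLogger(__name__)

TABLE_COLUMNS = ["subject", "rater", "system", "session", "parameter", "value"]


def read_measurement_csv(path) -> pd.DataFrame:
    """Read and validate a long-format measurement table."""
    df = pd.read_csv(path, dtype={"subject": str, "rater": str,
                                  "system": str, "session": str})
    return validate_measurement_table(df)


def validate_measurement_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"measurement table missing columns {missing}")
    unknown = set(df["parameter"]) - set(PARAMETERS)
    if unknown:
        raise ValidationError(f"unknown parameter names {sorted(unknown)}")
    keys = df[TABLE_COLUMNS[:5]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].tolist()
        raise ValidationError(f"duplicate measurement cell {dup}")
    return df


@dataclass(frozen=True)
class ReliabilitySection:
    """Reliability results for one (system, analysis) combination."""

    system: str
    analysis: str  # "intra_rater" | "inter_rater"
    rater: str | None
    results: dict[str, rel.ReliabilityResult]
    ba: dict[str, ag.BAResult]
    means: dict[str, tuple[tuple[float, float], tuple[float, float]]]
    n_subjects: int
    n_dropped: int


@dataclass(frozen=True)
class StudyReport:
    intra_rater: list[ReliabilitySection]
    inter_rater: list[ReliabilitySection]
    validity: dict[str, ag.ValidityReport]
    provenance: dict


def _pivot_complete(sub: pd.DataFrame, columns: str) -> tuple[pd.DataFrame, int]:
    """Pivot subject x <columns> for one parameter; drop incomplete subjects."""
    wide = sub.pivot_table(index="subject", columns=columns, values="value",
                           aggfunc="mean")
    complete = wide.dropna()
    return complete, len(wide) - len(complete)


def run_intra_rater(table: pd.DataFrame, system: str, rater: str,
                    sem_spread: str = "pooled_sd") -> ReliabilitySection:
    """One-way test-retest reliability across sessions for one system and rater."""
    sub = table[(table["system"] == system) & (table["rater"] == rater)]
    if sub.empty:
        raise DomainError(f"no measurements for system={system!r} rater={rater!r}")
    results, ba, means = {}, {}, {}
    n_used = n_dropped = 0
    for p in PARAMETERS:
        wide, dropped = _pivot_complete(sub[sub["parameter"] == p], "session")
        if len(wide) < 2:
            raise DomainError(f"{p}: fewer than 2 complete subjects")
        if dropped:
            logger.warning("%s intra-rater %s/%s: dropped %d incomplete subject(s)",
                           p, system, rater, dropped)
        tab = wide.to_numpy()
        a = rel.anova_one_way(tab)
        icc = rel.icc_1_1(a)
        s = rel.sem(rel.spread_measure(tab, sem_spread), icc)
        results[p] = rel.ReliabilityResult(
            parameter=p, model="one_way", icc=icc, icc_ci=rel.icc_ci(a),
            sem=s, mdc=rel.mdc(s), band=rel.classify_icc(icc),
            n_subjects=len(wide), n_dropped=dropped)
        ba[p] = ag.ba_fit(tab[:, 0], tab[:, 1])
        means[p] = ((float(tab[:, 0].mean()), float(np.std(tab[:, 0], ddof=1))),
                    (float(tab[:, 1].mean()), float(np.std(tab[:, 1], ddof=1))))
        n_used, n_dropped = len(wide), dropped
    return ReliabilitySection(system=system, analysis="intra_rater", rater=rater,
                              results=results, ba=ba, means=means,
                              n_subjects=n_used, n_dropped=n_dropped)


def run_inter_rater(table: pd.DataFrame, system: str,
                    sem_spread: str = "pooled_sd") -> ReliabilitySection:
    """Two-way inter-rater reliability for one system (sessions averaged first)."""
    sub = table[table["system"] == system]
    if sub.empty:
        raise DomainError(f"no measurements for system={system!r}")
    results, ba, means = {}, {}, {}
    n_used = n_dropped = 0
    for p in PARAMETERS:
        wide, dropped = _pivot_complete(sub[sub["parameter"] == p], "rater")
        if len(wide) < 2:
            raise DomainError(f"{p}: fewer than 2 complete subjects")
        if dropped:
            logger.warning("%s inter-rater %s: dropped %d incomplete subject(s)",
                           p, system, dropped)
        tab = wide.to_numpy()
        a = rel.anova_two_way(tab)
        icc = rel.icc_2_1(a)
        s = rel.sem(rel.spread_measure(tab, sem_spread), icc)
        results[p] = rel.ReliabilityResult(
            parameter=p, model="two_way", icc=icc, icc_ci=rel.icc_ci(a),
            sem=s, mdc=rel.mdc(s), band=rel.classify_icc(icc),
            n_subjects=len(wide), n_dropped=dropped)
        ba[p] = ag.ba_fit(tab[:, 0], tab[:, 1])
        means[p] = ((float(tab[:, 0].mean()), float(np.std(tab[:, 0], ddof=1))),
                    (float(tab[:, 1].mean()), float(np.std(tab[:, 1], ddof=1))))
        n_used, n_dropped = len(wide), dropped
    return ReliabilitySection(system=system, analysis="inter_rater", rater=None,
                              results=results, ba=ba, means=means,
                              n_subjects=n_used, n_dropped=n_dropped)


def run_validity(table: pd.DataFrame, test_system: str, reference_system: str,
                 pairing: str = "averaged") -> dict[str, ag.ValidityReport]:
    """Concurrent validity of the test system against the reference.

    ``pairing="averaged"`` (default) averages each subject's available trials
    per system before pairing; ``pairing="session:<rater>/<session>"`` pairs a
    single rater/session combination instead.
    """
    reports = {}
    for p in PARAMETERS:
        sub = table[table["parameter"] == p]
        if pairing.startswith("session:"):
            rater, session = pairing.removeprefix("session:").split("/")
            sub = sub[(sub["rater"] == rater) & (sub["session"] == session)]
        elif pairing != "averaged":
            raise DomainError(f"unknown pairing {pairing!r}")
        wide, dropped = _pivot_complete(sub, "system")
        for sysid in (test_system, reference_system):
            if sysid not in wide.columns:
                raise DomainError(f"{p}: no measurements for system {sysid!r}")
        wide = wide[[reference_system, test_system]].dropna()
        if len(wide) < 5:
            raise DomainError(f"{p}: fewer than 5 complete subjects for validity")
        if dropped:
            logger.warning("%s validity: dropped %d incomplete subject(s)", p, dropped)
        reports[p] = ag.validity_report(
            p, wide[reference_system].to_numpy(), wide[test_system].to_numpy())
    return reports


def run_study(table: pd.DataFrame, test_system: str, reference_system: str,
              raters: Mapping[str, str] | None = None,
              sem_spread: str = "pooled_sd",
              provenance: dict | None = None) -> StudyReport:
    """Run the complete analysis battery on a measurement table.

    ``raters`` maps system id to the rater whose sessions feed that system's
    intra-rater analysis; by default every rater present is analysed.
    """
    table = validate_measurement_table(table)
    systems = [test_system, reference_system]
    intra = []
    for system in systems:
        rlist = ([raters[system]] if raters and system in raters
                 else sorted(table.loc[table["system"] == system, "rater"].unique()))
        for rater in rlist:
            intra.append(run_intra_rater(table, system, rater, sem_spread))
    inter = [run_inter_rater(table, system, sem_spread) for system in systems]
    validity = run_validity(table, test_system, reference_system)
    prov = dict(provenance or {})
    prov.update({
        "test_system": test_system, "reference_system": reference_system,
        "n_rows": int(len(table)),
        "table_sha256": hashlib.sha256(
            table.sort_values(TABLE_COLUMNS[:5]).to_csv(index=False).encode()
        ).hexdigest(),
        "inclusion": {
            "validity_n": int(min(r.n for r in validity.values())),
            "intra_n": [s.n_subjects for s in intra],
            "inter_n": [s.n_subjects for s in inter],
        },
    })
    return StudyReport(intra_rater=intra, inter_rater=inter,
                       validity=validity, provenance=prov)


# ---------------------------------------------------------------------------
# Report rendering


def _reliability_frame(section: ReliabilitySection) -> pd.DataFrame:
    rows = []
    for p in PARAMETERS:
        r, b = section.results[p], section.ba[p]
        (m1, s1), (m2, s2) = section.means[p]
        rows.append({
            "parameter": LABELS[p],
            "mean_sd_1": f"{m1:.2f} ± {s1:.2f}",
            "mean_sd_2": f"{m2:.2f} ± {s2:.2f}",
            "icc": r.icc, "icc_ci_low": r.icc_ci[0], "icc_ci_high": r.icc_ci[1],
            "sem": r.sem, "mdc": r.mdc,
            "bias": b.bias, "bias_ci_low": b.bias_ci[0], "bias_ci_high": b.bias_ci[1],
            "loa_low": b.loa[0], "loa_high": b.loa[1],
            "band": r.band, "n": r.n_subjects,
        })
    return pd.DataFrame(rows)


def _validity_frames(validity: dict[str, ag.ValidityReport]
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    desc_rows, reg_rows, verdict_rows = [], [], []
    for p in PARAMETERS:
        v = validity[p]
        desc_rows.append({
            "parameter": LABELS[p],
            "test_mean_sd": f"{v.mean_y:.2f} ± {v.sd_y:.2f}",
            "reference_mean_sd": f"{v.mean_x:.2f} ± {v.sd_x:.2f}",
            "test_name": v.test.test_name,
            "p_value": "<0.001" if v.test.p_value < 0.001 else f"{v.test.p_value:.3f}",
            "p_value_raw": v.test.p_value,
            "spearman_r": v.spearman_r, "correlation_band": v.correlation_band,
        })
        reg_rows.append({
            "parameter": LABELS[p],
            "m": v.pb.m, "m_ci_low": v.pb.m_ci[0], "m_ci_high": v.pb.m_ci[1],
            "q": v.pb.q, "q_ci_low": v.pb.q_ci[0], "q_ci_high": v.pb.q_ci[1],
            "bias": v.ba.bias, "bias_ci_low": v.ba.bias_ci[0],
            "bias_ci_high": v.ba.bias_ci[1],
            "loa_low": v.ba.loa[0], "loa_high": v.ba.loa[1], "n": v.n,
        })
        verdict_rows.append({
            "parameter": LABELS[p],
            "agreement": "Agreement" if v.agreement == "agreement" else "No Agreement",
            "error_type": v.error_type,
        })
    return (pd.DataFrame(desc_rows), pd.DataFrame(reg_rows),
            pd.DataFrame(verdict_rows))


def _write_rounded(df: pd.DataFrame, path: Path) -> None:
    # Display CSV rounded to 2 decimals; full precision goes to the companion.
    df.round(2).to_csv(path, index=False)
    df.to_csv(path.with_name(path.stem + "_full.csv"), index=False)


def render_report(report: StudyReport, outdir) -> list[Path]:
    """Write the report tables as CSV files and a JSON run log; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for section in report.intra_rater:
        name = f"intra_rater_{section.system}_rater_{section.rater}.csv"
        _write_rounded(_reliability_frame(section), outdir / name)
        written.append(outdir / name)
    for section in report.inter_rater:
        name = f"inter_rater_{section.system}.csv"
        _write_rounded(_reliability_frame(section), outdir / name)
        written.append(outdir / name)

    bands = pd.DataFrame(
        [{"parameter": LABELS[p],
          **{f"{s.analysis}_{s.system}" + (f"_rater_{s.rater}" if s.rater else ""):
             s.results[p].band
             for s in (*report.intra_rater, *report.inter_rater)}}
         for p in PARAMETERS])
    bands.to_csv(outdir / "reliability_bands.csv", index=False)
    written.append(outdir / "reliability_bands.csv")

    desc, reg, verdicts = _validity_frames(report.validity)
    _write_rounded(desc.drop(columns=["p_value_raw"]), outdir / "validity_tests.csv")
    (outdir / "validity_tests_full.csv").write_text(desc.to_csv(index=False))
    _write_rounded(reg, outdir / "validity_regression.csv")
    verdicts.to_csv(outdir / "validity_verdicts.csv", index=False)
    written += [outdir / "validity_tests.csv", outdir / "validity_regression.csv",
                outdir / "validity_verdicts.csv"]

    with open(outdir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(report.provenance, fh, indent=2, sort_keys=True)
    written.append(outdir / "run_log.json")
    return written


def export_ba_coordinates(table: pd.DataFrame, test_system: str,
                          reference_system: str, outdir) -> list[Path]:
    """Per-parameter difference-vs-mean coordinates for external BA plotting."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for p in PARAMETERS:
        sub = table[table["parameter"] == p]
        wide, _ = _pivot_complete(sub, "system")
        wide = wide[[reference_system, test_system]].dropna()
        coords = ag.ba_coordinates(wide[reference_system].to_numpy(),
                                   wide[test_system].to_numpy())
        out = outdir / f"ba_coordinates_{p}.csv"
        pd.DataFrame(coords, columns=["mean", "difference"]).to_csv(out, index=False)
        written.append(out)
    return written
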