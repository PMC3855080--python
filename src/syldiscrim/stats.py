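"""Relative Threshold Index transform and the cohort comparison pipeline.

The RTI rescales a raw discrimination threshold onto a unitless 0-1 axis,

    RTI = 1 - (threshold - reference) / range,

so that a threshold at the reference endpoint maps to 1 (best possible
discrimination) and one at the far endpoint maps to 0.  The /ba/-/da/
continuum spans 800-1600 Hz of F2 onset, /ba/-/wa/ 25-100 ms of transition
duration, and /ga/-/ka/ 0-50 ms of VOT.

The group analysis mirrors the study design: a 2x3 mixed ANOVA
(musicianship between subjects, continuum as the repeated measure) on the
RTIs, one-tailed two-sample t-tests per continuum (a priori direction:
musicians better), paired t-tests between continua, and Pearson
correlations of RTI with years and weekly hours of musical practice, with
Benjamini-Hochberg FDR control over each test family.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .continua import ContinuumSpec
from .synthesis import ParameterError

__all__ = [
    "RTIRecord",
    "StatsReport",
    "compute_rti",
    "bh_fdr",
    "cohort_analysis",
    "AnalysisError",
]


class AnalysisError(RuntimeError):
    pass


@dataclass(frozen=True)
class RTIRecord:
    participant_id: str
    group: str
    continuum: str
    raw_threshold: float
    rti: float


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    df: float
    p: float
    rejected: bool | None = None  # filled after FDR


@dataclass
class StatsReport:
    anova: pd.DataFrame
    pairwise_group: list[TestResult]
    paired_continua: list[TestResult]
    correlations: list[TestResult]
    fdr_q: float
    corrected_families: dict[str, list[str]]

    def to_json(self, path: str | Path | None = None) -> str:
        def _tests(ts):
            return [
                dict(name=t.name, statistic=t.statistic, df=t.df, p=t.p,
                     rejected=t.rejected)
                for t in ts
            ]

        payload = dict(
            anova=self.anova.to_dict(orient="records"),
            pairwise_group=_tests(self.pairwise_group),
            paired_continua=_tests(self.paired_continua),
            correlations=_tests(self.correlations),
            fdr_q=self.fdr_q,
            corrected_families=self.corrected_families,
        )
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        lines = ["2x3 mixed ANOVA (group x continuum):"]
        for _, row in self.anova.iterrows():
            lines.append(
                f"  {row['Source']}: F({row['DF1']:g}, {row['DF2']:g}) = "
                f"{row['F']:.2f}, p = {row['p_unc']:.4g}"
            )
        lines.append("Per-continuum group comparisons (one-tailed, musicians better):")
        for t in self.pairwise_group:
            flag = "*" if t.rejected else " "
            lines.append(f"  {t.name}: t({t.df:g}) = {t.statistic:.2f}, p = {t.p:.4g}{flag}")
        lines.append("Paired continuum contrasts:")
        for t in self.paired_continua:
            flag = "*" if t.rejected else " "
            lines.append(f"  {t.name}: t({t.df:g}) = {t.statistic:.2f}, p = {t.p:.4g}{flag}")
        lines.append("Practice correlations (Pearson):")
        for t in self.correlations:
            flag = "*" if t.rejected else " "
            lines.append(f"  {t.name}: r = {t.statistic:.2f}, p = {t.p:.4g}{flag}")
        lines.append("(* = significant after Benjamini-Hochberg FDR control)")
        return "\n".join(lines)


def compute_rti(continuum: ContinuumSpec, raw_threshold: float) -> float:
    """Map a raw threshold (native units) to the 0-1 index.

    Values outside the continuum range are clamped with a warning — the
    staircase cannot produce them, so they usually signal a unit mix-up.
    """
    lo, hi = continuum.reference_value, continuum.far_value
    if not lo <= raw_threshold <= hi:
        warnings.warn(
            f"threshold {raw_threshold} {continuum.unit} outside "
            f"[{lo}, {hi}] for {continuum.name}; clamping",
            stacklevel=2,
        )
        raw_threshold = min(max(raw_threshold, lo), hi)
    return 1.0 - (raw_threshold - lo) / (hi - lo)


def bh_fdr(p_values, q: float = 0.05) -> list[bool]:
    """Benjamini-Hochberg step-up decisions at level ``q``."""
    p = list(p_values)
    if not p:
        raise ParameterError("empty p-value list")
    if any(not 0 <= v <= 1 for v in p):
        raise ParameterError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return [bool(r) for r in reject]


def _mixed_anova(table: pd.DataFrame) -> pd.DataFrame:
    import pingouin as pg

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(
            data=table, dv="rti", within="continuum", subject="participant_id",
            between="group", correction="auto",
        )
    return aov


def cohort_analysis(
    rti_table: pd.DataFrame,
    q: float = 0.05,
    corrected_families: dict[str, list[str]] | None = None,
) -> StatsReport:
    """Run the full group comparison on a tidy RTI table.

    ``rti_table`` needs columns ``participant_id, group, continuum, rti``
    and, for the practice correlations, ``years`` and ``hours``.  The table
    must be balanced: every participant contributes every continuum.
    Which test families are jointly FDR-corrected is configurable; by
    default each family (group contrasts, paired contrasts, correlations)
    is corrected on its own.
    """
    required = {"participant_id", "group", "continuum", "rti"}
    missing = required - set(rti_table.columns)
    if missing:
        raise AnalysisError(f"missing columns: {sorted(missing)}")
    continua = sorted(rti_table["continuum"].unique())
    groups = sorted(rti_table["group"].unique())
    cell = rti_table.groupby(["participant_id", "continuum"]).size()
    if (cell != 1).any():
        bad = cell[cell != 1].index[0]
        raise AnalysisError(f"unbalanced cell {bad}: each participant needs one RTI per continuum")
    per_p = rti_table.groupby("participant_id")["continuum"].nunique()
    if (per_p != len(continua)).any():
        bad = per_p[per_p != len(continua)].index[0]
        raise AnalysisError(f"participant {bad} is missing a continuum")

    anova = _mixed_anova(rti_table) if len(continua) > 1 and len(groups) > 1 else None

    pairwise = []
    if len(groups) == 2:
        g1, g2 = "musician", "non-musician"
        for c in continua:
            a = rti_table.query("continuum == @c and group == @g1")["rti"]
            b = rti_table.query("continuum == @c and group == @g2")["rti"]
            t, p = sps.ttest_ind(a, b, alternative="greater")
            pairwise.append(
                TestResult(name=f"{c}: musician > non-musician",
                           statistic=float(t), df=len(a) + len(b) - 2, p=float(p))
            )

    paired = []
    wide = rti_table.pivot(index="participant_id", columns="continuum", values="rti")
    for i, c1 in enumerate(continua):
        for c2 in continua[i + 1 :]:
            t, p = sps.ttest_rel(wide[c1], wide[c2])
            paired.append(
                TestResult(name=f"{c1} vs {c2}", statistic=float(t),
                           df=len(wide) - 1, p=float(p))
            )

    correlations = []
    if {"years", "hours"} <= set(rti_table.columns):
        for c in continua:
            sub = rti_table.query("continuum == @c")
            for covar in ("years", "hours"):
                if sub[covar].nunique() > 1 and sub["rti"].nunique() > 1:
                    r, p = sps.pearsonr(sub[covar], sub["rti"])
                    if not (np.isfinite(r) and np.isfinite(p)):
                        continue
                    correlations.append(
                        TestResult(name=f"{c}: rti ~ {covar}", statistic=float(r),
                                   df=len(sub) - 2, p=float(p))
                    )

    families = corrected_families or {
        "pairwise_group": [t.name for t in pairwise],
        "paired_continua": [t.name for t in paired],
        "correlations": [t.name for t in correlations],
    }
    all_tests = {t.name: t for t in pairwise + paired + correlations}
    corrected: dict[str, TestResult] = {}
    for fam_tests in families.values():
        names = [n for n in fam_tests if n in all_tests]
        if not names:
            continue
        decisions = bh_fdr([all_tests[n].p for n in names], q=q)
        for n, d in zip(names, decisions):
            t = all_tests[n]
            corrected[n] = TestResult(t.name, t.statistic, t.df, t.p, rejected=d)
    final = lambda ts: [corrected.get(t.name, t) for t in ts]

    if anova is None:
        anova = pd.DataFrame(columns=["Source", "DF1", "DF2", "F", "p-unc"])
    return StatsReport(
        anova=anova,
        pairwise_group=final(pairwise),
        paired_continua=final(paired),
        correlations=final(correlations),
        fdr_q=q,
        corrected_families=families,
    )
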