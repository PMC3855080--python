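"""RTI transform, FDR control, and the cohort statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from syldiscrim import bh_fdr, cohort_analysis, compute_rti
from syldiscrim.stats import AnalysisError
from syldiscrim.synthesis import ParameterError


class TestRTI:
    def test_worked_examples(self, continua):
        # the published worked examples of the index
        assert compute_rti(continua["ba_da"], 1400.0) == pytest.approx(0.25)
        assert compute_rti(continua["ba_da"], 1000.0) == pytest.approx(0.75)

    def test_formula_endpoints(self, continua):
        assert compute_rti(continua["ga_ka"], 0.0) == 1.0
        assert compute_rti(continua["ga_ka"], 50.0) == 0.0

    def test_out_of_range_clamped_with_warning(self, continua):
        with pytest.warns(UserWarning):
            assert compute_rti(continua["ba_da"], 300.0) == 1.0
        with pytest.warns(UserWarning):
            assert compute_rti(continua["ba_wa"], 400.0) == 0.0

    def test_affine_and_order_reversing(self, continua, rng):
        c = continua["ba_wa"]
        raws = np.sort(rng.uniform(25.0, 100.0, size=20))
        rtis = [compute_rti(c, r) for r in raws]
        assert all(b < a for a, b in zip(rtis, rtis[1:]))
        # affine: equal raw increments give equal RTI decrements
        assert compute_rti(c, 50.0) - compute_rti(c, 60.0) == pytest.approx(
            compute_rti(c, 80.0) - compute_rti(c, 90.0)
        )


def _bh_oracle(ps, q):
    # hand-applied step-up: largest k with p_(k) <= k q / m survives
    m = len(ps)
    order = np.argsort(ps)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if ps[idx] <= rank * q / m:
            k_max = rank
    decisions = [False] * m
    for rank, idx in enumerate(order, start=1):
        if rank <= k_max:
            decisions[idx] = True
    return decisions


class TestFDR:
    def test_step_up_examples(self):
        # hand-applied step-up at q = 0.05, m = 3: thresholds are
        # 0.0167 / 0.0333 / 0.05 for the sorted p-values
        assert bh_fdr([0.001, 0.04, 0.2], q=0.05) == [True, False, False]
        assert bh_fdr([0.001, 0.03, 0.2], q=0.05) == [True, True, False]

    def test_all_ones_rejects_nothing(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == [False, False, False]

    def test_single_small_p_rejected(self):
        assert bh_fdr([0.01], q=0.05) == [True]

    def test_empty_and_invalid_inputs_rejected(self):
        with pytest.raises(ParameterError):
            bh_fdr([])
        with pytest.raises(ParameterError):
            bh_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=12))
    def test_matches_hand_applied_step_up(self, ps):
        assert bh_fdr(ps, q=0.05) == _bh_oracle(ps, 0.05)

    def test_decisions_monotone_in_p(self, rng):
        ps = list(rng.uniform(0, 1, size=10))
        decisions = dict(zip(ps, bh_fdr(ps)))
        rejected = [p for p, d in decisions.items() if d]
        kept = [p for p, d in decisions.items() if not d]
        if rejected and kept:
            assert max(rejected) < min(kept)


def _toy_table(rng, n=8, shift=None):
    shift = shift or {}
    rows = []
    for g_idx, group in enumerate(("musician", "non-musician")):
        for i in range(n):
            pid = f"{group[:3]}{i}"
            years = 12.0 + rng.normal(0, 2) if group == "musician" else rng.uniform(0, 3)
            for cont in ("ba_da", "ba_wa", "ga_ka"):
                mu = 0.55 + (shift.get(cont, 0.0) if group == "musician" else 0.0)
                rows.append(
                    dict(participant_id=pid, group=group, continuum=cont,
                         years=years, hours=10.0 if group == "musician" else 0.0,
                         rti=np.clip(mu + rng.normal(0, 0.1), 0, 1))
                )
    return pd.DataFrame(rows)


def _manual_mixed_anova(table):
    """Balanced two-way mixed-design ANOVA from cell means (oracle)."""
    wide = table.pivot(index="participant_id", columns="continuum", values="rti")
    groups = table.drop_duplicates("participant_id").set_index("participant_id")["group"]
    g_levels = sorted(groups.unique())
    c_levels = list(wide.columns)
    n = (groups == g_levels[0]).sum()
    a, b = len(g_levels), len(c_levels)
    gm = wide.values.mean()
    subj_means = wide.mean(axis=1)
    group_means = subj_means.groupby(groups).mean()
    cont_means = wide.mean(axis=0)
    cell_means = wide.groupby(groups).mean()

    ss_group = b * n * sum((group_means[g] - gm) ** 2 for g in g_levels)
    ss_subj = b * sum((subj_means[i] - group_means[groups[i]]) ** 2
                      for i in wide.index)
    ss_cont = a * n * sum((cont_means[c] - gm) ** 2 for c in c_levels)
    ss_inter = n * sum(
        (cell_means.loc[g, c] - group_means[g] - cont_means[c] + gm) ** 2
        for g in g_levels for c in c_levels
    )
    ss_err = sum(
        (wide.loc[i, c] - cell_means.loc[groups[i], c] - subj_means[i]
         + group_means[groups[i]]) ** 2
        for i in wide.index for c in c_levels
    )
    df_group, df_subj = a - 1, a * (n - 1)
    df_cont, df_inter = b - 1, (a - 1) * (b - 1)
    df_err = (b - 1) * a * (n - 1)
    return {
        "group": (ss_group / df_group) / (ss_subj / df_subj),
        "continuum": (ss_cont / df_cont) / (ss_err / df_err),
        "Interaction": (ss_inter / df_inter) / (ss_err / df_err),
    }


class TestCohortAnalysis:
    def test_anova_matches_sums_of_squares_oracle(self, rng):
        table = _toy_table(rng, n=10, shift={"ba_wa": 0.15})
        report = cohort_analysis(table)
        oracle = _manual_mixed_anova(table)
        for _, row in report.anova.iterrows():
            assert row["F"] == pytest.approx(oracle[row["Source"]], abs=1e-8)

    def test_group_effect_pattern_recovered(self, rng):
        table = _toy_table(rng, n=14, shift={"ba_wa": 0.18, "ga_ka": 0.12})
        report = cohort_analysis(table)
        by_name = {t.name: t for t in report.pairwise_group}
        assert by_name["ba_wa: musician > non-musician"].rejected
        assert by_name["ga_ka: musician > non-musician"].rejected
        assert not by_name["ba_da: musician > non-musician"].rejected

    def test_unbalanced_table_names_missing_cell(self, rng):
        table = _toy_table(rng, n=4).iloc[:-1]
        with pytest.raises(AnalysisError, match="missing a continuum"):
            cohort_analysis(table)

    def test_duplicate_cell_rejected(self, rng):
        table = _toy_table(rng, n=4)
        with pytest.raises(AnalysisError):
            cohort_analysis(pd.concat([table, table.iloc[[0]]]))

    def test_report_serializes(self, rng, tmp_path):
        import json

        table = _toy_table(rng, n=6)
        report = cohort_analysis(table)
        payload = json.loads(report.to_json(tmp_path / "stats.json"))
        assert set(payload) >= {"anova", "pairwise_group", "correlations"}
        assert report.summary().startswith("2x3 mixed ANOVA")
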