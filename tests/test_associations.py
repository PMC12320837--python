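"""Pathogen-burden, cytokine and covariate association statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ugityper.associations import (
    covariate_check,
    cytokine_correlation,
    group_compare,
    hacek_abundance,
)
from ugityper.contamination import benjamini_hochberg
from ugityper.core_tables import RelAbundanceTable, to_relative


class TestHacek:
    def test_summation_example(self):
        rel = RelAbundanceTable(
            pd.DataFrame(
                {"s": [0.02, 0.01, 0.0, 0.005, 0.0, 0.965]},
                index=[
                    "Haemophilus",
                    "Aggregatibacter",
                    "Cardiobacterium",
                    "Eikenella",
                    "Kingella",
                    "Prevotella 7",
                ],
            )
        )
        assert hacek_abundance(rel)["s"] == pytest.approx(0.035)

    def test_prefix_matching_tolerates_silva_suffixes(self):
        rel = RelAbundanceTable(
            pd.DataFrame(
                {"s": [0.01, 0.99]},
                index=["Haemophilus parainfluenzae group", "Other"],
            )
        )
        assert hacek_abundance(rel)["s"] == pytest.approx(0.01)

    def test_none_present_gives_zero(self):
        rel = RelAbundanceTable(pd.DataFrame({"s": [1.0]}, index=["Prevotella 7"]))
        assert hacek_abundance(rel)["s"] == 0.0

    def test_complement_sums_to_one(self, default_cohort):
        table, _, _ = default_cohort
        rel = to_relative(table, 0)
        h = hacek_abundance(rel)
        from ugityper.community_typing import cumulative_abundance

        non_hacek = [
            t
            for t in rel.taxa
            if not any(t.startswith(p) for p in ("Haemophilus", "Aggregatibacter", "Cardiobacterium", "Eikenella", "Kingella"))
        ]
        other = cumulative_abundance(rel, non_hacek)
        np.testing.assert_allclose(h + other, 1.0, atol=1e-9)


class TestGroupCompare:
    def test_forced_wilcoxon_exact_p(self):
        values = pd.Series([1, 2, 3, 10, 11, 12], index=[f"s{i}" for i in range(6)], dtype=float)
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=values.index)
        out = group_compare(values, groups, force_test="wilcoxon")
        assert out.p == pytest.approx(0.1, abs=1e-12)
        assert out.direction == "a<b"

    def test_identical_groups(self):
        values = pd.Series([1, 2, 3, 1, 2, 3], index=[f"s{i}" for i in range(6)], dtype=float)
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=values.index)
        out = group_compare(values, groups, force_test="wilcoxon")
        assert out.p > 0.9
        assert out.direction == "none"

    def test_normality_gate_picks_wilcoxon_for_skewed_data(self):
        rng = np.random.default_rng(0)
        values = pd.Series(
            np.concatenate([rng.lognormal(0, 2, 30), rng.lognormal(0, 2, 30)]),
            index=[f"s{i}" for i in range(60)],
        )
        groups = pd.Series(["a"] * 30 + ["b"] * 30, index=values.index)
        assert group_compare(values, groups).test == "wilcoxon"

    def test_normality_gate_picks_t_for_gaussian_data(self):
        rng = np.random.default_rng(0)
        values = pd.Series(
            rng.normal(0, 1, 60), index=[f"s{i}" for i in range(60)]
        )
        groups = pd.Series(["a"] * 30 + ["b"] * 30, index=values.index)
        assert group_compare(values, groups).test == "t"

    def test_wilcoxon_type_i_error_calibrated(self):
        rng = np.random.default_rng(2)
        rejections = 0
        reps = 400
        for _ in range(reps):
            values = pd.Series(
                rng.normal(size=20), index=[f"s{i}" for i in range(20)]
            )
            groups = pd.Series(["a"] * 10 + ["b"] * 10, index=values.index)
            if group_compare(values, groups, force_test="wilcoxon").p < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.025)

    def test_small_group_rejected(self):
        values = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("wxyz"))
        groups = pd.Series(["a", "a", "a", "b"], index=values.index)
        with pytest.raises(ValueError):
            group_compare(values, groups)


@settings(deadline=None, max_examples=40)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
def test_bh_monotone_and_never_below_raw(pvals):
    p = np.asarray(pvals)
    q = benjamini_hochberg(p)
    assert (q >= p - 1e-12).all()
    assert (q <= 1.0).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


class TestCytokineCorrelation:
    def test_strictly_decreasing_gives_minus_one(self):
        cum = pd.Series([0.1, 0.2, 0.3, 0.4, 0.5], index=list("abcde"))
        cyto = pd.Series([50, 40, 30, 20, 10], index=list("abcde"), dtype=float)
        rho, p = cytokine_correlation(cum, cyto)
        assert rho == pytest.approx(-1.0)

    def test_constant_cytokine_rejected(self):
        cum = pd.Series([0.1, 0.2, 0.3, 0.4, 0.5], index=list("abcde"))
        cyto = pd.Series([10.0] * 5, index=list("abcde"))
        with pytest.raises(ValueError, match="constant"):
            cytokine_correlation(cum, cyto)

    def test_missing_values_dropped_pairwise(self):
        cum = pd.Series([0.1, 0.2, 0.3, 0.4, 0.5, 0.6], index=list("abcdef"))
        cyto = pd.Series([60, 50, np.nan, 30, 20, 10], index=list("abcdef"))
        rho, _ = cytokine_correlation(cum, cyto)
        assert rho == pytest.approx(-1.0)

    def test_too_few_pairs_rejected(self):
        cum = pd.Series([0.1, 0.2], index=list("ab"))
        cyto = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(ValueError):
            cytokine_correlation(cum, cyto)

    def test_negative_slope_recovered_on_synthetic_cohort(self, default_cohort):
        table, meta, _ = default_cohort
        rel = to_relative(table, 0)
        from ugityper.community_typing import cumulative_abundance, reference_clusters

        ref = reference_clusters()
        m = meta.set_index("sample_id")
        duo = [s for s in rel.samples if m.loc[s, "location"] == "duodenum" and m.loc[s, "amplicon"] == "DNA"]
        cum = cumulative_abundance(RelAbundanceTable(rel.data[duo]), ref["Prevotella 7"])
        cum.index = [m.loc[s, "subject_id"] for s in cum.index]
        tnf = meta.drop_duplicates("subject_id").set_index("subject_id")["cytokine_TNFa"]
        rho, p = cytokine_correlation(cum, tnf)
        assert rho < 0 and p < 0.01


class TestCovariateCheck:
    def _subjects(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"subj{i}" for i in range(n)]
        cov = pd.DataFrame(
            {
                "sex": rng.choice(["F", "M"], n),
                "age": rng.integers(20, 75, n).astype(float),
            },
            index=idx,
        )
        types = pd.Series(rng.choice(["Prevotella7", "other"], n), index=idx)
        return types, cov

    def test_balanced_covariate_odds_ratio_near_one(self):
        idx = [f"s{i}" for i in range(40)]
        types = pd.Series(["Prevotella7", "other"] * 20, index=idx)
        cov = pd.DataFrame({"sex": ["F", "F", "M", "M"] * 10}, index=idx)
        out = covariate_check(types, cov).set_index("covariate")
        assert out.iloc[0]["odds_ratio"] == pytest.approx(1.0, abs=1e-4)

    def test_constant_covariate_dropped(self):
        types, cov = self._subjects()
        cov["site"] = "lübeck"
        out = covariate_check(types, cov)
        note = out.set_index("covariate").loc["site", "note"]
        assert "no variance" in note

    def test_complete_separation_flagged(self):
        idx = [f"s{i}" for i in range(20)]
        types = pd.Series(["Prevotella7"] * 10 + ["other"] * 10, index=idx)
        cov = pd.DataFrame({"marker": [1.0] * 10 + [0.0] * 10}, index=idx)
        out = covariate_check(types, cov)
        assert out["note"].str.contains("separation").any()

    def test_null_covariates_calibrated(self):
        rejections = 0
        reps = 150
        for seed in range(reps):
            types, cov = self._subjects(seed=seed)
            if types.nunique() < 2:
                continue
            out = covariate_check(types, cov)
            rejections += (out["p"].dropna() < 0.05).sum()
        n_tests = reps * 2
        assert rejections / n_tests == pytest.approx(0.05, abs=0.03)


def test_hacek_burden_lower_in_p7_typed_samples(default_cohort):
    """HACEK genera ride with the Neisseria block, so Prevotella 7-typed
    samples carry lower HACEK burdens (the recoverable pathogen pattern)."""
    table, meta, truth = default_cohort
    rel = to_relative(table, 0)
    h = hacek_abundance(rel)
    m = meta.set_index("sample_id")
    p7_subjects = {s for s, t in truth.subject_type.items() if t == "Prevotella7"}
    mask = m.loc[h.index, "subject_id"].isin(p7_subjects).to_numpy()
    assert np.median(h[mask]) < np.median(h[~mask])
    groups = pd.Series(np.where(mask, "p7", "other"), index=h.index)
    out = group_compare(h, groups, force_test="wilcoxon")
    assert out.p < 0.01
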