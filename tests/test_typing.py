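"""Spearman clustering, silhouette validation and the 2.5-fold typing rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ugityper.community_typing import (
    anchor_cluster,
    assign_type,
    cluster_taxa,
    cross_site_consistency,
    cross_site_taxon_correlation,
    cumulative_abundance,
    reference_clusters,
    spearman_matrix,
    type_cohort,
)
from ugityper.config import AnalysisConfig
from ugityper.core_tables import RelAbundanceTable, to_relative


def brute_spearman(x, y):
    """Rank-then-Pearson with average ranks, independent of scipy."""
    def avg_rank(v):
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks
    rx, ry = avg_rank(np.asarray(x)), avg_rank(np.asarray(y))
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


class TestSpearmanMatrix:
    def _rel(self, data):
        df = pd.DataFrame(data)
        return RelAbundanceTable(df / df.sum(axis=0))

    def test_monotone_pair_is_one(self):
        rel = self._rel(
            {f"s{i}": [1 + i, 2 + 2 * i, 10] for i in range(6)}
        )
        rel.data.index = ["a", "b", "c"]
        rho = spearman_matrix(rel, min_samples=5)
        assert rho.loc["a", "b"] == pytest.approx(1.0)
        assert (np.diag(rho) == 1.0).all()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.dirichlet(np.ones(6), size=7).T
        rel = RelAbundanceTable(
            pd.DataFrame(x, index=[f"t{i}" for i in range(6)], columns=[f"s{j}" for j in range(7)])
        )
        rho = spearman_matrix(rel, min_samples=5)
        for a in rho.index:
            for b in rho.index:
                assert rho.loc[a, b] == pytest.approx(
                    brute_spearman(rel.data.loc[a].to_numpy(), rel.data.loc[b].to_numpy()),
                    abs=1e-12,
                )

    def test_constant_taxon_dropped(self):
        rho = spearman_matrix(
            RelAbundanceTable(
                pd.DataFrame(
                    {f"s{i}": [0.2 + 0.01 * i, 0.3, 0.5 - 0.01 * i] for i in range(6)},
                    index=["a", "const", "c"],
                )
            ),
            min_samples=5,
        )
        assert "const" not in rho.index


def _block_rho(n1=3, n2=3, within=0.8, between=-0.5):
    k = n1 + n2
    rho = np.full((k, k), between)
    rho[:n1, :n1] = within
    rho[n1:, n1:] = within
    np.fill_diagonal(rho, 1.0)
    names = [f"p{i}" for i in range(n1)] + [f"n{i}" for i in range(n2)]
    return pd.DataFrame(rho, index=names, columns=names)


class TestClusterTaxa:
    def test_recovers_planted_blocks(self, cfg):
        cs = cluster_taxa(_block_rho(), cfg)
        lab = cs.labels
        assert lab["p0"] == lab["p1"] == lab["p2"]
        assert lab["n0"] == lab["n1"] == lab["n2"]
        assert lab["p0"] != lab["n0"]

    def test_tie_at_cut_height_keeps_taxa_merged(self, cfg):
        # all off-diagonal rho = 0 -> all pairwise d = 1 = cut height
        k = 4
        rho = pd.DataFrame(np.eye(k), index=list("abcd"), columns=list("abcd"))
        cs = cluster_taxa(rho, cfg)
        assert cs.labels.nunique() == 1

    def test_silhouette_hand_example(self, cfg):
        # {a,b}, {c,d} with d(a,b)=d(c,d)=0.1, cross 1.8: the cut at 1
        # separates the blocks and s(i) = (1.8 - 0.1) / 1.8 for all points
        d = np.array(
            [
                [0.0, 0.1, 1.8, 1.8],
                [0.1, 0.0, 1.8, 1.8],
                [1.8, 1.8, 0.0, 0.1],
                [1.8, 1.8, 0.1, 0.0],
            ]
        )
        rho = pd.DataFrame(1 - d, index=list("abcd"), columns=list("abcd"))
        cs = cluster_taxa(rho, cfg)
        assert cs.labels.nunique() == 2
        np.testing.assert_allclose(cs.silhouette, (1.8 - 0.1) / 1.8, atol=1e-12)

    def test_silhouette_matches_direct_formula(self, cfg):
        # two-point clusters with cross distance 0.9: s = (0.9 - 0.1)/0.9
        # for every point, from the silhouette definition applied to the
        # fixed partition {a,b}, {c,d}
        from sklearn.metrics import silhouette_samples

        d = np.array(
            [
                [0.0, 0.1, 0.9, 0.9],
                [0.1, 0.0, 0.9, 0.9],
                [0.9, 0.9, 0.0, 0.1],
                [0.9, 0.9, 0.1, 0.0],
            ]
        )
        s_vals = silhouette_samples(d, [1, 1, 2, 2], metric="precomputed")
        np.testing.assert_allclose(s_vals, 0.8889, atol=1e-4)

    def test_strong_correlation_count(self, cfg):
        cs = cluster_taxa(_block_rho(within=0.8, between=-0.75), cfg)
        # 3+3 within pairs at |0.8| plus 9 between pairs at |-0.75|
        assert cs.n_strong_correlations == 15

    def test_too_few_taxa_rejected(self, cfg):
        rho = pd.DataFrame(np.eye(2), index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            cluster_taxa(rho, cfg)


class TestAnchorCluster:
    def test_planted_anchor_returns_planted_members(self, cfg):
        rho = _block_rho()
        rho = rho.rename(index={"p0": "Prevotella 7"}, columns={"p0": "Prevotella 7"})
        cs = cluster_taxa(rho, cfg)
        assert sorted(anchor_cluster(cs, "Prevotella 7")) == ["Prevotella 7", "p1", "p2"]

    def test_negative_silhouette_member_excluded(self, cfg):
        cs = cluster_taxa(_block_rho(), cfg)
        cs.silhouette["p1"] = -0.1
        assert "p1" not in anchor_cluster(cs, "p0")

    def test_anchor_always_included_even_with_zero_silhouette(self, cfg):
        cs = cluster_taxa(_block_rho(), cfg)
        cs.silhouette["p0"] = -0.5
        assert "p0" in anchor_cluster(cs, "p0")

    def test_missing_anchor_lists_available(self, cfg):
        cs = cluster_taxa(_block_rho(), cfg)
        with pytest.raises(KeyError, match="p0"):
            anchor_cluster(cs, "Neisseria")


class TestAssignType:
    @pytest.mark.parametrize(
        "p7, neis, expected_type, expected_low",
        [
            (0.30, 0.10, "Prevotella7", False),
            (0.20, 0.10, "other", False),
            (0.25, 0.10, "Prevotella7", False),  # exactly 2.5 => "at least"
            (0.08, 0.05, "other", True),
        ],
    )
    def test_rule(self, p7, neis, expected_type, expected_low, cfg):
        typ, ratio, low_both, _ = assign_type(p7, neis, cfg)
        assert typ == expected_type
        assert low_both == expected_low

    def test_zero_neisseria_edge(self, cfg):
        typ, ratio, _, degen = assign_type(0.2, 0.0, cfg)
        assert typ == "Prevotella7" and np.isinf(ratio) and degen
        typ0, ratio0, _, degen0 = assign_type(0.0, 0.0, cfg)
        assert typ0 == "other" and np.isnan(ratio0) and degen0

    def test_out_of_range_rejected(self, cfg):
        with pytest.raises(ValueError):
            assign_type(1.2, 0.1, cfg)


class TestCumulativeAbundance:
    def test_examples(self):
        rel = RelAbundanceTable(
            pd.DataFrame({"s": [0.10, 0.05, 0.15, 0.70]}, index=list("abcd"))
        )
        assert cumulative_abundance(rel, ["a", "b", "c"])["s"] == pytest.approx(0.30)
        assert cumulative_abundance(rel, ["ghost"])["s"] == 0.0
        assert cumulative_abundance(rel, list("abcd"))["s"] == pytest.approx(1.0)
        with pytest.raises(ValueError):
            cumulative_abundance(rel, [])


class TestCrossSite:
    def test_consistency_table(self):
        recs = pd.DataFrame(
            {
                "subject_id": ["x", "x", "x", "y", "y", "z"],
                "amplicon": ["DNA"] * 6,
                "location": ["saliva", "stomach", "duodenum", "saliva", "duodenum", "saliva"],
                "type": ["Prevotella7"] * 3 + ["Prevotella7", "other", "other"],
            }
        )
        out = cross_site_consistency(recs).set_index("subject_id")
        assert out.loc["x", "consistent"]
        assert not out.loc["y", "consistent"] and out.loc["y", "n_switches"] == 1
        assert out.loc["z", "consistent"] is None  # single-site subject excluded

    def test_identical_sites_correlate_perfectly(self):
        rng = np.random.default_rng(1)
        x = rng.dirichlet(np.ones(8), size=6).T
        rel = RelAbundanceTable(
            pd.DataFrame(x, index=[f"t{i}" for i in range(8)], columns=[f"s{j}" for j in range(6)])
        )
        rho, _ = cross_site_taxon_correlation(rel, rel)
        assert rho == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        x = rng.dirichlet(np.ones(8), size=6).T
        rel_a = RelAbundanceTable(
            pd.DataFrame(x, index=[f"t{i}" for i in range(8)], columns=[f"s{j}" for j in range(6)])
        )
        means_a = rel_a.data.mean(axis=1)
        # construct site B with means an increasing transform of A's means
        vals = np.exp(means_a.to_numpy())
        rel_c = RelAbundanceTable(
            pd.DataFrame(
                np.tile(vals / vals.sum(), (6, 1)).T,
                index=rel_a.taxa,
                columns=rel_a.samples,
            )
        )
        rho, _ = cross_site_taxon_correlation(rel_a, rel_c)
        assert rho == pytest.approx(1.0)

    def test_too_few_shared_taxa_rejected(self):
        rel = RelAbundanceTable(pd.DataFrame({"s": [0.5, 0.5]}, index=["a", "b"]))
        with pytest.raises(ValueError):
            cross_site_taxon_correlation(rel, rel)


class TestCohortProperties:
    def test_reference_clusters_have_expected_sizes(self):
        ref = reference_clusters()
        assert len(ref["Prevotella 7"]) == 10
        assert len(ref["Neisseria"]) == 13
        assert "Prevotella 7" in ref["Prevotella 7"]
        assert "Neisseria" in ref["Neisseria"]

    def test_fold_threshold_monotonicity(self, default_cohort):
        table, meta, _ = default_cohort
        rel = to_relative(table, 0)
        ref = reference_clusters()
        counts = []
        for fold in (1.5, 2.0, 2.5, 3.0):
            cfg = AnalysisConfig(fold_threshold=fold)
            recs = type_cohort(rel, meta, ref["Prevotella 7"], ref["Neisseria"], cfg)
            counts.append((recs["type"] == "Prevotella7").sum())
        assert counts == sorted(counts, reverse=True)

    def test_typing_depth_invariance(self, default_cohort):
        """Typing operates on proportions: scaling a sample's counts is a no-op."""
        table, meta, _ = default_cohort
        rel = to_relative(table, 0)
        ref = reference_clusters()
        a = type_cohort(rel, meta, ref["Prevotella 7"], ref["Neisseria"])
        scaled = RelAbundanceTable(rel.data.copy())
        b = type_cohort(scaled, meta, ref["Prevotella 7"], ref["Neisseria"])
        assert a["type"].tolist() == b["type"].tolist()

    def test_cluster_cumulative_abundances_inversely_correlated(self, default_cohort):
        table, meta, _ = default_cohort
        rel = to_relative(table, 0)
        ref = reference_clusters()
        p7 = cumulative_abundance(rel, ref["Prevotella 7"])
        ne = cumulative_abundance(rel, ref["Neisseria"])
        from scipy.stats import spearmanr

        rho, p = spearmanr(p7, ne)
        assert rho < 0 and p < 1e-6

    @settings(deadline=None, max_examples=50)
    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(1.0, 10.0)
    )
    def test_assign_type_invariants(self, p7, neis, fold):
        cfg = AnalysisConfig(fold_threshold=fold)
        typ, ratio, low_both, degen = assign_type(p7, neis, cfg)
        assert typ in {"Prevotella7", "other"}
        if neis > 0:
            assert (typ == "Prevotella7") == (p7 >= fold * neis)
        assert low_both == (p7 < 0.1 and neis < 0.1)
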