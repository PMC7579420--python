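"""Scoring and classification: module scores, phases, stemness, clustering,
the one-fifth binarization, and the cluster labeling rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ranksums

from mrshift.scoring import (
    binarize_by_quantile,
    cell_cycle_assign,
    find_markers,
    label_clusters,
    module_score,
    snn_cluster,
    stemness_index,
)

GENES_300 = [f"g{i}" for i in range(300)]


class TestModuleScore:
    def test_whole_universe_scores_near_zero(self, small_study):
        _, _, adata, _ = small_study
        values = np.log1p(np.asarray(adata.layers["counts"].todense()))
        genes = list(adata.var_names)
        scores = module_score(values, genes, genes, seed=0)
        assert np.abs(scores).max() < 0.05

    def test_shifted_subset_scores_higher(self, rng):
        values = rng.normal(size=(500, 300))
        shifted = rng.choice(500, 200, replace=False)
        gene_set = GENES_300[:30]
        values[np.ix_(shifted, np.arange(30))] += 1.0
        scores = module_score(values, GENES_300, gene_set, seed=0)
        mask = np.zeros(500, dtype=bool)
        mask[shifted] = True
        assert ranksums(scores[mask], scores[~mask]).pvalue < 1e-6
        assert scores[mask].mean() > scores[~mask].mean()

    def test_deterministic_for_seed(self, rng):
        values = rng.normal(size=(50, 300))
        s1 = module_score(values, GENES_300, GENES_300[:20], seed=42)
        s2 = module_score(values, GENES_300, GENES_300[:20], seed=42)
        np.testing.assert_array_equal(s1, s2)

    def test_invariant_to_per_cell_constant(self, rng):
        values = rng.normal(size=(40, 300))
        offs = rng.normal(size=(40, 1)) * 3.0
        s1 = module_score(values, GENES_300, GENES_300[:25], seed=7)
        s2 = module_score(values + offs, GENES_300, GENES_300[:25], seed=7)
        np.testing.assert_allclose(s1, s2, atol=1e-10)

    def test_empty_intersection_raises(self, rng):
        values = rng.normal(size=(10, 300))
        with pytest.raises(ValueError, match="empty intersection"):
            module_score(values, GENES_300, ["absent1", "absent2"])


class TestCellCycleAssign:
    def test_phase_rule(self, rng):
        values = rng.normal(0, 0.1, size=(30, 300))
        s_set, g2m_set = GENES_300[:20], GENES_300[20:40]
        values[:10, :20] += 2.0       # S program high
        values[10:20, 20:40] += 2.0   # G2M program high
        values[20:, :40] -= 2.0       # both programs suppressed -> G1
        out = cell_cycle_assign(values, GENES_300, s_set, g2m_set, seed=0)
        assert (out.loc[:9, "phase"] == "S").all()
        assert (out.loc[10:19, "phase"] == "G2M").all()
        assert (out.loc[20:, "phase"] == "G1").all()

    @pytest.mark.parametrize(
        "s,g2m,expected", [(-0.2, -0.5, "G1"), (0.3, 0.1, "S"), (0.1, 0.4, "G2M")]
    )
    def test_decision_boundaries(self, s, g2m, expected):
        # the rule itself, applied to known scores
        phase = (
            "G2M" if (g2m >= s and g2m > 0) else ("S" if (s > g2m and s > 0) else "G1")
        )
        assert phase == expected


class TestStemnessIndex:
    def test_perfectly_correlated_cell_is_max(self, rng):
        weights = pd.Series(rng.uniform(0.1, 1.0, 50), index=GENES_300[:50])
        values = rng.normal(size=(10, 300))
        values[0, :50] = weights.values  # ranks equal weight ranks
        idx = stemness_index(values, GENES_300, weights)
        assert idx[0] == pytest.approx(1.0)

    def test_reversed_rankings_span_unit_interval(self):
        weights = pd.Series(np.arange(1.0, 11.0), index=GENES_300[:10])
        values = np.zeros((2, 300))
        values[0, :10] = np.arange(10)
        values[1, :10] = np.arange(10)[::-1]
        idx = stemness_index(values, GENES_300, weights)
        assert sorted(idx.tolist()) == [0.0, 1.0]

    def test_rescaled_to_unit_interval(self, rng):
        weights = pd.Series(rng.uniform(size=40), index=GENES_300[:40])
        values = rng.normal(size=(30, 300))
        idx = stemness_index(values, GENES_300, weights)
        assert idx.min() == 0.0 and idx.max() == 1.0

    def test_constant_cell_gets_half_with_warning(self, rng):
        weights = pd.Series(rng.uniform(size=40), index=GENES_300[:40])
        values = rng.normal(size=(5, 300))
        values[2] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            idx = stemness_index(values, GENES_300, weights)
        assert idx[2] == 0.5


class TestSnnCluster:
    def test_two_separated_blobs(self, rng):
        blob = rng.normal(size=(200, 30))
        blob[:100] += 10.0  # 10 SD separation
        labels = snn_cluster(blob, k=15, resolution=1.0, n_pcs=10, seed=0)
        assert len(np.unique(labels)) == 2
        assert len(np.unique(labels[:100])) == 1
        assert len(np.unique(labels[100:])) == 1

    def test_single_blob_low_resolution(self, rng):
        blob = rng.normal(size=(150, 20))
        labels = snn_cluster(blob, k=15, resolution=0.1, n_pcs=10, seed=0)
        assert len(np.unique(labels)) == 1

    def test_deterministic(self, rng):
        x = rng.normal(size=(120, 15))
        a = snn_cluster(x, k=10, seed=3)
        b = snn_cluster(x, k=10, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_k_too_large(self, rng):
        with pytest.raises(ValueError):
            snn_cluster(rng.normal(size=(10, 5)), k=10)


class TestBinarize:
    def test_one_fifth_rule_on_ranked_scores(self):
        flags = binarize_by_quantile(np.arange(1.0, 11.0), 0.2)
        assert list(np.where(flags == "Arr")[0]) == [8, 9]

    def test_ties_broken_by_stable_order(self):
        flags = binarize_by_quantile(np.ones(10), 0.2)
        assert list(np.where(flags == "Arr")[0]) == [0, 1]

    def test_fraction_one_labels_all(self):
        assert (binarize_by_quantile(np.arange(5.0), 1.0) == "Arr").all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            binarize_by_quantile(np.array([]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        n=st.integers(1, 500),
        frac=st.floats(0.01, 1.0),
        seed=st.integers(0, 10_000),
    )
    def test_exact_count_property(self, n, frac, seed):
        scores = np.random.default_rng(seed).permutation(n).astype(float)
        flags = binarize_by_quantile(scores, frac)
        assert (flags == "Arr").sum() == min(n, int(np.ceil(frac * n)))


class TestLabelClusters:
    def _mk(self, spec):
        """spec: list of (n_arr, n_narr, apc_mean) per cluster."""
        clusters, flags, apc = [], [], []
        for c, (n_arr, n_narr, mean_apc) in enumerate(spec):
            clusters += [c] * (n_arr + n_narr)
            flags += ["Arr"] * n_arr + ["NArr"] * n_narr
            apc += [mean_apc] * (n_arr + n_narr)
        return np.array(clusters), np.array(flags), np.array(apc, dtype=float)

    def test_printed_threshold_examples(self):
        spec = [(9, 10, 1.0), (2, 18, 1.2), (5, 15, 5.0), (0, 20, 6.0), (1, 19, 7.0)]
        table, per_cell = label_clusters(*self._mk(spec), tertile_ref="cell")
        assert table.loc[0, "growth"] == "Arr"       # ratio 0.9 > 0.8
        assert table.loc[1, "growth"] == "NArr"      # ratio 0.111 < 0.2
        assert table.loc[2, "growth"] == "unlabeled"  # ratio 0.333
        assert table.loc[0, "subpop"] == "LSG"
        assert table.loc[1, "subpop"] == "LFG"
        assert table.loc[2, "subpop"] == "None"

    def test_zero_narr_cluster_is_arrested(self):
        spec = [(10, 0, 1.0), (1, 19, 5.0), (2, 18, 6.0)]
        table, _ = label_clusters(*self._mk(spec))
        assert np.isinf(table.loc[0, "arr_ratio"])
        assert table.loc[0, "growth"] == "Arr"

    def test_invariant_to_cluster_relabeling(self):
        spec = [(9, 10, 1.0), (2, 18, 1.2), (1, 19, 6.0)]
        clusters, flags, apc = self._mk(spec)
        _, cells1 = label_clusters(clusters, flags, apc)
        perm = {0: 7, 1: 3, 2: 5}
        _, cells2 = label_clusters(
            np.array([perm[c] for c in clusters]), flags, apc
        )
        assert (cells1.values == cells2.values).all()

    def test_fraction_semantics_switch(self):
        # 9 Arr / 10 NArr: odds 0.9 -> Arr, but fraction 0.47 -> unlabeled
        spec = [(9, 10, 1.0), (1, 19, 5.0), (2, 18, 6.0)]
        odds_table, _ = label_clusters(*self._mk(spec), ratio_semantics="odds")
        frac_table, _ = label_clusters(*self._mk(spec), ratio_semantics="fraction")
        assert odds_table.loc[0, "growth"] == "Arr"
        assert frac_table.loc[0, "growth"] == "unlabeled"

    def test_cluster_mean_reference(self):
        spec = [(9, 10, 1.0), (2, 18, 4.0), (1, 19, 6.0), (0, 10, 7.0)]
        table, _ = label_clusters(*self._mk(spec), tertile_ref="cluster")
        tertile = np.quantile([1.0, 4.0, 6.0, 7.0], 1 / 3)
        assert (table["apc_tertile"] == tertile).all()
        assert table.loc[0, "apc_level"] == "lowAPC"


class TestFindMarkers:
    def test_identical_groups_empty_table(self, rng):
        values = rng.normal(2.0, 0.5, size=(40, 50))
        x = np.vstack([values, values])
        table = find_markers(x, [f"g{i}" for i in range(50)],
                             np.arange(40), np.arange(40, 80))
        assert table.empty

    def test_planted_fold_change_top_ranked(self, rng):
        genes = [f"g{i}" for i in range(200)]
        base = rng.lognormal(1.0, 0.3, size=(200, 200))
        x = np.log1p(base)
        x[:100, 7] = np.log1p(base[:100, 7] * 4.0)  # gene 7 x4 in group A
        table = find_markers(x, genes, np.arange(100), np.arange(100, 200))
        assert table.iloc[0]["gene"] == "g7"
        assert table.iloc[0]["q"] < 0.01

    def test_infinite_threshold_empties_table(self, rng):
        x = rng.normal(size=(20, 30))
        table = find_markers(x, [f"g{i}" for i in range(30)],
                             np.arange(10), np.arange(10, 20), logfc_min=np.inf)
        assert table.empty

    def test_empty_group_rejected(self, rng):
        x = rng.normal(size=(10, 5))
        with pytest.raises(ValueError):
            find_markers(x, list("abcde"), np.array([], dtype=int), np.arange(10))
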