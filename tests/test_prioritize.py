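"""Target-selection cascade: filters, shortlist semantics, graph evidence,
MINDy modulation statistics, and the master-regulator pick."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrshift.prioritize import (
    filter_by_da,
    mindy_modulation,
    rank_shortlist,
    select_master,
    shared_regulon_ratio,
    shortest_path_to_anchor,
    split_by_direction,
)
from mrshift.regulons import Regulon


def _reg(genes, tf="tfX"):
    return Regulon(tf, {g: (1, 0.8) for g in genes})


class TestFilterByDa:
    def test_threshold_count(self):
        da = pd.DataFrame({"p": [0.005, 0.02, 0.5]}, index=list("abc"))
        assert list(filter_by_da(da, 0.01).index) == ["a"]

    def test_alpha_one_keeps_all(self):
        da = pd.DataFrame({"p": [0.005, 0.02, 0.5]}, index=list("abc"))
        assert len(filter_by_da(da, 1.0)) == 3

    def test_alpha_zero_rejected(self):
        da = pd.DataFrame({"p": [0.005]}, index=["a"])
        with pytest.raises(ValueError):
            filter_by_da(da, 0.0)

    def test_no_survivor_raises(self):
        da = pd.DataFrame({"p": [0.5, 0.9]}, index=list("ab"))
        with pytest.raises(ValueError, match="no regulator"):
            filter_by_da(da, 0.01)


class TestSplitByDirection:
    def _cands(self, deltas, rng):
        mean_b = rng.normal(0, 0.05, len(deltas))
        return pd.DataFrame(
            {"mean_a": mean_b + deltas, "mean_b": mean_b},
            index=[f"c{i}" for i in range(len(deltas))],
        )

    def test_separated_groups_negative_returned(self, rng):
        deltas = np.array([-3.0, -3.1, -2.9, 3.0, 3.1, 2.9])
        out = split_by_direction(self._cands(deltas, rng))
        assert set(out.index) == {"c0", "c1", "c2"}

    def test_identical_candidates_deterministic(self, rng):
        cands = pd.DataFrame(
            {"mean_a": [1.0] * 4, "mean_b": [1.0] * 4}, index=list("abcd")
        )
        out1 = split_by_direction(cands)
        out2 = split_by_direction(cands)
        pd.testing.assert_frame_equal(out1, out2)

    def test_sign_flip_flips_returned_group(self, rng):
        deltas = np.array([-2.0, -2.2, 2.0, 2.1])
        cands = self._cands(deltas, rng)
        out_fwd = split_by_direction(cands)
        flipped = cands.copy()
        flipped[["mean_a", "mean_b"]] = -cands[["mean_a", "mean_b"]].values
        out_rev = split_by_direction(flipped)
        assert set(out_fwd.index) & set(out_rev.index) == set()

    def test_single_candidate_rule(self):
        down = pd.DataFrame({"mean_a": [0.0], "mean_b": [1.0]}, index=["x"])
        up = pd.DataFrame({"mean_a": [1.0], "mean_b": [0.0]}, index=["x"])
        assert len(split_by_direction(down)) == 1
        assert len(split_by_direction(up)) == 0


class TestRankShortlist:
    def _cands(self, n, rng):
        return pd.DataFrame(
            {
                "delta_activity": rng.normal(size=n),
                "delta_expression": rng.normal(size=n),
            },
            index=[f"c{i}" for i in range(n)],
        )

    def test_twelve_candidates_at_most_two_survive(self, rng):
        out = rank_shortlist(self._cands(12, rng))
        assert len(out) <= 2  # activity cut ceil(12/6) = 2

    def test_unit_fractions_keep_all(self, rng):
        out = rank_shortlist(self._cands(9, rng), 1.0, 1.0)
        assert len(out) == 9

    def test_double_top_candidate_always_survives(self, rng):
        cands = self._cands(12, rng)
        cands.loc["c3", ["delta_activity", "delta_expression"]] = [99.0, 99.0]
        out = rank_shortlist(cands)
        assert "c3" in out.index

    def test_empty_intersection_falls_back_to_activity(self):
        cands = pd.DataFrame(
            {
                "delta_activity": [3.0, 2.0, 1.0, 0.5, 0.4, 0.3],
                "delta_expression": [0.1, 0.2, 0.3, 3.0, 2.0, 1.0],
            },
            index=list("abcdef"),
        )
        with pytest.warns(UserWarning, match="fall"):
            out = rank_shortlist(cands)
        assert list(out.index) == ["a"]


class TestGraphEvidence:
    def test_direct_edge_is_one_hop(self):
        edges = [("cand", "APC"), ("APC", "CTNNB1")]
        assert shortest_path_to_anchor(edges, "cand", _reg(["t1"])) == 1.0

    def test_planted_three_hop_path(self):
        edges = [
            ("cand", "t1"), ("t1", "CTNNB1"), ("CTNNB1", "APC"),
            ("t1", "t2"), ("t2", "noise"),
        ]
        reg = _reg(["t1", "t2"])
        assert shortest_path_to_anchor(edges, "cand", reg) == 3.0
        # oracle on the induced subgraph
        g = nx.Graph([e for e in edges if e != ("t2", "noise")])
        assert nx.shortest_path_length(g, "cand", "APC") == 3

    def test_path_must_stay_inside_candidate_gene_list(self):
        # shortcut through a gene outside the candidate's regulon is ignored
        edges = [
            ("cand", "shortcut"), ("shortcut", "APC"),
            ("cand", "t1"), ("t1", "CTNNB1"), ("CTNNB1", "APC"),
        ]
        assert shortest_path_to_anchor(edges, "cand", _reg(["t1"])) == 3.0

    def test_isolated_candidate_infinite(self):
        edges = [("APC", "CTNNB1"), ("a", "b")]
        assert math.isinf(shortest_path_to_anchor(edges, "cand", _reg(["t1"])))

    def test_missing_apc_rejected(self):
        with pytest.raises(ValueError, match="APC"):
            shortest_path_to_anchor([("a", "b")], "a", _reg(["b"]))

    @pytest.mark.parametrize(
        "cand,apc,expected",
        [
            (["a", "b", "c", "d"], ["c", "d", "e"], 0.5),
            (["a", "b"], ["c", "d"], 0.0),
            (["a", "b"], ["a", "b", "c"], 1.0),
        ],
    )
    def test_shared_ratio_closed_forms(self, cand, apc, expected):
        assert shared_regulon_ratio(_reg(cand), _reg(apc, tf="APC")) == expected

    def test_empty_apc_regulon_warns_zero(self):
        with pytest.warns(UserWarning, match="APC regulon"):
            assert shared_regulon_ratio(_reg(["a"]), None) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(extra=st.lists(st.sampled_from([f"x{i}" for i in range(8)]),
                          min_size=0, max_size=8, unique=True))
    def test_shared_ratio_monotone_in_intersection(self, extra):
        apc = _reg(["a", "b"] + extra, tf="APC")
        base = shared_regulon_ratio(_reg(["a", "b", "c", "d"]), _reg(["a"], tf="APC"))
        more = shared_regulon_ratio(_reg(["a", "b", "c", "d"]), apc)
        assert more >= base


class TestMindy:
    GENES = ["mod", "tf"] + [f"t{i}" for i in range(5)]

    def _planted(self, n, rng, coupled=True):
        mod = rng.normal(size=n)
        tf = rng.normal(size=n)
        gate = (mod > 0).astype(float) if coupled else 1.0
        values = np.column_stack(
            [mod, tf]
            + [tf * gate + rng.normal(0, 0.4, n) for _ in range(5)]
        )
        return values

    def test_planted_modulation_detected(self, rng):
        values = self._planted(1000, rng)
        di, p = mindy_modulation(
            values, self.GENES, "mod", "tf", [f"t{i}" for i in range(5)],
            n_perm=500, seed=0,
        )
        assert di > 0
        assert p < 0.01

    def test_antisymmetric_under_split_exchange(self, rng):
        values = self._planted(400, rng)
        flipped = values.copy()
        flipped[:, 0] = -flipped[:, 0]  # reverses the top/bottom split
        di1, _ = mindy_modulation(values, self.GENES, "mod", "tf",
                                  ["t0", "t1"], n_perm=10, seed=0)
        di2, _ = mindy_modulation(flipped, self.GENES, "mod", "tf",
                                  ["t0", "t1"], n_perm=10, seed=0)
        assert di2 == pytest.approx(-di1, abs=1e-12)

    def test_constant_modulator_missing_result(self, rng):
        values = self._planted(100, rng)
        values[:, 0] = 1.0
        di, p = mindy_modulation(values, self.GENES, "mod", "tf", ["t0"], n_perm=10)
        assert np.isnan(di) and np.isnan(p)

    def test_too_few_cells_rejected(self, rng):
        with pytest.raises(ValueError):
            mindy_modulation(self._planted(30, rng), self.GENES, "mod", "tf", ["t0"])


class TestSelectMaster:
    def _mod(self, rows):
        return pd.DataFrame(rows, columns=["modulator", "tf", "delta_i", "p"])

    def test_degree_count_and_cross_pair(self):
        mod = self._mod([
            ("A", "B", 0.2, 1e-4), ("B", "A", 0.2, 1e-4),
            ("A", "C", 0.1, 1e-3), ("B", "C", 0.0, 0.9), ("C", "A", 0.0, 0.8),
        ])
        out = select_master(mod)
        assert out["master"] == "A"
        assert dict(out["ranking"]) == {"A": 3, "B": 2, "C": 1}
        assert out["cross_modulating"] == [("A", "B")]

    def test_degree_tie_broken_by_delta_activity(self):
        mod = self._mod([("A", "B", 0.2, 1e-4)])
        out = select_master(mod, delta_activity={"A": 1.0, "B": 2.0})
        assert out["master"] == "B"

    def test_empty_network_reports_no_selection(self):
        mod = self._mod([("A", "B", 0.0, 0.9)])
        out = select_master(mod)
        assert out["master"] is None and out["note"]

    def test_hub_modulator_recovered_from_simulated_programs(self, rng):
        """One MR modulating two others is picked as the hub."""
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            n = 400
            a, b, c = r.normal(size=(3, n))
            genes = ["A", "B", "C"] + [f"bt{i}" for i in range(3)] + [
                f"ct{i}" for i in range(3)
            ]
            gate = (a > 0).astype(float)
            cols = [a, b, c]
            cols += [b * gate + r.normal(0, 0.4, n) for _ in range(3)]  # A modulates B
            cols += [c * gate + r.normal(0, 0.4, n) for _ in range(3)]  # A modulates C
            values = np.column_stack(cols)
            rows = []
            targets = {"B": ["bt0", "bt1", "bt2"], "C": ["ct0", "ct1", "ct2"],
                       "A": ["bt0", "ct0", "bt1"]}
            for m in "ABC":
                for t in "ABC":
                    if m == t:
                        continue
                    di, p = mindy_modulation(
                        values, genes, m, t, targets[t], n_perm=200, seed=seed
                    )
                    rows.append((m, t, di, p))
            out = select_master(self._mod(rows))
            hits += out["master"] == "A"
        assert hits >= 4
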