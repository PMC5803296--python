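"""Upstream-regulator inference: ORA, activation z-scores, network algebra."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from duosig.tfnet import (TFNetwork, build_literature_network,
                          build_sequence_network, causal_activation_scores,
                          intersect_networks, ora)


def make_de(direction_by_gene, called=None, extra_uncalled=()):
    genes = list(direction_by_gene) + list(extra_uncalled)
    return pd.DataFrame({
        "gene": genes,
        "direction": [direction_by_gene.get(g, "up") for g in genes],
        "called": [g in direction_by_gene if called is None else called[g]
                   for g in genes],
        "ratio": [2.0 if direction_by_gene.get(g) == "up" else 0.5 for g in genes],
        "q": 0.01,
    }).set_index("gene")


def make_edges(rows):
    return pd.DataFrame(rows, columns=["tf", "target", "sign"])


class TestORA:
    def test_query_equals_universe_gives_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        sets = {"S1": {"g0", "g1", "g2"}, "S2": {"g5"}}
        out = ora(universe, sets, universe).set_index("set")
        assert (out["p"] == 1.0).all()
        assert out.loc["S1", "k"] == 3

    def test_disjoint_query_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        out = ora({"g8", "g9"}, {"S": {"g0", "g1"}}, universe)
        assert out["k"].iloc[0] == 0 and out["p"].iloc[0] == 1.0

    def test_small_enumeration_case(self):
        universe = {f"g{i}" for i in range(10)}
        out = ora({"g0", "g1", "g9"}, {"S": {"g0", "g1", "g2", "g3"}}, universe)
        assert out["p"].iloc[0] == pytest.approx(1 / 3, rel=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty universe"):
            ora({"a"}, {"S": {"a"}}, set())


class TestActivationScores:
    def test_perfectly_consistent_activation(self):
        edges = make_edges([("R", f"g{i}", 1) for i in range(4)])
        de = make_de({f"g{i}": "up" for i in range(4)})
        out = causal_activation_scores(edges, de, universe_size=100)
        assert out["z"].iloc[0] == pytest.approx(2.0)
        assert out["state"].iloc[0] == "activated"

    def test_balanced_directions_score_zero(self):
        edges = make_edges([("R", f"g{i}", 1) for i in range(4)])
        de = make_de({"g0": "up", "g1": "up", "g2": "down", "g3": "down"})
        out = causal_activation_scores(edges, de, 100)
        assert out["z"].iloc[0] == 0.0 and out["state"].iloc[0] == "none"

    def test_three_one_split_is_subthreshold(self):
        edges = make_edges([("R", f"g{i}", 1) for i in range(4)])
        de = make_de({"g0": "up", "g1": "up", "g2": "up", "g3": "down"})
        out = causal_activation_scores(edges, de, 100)
        assert out["z"].iloc[0] == pytest.approx(1.0)
        assert out["state"].iloc[0] == "none"

    def test_regulator_without_matched_targets_omitted(self):
        edges = make_edges([("R", "absent", 1)])
        de = make_de({"g0": "up"})
        out = causal_activation_scores(edges, de, 100)
        assert out.empty

    def test_antisymmetric_under_direction_flip(self, rng):
        edges = make_edges([("R", f"g{i}", int(s))
                            for i, s in enumerate(rng.choice([-1, 1], 20))])
        dirs = {f"g{i}": d for i, d in
                enumerate(rng.choice(["up", "down"], 20))}
        flipped = {g: ("down" if d == "up" else "up") for g, d in dirs.items()}
        z1 = causal_activation_scores(edges, make_de(dirs), 100)["z"].iloc[0]
        z2 = causal_activation_scores(edges, make_de(flipped), 100)["z"].iloc[0]
        assert z1 == pytest.approx(-z2)

    @given(st.lists(st.tuples(st.sampled_from([-1, 1]), st.sampled_from(["up", "down"])),
                    min_size=1, max_size=40))
    def test_z_bounded_by_sqrt_n(self, pairs):
        edges = make_edges([("R", f"g{i}", s) for i, (s, _) in enumerate(pairs)])
        de = make_de({f"g{i}": d for i, (_, d) in enumerate(pairs)})
        out = causal_activation_scores(edges, de, 1000)
        assert abs(out["z"].iloc[0]) <= math.sqrt(len(pairs)) + 1e-12

    def test_random_direction_calibration(self, rng):
        """With random target directions the |z| ≥ 2 rate equals the exact
        binomial two-sided tail (≈4.6% at n = 1000 targets)."""
        n, n_reg = 1000, 4000
        signs = rng.choice([-1, 1], (n_reg, n))
        z = signs.sum(axis=1) / math.sqrt(n)  # equivalent: directions random
        rate = (np.abs(z) >= 2).mean()
        k_star = math.ceil((n + 2 * math.sqrt(n)) / 2)
        exact = 2 * stats.binom.sf(k_star - 1, n, 0.5)
        assert 0.035 <= exact <= 0.055  # close to the nominal two-sided 4.6%
        se = math.sqrt(exact * (1 - exact) / n_reg)
        assert abs(rate - exact) < 4 * se


class TestSequenceNetwork:
    def test_motif_set_matching_module_is_enriched(self):
        universe = {f"g{i}" for i in range(1000)}
        module = {f"g{i}" for i in range(30)}
        net = build_sequence_network({"M1": module}, {"TF1": set(module)},
                                     universe, alpha=0.05)
        assert len(net.edges) == 30
        assert net.tfs() == {"TF1"}
        assert (net.edges["module"] == "M1").all()

    def test_tf_without_module_targets_contributes_nothing(self):
        universe = {f"g{i}" for i in range(100)}
        net = build_sequence_network({"M1": {"g0", "g1"}},
                                     {"TF1": {"g50", "g51"}}, universe)
        assert net.edges.empty

    def test_alpha_zero_gives_empty_network(self):
        universe = {f"g{i}" for i in range(100)}
        module = {f"g{i}" for i in range(10)}
        net = build_sequence_network({"M1": module}, {"TF1": module},
                                     universe, alpha=0.0)
        assert net.edges.empty

    def test_module_genes_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside universe"):
            build_sequence_network({"M1": {"zzz"}}, {"TF1": {"zzz"}},
                                   {f"g{i}" for i in range(10)})


class TestLiteratureNetwork:
    def test_planted_activated_regulator_included(self):
        edges = make_edges([("R", f"g{i}", 1) for i in range(8)])
        de = make_de({f"g{i}": "up" for i in range(8)},
                     extra_uncalled=[f"x{i}" for i in range(92)])
        net = build_literature_network(edges, de, None, universe_size=100)
        assert net.tfs() == {"R"}
        assert len(net.edges) == 8
        assert net.scores.set_index("tf").loc["R", "state"] == "activated"

    def test_balanced_regulator_excluded_despite_overlap(self):
        edges = make_edges([("R", f"g{i}", 1) for i in range(8)])
        dirs = {f"g{i}": ("up" if i % 2 else "down") for i in range(8)}
        de = make_de(dirs, extra_uncalled=[f"x{i}" for i in range(92)])
        net = build_literature_network(edges, de, None, 100)
        assert net.edges.empty

    def test_planted_regulators_rank_top3_by_abs_z(self, default_runs):
        """All planted active regulators outrank every inactive one."""
        for truth, res in default_runs:
            scores = res.networks["literature"].scores
            top3 = set(scores.sort_values("z", key=np.abs, ascending=False)
                       ["tf"].head(3))
            assert top3 == set(truth.active_regulators)

    def test_intersection_recovers_planted_regulators(self, default_runs):
        """Intersection-network TF precision and recall ≥ 0.8 (5 seeds)."""
        precisions, recalls = [], []
        for truth, res in default_runs:
            tfs = res.networks["intersection"].tfs()
            active = set(truth.active_regulators)
            precisions.append(len(tfs & active) / max(len(tfs), 1))
            recalls.append(len(tfs & active) / len(active))
        assert np.mean(precisions) >= 0.8
        assert np.mean(recalls) >= 0.8


class TestIntersection:
    def net(self, pairs, channel="literature"):
        edges = pd.DataFrame([{"tf": a, "target": b, "channel": channel,
                               "module": None} for a, b in pairs])
        if edges.empty:
            edges = pd.DataFrame(columns=["tf", "target", "channel", "module"])
        return TFNetwork(edges=edges, scores=pd.DataFrame(), channel=channel)

    def test_disjoint_edge_sets_give_empty_network(self):
        out = intersect_networks(self.net([("A", "x")]), self.net([("B", "y")]))
        assert out.edges.empty

    def test_identical_edge_sets_reproduce_parent(self):
        pairs = [("A", "x"), ("A", "y"), ("B", "x")]
        out = intersect_networks(self.net(pairs), self.net(pairs))
        assert out.edge_set() == set(pairs)

    def test_matches_brute_force_set_intersection(self, rng):
        pool = [(f"T{i}", f"g{j}") for i in range(10) for j in range(20)]
        a = [pool[i] for i in rng.choice(len(pool), 50, replace=False)]
        b = [pool[i] for i in rng.choice(len(pool), 60, replace=False)]
        out = intersect_networks(self.net(a), self.net(b))
        assert out.edge_set() == set(a) & set(b)

    def test_set_identities(self, rng):
        pool = [(f"T{i}", f"g{j}") for i in range(5) for j in range(8)]
        a = self.net([pool[i] for i in rng.choice(len(pool), 15, replace=False)])
        b = self.net([pool[i] for i in rng.choice(len(pool), 15, replace=False)])
        c = self.net([pool[i] for i in rng.choice(len(pool), 15, replace=False)])
        ab = intersect_networks(a, b)
        ba = intersect_networks(b, a)
        assert ab.edge_set() == ba.edge_set()                       # commutative
        assert intersect_networks(ab, c).edge_set() == \
            intersect_networks(a, intersect_networks(b, c)).edge_set()  # associative
        assert intersect_networks(a, a).edge_set() == a.edge_set()  # idempotent

    def test_hive_table_lists_every_node_with_degree(self):
        net = self.net([("A", "x"), ("A", "y"), ("B", "x")])
        hive = net.hive_table()
        assert set(hive["node"]) == {"A", "B", "x", "y"}
        assert hive.set_index("node").loc["A", "degree"] == 2
        assert hive.set_index("node").loc["A", "axis"] == "tf"
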