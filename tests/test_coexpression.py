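"""Network construction, module detection, eigengenes and overlap tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from duosig.coexpression import (build_network, detect_modules, eigengenes_kme,
                                 module_overlap, pick_soft_power,
                                 signature_module_enrichment,
                                 topological_overlap, trait_correlation)

from conftest import make_bundle


def block_values(rng, n_per_block=50, n_samples=60, cor=0.8, n_blocks=2):
    """Planted co-expression blocks via a one-factor model per block."""
    loading = math.sqrt(cor / (1 - cor))  # unit noise → within-block cor
    rows, labels = [], []
    for b in range(n_blocks):
        f = rng.standard_normal(n_samples)
        for _ in range(n_per_block):
            rows.append(loading * f + rng.standard_normal(n_samples))
            labels.append(f"block{b}")
    values = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                          columns=[f"s{i}" for i in range(n_samples)])
    return values, np.array(labels)


class TestTopologicalOverlap:
    def test_hand_computed_three_node_case(self):
        # all pairwise a = 0.5: ω12 = (0.25 + 0.5)/(1 + 1 − 0.5) = 0.5
        adj = np.full((3, 3), 0.5)
        np.fill_diagonal(adj, 0.0)
        tom = topological_overlap(adj)
        off = tom[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.5, atol=1e-12)
        np.testing.assert_allclose(np.diag(tom), 1.0)

    def test_entries_bounded_symmetric_unit_diagonal(self, rng):
        a = rng.uniform(0, 1, (20, 20))
        adj = (a + a.T) / 2
        np.fill_diagonal(adj, 0.0)
        tom = topological_overlap(adj)
        assert ((tom >= 0) & (tom <= 1)).all()
        np.testing.assert_allclose(tom, tom.T)
        np.testing.assert_allclose(np.diag(tom), 1.0)


class TestBuildNetwork:
    def test_perfectly_correlated_pair_has_unit_adjacency(self):
        base = np.arange(10, dtype=float)
        values = pd.DataFrame([base, 2 * base + 3, -base],
                              index=["a", "b", "c"],
                              columns=[f"s{i}" for i in range(10)])
        net = build_network(values, beta=6)
        assert net.adjacency.loc["a", "b"] == pytest.approx(1.0)
        assert net.adjacency.loc["a", "c"] == pytest.approx(1.0)  # unsigned

    def test_orthogonal_genes_have_zero_overlap(self):
        values = pd.DataFrame([[1, 1, -1, -1], [1, -1, 1, -1], [1, -1, -1, 1]],
                              index=["a", "b", "c"], columns=list("wxyz"),
                              dtype=float)
        net = build_network(values, beta=6)
        off = net.tom.to_numpy()[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    def test_zero_variance_gene_rejected(self, rng):
        values = pd.DataFrame(rng.normal(size=(3, 6)))
        values.iloc[1] = 4.0
        with pytest.raises(ValueError, match="zero-variance"):
            build_network(values)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="4 samples"):
            build_network(pd.DataFrame(rng.normal(size=(5, 3))))


class TestSoftPowerChooser:
    def test_returns_candidate_from_list(self, rng):
        values, _ = block_values(rng, n_per_block=40, n_blocks=2)
        beta = pick_soft_power(values, candidates=(2, 4, 6))
        assert beta in (2.0, 4.0, 6.0)


class TestDetectModules:
    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_planted_blocks_exactly(self, seed):
        """Two 50-gene blocks at within-correlation 0.8 → ARI 1.0."""
        values, labels = block_values(np.random.default_rng(seed))
        net = build_network(values, beta=6)
        assign = detect_modules(net, cut_height=0.9, min_size=20)
        assert adjusted_rand_score(labels, assign.to_numpy()) == 1.0
        assert len(set(assign)) == 2

    def test_identical_genes_form_one_module(self, rng):
        base = rng.normal(0, 1, 30)
        values = pd.DataFrame([base] * 25, index=[f"g{i}" for i in range(25)],
                              columns=[f"s{i}" for i in range(30)])
        net = build_network(values)
        assign = detect_modules(net, min_size=20)
        assert set(assign) == {"M1"}

    def test_min_size_larger_than_universe_unassigns_all(self, rng):
        values, _ = block_values(rng, n_per_block=10, n_blocks=1)
        net = build_network(values)
        assign = detect_modules(net, min_size=50)
        assert set(assign) == {"unassigned"}

    def test_gene_permutation_invariance_up_to_labels(self, rng):
        values, _ = block_values(rng)
        net = build_network(values)
        a1 = detect_modules(net)
        perm = values.sample(frac=1, random_state=5)
        a2 = detect_modules(build_network(perm))
        assert adjusted_rand_score(a1.loc[a2.index].to_numpy(), a2.to_numpy()) == 1.0


class TestEigengenes:
    def test_singleton_module_kme_is_one(self, rng):
        values = pd.DataFrame(rng.normal(size=(3, 10)),
                              index=["a", "b", "c"],
                              columns=[f"s{i}" for i in range(10)])
        assign = pd.Series({"a": "M1", "b": "unassigned", "c": "unassigned"})
        ms = eigengenes_kme(values, assign)
        assert ms.kme.loc["a", "M1"] == pytest.approx(1.0)

    def test_two_gene_module_closed_form(self, rng):
        # kME of each gene = sqrt((1 + r)/2) for a two-gene module
        n = 2000
        f = rng.standard_normal(n)
        x1 = f + 0.5 * rng.standard_normal(n)
        x2 = f + 0.5 * rng.standard_normal(n)
        values = pd.DataFrame([x1, x2], index=["a", "b"],
                              columns=[f"s{i}" for i in range(n)])
        r = np.corrcoef(x1, x2)[0, 1]
        ms = eigengenes_kme(values, pd.Series({"a": "M1", "b": "M1"}))
        expected = math.sqrt((1 + r) / 2)
        assert abs(ms.kme.loc["a", "M1"]) == pytest.approx(expected, abs=1e-6)
        assert abs(ms.kme.loc["b", "M1"]) == pytest.approx(expected, abs=1e-6)

    def test_sign_orientation_mean_kme_nonnegative(self, rng):
        values, labels = block_values(rng, n_per_block=20, n_blocks=1)
        assign = pd.Series("M1", index=values.index)
        ms_pos = eigengenes_kme(values, assign)
        ms_neg = eigengenes_kme(-values, assign)
        assert ms_pos.kme["M1"].mean() >= 0
        assert ms_neg.kme["M1"].mean() >= 0

    def test_eigengene_matches_first_pc_of_standardized_module(self, rng):
        values, _ = block_values(rng, n_per_block=30, n_blocks=1)
        assign = pd.Series("M1", index=values.index)
        ms = eigengenes_kme(values, assign)
        z = ((values.T - values.T.mean()) / values.T.std(ddof=1)).T
        pc1 = PCA(n_components=1).fit_transform(z.to_numpy().T)[:, 0]
        r = abs(np.corrcoef(pc1, ms.eigengenes["M1"])[0, 1])
        assert r == pytest.approx(1.0, abs=1e-10)
        assert ms.eigengenes["M1"].std(ddof=1) == pytest.approx(1.0)

    def test_hubs_are_top_k_by_abs_kme(self, rng):
        values, labels = block_values(rng, n_per_block=30, n_blocks=1)
        assign = pd.Series("M1", index=values.index)
        ms = eigengenes_kme(values, assign, top_k=5)
        ranked = ms.kme["M1"].abs().sort_values(ascending=False)
        assert ms.hubs["M1"] == list(ranked.index[:5])


class TestModuleOverlap:
    def test_identical_two_way_partition_enumeration(self):
        genes = [f"g{i}" for i in range(10)]
        a = pd.Series(["M1"] * 5 + ["M2"] * 5, index=genes)
        out = module_overlap(a, a)
        diag = out[(out["module_a"] == "M1") & (out["module_b"] == "M1")]
        assert diag["p"].iloc[0] == pytest.approx(1 / math.comb(10, 5), rel=1e-9)

    def test_disjoint_modules_overlap_zero_p_one(self):
        genes = [f"g{i}" for i in range(10)]
        a = pd.Series(["M1"] * 5 + ["unassigned"] * 5, index=genes)
        b = pd.Series(["unassigned"] * 5 + ["M1"] * 5, index=genes)
        out = module_overlap(a, b)
        assert out["k"].iloc[0] == 0 and out["p"].iloc[0] == 1.0

    def test_random_partition_calibration(self, rng):
        """Fraction of pairs with p below the discrete 5% line matches the
        exact tail mass of the hypergeometric."""
        n_univ, size = 1000, 250
        genes = [f"g{i}" for i in range(n_univ)]
        hits = 0
        n_rep = 400
        # exact threshold: smallest k with upper-tail p ≤ 0.05
        from duosig.signature import hypergeom_tail
        k_star = next(k for k in range(size + 1)
                      if hypergeom_tail(k, size, size, n_univ) <= 0.05)
        expected = hypergeom_tail(k_star, size, size, n_univ)
        for _ in range(n_rep):
            overlap = len(set(rng.choice(n_univ, size, replace=False))
                          & set(rng.choice(n_univ, size, replace=False)))
            hits += overlap >= k_star
        se = math.sqrt(expected * (1 - expected) / n_rep)
        assert 0.02 <= expected <= 0.05
        assert abs(hits / n_rep - expected) < 4 * se


class TestTraitCorrelation:
    def test_trait_equal_to_eigengene(self, rng):
        e = pd.DataFrame({"M1": rng.normal(size=20)})
        out = trait_correlation(e, pd.DataFrame({"t": e["M1"]}))
        row = out.iloc[0]
        assert row["r"] == pytest.approx(1.0) and row["p"] == 0.0
        assert row["flag"] == "perfect_correlation"

    def test_trait_equal_to_negated_eigengene(self, rng):
        e = pd.DataFrame({"M1": rng.normal(size=20)})
        out = trait_correlation(e, pd.DataFrame({"t": -e["M1"]}))
        assert out.iloc[0]["r"] == pytest.approx(-1.0)

    def test_hand_built_vectors_match_direct_formula(self):
        e = pd.DataFrame({"M1": [1.0, 2.0, 3.0, 4.0, 5.0]})
        t = pd.DataFrame({"t": [2.0, 1.0, 4.0, 3.0, 6.0]})
        out = trait_correlation(e, t).iloc[0]
        r_ref, p_ref = stats.pearsonr(e["M1"], t["t"])
        assert out["r"] == pytest.approx(r_ref, rel=1e-12)
        assert out["p"] == pytest.approx(p_ref, rel=1e-9)

    def test_constant_trait_reported_missing_with_reason(self, rng):
        e = pd.DataFrame({"M1": rng.normal(size=10)})
        out = trait_correlation(e, pd.DataFrame({"t": [3.0] * 10}))
        assert np.isnan(out.iloc[0]["r"])
        assert out.iloc[0]["flag"] == "constant_input"

    def test_driving_trait_detected_on_synthetic_runs(self, default_runs):
        """The module driving a trait correlates more strongly with it than
        any other module (detected labels mapped to truth by majority vote)."""
        for truth, res in default_runs:
            assign = res.module_sets["OD"].assignment
            # detected label → dominant truth module
            detected_for = {}
            for m in set(assign) - {"unassigned"}:
                genes = assign.index[assign == m]
                counts = pd.Series([truth.module_assignment.get(g) for g in genes]
                                   ).value_counts()
                detected_for[counts.idxmax()] = m
            tc = res.trait_corr
            for trait, truth_module in truth.trait_map.items():
                sub = tc[tc["trait"] == trait].set_index("module")
                assert sub["r"].abs().idxmax() == detected_for[truth_module]


class TestSignatureEnrichment:
    def test_disjoint_signature_p_one(self):
        assign = pd.Series({"g1": "M1", "g2": "M1"})
        out = signature_module_enrichment({"x", "y"} , assign, ["M1"], 100)
        assert out.k == 0 and out.p == 1.0

    def test_matches_enumeration_oracle(self):
        assign = pd.Series({f"g{i}": "M1" for i in range(500)}
                           | {f"h{i}": "unassigned" for i in range(100)})
        sig = {f"g{i}" for i in range(14)} | {f"x{i}" for i in range(5)}
        out = signature_module_enrichment(sig, assign, ["M1"], 2000)
        total = math.comb(2000, 19)
        expected = sum(math.comb(500, i) * math.comb(1500, 19 - i)
                       for i in range(14, 20)) / total
        assert out.p == pytest.approx(expected, rel=1e-9)
        assert (out.k, out.K, out.n, out.N) == (14, 500, 19, 2000)

    def test_full_containment_minimal_p(self):
        assign = pd.Series({f"g{i}": "M1" for i in range(5)})
        sig = {f"g{i}" for i in range(5)}
        out = signature_module_enrichment(sig, assign, ["M1"], 30)
        assert out.p == pytest.approx(1 / math.comb(30, 5), rel=1e-9)
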