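import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pathconcord import (
    adjacency_matrix,
    call_edges,
    connectivity_significance,
    differential_expression,
    pick_soft_power,
    simulate_study,
    tom_from_adjacency,
    tom_matrix,
)
from pathconcord._stats import bh_qvalues
from pathconcord.io import ExpressionStudy
from pathconcord.network import TOMNetwork, de_class

from conftest import make_unpaired_study, null_design, planted_design


def brute_force_tom(A):
    """Independent triple-loop TOM oracle (zero-diagonal adjacency)."""
    n = A.shape[0]
    tom = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            ki = sum(A[i, u] for u in range(n) if u != i)
            kj = sum(A[j, u] for u in range(n) if u != j)
            tom[i, j] = (shared + A[i, j]) / (min(ki, kj) + 1.0 - A[i, j])
    return tom


def random_network(n_genes=10, n_samples=20, seed=0, beta=6):
    study = make_unpaired_study(n_genes=n_genes, n_case=n_samples // 2,
                                n_control=n_samples - n_samples // 2, seed=seed)
    return study, tom_matrix(study, beta)


class TestTOM:
    def test_perfect_module_gives_unit_tom(self):
        A = np.ones((3, 3)) - np.eye(3)
        np.testing.assert_allclose(tom_from_adjacency(A), np.ones((3, 3)))

    def test_empty_adjacency_gives_zero_tom(self):
        tom = tom_from_adjacency(np.zeros((4, 4)))
        np.testing.assert_allclose(tom - np.diag(np.diag(tom)), 0.0)
        np.testing.assert_allclose(np.diag(tom), 1.0)

    def test_matches_bruteforce_oracle(self):
        _, net = random_network(n_genes=10, n_samples=20, seed=3)
        np.testing.assert_allclose(
            net.tom, brute_force_tom(net.adjacency), atol=1e-10
        )

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_bounds_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 15))
        A = rng.uniform(0, 1, size=(n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        tom = tom_from_adjacency(A)
        assert np.all(tom >= -1e-12)
        assert np.all(tom <= 1.0 + 1e-12)
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)

    def test_sample_permutation_invariance(self):
        study, net = random_network(seed=5)
        perm = np.random.default_rng(1).permutation(study.matrix.shape[1])
        permuted = ExpressionStudy(
            "toy", study.matrix.iloc[:, perm], study.samples, "unpaired"
        )
        net2 = tom_matrix(permuted, 6)
        np.testing.assert_allclose(net.tom, net2.tom, atol=1e-12)

    def test_beta_monotonicity(self):
        study, _ = random_network(seed=6)
        X = study.matrix.to_numpy()
        a4 = adjacency_matrix(X, 4)
        a8 = adjacency_matrix(X, 8)
        assert np.all(a8 <= a4 + 1e-15)

    def test_zero_variance_gene_dropped(self, caplog):
        study = make_unpaired_study(n_genes=8, seed=7)
        X = study.matrix.to_numpy()
        X[0] = 5.0
        study.matrix.iloc[:, :] = X
        with caplog.at_level(logging.INFO, logger="pathconcord"):
            net = tom_matrix(study, 6)
        assert len(net.genes) == 7
        assert "G000" not in net.genes

    def test_signed_mode_bounds(self):
        study, _ = random_network(seed=8)
        net = tom_matrix(study, 6, mode="signed")
        assert np.all(net.adjacency >= 0)
        assert np.all(net.adjacency <= 1)
        off = net.offdiag_values()
        assert np.all(off >= -1e-12) and np.all(off <= 1 + 1e-12)

    def test_connectivity_excludes_diagonal(self):
        _, net = random_network(seed=9)
        k = net.connectivity
        expected = net.tom.sum(axis=1) - 1.0
        np.testing.assert_allclose(k.to_numpy(), expected, atol=1e-12)


class TestSoftPower:
    def test_noise_falls_back_to_default(self, caplog):
        study = make_unpaired_study(n_genes=300, n_case=15, n_control=15, seed=0)
        with caplog.at_level(logging.WARNING, logger="pathconcord"):
            beta, scan = pick_soft_power(study)
        assert beta == 6.0
        assert any("falling back" in r.message for r in caplog.records)

    def test_block_structure_reaches_scale_free_fit(self):
        # five modules (rho 0.7 hubs, 0.2 background members) + noise genes
        d = null_design(n_genes=350, n_case=30, n_control=30, seed=1,
                        set_sizes=(50, 50, 50, 50, 50))
        for gs in d.gene_sets:
            gs.n_hubs = 10
            gs.rho_hub = 0.7
            gs.rho_nonhub = 0.2
        study, _ = simulate_study(d, "s1")
        beta, scan = pick_soft_power(study)
        assert beta <= 12
        row = scan[scan["power"] == beta].iloc[0]
        assert row["r2"] >= 0.8 and row["slope"] < 0

    def test_deterministic(self):
        study = make_unpaired_study(n_genes=100, n_case=10, n_control=10, seed=2)
        assert pick_soft_power(study)[0] == pick_soft_power(study)[0]

    def test_preconditions(self):
        with pytest.raises(ValueError, match=">= 10 genes"):
            pick_soft_power(make_unpaired_study(n_genes=5))


class TestEdgeCalls:
    def test_top_quantile_keeps_exact_count(self):
        rng = np.random.default_rng(0)
        study = make_unpaired_study(n_genes=15, n_case=8, n_control=7, seed=1)
        net = tom_matrix(study, 6)
        assert net.offdiag_values().size == 105
        calls = call_edges(net, rule="top_quantile", top_q=3 / 105)
        assert len(calls.edges) == 3
        assert calls.edges["tom"].min() >= calls.threshold

    def test_ties_at_cutoff_all_kept(self, caplog):
        genes = [f"g{i}" for i in range(5)]
        tom = np.full((5, 5), 0.5)
        np.fill_diagonal(tom, 1.0)
        net = TOMNetwork(study="x", genes=genes, beta=6, mode="unsigned",
                         adjacency=tom, tom=tom)
        with caplog.at_level(logging.INFO, logger="pathconcord"):
            calls = call_edges(net, rule="top_quantile", top_q=0.1)
        assert len(calls.edges) == 10  # all pairs tie
        assert any("ties" in r.message for r in caplog.records)

    def test_bh_hand_example(self):
        np.testing.assert_allclose(
            bh_qvalues(np.array([0.01, 0.02, 0.03, 0.04])), 0.04
        )

    def test_fdr_rule_on_null_data_calls_no_edges(self):
        study = make_unpaired_study(n_genes=20, n_case=10, n_control=10, seed=4)
        net = tom_matrix(study, 6)
        calls = call_edges(net, study, rule="fdr", fdr_q=0.001, B=100, seed=0)
        assert len(calls.edges) == 0

    def test_fdr_rule_detects_planted_block(self):
        d = null_design(n_genes=30, n_case=25, n_control=25, seed=3, set_sizes=(10,))
        d.gene_sets[0].n_hubs = 10
        d.gene_sets[0].rho_hub = 0.8
        study, _ = simulate_study(d, "s1")
        net = tom_matrix(study, 6)
        calls = call_edges(net, study, rule="fdr", fdr_q=0.05, B=100, seed=0)
        block = {f"G{i:05d}" for i in range(10)}
        assert len(calls.edges) > 0
        in_block = calls.edges.apply(
            lambda e: e["gene_i"] in block and e["gene_j"] in block, axis=1
        )
        assert in_block.mean() > 0.8

    def test_combined_rule_is_intersection(self):
        d = null_design(n_genes=25, n_case=20, n_control=20, seed=5, set_sizes=(8,))
        d.gene_sets[0].n_hubs = 8
        d.gene_sets[0].rho_hub = 0.7
        study, _ = simulate_study(d, "s1")
        net = tom_matrix(study, 6)
        top = call_edges(net, study, rule="top_quantile", top_q=0.05)
        fdr = call_edges(net, study, rule="fdr", fdr_q=0.05, B=100, seed=1)
        both = call_edges(net, study, rule="combined", top_q=0.05, fdr_q=0.05,
                          B=100, seed=1)
        top_pairs = set(map(tuple, top.edges[["gene_i", "gene_j"]].to_numpy()))
        fdr_pairs = set(map(tuple, fdr.edges[["gene_i", "gene_j"]].to_numpy()))
        both_pairs = set(map(tuple, both.edges[["gene_i", "gene_j"]].to_numpy()))
        assert both_pairs == (top_pairs & fdr_pairs)

    def test_parameter_validation(self):
        _, net = random_network()
        with pytest.raises(ValueError, match="top_q"):
            call_edges(net, rule="top_quantile", top_q=1.5)
        with pytest.raises(ValueError, match="rule"):
            call_edges(net, rule="best")
        with pytest.raises(ValueError, match="expression matrix"):
            call_edges(net, rule="fdr")

    def test_components_and_graphml(self, tmp_path):
        study, net = random_network(n_genes=12, seed=2)
        de = differential_expression(study)
        calls = call_edges(net, rule="top_quantile", top_q=0.05, de=de)
        comps = calls.components()
        assert sum(len(c) for c in comps) >= 2
        calls.to_graphml(tmp_path / "net.graphml")
        assert (tmp_path / "net.graphml").exists()


class TestConnectivitySignificance:
    def test_zero_variance_connectivity_error(self):
        genes = [f"g{i}" for i in range(4)]
        tom = np.full((4, 4), 0.3)
        np.fill_diagonal(tom, 1.0)
        net = TOMNetwork(study="x", genes=genes, beta=6, mode="unsigned",
                         adjacency=tom, tom=tom)
        study = make_unpaired_study(n_genes=4, seed=0)
        study.matrix.index = genes
        de = differential_expression(study)
        with pytest.raises(ValueError, match="zero variance"):
            connectivity_significance(net, de)

    def test_small_example_matches_pearson_oracle(self):
        from scipy import stats as sps

        genes = [f"G{i:03d}" for i in range(4)]
        study = make_unpaired_study(n_genes=4, n_case=5, n_control=5, seed=3)
        de = differential_expression(study)
        k_target = np.array([3.0, 2.0, 1.0, 0.5])
        tom = np.diag(np.ones(4))
        net = TOMNetwork(study="x", genes=genes, beta=6, mode="unsigned",
                         adjacency=tom, tom=tom)
        # freeze a TOM whose connectivity equals k_target
        net.tom = np.diag(1.0 - k_target / 3.0) + np.tile(k_target / 3.0, (4, 1)).T
        r, p, tab = connectivity_significance(net, de)
        k = net.tom.sum(axis=1) - np.diag(net.tom)
        ref = sps.pearsonr(k, de.table["neglog10p"].to_numpy())
        assert r == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)
        assert list(tab.index) == [genes[i] for i in np.argsort(-k)]

    def test_hub_planted_association(self):
        d = planted_design(n_genes=200, set_size=60, effect=1.2, n_case=30,
                           n_control=30, seed=11, n_hubs=15, rho_hub=0.7,
                           rho_nonhub=0.1, effect_scope="hubs", studies=("s1",))
        study, _ = simulate_study(d, "s1")
        pathway = study.subset_features([f"G{i:05d}" for i in range(60)])
        net = tom_matrix(pathway, 6)
        de = differential_expression(study)
        r, _, _ = connectivity_significance(net, de)
        assert r > 0.4

    def test_de_class_labels(self):
        study = make_unpaired_study(n_genes=30, seed=12)
        de = differential_expression(study)
        cls = de_class(de)
        sig = de.table["p"] < 0.05
        assert set(cls[sig]) <= {"up-significant", "down-significant"}
        assert (cls[~sig] == "not-significant").all()
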