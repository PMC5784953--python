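"""The seven pathway-level tests: hand examples, oracles, invariants."""

import numpy as np
import pandas as pd
import pytest

import topopath as tp
from topopath.methods import (
    MethodConfig,
    accumulation,
    hotelling_f_pvalue,
    pci_scores,
    results_table,
    run_method,
    signed_adjacency,
    spectral_basis,
)
from topopath.methods.ggm import _DecomposableModel
from topopath.pathways import Edge
from tests.conftest import make_dataset


def chain_graph(*itypes):
    genes = tuple(chr(ord("A") + i) for i in range(len(itypes) + 1))
    edges = tuple(
        Edge(genes[i], genes[i + 1], True, t) for i, t in enumerate(itypes)
    )
    return tp.PathwayGraph("chain", genes, edges)


def manual_degs(genes, logfc, deg_genes, theta=0.05):
    p = np.where(np.isin(genes, list(deg_genes)), 0.01, 0.5)
    tbl = pd.DataFrame(
        {"logFC": logfc, "t": logfc, "p": p, "constant": False}, index=genes
    )
    return tp.DEGResult(tbl, d0=1.0, s0_sq=1.0, theta=theta,
                        deg_set=frozenset(deg_genes))


@pytest.fixture
def tiny_data():
    rng = np.random.default_rng(0)
    genes = [chr(ord("A") + i) for i in range(10)]
    X = rng.normal(5, 1, size=(10, 12))
    return make_dataset(X, [1] * 6 + [2] * 6, genes)


class TestSPIA:
    def test_chain_activation_propagates(self):
        g = chain_graph("activation")
        B = signed_adjacency(g, list(g.genes))
        pf, acc = accumulation(B, np.array([1.0, 0.0]))
        np.testing.assert_allclose(pf, [1.0, 1.0])
        np.testing.assert_allclose(acc, [0.0, 1.0])
        assert acc.sum() == pytest.approx(1.0)

    def test_inhibition_flips_sign(self):
        g = chain_graph("inhibition")
        B = signed_adjacency(g, list(g.genes))
        _, acc = accumulation(B, np.array([2.0, 0.0]))
        assert acc[1] == pytest.approx(-2.0)

    def test_accumulation_is_linear(self):
        rng = np.random.default_rng(1)
        g = chain_graph("activation", "inhibition", "activation", "activation")
        B = signed_adjacency(g, list(g.genes))
        de = rng.normal(size=5)
        _, acc1 = accumulation(B, de)
        _, acc3 = accumulation(B, 3.0 * de)
        np.testing.assert_allclose(acc3, 3.0 * acc1, atol=1e-12)

    def test_linear_solve_matches_fixed_point(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(4, 15))
            genes = tuple(f"v{i}" for i in range(n))
            edges = tuple(
                Edge(genes[i], genes[j], True,
                     "activation" if rng.random() < 0.7 else "inhibition")
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.3
            )
            g = tp.PathwayGraph("dag", genes, edges)
            B = signed_adjacency(g, list(genes))
            de = np.where(rng.random(n) < 0.3, rng.normal(size=n), 0.0)
            pf, acc = accumulation(B, de)
            # oracle: damped fixed-point iteration pf <- de + B pf
            x = de.copy()
            for _ in range(10000):
                x_new = de + B @ x
                if np.abs(x_new - x).max() < 1e-13:
                    x = x_new
                    break
                x = x_new
            np.testing.assert_allclose(pf, x, atol=1e-8)

    def test_no_degs_gives_p_one(self, tiny_data):
        g = chain_graph("activation")
        degs = manual_degs(list(tiny_data.genes), np.zeros(10), set())
        res = tp.spia(tiny_data, g, degs, MethodConfig(n_permutations=50, seed=0))
        assert res.p_value == 1.0
        assert res.extras["pNDE"] == 1.0

    def test_edgeless_reduces_to_over_representation(self, tiny_data):
        g = tp.strip_interactions(chain_graph("activation", "activation"))
        degs = manual_degs(list(tiny_data.genes), np.ones(10), {"A"})
        res = tp.spia(tiny_data, g, degs, MethodConfig(n_permutations=50, seed=0))
        assert res.extras["tA"] == 0.0
        assert res.p_value == pytest.approx(res.extras["pNDE"])


class TestPRS:
    def test_chain_hand_example(self, tiny_data):
        g = chain_graph("activation", "activation")  # A -> B -> C
        lfc = np.ones(10)
        degs = manual_degs(list(tiny_data.genes), lfc, {"A", "C"})
        res = tp.prs(tiny_data, g, degs, MethodConfig(n_permutations=20, seed=0))
        # w(A) = 1 + downstream DEGs {C} = 2; w(C) = 1; score = 1*2 + 1*1
        assert res.statistic == pytest.approx(3.0)

    def test_edgeless_score_is_plain_sum(self, tiny_data):
        g = tp.strip_interactions(chain_graph("activation", "activation"))
        lfc = np.linspace(0.5, 1.4, 10)
        degs = manual_degs(list(tiny_data.genes), lfc, {"A", "B"})
        res = tp.prs(tiny_data, g, degs, MethodConfig(n_permutations=20, seed=0))
        assert res.statistic == pytest.approx(abs(lfc[0]) + abs(lfc[1]))

    def test_score_linear_in_logfc(self, tiny_data):
        g = chain_graph("activation", "activation", "inhibition")
        lfc = np.linspace(-1, 1, 10)
        degs1 = manual_degs(list(tiny_data.genes), lfc, {"A", "D"})
        degs2 = manual_degs(list(tiny_data.genes), 2 * lfc, {"A", "D"})
        cfg = MethodConfig(n_permutations=50, seed=3)
        r1 = tp.prs(tiny_data, g, degs1, cfg)
        r2 = tp.prs(tiny_data, g, degs2, cfg)
        assert r2.statistic == pytest.approx(2 * r1.statistic)
        assert r2.p_value == pytest.approx(r1.p_value)

    def test_no_universe_degs_not_testable(self, tiny_data):
        g = chain_graph("activation")
        degs = manual_degs(list(tiny_data.genes), np.ones(10), set())
        res = tp.prs(tiny_data, g, degs, MethodConfig(n_permutations=20, seed=0))
        assert res.status == "not_testable"


class TestCePa:
    def test_star_center_scores(self, tiny_data):
        genes = ("A", "B", "C", "D", "E")
        edges = tuple(Edge("A", x, True, "activation") for x in genes[1:])
        g = tp.PathwayGraph("star", genes, edges)
        degs = manual_degs(list(tiny_data.genes), np.ones(10), {"A"})
        res = tp.cepa_ora(tiny_data, g, degs, MethodConfig(n_permutations=50, seed=0))
        assert res.extras["score_out_degree"] == pytest.approx(4.0)
        assert res.extras["score_equal_weight"] == pytest.approx(1.0)
        assert res.extras["score_in_degree"] == pytest.approx(0.0)

    def test_edgeless_only_equal_weight_informative(self, tiny_data):
        g = tp.strip_interactions(chain_graph("activation", "activation"))
        degs = manual_degs(list(tiny_data.genes), np.ones(10), {"A", "B"})
        res = tp.cepa_ora(tiny_data, g, degs, MethodConfig(n_permutations=100, seed=0))
        for name in ("in_degree", "out_degree", "betweenness", "in_reach", "out_reach"):
            assert res.extras[f"score_{name}"] == 0.0
        assert res.extras["score_equal_weight"] == 2.0


class TestTAPPA:
    def test_edgeless_pci_closed_form(self, tiny_data):
        g = tp.strip_interactions(chain_graph("activation", "activation", "activation"))
        nodes, pci = pci_scores(tiny_data, g)
        rows = tiny_data.genes.get_indexer(nodes)
        X = tiny_data.X[rows]
        z = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        expected = np.abs(z).sum(axis=0) / len(nodes)
        np.testing.assert_allclose(pci, expected, atol=1e-12)

    def test_pci_invariant_to_relabeling(self, tiny_data):
        g = chain_graph("activation", "activation")
        _, pci = pci_scores(tiny_data, g)
        relabeled = make_dataset(tiny_data.X, np.where(tiny_data.y == 1, 2, 1),
                                 list(tiny_data.genes))
        _, pci2 = pci_scores(relabeled, g)
        np.testing.assert_allclose(pci, pci2, atol=1e-15)

    def test_identical_groups_give_high_p(self):
        rng = np.random.default_rng(4)
        half = rng.normal(size=(5, 8))
        X = np.concatenate([half, half], axis=1)  # both groups identical
        data = make_dataset(X, [1] * 8 + [2] * 8, list("ABCDE"))
        g = chain_graph("activation", "activation")
        res = tp.tappa(data, g, cfg=MethodConfig())
        assert res.p_value > 0.9


class TestDecomposableGGM:
    @staticmethod
    def random_graph_and_data(rng, n_nodes, n_samples):
        genes = tuple(f"v{i}" for i in range(n_nodes))
        edges = tuple(
            Edge(genes[i], genes[j], True, "activation")
            for i in range(n_nodes)
            for j in range(i + 1, n_nodes)
            if rng.random() < 0.35
        )
        g = tp.PathwayGraph("r", genes, edges)
        X = rng.normal(size=(n_nodes, n_samples))
        return g, genes, X

    def test_constrained_mle_matches_clique_marginals(self):
        rng = np.random.default_rng(12)
        for _ in range(8):
            g, genes, X = self.random_graph_and_data(rng, int(rng.integers(4, 9)), 40)
            decomp = tp.decompose_to_cliques(g, set(genes))
            model = _DecomposableModel(decomp, list(genes))
            Xc = X - X.mean(1, keepdims=True)
            S = (Xc @ Xc.T / X.shape[1])[None]
            K, logdet, ok = model.fit(S)
            assert ok[0]
            sigma = np.linalg.inv(K[0])
            for idx in model.cliques:
                np.testing.assert_allclose(
                    sigma[np.ix_(idx, idx)], S[0][np.ix_(idx, idx)], atol=1e-8
                )
            sign, ld = np.linalg.slogdet(sigma)
            assert sign > 0
            assert ld == pytest.approx(logdet[0], abs=1e-8)

    def test_not_testable_exactly_when_samples_too_few(self):
        rng = np.random.default_rng(5)
        genes = tuple(f"v{i}" for i in range(6))
        # co-parent fan: five parents of one child -> one 6-clique after moralization
        edges = tuple(Edge(p, "v5", True, "activation") for p in genes[:5])
        g = tp.PathwayGraph("fan", genes, edges)
        X = rng.normal(size=(6, 12))
        data6 = make_dataset(X, [1] * 6 + [2] * 6, list(genes))
        res = tp.topology_gsa(data6, g, cfg=MethodConfig(n_permutations=20, seed=0))
        assert res.status == "not_testable"  # min group = 6 = clique size
        X2 = rng.normal(size=(6, 14))
        data7 = make_dataset(X2, [1] * 7 + [2] * 7, list(genes))
        res2 = tp.topology_gsa(data7, g, cfg=MethodConfig(n_permutations=20, seed=0))
        assert res2.status == "ok"

    def test_clipper_without_shrinkage_equals_topologygsa(self):
        rng = np.random.default_rng(6)
        g, genes, X = self.random_graph_and_data(rng, 6, 60)
        data = make_dataset(X, [1] * 30 + [2] * 30, list(genes))
        cfg = MethodConfig(n_permutations=50, seed=9, clipper_shrinkage=False)
        r_gsa = tp.topology_gsa(data, g, cfg=cfg)
        r_cl = tp.clipper(data, g, cfg=cfg)
        assert r_cl.statistic == pytest.approx(r_gsa.statistic, abs=1e-6)
        assert r_cl.p_value == pytest.approx(r_gsa.p_value, abs=1e-12)

    def test_clipper_handles_wide_clique(self):
        rng = np.random.default_rng(8)
        genes = tuple(f"v{i}" for i in range(30))
        edges = tuple(
            Edge(genes[i], genes[j], False, "binding")
            for i in range(30)
            for j in range(i + 1, 30)
        )
        g = tp.PathwayGraph("clique30", genes, edges)
        X = rng.normal(size=(30, 20))
        data = make_dataset(X, [1] * 10 + [2] * 10, list(genes))
        cfg = MethodConfig(n_permutations=30, seed=2)
        assert tp.topology_gsa(data, g, cfg=cfg).status == "not_testable"
        res = tp.clipper(data, g, cfg=cfg)
        assert res.status == "ok"
        assert 0 < res.p_value <= 1

    def test_edgeless_graph_uses_diagonal_model(self):
        rng = np.random.default_rng(10)
        genes = tuple("ABCD")
        g = tp.PathwayGraph("e", genes, ())
        X = rng.normal(size=(4, 30))
        data = make_dataset(X, [1] * 15 + [2] * 15, list(genes))
        res = tp.topology_gsa(data, g, cfg=MethodConfig(n_permutations=50, seed=1))
        assert res.status == "ok"
        assert res.extras["max_clique_size"] == 1


class TestDEGraph:
    def test_two_node_component_spectrum(self):
        g = tp.PathwayGraph("ab", ("A", "B"), (Edge("A", "B", False, "binding"),))
        evals, evecs = spectral_basis(g, ("A", "B"))
        np.testing.assert_allclose(evals, [0.0, 2.0], atol=1e-12)
        np.testing.assert_allclose(np.abs(evecs[:, 0]), [1 / np.sqrt(2)] * 2, atol=1e-12)

    def test_full_basis_equals_classical_hotelling(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            m = int(rng.integers(2, 6))
            genes = tuple(f"v{i}" for i in range(m))
            edges = tuple(
                Edge(genes[i], genes[i + 1], True, "activation") for i in range(m - 1)
            )
            g = tp.PathwayGraph("c", genes, edges)
            X = rng.normal(size=(m, 40))
            data = make_dataset(X, [1] * 22 + [2] * 18, list(genes))
            cfg = MethodConfig(degraph_energy_fraction=1.0)
            res = tp.degraph(data, g, cfg=cfg)
            ref = hotelling_f_pvalue(X, data.group_columns(1), data.group_columns(2))
            assert res.p_value == pytest.approx(ref[1], abs=1e-10)

    def test_edgeless_pathway_per_gene_bonferroni(self):
        from scipy import stats as sps

        rng = np.random.default_rng(14)
        genes = tuple("ABC")
        g = tp.PathwayGraph("e", genes, ())
        X = rng.normal(size=(3, 20))
        data = make_dataset(X, [1] * 10 + [2] * 10, list(genes))
        res = tp.degraph(data, g, cfg=MethodConfig())
        ps = []
        for row in X:
            t, p = sps.ttest_ind(row[10:], row[:10], equal_var=True)
            ps.append(p)
        assert res.p_value == pytest.approx(min(1.0, 3 * min(ps)), abs=1e-10)


class TestRunnerAndInvariants:
    def test_unknown_method_rejected(self, small_null_data):
        with pytest.raises(ValueError, match="unknown method"):
            run_method("notamethod", small_null_data, [])

    def test_empty_pathway_list(self, small_null_data):
        assert run_method("spia", small_null_data, []) == []

    def test_determinism_and_uniqueness(self, small_null_data, toy_suite):
        pws = [toy_suite["chain"], toy_suite["star"], toy_suite["triangle"]]
        cfg = MethodConfig(n_permutations=50, seed=42)
        t1 = results_table(run_method("prs", small_null_data, pws, cfg))
        t2 = results_table(run_method("prs", small_null_data, pws, cfg))
        pd.testing.assert_frame_equal(t1, t2)
        assert t1["pathway_id"].is_unique

    def test_permutation_p_never_zero(self, small_null_data, toy_suite):
        cfg = MethodConfig(n_permutations=19, seed=0)
        for name in ("prs", "cepa", "topologygsa", "clipper"):
            res = run_method(name, small_null_data, [toy_suite["chain"]], cfg)[0]
            if res.p_value is not None:
                assert 1 / 20 <= res.p_value <= 1

    def test_self_contained_vs_competitive_background_sensitivity(self, toy_suite):
        rng = np.random.default_rng(21)
        g = toy_suite["random_dag30"]
        base_genes = list(g.genes)
        decoys = [f"z{i:04d}" for i in range(300)]
        n = 30
        y = [1] * 18 + [2] * 12
        X_path = rng.normal(6, 1, size=(len(base_genes), n))
        X_path[:5, 18:] += 0.8  # some signal inside the pathway
        X_decoy = rng.normal(6, 1, size=(300, n))
        X_decoy[:40, 18:] += 0.8  # and among the decoys
        small = make_dataset(
            np.vstack([X_path, X_decoy[:50]]), y, base_genes + decoys[:50]
        )
        large = make_dataset(
            np.vstack([X_path, X_decoy]), y, base_genes + decoys
        )
        cfg = MethodConfig(n_permutations=100, seed=5)
        for name in ("tappa", "topologygsa", "clipper", "degraph"):
            p_small = run_method(name, small, [g], cfg)[0].p_value
            p_large = run_method(name, large, [g], cfg)[0].p_value
            assert p_small == pytest.approx(p_large, abs=1e-12), name
        changed = []
        for name in ("spia", "prs", "cepa"):
            p_small = run_method(name, small, [g], cfg)[0].p_value
            p_large = run_method(name, large, [g], cfg)[0].p_value
            changed.append(p_small != p_large)
        assert any(changed)
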