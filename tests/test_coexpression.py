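import numpy as np
import pandas as pd
import pytest

from netconverge import (
    ModulePartition,
    SimConfig,
    bicor_matrix,
    consensus_modules,
    consensus_tom,
    cut_modules,
    diffcoex_tom,
    differential_modules,
    gen_expression_panel,
    module_eigengene,
    select_soft_threshold,
    tom,
)
from netconverge.coexpression import build_similarity_stack
from netconverge.preprocess import ExpressionPanel

from .oracles import tom_oracle


def _df(arr, prefix="g"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"s{j}" for j in range(arr.shape[1])],
    )


def _random_adjacency(rng, n):
    a = np.abs(rng.normal(size=(n, n)))
    a = (a + a.T) / 2
    a /= a.max()
    np.fill_diagonal(a, 1.0)
    return a


class TestBicor:
    def test_self_and_mirror_correlation(self, rng):
        x = rng.normal(size=30)
        df = _df(np.vstack([x, -x]))
        b = bicor_matrix(df).values
        assert b[0, 0] == pytest.approx(1.0)
        assert b[0, 1] == pytest.approx(-1.0)

    def test_close_to_pearson_for_clean_gaussian(self):
        rng = np.random.default_rng(7)
        z = rng.multivariate_normal([0, 0], [[1, 0.7], [0.7, 1]], size=200)
        df = _df(z.T)
        b = bicor_matrix(df).values[0, 1]
        p = np.corrcoef(z.T)[0, 1]
        assert abs(b - p) < 0.05

    def test_zero_mad_falls_back_to_pearson(self, rng):
        x = rng.normal(size=20)
        flat = np.zeros(20)
        flat[0] = 1.0  # median-absolute-deviation is 0, variance is not
        df = _df(np.vstack([x, flat]))
        with pytest.warns(UserWarning, match="zero MAD"):
            b = bicor_matrix(df).values
        expected = np.corrcoef(x, flat)[0, 1]
        assert abs(b[0, 1]) <= 1

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            bicor_matrix(_df(rng.normal(size=(5, 3))))


class TestSoftThreshold:
    def test_scale_free_graph_reaches_criterion(self):
        import networkx as nx

        g = nx.barabasi_albert_graph(500, 3, seed=0)
        corr = nx.to_numpy_array(g)
        np.fill_diagonal(corr, 1.0)
        beta, fit = select_soft_threshold(corr, list(range(1, 13)))
        assert fit["fit_index"].max() > 0.8
        assert beta <= 12

    def test_single_candidate_returned_as_given(self, rng):
        corr = np.clip(rng.normal(0, 0.2, (80, 80)), -1, 1)
        corr = (corr + corr.T) / 2
        np.fill_diagonal(corr, 1.0)
        import warnings

        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            beta, fit = select_soft_threshold(corr, [7])
        assert beta == 7
        index = fit["fit_index"].iloc[0]
        assert (len(caught) > 0) == (index <= 0.8)

    def test_identity_correlation_rejected(self):
        with pytest.raises(ValueError):
            select_soft_threshold(np.eye(20), [6])


class TestTom:
    def test_triangle_graph_is_fully_overlapping(self):
        a = np.ones((3, 3))
        t = tom(a)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(t[off], 1.0)

    def test_disconnected_pair_is_zero(self):
        a = np.eye(4)
        a[0, 1] = a[1, 0] = 1.0  # one isolated edge; nodes 2,3 disconnected
        t = tom(a)
        assert t[2, 3] == 0.0

    def test_star_centre_leaf_overlap_is_one(self):
        n = 5
        a = np.eye(n)
        a[0, 1:] = a[1:, 0] = 1.0
        t = tom(a)
        assert np.allclose(t[0, 1:], 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = _random_adjacency(rng, 20)
        assert np.abs(tom(a) - tom_oracle(a)).max() < 1e-12

    def test_asymmetric_adjacency_rejected(self, rng):
        a = rng.random((5, 5))
        with pytest.raises(ValueError):
            tom(a)


class TestConsensusTom:
    def test_identical_toms_pass_through(self, rng):
        t = tom(_random_adjacency(rng, 30))
        cons = consensus_tom({"a": t, "b": t.copy()})
        assert np.allclose(cons, t)

    def test_power_related_toms_calibrate_exactly(self, rng):
        t = tom(_random_adjacency(rng, 30))
        cons = consensus_tom({"a": t, "b": t**2})
        assert np.abs(cons - t).max() < 1e-8

    def test_consensus_never_exceeds_reference(self, rng):
        t1 = tom(_random_adjacency(rng, 25))
        t2 = tom(_random_adjacency(rng, 25))
        cons = consensus_tom({"a": t1, "b": t2})
        assert (cons <= t1 + 1e-12).all()

    def test_single_condition_rejected(self, rng):
        with pytest.raises(ValueError):
            consensus_tom({"a": tom(_random_adjacency(rng, 10))})


class TestDiffcoex:
    def test_identical_adjacencies_give_no_structure(self, rng):
        a = _random_adjacency(rng, 20)
        dis = diffcoex_tom({"a": a, "b": a.copy(), "c": a.copy()})
        off = ~np.eye(20, dtype=bool)
        assert np.allclose(dis[off], 1.0)
        assert np.allclose(np.diag(dis), 0.0)

    def test_condition_specific_module_stands_out(self, small_study):
        panel, truth = small_study
        stack = build_similarity_stack(panel, beta=7)
        dis = diffcoex_tom(stack.adjacency)
        genes = panel.gene_universe
        idx = {g: i for i, g in enumerate(genes)}
        diff_genes = [idx[g] for g in truth.true_partition.module_genes(truth.differential_modules[0])]
        bg = [idx[g] for g, l in truth.true_partition.assignment.items() if l == "unassigned"]
        within = dis[np.ix_(diff_genes, diff_genes)][np.triu_indices(len(diff_genes), 1)].mean()
        background = dis[np.ix_(bg[:100], bg[:100])][np.triu_indices(100, 1)].mean()
        assert within < background

    def test_single_condition_rejected(self, rng):
        with pytest.raises(ValueError):
            diffcoex_tom({"a": _random_adjacency(rng, 10)})


class TestCutModules:
    def test_recovers_planted_modules(self, small_study):
        panel, truth = small_study
        partition = consensus_modules(panel)
        for lab in truth.consensus_modules:
            true_genes = set(truth.true_partition.module_genes(lab))
            best = max(
                len(true_genes & set(partition.module_genes(m)))
                / len(true_genes | set(partition.module_genes(m)))
                for m in partition.labels
            )
            assert best > 0.9

    def test_pure_noise_leaves_genes_unassigned(self):
        config = SimConfig(
            n_genes=300,
            n_conditions=2,
            n_samples_per_condition=40,
            module_sizes=[50],
            n_differential_modules=0,
            n_hidden_factors=0,
            module_signal_sd=0.0,
            seed=3,
        )
        panel, _ = gen_expression_panel(config)
        partition = consensus_modules(panel)
        frac_unassigned = np.mean(
            [partition.assignment[g] == "unassigned" for g in panel.gene_universe]
        )
        assert frac_unassigned >= 0.9

    def test_modules_sharing_a_factor_are_merged(self, rng):
        factor = rng.normal(size=60)
        block = np.vstack(
            [2 * factor + rng.normal(size=60) for _ in range(100)]
        )
        mat = _df(block)
        panel = ExpressionPanel(conditions=["c"], matrices={"c": mat})
        partition = consensus_modules(panel, min_module_size=40)
        assert len(partition.labels) == 1
        assert len(partition.module_genes(partition.labels[0])) >= 80

    def test_fewer_genes_than_min_size_all_unassigned(self, rng):
        d = np.abs(rng.normal(size=(10, 10)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dis = pd.DataFrame(d, index=[f"g{i}" for i in range(10)], columns=[f"g{i}" for i in range(10)])
        mat = _df(rng.normal(size=(10, 20)))
        panel = ExpressionPanel(conditions=["c"], matrices={"c": mat})
        with pytest.warns(UserWarning, match="fewer genes"):
            partition = cut_modules(dis, panel, min_module_size=40)
        assert partition.labels == []

    def test_differential_module_recovered_by_diffcoex(self, small_study):
        panel, truth = small_study
        partition = differential_modules(panel)
        true_genes = set(
            truth.true_partition.module_genes(truth.differential_modules[0])
        )
        best = max(
            len(true_genes & set(partition.module_genes(m)))
            / len(true_genes | set(partition.module_genes(m)))
            for m in partition.labels
        )
        assert best >= 0.7


class TestEigengene:
    def test_identical_rows_give_that_profile(self, rng):
        x = rng.normal(size=20)
        mat = _df(np.tile(x, (5, 1)))
        eig = module_eigengene(mat, list(mat.index))
        z = (x - x.mean()) / x.std()
        assert eig.variance_explained == pytest.approx(1.0)
        assert np.allclose(np.abs(eig.scores.values), np.abs(z), atol=1e-8)

    def test_antipodal_rows_are_rank_one(self, rng):
        x = rng.normal(size=15)
        mat = _df(np.vstack([x, -x]))
        eig = module_eigengene(mat, list(mat.index))
        assert eig.variance_explained == pytest.approx(1.0)

    def test_recovers_planted_factor(self, rng):
        factor = rng.normal(size=50)
        mat = _df(np.vstack([2 * factor + rng.normal(size=50) for _ in range(50)]))
        eig = module_eigengene(mat, list(mat.index))
        r = np.corrcoef(eig.scores.values, factor)[0, 1]
        assert abs(r) > 0.95
        # sign orientation: positively correlated with the (mostly positive) module
        assert r > 0

    def test_single_gene_module(self, rng):
        mat = _df(rng.normal(size=(3, 10)))
        eig = module_eigengene(mat, ["g0"])
        assert eig.variance_explained == 1.0
        assert eig.scores.std(ddof=0) == pytest.approx(1.0)

    def test_empty_module_rejected(self, rng):
        with pytest.raises(ValueError):
            module_eigengene(_df(rng.normal(size=(3, 10))), [])


class TestNewickExport:
    def test_newick_parses_and_preserves_cophenetic_heights(self, rng):
        from io import StringIO

        from Bio import Phylo
        from netconverge.coexpression import dendrogram_newick

        d = np.abs(rng.normal(size=(8, 8)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        genes = [f"g{i}" for i in range(8)]
        dis = pd.DataFrame(d, index=genes, columns=genes)
        newick = dendrogram_newick(dis)
        tree = Phylo.read(StringIO(newick), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(genes)
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        Z = linkage(squareform(d, checks=False), method="average")
        coph = squareform(cophenet(Z))
        i, j = genes.index("g0"), genes.index("g5")
        # leaf-to-leaf path length in an ultrametric tree is twice the
        # cophenetic merge height
        assert tree.distance("g0", "g5") == pytest.approx(2 * coph[i, j], rel=1e-4)
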