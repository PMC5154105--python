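import numpy as np
import pandas as pd
import pytest

from netconverge import (
    SimConfig,
    dnm_fet,
    gen_disease_de,
    gen_dnm_catalog,
    gen_expression_panel,
    gen_gene_pvalues,
    gen_ppi,
    gwas_set_enrichment,
    ppi_node_enrichment,
)
from netconverge.synthetic_data import write_study


class TestSimConfig:
    def test_oversized_modules_rejected(self):
        with pytest.raises(ValueError, match="module sizes"):
            SimConfig(n_genes=100, module_sizes=[80, 30])

    def test_bad_counts_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_genes=0)


class TestExpressionPanel:
    def test_shapes_follow_config(self):
        config = SimConfig(
            n_genes=500, n_conditions=4, n_samples_per_condition=30,
            module_sizes=[100, 80, 60], n_differential_modules=0, seed=0,
        )
        panel, truth = gen_expression_panel(config)
        assert len(panel.conditions) == 4
        for c in panel.conditions:
            assert panel.matrices[c].shape == (500, 30)
        assert set(truth.true_partition.labels) == {"M1", "M2", "M3"}

    def test_determinism_byte_identical(self):
        config = SimConfig(n_genes=200, n_conditions=2, n_samples_per_condition=15,
                           module_sizes=[50], seed=9)
        a, _ = gen_expression_panel(config)
        b, _ = gen_expression_panel(config)
        for c in a.conditions:
            assert a.matrices[c].to_csv() == b.matrices[c].to_csv()

    def test_no_signal_no_module_structure(self):
        config = SimConfig(
            n_genes=300, n_conditions=1, n_samples_per_condition=100,
            module_sizes=[60], n_differential_modules=0, n_hidden_factors=0,
            module_signal_sd=0.0, seed=4,
        )
        panel, truth = gen_expression_panel(config)
        x = panel.matrices["R1"]
        corr = np.corrcoef(x)
        idx = [i for i, g in enumerate(panel.gene_universe)
               if truth.true_partition.assignment[g] == "M1"]
        bg = [i for i in range(300) if i not in idx][:60]
        within = np.abs(corr[np.ix_(idx, idx)][np.triu_indices(60, 1)]).mean()
        between = np.abs(corr[np.ix_(bg, bg)][np.triu_indices(60, 1)]).mean()
        assert abs(within - between) < 0.05

    def test_planted_module_strongly_correlated(self):
        config = SimConfig(
            n_genes=300, n_conditions=1, n_samples_per_condition=100,
            module_sizes=[60], n_differential_modules=0, n_hidden_factors=0,
            module_signal_sd=2.0, noise_sd=1.0, seed=1,
        )
        panel, truth = gen_expression_panel(config)
        x = panel.matrices["R1"]
        idx = [i for i, g in enumerate(panel.gene_universe)
               if truth.true_partition.assignment[g] == "M1"]
        corr = np.corrcoef(x)
        within = corr[np.ix_(idx, idx)][np.triu_indices(60, 1)].mean()
        # factor model with mostly-positive loadings: r = s^2/(s^2+sigma^2) = 0.8
        assert within > 0.5


class TestDnmCatalog:
    def test_trio_counts_match_design(self, small_study):
        _, truth = small_study
        catalog = gen_dnm_catalog(truth, n_case_trios=356, n_control_trios=1891, seed=0)
        assert catalog.trio_counts == {"case": 356, "control": 1891}

    def test_null_factor_gives_null_or(self, small_study):
        _, truth = small_study
        ors = []
        for rep in range(50):
            catalog = gen_dnm_catalog(
                truth, 300, 600, base_rate=2.0, enrichment_factor=1.0, seed=rep
            )
            res = dnm_fet(
                catalog, truth.disease_genes(),
                set(truth.true_partition.assignment), "case", "control",
            )
            ors.append(res.statistic)
        assert 0.8 < np.median(ors) < 1.25

    def test_monotone_in_enrichment_factor(self, small_study):
        _, truth = small_study
        meds = []
        for factor in (1.0, 2.0, 5.0):
            ors = []
            for rep in range(20):
                catalog = gen_dnm_catalog(
                    truth, 300, 600, base_rate=1.0, enrichment_factor=factor, seed=rep
                )
                res = dnm_fet(
                    catalog, truth.disease_genes(),
                    set(truth.true_partition.assignment), "case", "control",
                )
                ors.append(res.statistic)
            meds.append(np.median(ors))
        assert meds[0] <= meds[1] <= meds[2]


class TestGenePvalues:
    def test_monotone_in_shift(self, small_study):
        _, truth = small_study
        background = set(truth.true_partition.assignment)
        meds = []
        for shift in (0.0, 0.3, 0.8):
            zs = []
            for rep in range(15):
                table = gen_gene_pvalues(truth, shift=shift, seed=rep)
                res = gwas_set_enrichment(
                    table, truth.disease_genes(), background, n_boot=200, seed=rep
                )
                zs.append(res.statistic)
            meds.append(np.median(zs))
        assert meds[0] <= meds[1] <= meds[2]

    def test_no_snp_genes_flagged(self, small_study):
        _, truth = small_study
        table = gen_gene_pvalues(truth, shift=0.0, no_snp_fraction=0.2, seed=0)
        frac = (table.table["n_snps"] == 0).mean()
        assert 0.1 < frac < 0.3
        assert not (table.testable() <= 0).any()


class TestPpiGenerator:
    def test_no_self_loops_or_duplicates(self, small_study):
        _, truth = small_study
        net = gen_ppi(truth, n_edges=500, intra_module_extra=100, seed=0)
        seen = set()
        for a, b in net.edges:
            assert a != b
            key = (min(a, b), max(a, b))
            assert key not in seen
            seen.add(key)

    def test_monotone_in_planted_edges(self, small_study):
        _, truth = small_study
        background = set(truth.true_partition.assignment)
        stats = []
        for extra in (0, 100, 300):
            net = gen_ppi(truth, n_edges=500, intra_module_extra=extra, seed=1)
            res = ppi_node_enrichment(
                net, truth.disease_genes(), background, n_perm=100, seed=1
            )
            stats.append(res.statistic)
        assert stats[0] <= stats[1] <= stats[2]

    def test_degree_distribution_is_heterogeneous(self, small_study):
        _, truth = small_study
        net = gen_ppi(truth, n_edges=2000, intra_module_extra=0, seed=2)
        degrees = pd.Series([g for e in net.edges for g in e]).value_counts()
        assert degrees.max() > 4 * degrees.median()


class TestDiseaseDe:
    def test_seizures_anticorrelated_with_module_factor(self, small_study):
        _, truth = small_study
        _, seizures, _ = gen_disease_de(truth, down_effect=1.0, n_drugs=5, seed=0)
        r = np.corrcoef(seizures.values, truth.disease_factor.values)[0, 1]
        assert r < -0.3

    def test_null_effect_gives_centred_logfc(self, small_study):
        _, truth = small_study
        de, _, _ = gen_disease_de(truth, down_effect=0.0, n_drugs=2, seed=0)
        module_fc = de.set_index("gene").loc[sorted(truth.disease_genes()), "log2fc"]
        assert abs(module_fc.mean()) < 0.1

    def test_down_effect_shifts_module(self, small_study):
        _, truth = small_study
        de, _, _ = gen_disease_de(truth, down_effect=1.0, n_drugs=2, seed=0)
        module_fc = de.set_index("gene").loc[sorted(truth.disease_genes()), "log2fc"]
        assert module_fc.mean() < -0.7

    def test_library_contains_one_true_drug(self, small_study):
        _, truth = small_study
        _, _, library = gen_disease_de(truth, down_effect=1.0, n_drugs=20, seed=0)
        names = [s.drug for s in library.signatures]
        assert names.count(truth.drug_true_name) == 1
        assert len(names) == 20


class TestSerialisation:
    def test_write_study_roundtrips_core_files(self, tmp_path, small_study):
        panel, truth = small_study
        catalog = gen_dnm_catalog(truth, 50, 100, seed=0)
        table = gen_gene_pvalues(truth, seed=0)
        net = gen_ppi(truth, n_edges=200, intra_module_extra=0, seed=0)
        de, seizures, library = gen_disease_de(truth, n_drugs=3, seed=0)
        write_study(tmp_path, panel, truth, catalog, table, net, de, seizures, library)
        from netconverge import io

        mat = io.read_matrix(tmp_path / "expression_R1.tsv")
        assert mat.shape == panel.matrices["R1"].shape
        part = io.read_partition(tmp_path / "true_partition.tsv")
        assert part == truth.true_partition.assignment
        up = io.read_gmt(tmp_path / "drug_up.gmt")
        assert truth.drug_true_name in up
        edges = io.read_edges(tmp_path / "ppi_edges.tsv")
        assert len(edges) == net.n_edges
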