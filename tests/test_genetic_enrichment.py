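import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest
from statsmodels.stats.multitest import multipletests

from netconverge import (
    DNMCatalog,
    GenePValueTable,
    GroundTruth,
    ModulePartition,
    bh_adjust,
    dnm_fet,
    fisher_test_2x2,
    gen_dnm_catalog,
    gen_gene_pvalues,
    gwas_set_enrichment,
)

from .oracles import fisher_oracle


def _toy_truth(n_genes=400, module_size=60, seed_labels=True):
    genes = [f"G{i:04d}" for i in range(n_genes)]
    assign = {g: ("M1" if i < module_size else "unassigned") for i, g in enumerate(genes)}
    return GroundTruth(
        true_partition=ModulePartition(assign),
        disease_module="M1",
        consensus_modules=["M1"],
        differential_modules=[],
        differential_conditions={},
    )


class TestFisherMachinery:
    @pytest.mark.parametrize(
        "table",
        [
            [[20, 180], [10, 390]],
            [[3, 0], [0, 3]],
            [[0, 10], [10, 0]],
            [[50, 450], [50, 450]],
            [[1, 1], [1, 1]],
        ],
    )
    def test_p_matches_enumeration_oracle(self, table):
        res = fisher_test_2x2(table)
        assert res.p_value == pytest.approx(fisher_oracle(table), abs=1e-12)

    def test_known_odds_ratio_and_ci(self):
        res = fisher_test_2x2([[20, 180], [10, 390]])
        assert res.statistic == pytest.approx(20 * 390 / (180 * 10))
        assert res.ci_low < res.statistic < res.ci_high

    def test_independence_table_is_null(self):
        res = fisher_test_2x2([[50, 450], [50, 450]])
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_haldane_correction_on_zero_cell(self):
        res = fisher_test_2x2([[3, 0], [0, 3]])
        assert res.statistic == pytest.approx(49.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="no mutations"):
            fisher_test_2x2([[0, 0], [0, 0]])

    @given(st.lists(st.integers(0, 40), min_size=4, max_size=4))
    @settings(max_examples=60, deadline=None)
    def test_oracle_agreement_on_random_tables(self, cells):
        table = [cells[:2], cells[2:]]
        if sum(cells) == 0:
            return
        for alt in ("two-sided", "greater", "less"):
            assert fisher_test_2x2(table, alternative=alt).p_value == pytest.approx(
                fisher_oracle(table, alt), abs=1e-12
            )

    def test_bh_matches_reference_step_up(self, rng):
        p = rng.uniform(size=200)
        ours = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, ref, atol=1e-15)


class TestDnmFet:
    def _catalog(self, case_counts, control_counts):
        rows = []
        for g, n in case_counts.items():
            rows.append((g, "case", "nonsynonymous", n))
        for g, n in control_counts.items():
            rows.append((g, "control", "nonsynonymous", n))
        return DNMCatalog(
            counts=pd.DataFrame(rows, columns=["gene", "cohort", "mut_class", "count"]),
            trio_counts={"case": 100, "control": 100},
        )

    def test_table_construction_and_p(self):
        catalog = self._catalog({"g1": 20, "g2": 180}, {"g1": 10, "g2": 390})
        res = dnm_fet(catalog, {"g1"}, {"g1", "g2"}, "case", "control")
        assert res.extra["table"] == [[20.0, 180.0], [10.0, 390.0]]
        assert res.statistic == pytest.approx(4.3333, abs=1e-3)
        assert res.p_value == pytest.approx(
            fisher_oracle([[20, 180], [10, 390]]), abs=1e-12
        )

    def test_counts_enter_table_unnormalised(self):
        # the full-coverage assumption: raw event counts, no rate scaling
        catalog = self._catalog({"g1": 40, "g2": 360}, {"g1": 20, "g2": 780})
        res = dnm_fet(catalog, {"g1"}, {"g1", "g2"}, "case", "control")
        assert res.extra["table"] == [[40.0, 360.0], [20.0, 780.0]]

    def test_module_not_in_background_rejected(self):
        catalog = self._catalog({"g1": 1}, {"g1": 1})
        with pytest.raises(ValueError):
            dnm_fet(catalog, {"gX"}, {"g1"}, "case", "control")

    def test_synonymous_class_is_negative_control(self):
        # planted nonsynonymous enrichment must not leak into synonymous P's;
        # the exact test is conservative, so assert no inflation and a
        # centred P distribution rather than strict uniformity
        truth = _toy_truth()
        pvals = []
        for rep in range(200):
            catalog = gen_dnm_catalog(
                truth, n_case_trios=300, n_control_trios=600,
                base_rate=2.0, enrichment_factor=5.0, seed=rep,
            )
            res = dnm_fet(
                catalog, truth.disease_genes(),
                set(truth.true_partition.assignment), "case", "control",
                mutation_class="synonymous",
            )
            pvals.append(res.p_value)
        pvals = np.asarray(pvals)
        assert (pvals <= 0.05).mean() <= 0.08
        assert 0.35 < np.median(pvals) < 0.65

    def test_per_gene_counting_mode(self):
        catalog = self._catalog({"g1": 5, "g2": 1}, {"g1": 1, "g2": 1})
        res = dnm_fet(
            catalog, {"g1"}, {"g1", "g2"}, "case", "control", count_genes=True
        )
        assert res.extra["table"] == [[1.0, 1.0], [1.0, 1.0]]


class TestGwasEnrichment:
    def test_planted_shift_detected(self):
        truth = _toy_truth(n_genes=800, module_size=300)
        hits = 0
        for rep in range(30):
            table = gen_gene_pvalues(truth, shift=0.5, seed=rep)
            res = gwas_set_enrichment(
                table, truth.disease_genes(),
                set(truth.true_partition.assignment),
                n_boot=300, seed=rep,
            )
            hits += res.statistic > 2
        assert hits >= 24  # >= 80%

    def test_null_z_is_centred(self):
        truth = _toy_truth(n_genes=600, module_size=100)
        zs = []
        for rep in range(100):
            table = gen_gene_pvalues(truth, shift=0.0, seed=rep)
            res = gwas_set_enrichment(
                table, truth.disease_genes(),
                set(truth.true_partition.assignment),
                n_boot=300, seed=rep,
            )
            zs.append(res.statistic)
        assert abs(np.mean(zs)) < 0.3

    def test_empirical_and_normal_p_agree_in_band(self):
        truth = _toy_truth(n_genes=600, module_size=100)
        table = gen_gene_pvalues(truth, shift=0.1, seed=5)
        res = gwas_set_enrichment(
            table, truth.disease_genes(),
            set(truth.true_partition.assignment), n_boot=5000, seed=5,
        )
        if abs(res.statistic) < 4:
            ratio = res.extra["empirical_p"] / res.p_value
            assert 1 / 3 < ratio < 3

    def test_all_genes_without_snps_rejected(self):
        genes = [f"G{i}" for i in range(50)]
        table = GenePValueTable(
            table=pd.DataFrame({"gene": genes, "p": 0.5, "n_snps": 0})
        )
        with pytest.raises(ValueError, match="testable"):
            gwas_set_enrichment(table, set(genes[:20]), set(genes), n_boot=50)

    def test_exclusion_list_lowers_but_keeps_signal(self):
        truth = _toy_truth(n_genes=600, module_size=100)
        deltas = []
        for rep in range(20):
            table = gen_gene_pvalues(truth, shift=0.6, seed=rep)
            module = truth.disease_genes()
            background = set(truth.true_partition.assignment)
            full = gwas_set_enrichment(table, module, background, n_boot=300, seed=rep)
            testable = table.testable()
            top_gene = testable[testable.index.isin(module)].idxmin()
            drop = gwas_set_enrichment(
                table, module, background, n_boot=300, exclude={top_gene}, seed=rep
            )
            deltas.append((full.statistic, drop.statistic))
        full_med = np.median([d[0] for d in deltas])
        drop_med = np.median([d[1] for d in deltas])
        assert drop_med < full_med
        assert drop_med > 0

    def test_zero_pvalue_clamped_with_warning(self):
        genes = [f"G{i}" for i in range(60)]
        df = pd.DataFrame({"gene": genes, "p": 0.5, "n_snps": 5})
        df.loc[0, "p"] = 0.0
        table = GenePValueTable(table=df)
        with pytest.warns(UserWarning, match="clamped"):
            gwas_set_enrichment(table, set(genes[:20]), set(genes), n_boot=50)
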