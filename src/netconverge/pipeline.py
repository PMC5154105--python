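"""End-to-end orchestration of the synthetic systems-genetics pipeline.

Stages run in the order the analysis is designed: simulate (or load) inputs,
preprocess expression, infer consensus and differential co-expression
modules, test module preservation, test genetic convergence (de novo burden,
GWAS gene-set enrichment), PPI topology, directional disease-expression and
seizure-correlation enrichment, annotation, and the drug reversal screen.
The run emits a machine-readable JSON report plus TSV tables; the prioritised
module is the one jointly significant for de novo burden (Bonferroni over
modules x phenotypes) and GWAS enrichment (FDR < 5%).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import io
from .annotation import ora_fet, spatiotemporal_profile
from .coexpression import (
    ModulePartition,
    build_similarity_stack,
    consensus_modules,
    differential_modules,
)
from .drug_screen import replication_direction_test, screen_drugs
from .genetic_enrichment import bh_adjust, bonferroni, dnm_fet, gwas_set_enrichment
from .ppi_analysis import degree_dnm_enrichment, module_ppi_subgraph, ppi_node_enrichment
from .preprocess import (
    ExpressionPanel,
    em_expression_filter,
    fit_hidden_factors,
    quantile_normalise,
    residualise,
)
from .preservation import preservation_zsummary
from .ranked_gsea import gene_scores_correlation, gene_scores_de, gsea_preranked
from .synthetic_data import (
    SimConfig,
    gen_disease_de,
    gen_dnm_catalog,
    gen_drug_de_table,
    gen_expression_panel,
    gen_gene_pvalues,
    gen_ppi,
)

logger = logging.getLogger(__name__)


def _rng(seed: int, *tags: str) -> np.random.Generator:
    ints = [int(seed)] + [zlib.crc32(t.encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(ints))


@dataclass
class PipelineConfig:
    """All stage parameters of one run; serialisable to/from YAML."""

    seed: int = 0
    output_dir: str = "netconverge_out"
    simulate: bool = True
    input_dir: str | None = None

    # simulation design
    n_genes: int = 2000
    n_conditions: int = 9
    n_samples_per_condition: int = 50
    module_sizes: list[int] = field(default_factory=lambda: [320, 100, 80, 60])
    n_differential_modules: int = 1
    n_hidden_factors: int = 2
    module_signal_sd: float = 2.0
    noise_sd: float = 1.0
    dnm_enrichment_factor: float = 5.0
    dnm_base_rate: float = 1.0
    n_case_trios: int = 356
    n_control_trios: int = 1891
    gwas_shift: float = 0.5
    ppi_n_edges: int = 3000
    ppi_intra_module_extra: int = 300
    de_down_effect: float = 1.0
    n_drugs: int = 150

    # preprocessing
    quantile_normalise: bool = True
    n_hidden_factors_fit: int = 10
    regress_hidden_factors: list[str] = field(default_factory=lambda: ["F1", "F2"])
    apply_expression_filter: bool = True
    em_quantile: float = 0.95

    # network inference
    beta: int = 7
    min_module_size: int = 40
    merge_cut_height: float = 0.25
    min_block_size: int = 20000  # accepted for interface parity; single-block only

    # permutation/bootstrap sizes
    n_perm_preservation: int = 100
    n_boot_gwas: int = 5000
    n_perm_ppi: int = 2000
    n_perm_gsea: int = 2000

    # drug screen
    drug_fdr_cut: float = 0.10
    drug_min_de_genes: int = 10

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_genes=self.n_genes,
            n_conditions=self.n_conditions,
            n_samples_per_condition=self.n_samples_per_condition,
            module_sizes=list(self.module_sizes),
            n_differential_modules=self.n_differential_modules,
            n_hidden_factors=self.n_hidden_factors,
            module_signal_sd=self.module_signal_sd,
            noise_sd=self.noise_sd,
            seed=self.seed,
        )


def jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def best_match_jaccard(true_genes: set[str], partition: ModulePartition) -> float:
    """Jaccard of a true module against its best-matching recovered module."""
    best = 0.0
    for label in partition.labels:
        best = max(best, jaccard(true_genes, set(partition.module_genes(label))))
    return best


def preprocess_panel(
    panel: ExpressionPanel, config: PipelineConfig
) -> tuple[ExpressionPanel, dict]:
    """Quantile-normalise, regress out covariates + hidden factors, EM-filter."""
    report: dict = {}
    if config.quantile_normalise:
        panel = panel.map_matrices(quantile_normalise)
    adjusted: dict[str, pd.DataFrame] = {}
    for cond in panel.conditions:
        mat = panel.matrices[cond]
        k = min(config.n_hidden_factors_fit, mat.shape[1] - 1)
        factors = fit_hidden_factors(mat, k=k)
        use = [f for f in config.regress_hidden_factors if f in factors.columns]
        covs = factors[use]
        if panel.covariates is not None:
            covs = pd.concat([panel.covariates.loc[mat.columns], covs], axis=1)
        adjusted[cond] = residualise(mat, covs)
    panel_adj = ExpressionPanel(
        conditions=list(panel.conditions),
        matrices=adjusted,
        gene_universe=list(panel.gene_universe),
        covariates=panel.covariates,
    )
    if config.apply_expression_filter:
        # filter on pre-residualisation expression level (residuals are centred)
        mean_expr = pd.concat(
            [panel.matrices[c].mean(axis=1) for c in panel.conditions], axis=1
        ).mean(axis=1)
        filt = em_expression_filter(mean_expr, quantile=config.em_quantile)
        report["expression_filter"] = filt.to_dict()
        keep = [g for g in panel_adj.gene_universe if g in filt.expressed_genes]
        panel_adj = ExpressionPanel(
            conditions=list(panel_adj.conditions),
            matrices={c: panel_adj.matrices[c].loc[keep] for c in panel_adj.conditions},
            gene_universe=keep,
            covariates=panel_adj.covariates,
        )
    report["n_genes_analysed"] = panel_adj.n_genes
    return panel_adj, report


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return (and write) the report bundle."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config)}

    def stage(name: str) -> None:
        logger.info("[%7.1fs] stage: %s", time.time() - t0, name)

    if not config.simulate:
        raise NotImplementedError(
            "file-based input loading is handled by the individual CLI commands; "
            "run_pipeline operates on the simulated study"
        )

    stage("simulate")
    panel, truth = gen_expression_panel(config.sim_config())
    catalog = gen_dnm_catalog(
        truth,
        n_case_trios=config.n_case_trios,
        n_control_trios=config.n_control_trios,
        base_rate=config.dnm_base_rate,
        enrichment_factor=config.dnm_enrichment_factor,
        seed=config.seed,
    )
    gwas_table = gen_gene_pvalues(truth, shift=config.gwas_shift, seed=config.seed)
    ppi = gen_ppi(
        truth,
        n_edges=config.ppi_n_edges,
        intra_module_extra=config.ppi_intra_module_extra,
        seed=config.seed,
    )
    disease_de, seizures, library = gen_disease_de(
        truth,
        down_effect=config.de_down_effect,
        n_drugs=config.n_drugs,
        seed=config.seed,
    )
    io.write_partition(truth.true_partition.assignment, out / "true_partition.tsv")

    stage("preprocess")
    panel_adj, prep_report = preprocess_panel(panel, config)
    report["preprocess"] = prep_report

    stage("network")
    if panel_adj.n_genes > config.min_block_size:
        logger.warning(
            "min_block_size=%d ignored: single-block processing only",
            config.min_block_size,
        )
    stack = build_similarity_stack(panel_adj, beta=config.beta)
    consensus = consensus_modules(
        panel_adj,
        beta=config.beta,
        min_module_size=config.min_module_size,
        merge_cut_height=config.merge_cut_height,
        stack=stack,
    )
    differential = differential_modules(
        panel_adj,
        beta=config.beta,
        min_module_size=config.min_module_size,
        merge_cut_height=config.merge_cut_height,
        stack=stack,
    )
    io.write_partition(consensus.assignment, out / "consensus_partition.tsv")
    io.write_partition(differential.assignment, out / "differential_partition.tsv")
    io.write_gmt(consensus.modules(), out / "consensus_modules.gmt")

    expressed = panel_adj.gene_universe
    truth_cons = truth.consensus_truth()
    ari = adjusted_rand_score(
        truth_cons.labels_for(expressed), consensus.labels_for(expressed)
    )
    diff_jaccards = {
        lab: best_match_jaccard(
            set(truth.true_partition.module_genes(lab)) & set(expressed), differential
        )
        for lab in truth.differential_modules
    }
    disease_recovered_label = None
    disease_genes_expressed = truth.disease_genes() & set(expressed)
    best_j = 0.0
    for lab in consensus.labels:
        j = jaccard(disease_genes_expressed, set(consensus.module_genes(lab)))
        if j > best_j:
            best_j, disease_recovered_label = j, lab
    report["network"] = {
        "n_consensus_modules": len(consensus.labels),
        "n_differential_modules": len(differential.labels),
        "consensus_ari_vs_truth": float(ari),
        "differential_jaccard_vs_truth": diff_jaccards,
        "disease_module_recovered_as": disease_recovered_label,
        "disease_module_jaccard": best_j,
    }

    stage("preserve")
    ref_cond, test_cond = panel_adj.conditions[0], panel_adj.conditions[min(1, len(panel_adj.conditions) - 1)]
    preservation = preservation_zsummary(
        panel_adj.matrices[ref_cond],
        panel_adj.matrices[test_cond],
        consensus,
        n_permutations=config.n_perm_preservation,
        beta=config.beta,
        seed=_rng(config.seed, "preservation"),
    )
    io.write_table(preservation.to_frame(), out / "preservation.tsv")
    report["preservation"] = {
        m.module: {"z_summary": m.z_summary, "class": m.classification}
        for m in preservation.modules
    }

    stage("genetic enrichment")
    background = set(expressed)
    all_modules = {f"consensus:{lab}": set(consensus.module_genes(lab)) for lab in consensus.labels}
    all_modules.update(
        {f"differential:{lab}": set(differential.module_genes(lab)) for lab in differential.labels}
    )
    n_tests = max(1, len(all_modules))  # modules x phenotypes (one case phenotype)
    dnm_rows, gwas_rows = [], []
    for name, genes in all_modules.items():
        res = dnm_fet(catalog, genes, background, "case", "control")
        dnm_rows.append(
            {
                "module": name,
                "odds_ratio": res.statistic,
                "p_value": res.p_value,
                "bonferroni_p": bonferroni(res.p_value, n_tests),
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
            }
        )
        try:
            gres = gwas_set_enrichment(
                gwas_table,
                genes,
                background,
                n_boot=config.n_boot_gwas,
                seed=_rng(config.seed, "gwas", name),
            )
            gwas_rows.append(
                {
                    "module": name,
                    "z": gres.statistic,
                    "p_value": gres.p_value,
                    "n_testable": gres.extra["n_testable"],
                }
            )
        except ValueError as e:
            logger.warning("GWAS enrichment skipped for %s: %s", name, e)
    dnm_df = pd.DataFrame(dnm_rows)
    gwas_df = pd.DataFrame(gwas_rows)
    if len(gwas_df):
        gwas_df["fdr"] = bh_adjust(gwas_df["p_value"].values)
    io.write_table(dnm_df, out / "dnm_enrichment.tsv")
    io.write_table(gwas_df, out / "gwas_enrichment.tsv")

    dnm_hits = set(dnm_df.loc[dnm_df["bonferroni_p"] < 0.05, "module"])
    gwas_hits = set(gwas_df.loc[gwas_df["fdr"] < 0.05, "module"]) if len(gwas_df) else set()
    joint = sorted(dnm_hits & gwas_hits)
    prioritised = joint[0] if joint else None
    report["genetic_enrichment"] = {
        "dnm": dnm_df.to_dict(orient="records"),
        "gwas": gwas_df.to_dict(orient="records"),
        "prioritised_module": prioritised,
        "jointly_significant": joint,
    }
    if prioritised is None:
        logger.warning("no module passes the joint DNM + GWAS criterion")
        _write_report(report, out, t0)
        return report
    prio_genes = all_modules[prioritised]

    stage("ppi")
    ppi_res = ppi_node_enrichment(
        ppi,
        prio_genes,
        background,
        n_perm=config.n_perm_ppi,
        seed=_rng(config.seed, "ppi"),
    )
    _, degrees = module_ppi_subgraph(ppi, prio_genes)
    case_dnm_genes = set(catalog.cohort_counts("case").index) & prio_genes
    ppi_report = {"node_enrichment": ppi_res.to_dict()}
    if case_dnm_genes:
        fet, gsea_deg = degree_dnm_enrichment(
            degrees,
            case_dnm_genes,
            n_perm=config.n_perm_gsea,
            seed=_rng(config.seed, "ppi-gsea"),
        )
        ppi_report["degree_dnm_fet"] = fet.to_dict()
        ppi_report["degree_dnm_gsea"] = {"es": gsea_deg.es, "nes": gsea_deg.nes, "p": gsea_deg.p_value}
    report["ppi"] = ppi_report

    stage("gsea")
    de_scores = gene_scores_de(disease_de)
    de_gsea = gsea_preranked(
        de_scores,
        prio_genes,
        n_perm=config.n_perm_gsea,
        seed=_rng(config.seed, "gsea-de"),
    )
    seiz_scores = gene_scores_correlation(
        panel_adj.matrices[panel_adj.conditions[0]], seizures
    )
    seiz_gsea = gsea_preranked(
        seiz_scores,
        prio_genes,
        n_perm=config.n_perm_gsea,
        seed=_rng(config.seed, "gsea-seizure"),
    )
    report["gsea"] = {
        "disease_de": {"es": de_gsea.es, "nes": de_gsea.nes, "p": de_gsea.p_value, "fdr_q": de_gsea.fdr_q},
        "seizure_correlation": {"es": seiz_gsea.es, "nes": seiz_gsea.nes, "p": seiz_gsea.p_value},
    }

    stage("annotate")
    # synthetic marker set: half the disease module plus random background
    marker_rng = _rng(config.seed, "markers")
    disease_list = sorted(truth.disease_genes() & background)
    half = list(marker_rng.choice(disease_list, size=len(disease_list) // 2, replace=False))
    others = sorted(background - truth.disease_genes())
    marker_set = set(half) | set(marker_rng.choice(others, size=len(half), replace=False))
    ora = ora_fet(prio_genes, marker_set, background)
    # pseudo spatiotemporal grid: conditions as regions, age tertiles as periods
    cov = panel_adj.covariates
    periods = pd.qcut(cov["age"], q=3, labels=["P1", "P2", "P3"]).astype(str)
    combined = pd.concat(
        [
            panel_adj.matrices[c].rename(columns=lambda s, c=c: f"{c}:{s}")
            for c in panel_adj.conditions
        ],
        axis=1,
    )
    labels = pd.DataFrame(
        {
            "region": [s.split(":")[0] for s in combined.columns],
            "period": [periods[s.split(":")[1]] for s in combined.columns],
        },
        index=combined.columns,
    )
    grid = spatiotemporal_profile(combined, labels, prio_genes)
    io.write_table(grid.reset_index(), out / "spatiotemporal_grid.tsv")
    report["annotation"] = {
        "marker_ora": ora.to_dict(),
        "spatiotemporal_grid_shape": list(grid.shape),
    }

    stage("drug screen")
    screen = screen_drugs(library, prio_genes, background)
    io.write_table(screen, out / "drug_screen.tsv")
    true_row = screen[screen["drug"] == truth.drug_true_name]
    true_rank = int(true_row["rank"].iloc[0]) if len(true_row) else None
    # replication: an independent treatment DE dataset for the true compound
    rep_seed = int(_rng(config.seed, "replication").integers(0, 2**31 - 1))
    rep_table = gen_drug_de_table(truth, seed=rep_seed)
    up_frac, down_frac, rep_up, rep_down = replication_direction_test(
        rep_table, prio_genes, background, fdr_cut=config.drug_fdr_cut
    )
    replication = {
        "up_fraction": up_frac,
        "down_fraction": down_frac,
        "p_up": rep_up.p_value,
        "p_down": rep_down.p_value,
    }
    report["drug_screen"] = {
        "n_eligible": len(library.eligible()),
        "true_drug_rank": true_rank,
        "top_drug": screen["drug"].iloc[0],
        "top_adjusted_p": float(screen["adjusted_p"].iloc[0]),
        "replication": replication,
    }

    _write_report(report, out, t0)
    return report


def _write_report(report: dict, out: Path, t0: float) -> None:
    # wall time lives only in the in-memory report so the written JSON is
    # byte-identical across reruns of the same config and seed
    io.write_json(_jsonify(report), out / "report.json")
    report["elapsed_s"] = time.time() - t0


def _jsonify(obj):
    """Make a report JSON-serialisable (numpy scalars, sets, NaN)."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    return obj
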