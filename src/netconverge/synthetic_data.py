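"""Synthetic multi-omic inputs with planted ground truth.

Every input the pipeline consumes can be generated here with a known answer
planted, so each analysis stage's recovery and calibration are testable
without any external dataset:

* a multi-condition expression panel built from a latent-factor model
  (gene = loading x module factor + hidden batch structure + noise), with
  consensus modules driven in every condition, differential modules driven
  only in a subset, bimodal (low/high) per-gene expression means for the EM
  filter, and sample covariates (age, sex, batch);
* case/control trio de novo mutation catalogs with Poisson counts
  proportional to per-gene length weights, the planted disease module's
  nonsynonymous case rate multiplied by an enrichment factor (synonymous
  counts are the untouched negative-control class);
* gene-based GWAS P values uniform in the background and mean-shifted on the
  probit scale in the disease module;
* a degree-heterogeneous PPI edge list with extra intra-disease-module edges;
* a disease differential-expression table with the module pushed down, an
  over-dispersed seizure-count phenotype anti-correlated with the module
  factor, and a drug-signature library with one true module-upregulating
  drug among random decoys.

All generators are pure functions of their configuration and seed; each draws
from its own RNG stream so adding one generator call never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .coexpression import UNASSIGNED, ModulePartition
from .drug_screen import DrugSignature, DrugSignatureLibrary, drug_de_sets
from .genetic_enrichment import (
    NONSYNONYMOUS,
    SYNONYMOUS,
    DNMCatalog,
    GenePValueTable,
    bh_adjust,
)
from .ppi_analysis import PPINetwork
from .preprocess import ExpressionPanel

# distinct RNG stream tags per generator op
_STREAMS = {"expression": 11, "dnm": 23, "gwas": 37, "ppi": 53, "de": 71}

# fraction of module loadings with positive sign: predominantly coherent
# modules (so directional readouts are recoverable) while still exercising
# sign handling in the unsigned network
_POSITIVE_LOADING_PROB = 0.95

# two-component expression-level mixture (log2 scale) for the EM filter
_LOW_MEAN, _HIGH_MEAN, _LEVEL_SD, _LOW_FRACTION = 3.0, 8.0, 1.0, 0.4


def _stream(seed: int, op: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[op]]))


@dataclass
class SimConfig:
    """Design of the synthetic expression study."""

    n_genes: int = 2000
    n_conditions: int = 9
    n_samples_per_condition: int = 50
    module_sizes: list[int] = field(default_factory=lambda: [320, 100, 80, 60])
    n_differential_modules: int = 1
    n_hidden_factors: int = 2
    module_signal_sd: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed gene count")
        for name in ("n_genes", "n_conditions", "n_samples_per_condition"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 1")
        if self.n_differential_modules > len(self.module_sizes):
            raise ValueError("more differential modules than modules")
        if self.module_signal_sd < 0 or self.noise_sd <= 0:
            raise ValueError("signal sd must be >= 0 and noise sd > 0")


@dataclass
class GroundTruth:
    """What was planted: the partition, the disease module and effect sizes."""

    true_partition: ModulePartition
    disease_module: str
    consensus_modules: list[str]
    differential_modules: list[str]
    differential_conditions: dict[str, list[str]]
    dnm_enrichment_factor: float = 5.0
    gwas_shift: float = 0.5
    drug_true_name: str = "drug_true"
    disease_factor: pd.Series | None = None  # per-sample factor, first condition

    def __post_init__(self) -> None:
        if self.disease_module not in self.true_partition.labels:
            raise ValueError("disease module missing from the true partition")

    def disease_genes(self) -> set[str]:
        return set(self.true_partition.module_genes(self.disease_module))

    def consensus_truth(self) -> ModulePartition:
        """The partition a consensus network should recover: differential
        modules are not consensus structure, so their genes are unassigned."""
        assign = {}
        for g, lab in self.true_partition.assignment.items():
            assign[g] = lab if lab in self.consensus_modules else UNASSIGNED
        return ModulePartition(assign)

    def differential_truth(self) -> ModulePartition:
        assign = {}
        for g, lab in self.true_partition.assignment.items():
            assign[g] = lab if lab in self.differential_modules else UNASSIGNED
        return ModulePartition(assign)


# ---------------------------------------------------------------------------
# Expression panel
# ---------------------------------------------------------------------------

def gen_expression_panel(config: SimConfig) -> tuple[ExpressionPanel, GroundTruth]:
    """Latent-factor expression panel with planted consensus and differential modules.

    Each module is driven by its own per-condition latent factor; consensus
    modules are driven in every condition, differential modules only in the
    first third of conditions. Hidden batch factors add rank-one structure
    across all genes; per-gene means come from a low/high mixture so the EM
    expression filter has something to find. The same individuals (sample IDs
    and covariates) appear in every condition, emulating a multi-region
    design on one cohort.
    """
    rng = _stream(config.seed, "expression")
    G, C, S = config.n_genes, config.n_conditions, config.n_samples_per_condition
    genes = [f"G{i + 1:05d}" for i in range(G)]
    conditions = [f"R{c + 1}" for c in range(C)]
    samples = [f"S{s + 1:03d}" for s in range(S)]

    n_mod = len(config.module_sizes)
    labels = [f"M{m + 1}" for m in range(n_mod)]
    diff_labels = labels[n_mod - config.n_differential_modules :] if config.n_differential_modules else []
    cons_labels = [l for l in labels if l not in diff_labels]
    n_active = max(1, C // 3)
    diff_conditions = {l: conditions[:n_active] for l in diff_labels}

    assign: dict[str, str] = {g: UNASSIGNED for g in genes}
    start = 0
    members: dict[str, list[int]] = {}
    for lab, size in zip(labels, config.module_sizes):
        members[lab] = list(range(start, start + size))
        for i in members[lab]:
            assign[genes[i]] = lab
        start += size

    # per-gene expression-level means: module genes from the high component,
    # background genes from the low/high mixture
    level = np.where(
        rng.random(G) < _LOW_FRACTION,
        rng.normal(_LOW_MEAN, _LEVEL_SD, G),
        rng.normal(_HIGH_MEAN, _LEVEL_SD, G),
    )
    in_module = np.zeros(G, dtype=bool)
    for lab in labels:
        in_module[members[lab]] = True
    level[in_module] = rng.normal(_HIGH_MEAN, _LEVEL_SD, in_module.sum())

    # module loadings: fixed magnitude, predominantly positive sign
    loading = np.zeros((G, n_mod))
    for m, lab in enumerate(labels):
        signs = np.where(
            rng.random(len(members[lab])) < _POSITIVE_LOADING_PROB, 1.0, -1.0
        )
        loading[members[lab], m] = signs * config.module_signal_sd

    # hidden batch factors: per-sample values shared across conditions, with
    # loadings over all genes; batch structure must dominate global variance
    # (as technical factors do on real arrays) so the top principal
    # components identify it rather than the largest biological module
    H = config.n_hidden_factors
    hidden_loading = rng.normal(0.0, 1.5 * config.noise_sd, (G, H))
    hidden_factor = rng.normal(0.0, 1.0, (S, H))

    # covariates: age and sex (inert), batch with a real additive effect
    age = rng.uniform(20, 90, S)
    sex = rng.choice(["F", "M"], S)
    batch = rng.choice(["b1", "b2"], S)
    batch_effect_genes = rng.random(G) < 0.2
    covariates = pd.DataFrame(
        {"age": age, "sex": sex, "batch": batch}, index=samples
    )

    matrices: dict[str, pd.DataFrame] = {}
    disease_factor = None
    for c, cond in enumerate(conditions):
        factors = rng.normal(0.0, 1.0, (S, n_mod))
        active = np.ones(n_mod)
        for m, lab in enumerate(labels):
            if lab in diff_labels and cond not in diff_conditions[lab]:
                active[m] = 0.0
        x = (
            level[:, None]
            + (loading * active) @ factors.T
            + hidden_loading @ hidden_factor.T
            + rng.normal(0.0, config.noise_sd, (G, S))
        )
        x[batch_effect_genes] += 0.5 * (batch == "b2")[None, :]
        matrices[cond] = pd.DataFrame(x, index=genes, columns=samples)
        if c == 0:
            disease_factor = pd.Series(factors[:, 0], index=samples)

    panel = ExpressionPanel(
        conditions=conditions,
        matrices=matrices,
        gene_universe=genes,
        covariates=covariates,
    )
    truth = GroundTruth(
        true_partition=ModulePartition(assign),
        disease_module=labels[0],
        consensus_modules=cons_labels,
        differential_modules=diff_labels,
        differential_conditions=diff_conditions,
        disease_factor=disease_factor,
    )
    return panel, truth


# ---------------------------------------------------------------------------
# De novo mutation catalog
# ---------------------------------------------------------------------------

def gen_dnm_catalog(
    truth: GroundTruth,
    n_case_trios: int = 356,
    n_control_trios: int = 1891,
    base_rate: float = 1.0,
    enrichment_factor: float | None = None,
    synonymous_rate_fraction: float = 0.3,
    seed: int = 0,
) -> DNMCatalog:
    """Poisson DNM counts per (gene, cohort, class) with a planted case burden.

    Per-trio nonsynonymous rates are proportional to log-normal per-gene
    length weights and sum to ``base_rate`` per trio; disease-module genes
    have their *case* nonsynonymous rate multiplied by the enrichment factor
    (defaults to ``truth.dnm_enrichment_factor``). Synonymous rates are a
    fixed fraction of nonsynonymous and never receive the multiplier.
    """
    if base_rate <= 0:
        raise ValueError("base_rate must be positive")
    factor = truth.dnm_enrichment_factor if enrichment_factor is None else enrichment_factor
    rng = _stream(seed, "dnm")
    genes = list(truth.true_partition.assignment)
    weights = rng.lognormal(0.0, 0.5, len(genes))
    rates = base_rate * weights / weights.sum()
    disease = np.array([g in truth.disease_genes() for g in genes])

    rows = []
    for cohort, n_trios in (("case", n_case_trios), ("control", n_control_trios)):
        mult = np.where(disease & (cohort == "case"), factor, 1.0)
        nonsyn = rng.poisson(rates * mult * n_trios)
        syn = rng.poisson(rates * synonymous_rate_fraction * n_trios)
        for cls, counts in ((NONSYNONYMOUS, nonsyn), (SYNONYMOUS, syn)):
            nz = np.nonzero(counts)[0]
            for i in nz:
                rows.append((genes[i], cohort, cls, int(counts[i])))
    counts_df = pd.DataFrame(rows, columns=["gene", "cohort", "mut_class", "count"])
    return DNMCatalog(
        counts=counts_df,
        trio_counts={"case": n_case_trios, "control": n_control_trios},
        gene_lengths=pd.Series(weights, index=genes),
    )


# ---------------------------------------------------------------------------
# Gene-based GWAS P values
# ---------------------------------------------------------------------------

def gen_gene_pvalues(
    truth: GroundTruth,
    shift: float | None = None,
    no_snp_fraction: float = 0.05,
    seed: int = 0,
) -> GenePValueTable:
    """Uniform background P values with a probit-scale shift in the disease module.

    Background genes get P ~ U(0, 1); disease-module genes get
    P = 1 - Phi(Z + shift) with Z standard normal (defaults to
    ``truth.gwas_shift``). A fraction of genes is flagged with no genotyped
    SNP (n_snps = 0) and is excluded from testing downstream.
    """
    s = truth.gwas_shift if shift is None else shift
    if s < 0:
        raise ValueError("shift must be >= 0")
    rng = _stream(seed, "gwas")
    genes = list(truth.true_partition.assignment)
    disease = np.array([g in truth.disease_genes() for g in genes])
    p = rng.uniform(0.0, 1.0, len(genes))
    z = rng.normal(0.0, 1.0, int(disease.sum()))
    p[disease] = norm.sf(z + s)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    n_snps = 1 + rng.poisson(9.0, len(genes))
    n_snps[rng.random(len(genes)) < no_snp_fraction] = 0
    return GenePValueTable(
        table=pd.DataFrame({"gene": genes, "p": p, "n_snps": n_snps})
    )


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------

def gen_ppi(
    truth: GroundTruth,
    n_edges: int = 3000,
    intra_module_extra: int = 300,
    seed: int = 0,
) -> PPINetwork:
    """Degree-heterogeneous PPI edges plus planted intra-disease-module edges.

    Background endpoints are drawn with probability proportional to a
    Pareto-distributed per-gene attractiveness (a preferential-attachment
    analogue), then ``intra_module_extra`` distinct extra edges are added
    uniformly among disease-module gene pairs. No self-loops or duplicates.
    """
    if n_edges < 0 or intra_module_extra < 0:
        raise ValueError("edge counts must be >= 0")
    rng = _stream(seed, "ppi")
    genes = list(truth.true_partition.assignment)
    n = len(genes)
    attract = 1.0 + rng.pareto(2.0, n)
    prob = attract / attract.sum()
    edges: set[tuple[int, int]] = set()
    while len(edges) < n_edges:
        draw = rng.choice(n, size=2 * max(64, n_edges - len(edges)), p=prob)
        for a, b in draw.reshape(-1, 2):
            if a == b:
                continue
            key = (min(a, b), max(a, b))
            edges.add(key)
            if len(edges) >= n_edges:
                break
    disease_idx = sorted(
        i for i, g in enumerate(genes) if g in truth.disease_genes()
    )
    max_pairs = len(disease_idx) * (len(disease_idx) - 1) // 2
    n_extra = min(intra_module_extra, max_pairs)
    added = 0
    while added < n_extra:
        a, b = rng.choice(len(disease_idx), size=2, replace=False)
        key = (
            min(disease_idx[a], disease_idx[b]),
            max(disease_idx[a], disease_idx[b]),
        )
        if key not in edges:
            edges.add(key)
            added += 1
    edge_list = sorted((genes[a], genes[b]) for a, b in edges)
    return PPINetwork(edges=edge_list, universe=genes)


# ---------------------------------------------------------------------------
# Disease DE, seizure phenotype and drug library
# ---------------------------------------------------------------------------

def _de_table(
    rng: np.random.Generator,
    genes: list[str],
    effect: pd.Series | None,
    se: float = 0.2,
) -> pd.DataFrame:
    """Simulated DE table: observed log2FC = true effect + N(0, se) noise."""
    mu = np.zeros(len(genes))
    if effect is not None:
        idx = {g: i for i, g in enumerate(genes)}
        for g, e in effect.items():
            mu[idx[g]] = e
    obs = mu + rng.normal(0.0, se, len(genes))
    z = obs / se
    p = 2 * norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {"gene": genes, "log2fc": obs, "pvalue": p, "padj": bh_adjust(p)}
    )


def gen_drug_de_table(
    truth: GroundTruth,
    coverage: float = 0.6,
    effect_strength: float = 1.0,
    n_other_de: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """DE table of a drug that up-regulates part of the disease module.

    A ``coverage`` fraction of disease-module genes gets a positive log2FC of
    mean ``effect_strength`` (scaling with dose in dose-response designs),
    plus ``n_other_de`` unrelated genes moved in random directions.
    """
    rng = _stream(seed, "de")
    genes = list(truth.true_partition.assignment)
    disease = sorted(truth.disease_genes())
    n_cov = int(round(coverage * len(disease)))
    covered = list(rng.choice(disease, size=n_cov, replace=False))
    others = list(
        rng.choice(
            [g for g in genes if g not in truth.disease_genes()],
            size=n_other_de,
            replace=False,
        )
    )
    effect = pd.Series(
        np.concatenate(
            [
                np.full(n_cov, effect_strength),
                rng.choice([-1.0, 1.0], n_other_de) * effect_strength,
            ]
        ),
        index=covered + others,
    )
    return _de_table(rng, genes, effect)


def gen_disease_de(
    truth: GroundTruth,
    down_effect: float = 1.0,
    n_drugs: int = 150,
    true_drug_coverage: float = 0.6,
    nb_dispersion: float = 5.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, DrugSignatureLibrary]:
    """Disease DE table, seizure phenotype, and drug-signature library.

    Disease-module genes get log2FC centred at ``-down_effect``. The seizure
    phenotype is a per-sample negative-binomial count whose log-mean
    decreases with the disease-module latent factor (so module expression is
    anti-correlated with seizure frequency). The library holds one true drug
    whose up-set covers ``true_drug_coverage`` of the disease module plus
    ``n_drugs - 1`` decoys with random differential expression.
    """
    if down_effect < 0:
        raise ValueError("down_effect must be >= 0")
    if n_drugs < 1:
        raise ValueError("need at least one drug")
    rng = _stream(seed, "de")
    genes = list(truth.true_partition.assignment)
    disease = sorted(truth.disease_genes())

    effect = pd.Series(
        rng.normal(-down_effect, 0.25 * max(down_effect, 1e-12), len(disease))
        if down_effect > 0
        else np.zeros(len(disease)),
        index=disease,
    )
    disease_de = _de_table(rng, genes, effect if down_effect > 0 else None)

    # over-dispersed seizure counts, log-mean decreasing in the module factor
    if truth.disease_factor is None:
        raise ValueError("ground truth carries no disease factor scores")
    f = np.asarray(truth.disease_factor, dtype=float)
    mean = np.exp(2.0 - 0.7 * f)
    r = nb_dispersion
    seizures = pd.Series(
        rng.negative_binomial(r, r / (r + mean)),
        index=truth.disease_factor.index,
        name="seizure_count",
    )

    signatures = []
    for d in range(n_drugs - 1):
        decoy_genes = rng.choice(genes, size=50, replace=False)
        eff = pd.Series(rng.choice([-1.0, 1.0], 50), index=decoy_genes)
        table = _de_table(rng, genes, eff)
        signatures.append(
            drug_de_sets(table, drug=f"drug{d + 1:03d}", cell_line="cl1", concentration=1.0)
        )
    true_seed_rng = rng.integers(0, 2**31 - 1)
    true_table = gen_drug_de_table(
        truth, coverage=true_drug_coverage, effect_strength=1.0, seed=int(true_seed_rng)
    )
    signatures.append(
        drug_de_sets(
            true_table, drug=truth.drug_true_name, cell_line="cl1", concentration=1.0
        )
    )
    library = DrugSignatureLibrary(signatures=signatures)
    return disease_de, seizures, library


# ---------------------------------------------------------------------------
# Serialisation of a full simulated study
# ---------------------------------------------------------------------------

def write_study(
    outdir,
    panel: ExpressionPanel,
    truth: GroundTruth,
    catalog: DNMCatalog | None = None,
    gene_pvalues: GenePValueTable | None = None,
    ppi: PPINetwork | None = None,
    disease_de: pd.DataFrame | None = None,
    seizures: pd.Series | None = None,
    library: DrugSignatureLibrary | None = None,
) -> None:
    """Write every simulated input as plain text (TSV/GMT/JSON).

    Expression goes to one TSV per condition plus a covariate table; the true
    partition as gene/module TSV and GMT; DNM counts, trio counts, gene P
    values, PPI edges, the disease DE table and seizure counts as TSVs; the
    drug library as paired up/down GMT files; and the planted ground truth as
    JSON.
    """
    from pathlib import Path

    from . import io

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for cond in panel.conditions:
        io.write_matrix(panel.matrices[cond], out / f"expression_{cond}.tsv")
    if panel.covariates is not None:
        panel.covariates.to_csv(out / "covariates.tsv", sep="\t", index_label="sample")
    io.write_partition(truth.true_partition.assignment, out / "true_partition.tsv")
    io.write_gmt(truth.true_partition.modules(), out / "true_modules.gmt")
    io.write_json(
        {
            "disease_module": truth.disease_module,
            "consensus_modules": truth.consensus_modules,
            "differential_modules": truth.differential_modules,
            "dnm_enrichment_factor": truth.dnm_enrichment_factor,
            "gwas_shift": truth.gwas_shift,
            "drug_true_name": truth.drug_true_name,
        },
        out / "ground_truth.json",
    )
    if catalog is not None:
        io.write_table(catalog.counts, out / "dnm_counts.tsv")
        io.write_table(
            pd.DataFrame(
                {"cohort": list(catalog.trio_counts), "n_trios": list(catalog.trio_counts.values())}
            ),
            out / "trio_counts.tsv",
        )
    if gene_pvalues is not None:
        io.write_table(gene_pvalues.table, out / "gene_pvalues.tsv")
    if ppi is not None:
        io.write_edges(ppi.edges, out / "ppi_edges.tsv")
    if disease_de is not None:
        io.write_table(disease_de, out / "disease_de.tsv")
    if seizures is not None:
        seizures.to_csv(out / "seizure_counts.tsv", sep="\t", index_label="sample")
    if library is not None:
        io.write_gmt({s.drug: sorted(s.up_set) for s in library.signatures}, out / "drug_up.gmt")
        io.write_gmt({s.drug: sorted(s.down_set) for s in library.signatures}, out / "drug_down.gmt")
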