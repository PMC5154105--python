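"""Genetic convergence tests: de novo mutation burden and GWAS gene-set enrichment.

Two independent lines of genetic evidence are tested per module. The de novo
mutation (DNM) burden test compares the rate of nonsynonymous DNMs falling in
module genes between a case and a control trio cohort with a two-tailed
Fisher exact test (synonymous DNMs serve as a negative-control class). The
GWAS test standardises a module's mean per-gene association Z score against a
bootstrap null of random same-size gene sets drawn from the expressed
background, giving a one-sided enrichment Z.

The 2x2 contingency machinery here (exact P, Haldane-Anscombe-corrected odds
ratio, Woolf confidence interval) is shared by every Fisher-based test in the
package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, norm

logger = logging.getLogger(__name__)

NONSYNONYMOUS = "nonsynonymous"
SYNONYMOUS = "synonymous"


@dataclass
class EnrichmentResult:
    """A single enrichment test outcome (odds ratio, Z or enrichment score)."""

    statistic_name: str
    statistic: float
    p_value: float
    adjusted_p: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    direction: str | None = None
    null_mean: float | None = None
    null_sd: float | None = None
    n_resamples: int | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
        }
        for k in ("adjusted_p", "ci_low", "ci_high", "direction", "null_mean", "null_sd", "n_resamples"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        d.update(self.extra)
        return d


# ---------------------------------------------------------------------------
# Shared 2x2 Fisher machinery
# ---------------------------------------------------------------------------

def fisher_test_2x2(
    table: np.ndarray | list, alternative: str = "two-sided"
) -> EnrichmentResult:
    """Fisher exact test with Haldane-corrected OR and Woolf 95% CI.

    The odds ratio is the sample OR (ad/bc); when any cell is zero, 0.5 is
    added to every cell (Haldane-Anscombe) for both the OR and its Woolf
    log-OR confidence interval.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if t.sum() == 0:
        raise ValueError("no mutations")
    a, b, c, d = t.ravel()
    _, p = fisher_exact(t.astype(int), alternative=alternative)
    if min(a, b, c, d) == 0:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a2, b2, c2, d2 = a, b, c, d
    odds = (a2 * d2) / (b2 * c2)
    se = np.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
    lo = float(np.exp(np.log(odds) - 1.96 * se))
    hi = float(np.exp(np.log(odds) + 1.96 * se))
    direction = "enriched" if odds > 1 else ("depleted" if odds < 1 else "none")
    return EnrichmentResult(
        statistic_name="odds_ratio",
        statistic=float(odds),
        p_value=float(p),
        ci_low=lo,
        ci_high=hi,
        direction=direction,
        extra={"table": t.astype(float).tolist(), "alternative": alternative},
    )


def bonferroni(p: float, n_tests: int) -> float:
    return float(min(1.0, p * n_tests))


def bh_adjust(pvalues: np.ndarray | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# De novo mutation burden
# ---------------------------------------------------------------------------

@dataclass
class DNMCatalog:
    """Per (gene, cohort, mutation class) de novo mutation counts.

    ``counts`` has columns gene, cohort, mut_class, count; genes absent from
    the table carry an implicit zero. ``trio_counts`` maps cohort -> number of
    trios; ``gene_lengths`` carries per-gene coding-length weights used only
    when simulating (counts are compared directly across cohorts under the
    full-coverage assumption).
    """

    counts: pd.DataFrame
    trio_counts: dict[str, int]
    gene_lengths: pd.Series | None = None

    def cohort_counts(
        self, cohort: str, mut_class: str = NONSYNONYMOUS
    ) -> pd.Series:
        sub = self.counts[
            (self.counts["cohort"] == cohort) & (self.counts["mut_class"] == mut_class)
        ]
        return sub.groupby("gene")["count"].sum()


def dnm_fet(
    catalog: DNMCatalog,
    module: set[str],
    background: set[str],
    case_cohort: str,
    control_cohort: str,
    mutation_class: str = NONSYNONYMOUS,
    count_genes: bool = False,
) -> EnrichmentResult:
    """Two-tailed Fisher test of DNM burden in a module, cases vs controls.

    The 2x2 table counts DNM events (optionally distinct mutated genes with
    ``count_genes=True``) inside and outside the module in each cohort;
    counting events means recurrently hit genes contribute multiply.
    """
    if not module <= background:
        raise ValueError("module must be a subset of the background")
    for cohort in (case_cohort, control_cohort):
        if cohort not in catalog.trio_counts:
            raise ValueError(f"unknown cohort {cohort!r}")
    rest = background - module
    cells = []
    for cohort in (case_cohort, control_cohort):
        counts = catalog.cohort_counts(cohort, mutation_class)
        counts = counts[counts.index.isin(background)]
        if count_genes:
            counts = (counts > 0).astype(int)
        cells.append(counts[counts.index.isin(module)].sum())
        cells.append(counts[counts.index.isin(rest)].sum())
    table = np.array(cells, dtype=float).reshape(2, 2)
    res = fisher_test_2x2(table, alternative="two-sided")
    res.extra["mutation_class"] = mutation_class
    res.extra["case_cohort"] = case_cohort
    res.extra["control_cohort"] = control_cohort
    return res


# ---------------------------------------------------------------------------
# GWAS gene-set enrichment (bootstrap Z test)
# ---------------------------------------------------------------------------

@dataclass
class GenePValueTable:
    """Gene-based association P values; genes without genotyped SNPs excluded."""

    table: pd.DataFrame  # columns: gene, p, n_snps

    def __post_init__(self) -> None:
        required = {"gene", "p", "n_snps"}
        if not required <= set(self.table.columns):
            raise ValueError(f"table needs columns {sorted(required)}")

    def testable(self) -> pd.Series:
        """P values for genes with at least one genotyped SNP."""
        sub = self.table[self.table["n_snps"] > 0]
        return sub.set_index("gene")["p"].astype(float)


def gwas_set_enrichment(
    table: GenePValueTable,
    module: set[str],
    background: set[str],
    n_boot: int = 100_000,
    exclude: set[str] | None = None,
    statistic: str = "mean_z",
    min_testable: int = 10,
    seed: int | np.random.Generator = 0,
) -> EnrichmentResult:
    """Bootstrap Z-test of a module's gene-based GWAS association.

    Per-gene scores are Z_g = Phi^{-1}(1 - p_g) (or -log10 p_g with
    ``statistic="mean_neglog10"``); the observed module mean is standardised
    against ``n_boot`` random gene sets of the same testable size drawn from
    the background genes present in the table, and the one-sided P is
    1 - Phi(Z). An empirical bootstrap P is reported alongside. ``exclude``
    removes named genes before testing (leave-one-out style sensitivity).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    pvals = table.testable()
    if exclude:
        pvals = pvals[~pvals.index.isin(exclude)]
    pvals = pvals[pvals.index.isin(background)]
    if (pvals <= 0).any():
        warnings.warn("P values of 0 clamped to machine minimum", stacklevel=2)
        pvals = pvals.clip(lower=np.finfo(float).tiny)
    if statistic == "mean_z":
        scores = pd.Series(norm.isf(pvals.values), index=pvals.index)
    elif statistic == "mean_neglog10":
        scores = -np.log10(pvals)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    module_scores = scores[scores.index.isin(module)]
    size = len(module_scores)
    if size < min_testable:
        raise ValueError(
            f"module has {size} testable genes (< {min_testable}); cannot test"
        )
    obs = float(module_scores.mean())
    vals = scores.values
    null = np.empty(n_boot)
    for i in range(n_boot):
        null[i] = vals[rng.choice(len(vals), size=size, replace=False)].mean()
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    z = (obs - null_mean) / null_sd
    p = float(norm.sf(z))
    p_emp = float((1 + (null >= obs).sum()) / (n_boot + 1))
    return EnrichmentResult(
        statistic_name="enrichment_z",
        statistic=float(z),
        p_value=p,
        direction="enriched" if z > 0 else "depleted",
        null_mean=null_mean,
        null_sd=null_sd,
        n_resamples=n_boot,
        extra={
            "observed_mean": obs,
            "empirical_p": p_emp,
            "n_testable": size,
            "score_statistic": statistic,
        },
    )
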