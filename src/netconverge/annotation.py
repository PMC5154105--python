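"""Module annotation: marker-set over-representation and expression profiles.

Over-representation of a module in a named target set (cell-type markers,
transcription-factor target lists) is a Fisher test on the overlap within a
background universe, sharing the package's 2x2 machinery. Spatiotemporal and
cell-type profiles summarise a module's expression as the mean of gene-wise
z-scored values within (region, period) sample groups or cell types, so each
cell of the grid reads as "standard deviations from that gene's own mean".
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .genetic_enrichment import EnrichmentResult, bh_adjust, fisher_test_2x2


def ora_fet(
    module: set[str], target_set: set[str], background: set[str]
) -> EnrichmentResult:
    """Fisher over-representation of a target gene set in a module.

    The 2x2 table partitions the background by module membership and target
    membership; two-tailed P, Haldane-corrected OR and Woolf CI.
    """
    if not module or not target_set:
        raise ValueError("module and target set must be non-empty")
    mod = module & background
    tgt = target_set & background
    overlap = len(mod & tgt)
    table = [
        [overlap, len(mod) - overlap],
        [len(tgt) - overlap, len(background) - len(mod) - len(tgt) + overlap],
    ]
    res = fisher_test_2x2(table, alternative="two-sided")
    res.extra["overlap"] = overlap
    return res


def ora_fet_batch(
    module: set[str], target_sets: dict[str, set[str]], background: set[str]
) -> pd.DataFrame:
    """ORA of one module against many target sets, BH-adjusted across sets."""
    rows = []
    for name, tgt in target_sets.items():
        r = ora_fet(module, tgt, background)
        rows.append(
            {
                "target_set": name,
                "overlap": r.extra["overlap"],
                "odds_ratio": r.statistic,
                "p_value": r.p_value,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
            }
        )
    out = pd.DataFrame(rows)
    out["adjusted_p"] = bh_adjust(out["p_value"].values)
    return out.sort_values(["adjusted_p", "p_value"]).reset_index(drop=True)


def _zscore_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Population z-score per row; rows with zero variance flagged."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True, ddof=0)
    zero = sd[:, 0] == 0
    sd[sd == 0] = 1.0
    return (x - mu) / sd, zero


def spatiotemporal_profile(
    matrix: pd.DataFrame,
    sample_labels: pd.DataFrame,
    module: set[str],
) -> pd.DataFrame:
    """Mean scaled module expression per (region, period) sample group.

    Each gene is z-scored across all samples; within every (region, period)
    cell the z-scores are averaged over samples and then over module genes.
    Zero-variance genes are dropped with a warning; cells without samples are
    missing (NaN).
    """
    required = {"region", "period"}
    if not required <= set(sample_labels.columns):
        raise ValueError("sample labels need 'region' and 'period' columns")
    labels = sample_labels.loc[matrix.columns]
    genes = [g for g in matrix.index if g in module]
    if not genes:
        raise ValueError("module has no genes in the expression matrix")
    x = np.asarray(matrix.loc[genes], dtype=float)
    z, zero = _zscore_rows(x)
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} constant module gene(s) dropped from profile",
            stacklevel=2,
        )
        z = z[~zero]
        if z.shape[0] == 0:
            raise ValueError("module has no genes with expression variance")
    zdf = pd.DataFrame(z.T, index=matrix.columns)
    zdf["region"] = labels["region"].values
    zdf["period"] = labels["period"].values
    grouped = zdf.groupby(["region", "period"], sort=True).mean()
    grid = grouped.mean(axis=1).unstack("period")
    grid.index.name = "region"
    grid.columns.name = "period"
    return grid


def celltype_profile(
    matrix: pd.DataFrame,
    cell_types: pd.Series,
    module: set[str],
) -> pd.DataFrame:
    """Cell-type x gene matrix of scaled mean expression for module genes.

    Per gene: mean expression within each cell type, then z-scored across
    cell types (population sd), so values read as SDs from the gene's
    mean-centred cross-type profile. Cell types with zero cells are excluded
    with a warning.
    """
    ct = cell_types.loc[matrix.columns]
    present = ct.value_counts()
    empty = [t for t in ct.unique() if present.get(t, 0) == 0]
    if empty:
        warnings.warn(f"cell types with no cells excluded: {empty}", stacklevel=2)
    genes = [g for g in matrix.index if g in module]
    if not genes:
        raise ValueError("module has no genes in the expression matrix")
    means = (
        pd.DataFrame(
            np.asarray(matrix.loc[genes], dtype=float).T,
            index=matrix.columns,
            columns=genes,
        )
        .groupby(ct, sort=True)
        .mean()
    )  # cell types x genes
    z, zero = _zscore_rows(means.values.T)
    out = pd.DataFrame(z.T, index=means.index, columns=genes)
    if zero.any():
        out.loc[:, np.array(genes)[zero]] = 0.0
    return out
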