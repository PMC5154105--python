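"""Signed gene scoring and preranked gene-set enrichment (GSEA).

Gene-level scores combine significance and direction: for differential
expression, (-log10 adjusted P) x log2 fold change; for a count phenotype,
(-log10 P) x Spearman rho of expression with the phenotype. The preranked
engine walks the descending score ranking with the weighted Kolmogorov-
Smirnov-like running sum, takes the signed extremum as the enrichment score
(ES), and standardises it against a gene-permutation null of random same-size
sets to give NES, a sign-matched permutation P and a ratio-of-tails FDR q.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.stats import t as t_dist


@dataclass
class GseaResult:
    es: float
    nes: float
    p_value: float
    fdr_q: float
    leading_edge: list[str]
    n_permutations: int
    set_size: int


# ---------------------------------------------------------------------------
# Gene scores
# ---------------------------------------------------------------------------

def gene_scores_de(de_table: pd.DataFrame) -> pd.Series:
    """Score = (-log10 adjusted P) x log2 fold change, one score per gene."""
    required = {"gene", "log2fc", "padj"}
    if not required <= set(de_table.columns):
        raise ValueError(f"DE table needs columns {sorted(required)}")
    padj = de_table["padj"].astype(float)
    if (padj <= 0).any():
        warnings.warn("adjusted P of 0 clamped to machine minimum", stacklevel=2)
        padj = padj.clip(lower=np.finfo(float).tiny)
    scores = (-np.log10(padj)) * de_table["log2fc"].astype(float)
    return pd.Series(scores.values, index=de_table["gene"].values, name="de_score")


def gene_scores_correlation(
    matrix: pd.DataFrame, phenotype: pd.Series
) -> pd.Series:
    """Score = (-log10 P) x Spearman rho of each gene with a per-sample phenotype.

    P values come from the t approximation to the null distribution of rho.
    Genes with zero expression variance get score 0.
    """
    y = np.asarray(phenotype.loc[matrix.columns], dtype=float)
    n = len(y)
    if n < 5:
        raise ValueError("need at least 5 samples")
    if np.all(y == y[0]):
        raise ValueError("constant phenotype")
    x = np.asarray(matrix, dtype=float)
    rx = np.apply_along_axis(rankdata, 1, x)
    ry = rankdata(y)
    rx_c = rx - rx.mean(axis=1, keepdims=True)
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum(axis=1) * (ry_c**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, rx_c @ ry_c / denom, 0.0)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt((n - 2) / np.maximum(1e-300, 1 - rho**2))
    p = 2 * t_dist.sf(np.abs(tstat), df=n - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    scores = (-np.log10(p)) * rho
    return pd.Series(scores, index=matrix.index, name="correlation_score")


# ---------------------------------------------------------------------------
# Preranked GSEA engine
# ---------------------------------------------------------------------------

def _es_from_positions(
    positions: np.ndarray, weights_sorted: np.ndarray, n: int
) -> tuple[float, int]:
    """ES (signed extremum of the running sum) for hit positions in a ranking.

    The running sum increases by w_i / sum(set weights) at hits and decreases
    by 1/(N - N_hit) at misses; the extremum is attained either just after a
    hit (positive candidates) or just before one (negative candidates), so
    only hit positions need examining. Returns (ES, rank index of extremum).
    """
    m = len(positions)
    positions = np.sort(positions)
    w = weights_sorted[positions]
    wsum = w.sum()
    if wsum == 0:
        # degenerate all-zero weights: equal hit increments
        w = np.ones(m)
        wsum = float(m)
    miss = 1.0 / (n - m)
    cum_w = np.cumsum(w) / wsum
    ranks = np.arange(1, m + 1)
    after_hit = cum_w - (positions + 1 - ranks) * miss
    before_hit = np.concatenate(([0.0], cum_w[:-1])) - (positions - (ranks - 1)) * miss
    i_max = int(np.argmax(after_hit))
    i_min = int(np.argmin(before_hit))
    es_pos = after_hit[i_max]
    es_neg = before_hit[i_min]
    if abs(es_pos) >= abs(es_neg):
        return float(es_pos), int(positions[i_max])
    return float(es_neg), int(positions[i_min])


def gsea_preranked(
    scores: pd.Series,
    gene_set: set[str],
    n_perm: int = 10_000,
    weight: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> GseaResult:
    """Preranked GSEA of one gene set against a signed score ranking.

    Genes are ranked by descending score with ties broken by gene ID; the
    null permutes set membership (uniform random same-size sets), P is the
    sign-matched permutation tail with a +1 pseudocount, NES divides ES by the
    mean |null ES| of matching sign, and FDR q is the null tail fraction on
    the NES scale.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    genes = np.asarray(scores.index)
    vals = np.asarray(scores, dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("scores must be finite")
    order = np.lexsort((genes, -vals))
    genes_sorted = genes[order]
    vals_sorted = vals[order]
    n = len(genes_sorted)
    hit_mask = np.isin(genes_sorted, list(gene_set))
    m = int(hit_mask.sum())
    if m < 2:
        raise ValueError("gene set overlaps fewer than 2 scored genes")
    if m >= n:
        raise ValueError("gene set covers the whole ranking")
    weights_sorted = np.abs(vals_sorted) ** weight
    obs_positions = np.where(hit_mask)[0]
    es, extremum = _es_from_positions(obs_positions, weights_sorted, n)

    null_es = np.empty(n_perm)
    for i in range(n_perm):
        pos = rng.choice(n, size=m, replace=False)
        null_es[i], _ = _es_from_positions(pos, weights_sorted, n)

    same_sign = null_es > 0 if es >= 0 else null_es < 0
    n_same = int(same_sign.sum())
    if n_same > 0:
        mean_abs = float(np.abs(null_es[same_sign]).mean())
        p = float((1 + (np.abs(null_es[same_sign]) >= abs(es)).sum()) / (n_same + 1))
    else:
        mean_abs = float(np.abs(null_es).mean()) or 1.0
        p = 1.0 / (n_perm + 1)
    nes = es / mean_abs if mean_abs > 0 else 0.0
    # single-set ratio-of-tails FDR on the NES scale
    pos_mean = np.abs(null_es[null_es > 0]).mean() if (null_es > 0).any() else np.inf
    neg_mean = np.abs(null_es[null_es < 0]).mean() if (null_es < 0).any() else np.inf
    null_nes = np.where(null_es >= 0, null_es / pos_mean, null_es / neg_mean)
    same_sign_nes = null_nes > 0 if nes >= 0 else null_nes < 0
    if same_sign_nes.any():
        tail = (np.abs(null_nes[same_sign_nes]) >= abs(nes)).sum()
        fdr_q = float(min(1.0, tail / same_sign_nes.sum()))
    else:
        fdr_q = p
    if es >= 0:
        leading = genes_sorted[: extremum + 1]
    else:
        leading = genes_sorted[extremum:]
    leading_edge = [g for g in leading if g in gene_set]
    return GseaResult(
        es=float(es),
        nes=float(nes),
        p_value=p,
        fdr_q=fdr_q,
        leading_edge=leading_edge,
        n_permutations=n_perm,
        set_size=m,
    )
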