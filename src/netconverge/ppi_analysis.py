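"""Protein-protein interaction topology of modules.

A module's induced PPI subgraph is summarised by its node count (genes with at
least one intra-module interaction) and per-gene intra-modular degree. Node
count is tested against uniform random same-size gene sets from the expressed
background, and the relationship between hubness and de novo mutation burden
is probed two ways: a Fisher test at a degree cutoff and an unweighted
preranked enrichment of DNM genes in the degree ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic_enrichment import EnrichmentResult, fisher_test_2x2
from .ranked_gsea import GseaResult, gsea_preranked


@dataclass
class PPINetwork:
    """Undirected PPI edge set over a gene universe (no self-loops/duplicates)."""

    edges: list[tuple[str, str]]
    universe: list[str]
    _edge_idx: np.ndarray = field(init=False, repr=False)
    _pos: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._pos = {g: i for i, g in enumerate(self.universe)}
        seen: set[tuple[str, str]] = set()
        dedup: list[tuple[str, str]] = []
        for a, b in self.edges:
            if a == b:
                continue
            key = (a, b) if a <= b else (b, a)
            if key in seen:
                continue
            seen.add(key)
            dedup.append(key)
        self.edges = dedup
        if dedup:
            self._edge_idx = np.array(
                [[self._pos[a], self._pos[b]] for a, b in dedup], dtype=np.int64
            )
        else:
            self._edge_idx = np.empty((0, 2), dtype=np.int64)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, a: str, b: str) -> bool:
        key = (a, b) if a <= b else (b, a)
        return key in set(self.edges)


def _node_counts_for_sets(
    ppi: PPINetwork, membership: np.ndarray
) -> tuple[int, np.ndarray]:
    """Node count and per-node intra-set degree for one membership mask."""
    e = ppi._edge_idx
    mask = membership[e[:, 0]] & membership[e[:, 1]]
    deg = np.zeros(len(ppi.universe), dtype=np.int64)
    if mask.any():
        np.add.at(deg, e[mask, 0], 1)
        np.add.at(deg, e[mask, 1], 1)
    return int((deg > 0).sum()), deg


def module_ppi_subgraph(
    ppi: PPINetwork, module: set[str]
) -> tuple[list[tuple[str, str]], pd.Series]:
    """Induced subgraph edges and per-gene intra-modular degree.

    Degree is reported for every module gene (zero when isolated); the node
    count of the subgraph is the number of genes with degree >= 1.
    """
    membership = np.zeros(len(ppi.universe), dtype=bool)
    idx = [ppi._pos[g] for g in module if g in ppi._pos]
    membership[idx] = True
    e = ppi._edge_idx
    mask = membership[e[:, 0]] & membership[e[:, 1]]
    sub_edges = [ppi.edges[i] for i in np.where(mask)[0]]
    _, deg = _node_counts_for_sets(ppi, membership)
    genes = sorted(module)
    degrees = pd.Series(
        [deg[ppi._pos[g]] if g in ppi._pos else 0 for g in genes], index=genes
    )
    return sub_edges, degrees


def ppi_node_enrichment(
    ppi: PPINetwork,
    module: set[str],
    background: set[str],
    n_perm: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> EnrichmentResult:
    """Empirical P for the module's PPI node count vs random gene sets.

    Null sets are uniform same-size draws from the background (no degree
    matching), and P = (1 + #{null >= observed}) / (n_perm + 1), so it can
    never be exactly zero.
    """
    if len(module) > len(background):
        raise ValueError("module larger than background")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    membership = np.zeros(len(ppi.universe), dtype=bool)
    membership[[ppi._pos[g] for g in module if g in ppi._pos]] = True
    observed, _ = _node_counts_for_sets(ppi, membership)
    bg_idx = np.array(sorted(ppi._pos[g] for g in background if g in ppi._pos))
    size = len(module)
    null = np.empty(n_perm, dtype=np.int64)
    mask = np.zeros(len(ppi.universe), dtype=bool)
    for i in range(n_perm):
        pick = bg_idx[rng.choice(len(bg_idx), size=size, replace=False)]
        mask[:] = False
        mask[pick] = True
        null[i], _ = _node_counts_for_sets(ppi, mask)
    p = float((1 + (null >= observed).sum()) / (n_perm + 1))
    return EnrichmentResult(
        statistic_name="ppi_node_count",
        statistic=float(observed),
        p_value=p,
        direction="enriched" if observed > null.mean() else "depleted",
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        n_resamples=n_perm,
        extra={"module_size": size},
    )


def degree_dnm_enrichment(
    degrees: pd.Series,
    dnm_genes: set[str],
    degree_threshold: int = 2,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[EnrichmentResult, GseaResult]:
    """Are DNM-hit genes the intra-modular hubs?

    Fisher test of DNM membership against degree > ``degree_threshold``
    (two-tailed, shared OR/CI machinery), plus an unweighted preranked
    enrichment of the DNM genes in the descending degree ranking.
    """
    if not dnm_genes:
        raise ValueError("empty DNM gene set")
    unknown = dnm_genes - set(degrees.index)
    if unknown:
        raise ValueError(f"DNM genes absent from degree table: {sorted(unknown)[:5]}")
    is_dnm = degrees.index.isin(dnm_genes)
    is_hub = degrees.values > degree_threshold
    table = [
        [int((is_dnm & is_hub).sum()), int((is_dnm & ~is_hub).sum())],
        [int((~is_dnm & is_hub).sum()), int((~is_dnm & ~is_hub).sum())],
    ]
    fet = fisher_test_2x2(table, alternative="two-sided")
    fet.extra["degree_threshold"] = degree_threshold
    gsea = gsea_preranked(
        degrees.astype(float), dnm_genes, n_perm=n_perm, weight=0.0, seed=seed
    )
    return fet, gsea
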