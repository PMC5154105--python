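"""Permutation-based module preservation between two expression datasets.

For each module, density statistics (mean within-module adjacency in the test
data; test eigengene variance explained) and connectivity statistics (Spearman
correlation of intramodular connectivity and of within-module correlation
entries between reference and test) are compared against random same-size gene
sets drawn from the shared gene universe. Each statistic is standardised
against its permutation null, and Z_summary = mean(Z_density, Z_connectivity)
is interpreted on the conventional scale: < 2 not preserved, 2-10 weak to
moderate, > 10 strongly preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .coexpression import ModulePartition, bicor_matrix

logger = logging.getLogger(__name__)


@dataclass
class ModulePreservation:
    module: str
    size: int
    observed: dict[str, float]
    z_scores: dict[str, float]
    z_density: float
    z_connectivity: float
    z_summary: float
    classification: str


@dataclass
class PreservationReport:
    modules: list[ModulePreservation]
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.modules:
            row = {"module": m.module, "size": m.size}
            row.update({f"obs_{k}": v for k, v in m.observed.items()})
            row.update(
                {
                    "Z_density": m.z_density,
                    "Z_connectivity": m.z_connectivity,
                    "Z_summary": m.z_summary,
                    "classification": m.classification,
                }
            )
            rows.append(row)
        return pd.DataFrame(rows)


def _classify(z: float) -> str:
    if z > 10:
        return "strong"
    if z >= 2:
        return "moderate"
    return "not"


def _module_stats(
    idx: np.ndarray,
    ref_cor: np.ndarray,
    test_cor: np.ndarray,
    test_z: np.ndarray,
    beta: int,
) -> np.ndarray:
    """The four preservation statistics for one gene-index set."""
    rc = ref_cor[np.ix_(idx, idx)]
    tc = test_cor[np.ix_(idx, idx)]
    ta = np.abs(tc) ** beta
    m = len(idx)
    off = ~np.eye(m, dtype=bool)
    mean_adj = ta[off].mean()
    # eigengene variance explained in test
    sub = test_z[idx]
    s = np.linalg.svd(sub, compute_uv=False)
    var_expl = s[0] ** 2 / (s**2).sum()
    # intramodular connectivity correlation (ref vs test)
    k_ref = (np.abs(rc) ** beta).sum(axis=0) - 1.0
    k_test = ta.sum(axis=0) - 1.0
    cor_kim = spearmanr(k_ref, k_test).statistic
    # correlation of correlation entries
    iu = np.triu_indices(m, k=1)
    cor_cor = spearmanr(rc[iu], tc[iu]).statistic
    return np.array([mean_adj, var_expl, cor_kim, cor_cor])


STAT_NAMES = ["mean_adjacency", "var_explained", "cor_kIM", "cor_cor"]


def preservation_zsummary(
    reference: pd.DataFrame,
    test: pd.DataFrame,
    partition: ModulePartition,
    n_permutations: int = 200,
    beta: int = 7,
    min_module_genes: int = 10,
    seed: int | np.random.Generator = 0,
) -> PreservationReport:
    """Permutation Z_summary preservation of each module in a test dataset.

    The null draws random gene sets of the module's size (without replacement)
    from the genes shared by both datasets, so it expresses "no relationship
    between the module assignment and the test data structure".
    """
    if n_permutations < 20:
        raise ValueError("n_permutations must be at least 20 (null sd unstable)")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    shared = [g for g in reference.index if g in set(test.index)]
    dropped = len(set(partition.assignment) - set(shared))
    if dropped:
        logger.info("%d partition genes absent from shared universe; dropped", dropped)
    ref = reference.loc[shared]
    tst = test.loc[shared]
    ref_cor = np.asarray(bicor_matrix(ref))
    test_cor = np.asarray(bicor_matrix(tst))
    x = np.asarray(tst, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    test_z = (x - mu) / sd
    pos = {g: i for i, g in enumerate(shared)}

    results = []
    for label in partition.labels:
        genes = [g for g in partition.module_genes(label) if g in pos]
        if len(genes) < min_module_genes:
            logger.info("module %s: only %d shared genes; skipped", label, len(genes))
            continue
        idx = np.array([pos[g] for g in genes])
        obs = _module_stats(idx, ref_cor, test_cor, test_z, beta)
        null = np.empty((n_permutations, 4))
        for p in range(n_permutations):
            ridx = rng.choice(len(shared), size=len(idx), replace=False)
            null[p] = _module_stats(ridx, ref_cor, test_cor, test_z, beta)
        null_sd = null.std(axis=0, ddof=1)
        null_sd[null_sd == 0] = np.nan
        z = (obs - null.mean(axis=0)) / null_sd
        z = np.nan_to_num(z, nan=0.0)
        z_density = float(z[:2].mean())
        z_connectivity = float(z[2:].mean())
        z_summary = (z_density + z_connectivity) / 2.0
        results.append(
            ModulePreservation(
                module=label,
                size=len(idx),
                observed=dict(zip(STAT_NAMES, obs)),
                z_scores=dict(zip(STAT_NAMES, z)),
                z_density=z_density,
                z_connectivity=z_connectivity,
                z_summary=z_summary,
                classification=_classify(z_summary),
            )
        )
    return PreservationReport(modules=results, n_permutations=n_permutations)
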