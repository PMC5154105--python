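"""Consensus and differential weighted gene co-expression network inference.

The workflow is the weighted co-expression (WGCNA-style) recipe: a robust
correlation matrix per condition (biweight midcorrelation), soft-thresholded
to an unsigned adjacency |cor|^beta chosen by the scale-free topology
criterion, converted to a topological overlap matrix (TOM); per-condition TOMs
are quantile-calibrated and combined by a component-wise minimum into a
consensus TOM; 1 - TOM is clustered with average linkage and a dynamic branch
cut, and close modules are merged on eigengene correlation. The differential
(DiffCoEx-style) variant clusters the TOM of between-condition adjacency
differences instead, isolating gene groups whose co-expression changes across
conditions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .preprocess import ExpressionPanel

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class ModulePartition:
    """Gene -> module assignment with an explicit unassigned label."""

    assignment: dict[str, str]
    unassigned_label: str = UNASSIGNED

    @property
    def labels(self) -> list[str]:
        seen: list[str] = []
        for lab in self.assignment.values():
            if lab != self.unassigned_label and lab not in seen:
                seen.append(lab)
        return seen

    def module_genes(self, label: str) -> list[str]:
        return [g for g, lab in self.assignment.items() if lab == label]

    def modules(self) -> dict[str, list[str]]:
        return {lab: self.module_genes(lab) for lab in self.labels}

    def labels_for(self, genes: list[str]) -> np.ndarray:
        return np.array([self.assignment.get(g, self.unassigned_label) for g in genes])


@dataclass
class Eigengene:
    """First principal component of a module's (gene-standardised) expression."""

    module: str
    scores: pd.Series
    variance_explained: float


@dataclass
class SimilarityStack:
    """Per-condition correlation, soft-thresholded adjacency and TOM matrices."""

    conditions: list[str]
    genes: list[str]
    beta: int
    correlation: dict[str, np.ndarray] = field(default_factory=dict)
    adjacency: dict[str, np.ndarray] = field(default_factory=dict)
    tom: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Biweight midcorrelation
# ---------------------------------------------------------------------------

def bicor_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Biweight midcorrelation between all gene pairs (tuning constant 9).

    Each observation is weighted by Tukey's biweight w = (1 - u^2)^2 for
    |u| < 1, u = (x - median) / (9 * MAD), which makes the estimate resistant
    to outlying samples. Genes with zero MAD fall back to Pearson weighting
    for pairs involving them (with a warning).
    """
    x = np.asarray(matrix, dtype=float)
    if x.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True)
    zero_mad = mad[:, 0] == 0
    dev = x - med
    with np.errstate(divide="ignore", invalid="ignore"):
        u = dev / (9.0 * mad)
    w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    a = w * dev
    if zero_mad.any():
        warnings.warn(
            f"{int(zero_mad.sum())} gene(s) with zero MAD: Pearson fallback",
            stacklevel=2,
        )
        cdev = x - x.mean(axis=1, keepdims=True)
        a[zero_mad] = cdev[zero_mad]
    norms = np.sqrt((a**2).sum(axis=1, keepdims=True))
    norms[norms == 0] = 1.0
    a = a / norms
    r = np.clip(a @ a.T, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=matrix.index, columns=matrix.index)


# ---------------------------------------------------------------------------
# Soft threshold selection (scale-free topology criterion)
# ---------------------------------------------------------------------------

def scale_free_fit_index(correlation: np.ndarray, beta: int, n_bins: int = 10) -> float:
    """r^2 of log10 p(k) on log10 k, signed by the slope direction.

    A scale-free degree distribution gives a straight descending line, so the
    index approaches +1; ascending fits are penalised with a negative sign.
    """
    adj = np.abs(correlation) ** beta
    k = adj.sum(axis=1) - np.diag(adj)
    k = k[k > 0]
    if len(k) == 0:
        raise ValueError("all connectivities are zero")
    # equal-width bins on the connectivity scale (the conventional choice;
    # log-scale bins isolate single low-degree outliers into their own bin)
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * np.asarray(xs) + intercept
    ss_res = ((np.asarray(ys) - pred) ** 2).sum()
    ss_tot = ((np.asarray(ys) - np.mean(ys)) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(r2 * np.sign(-slope)) if slope != 0 else 0.0


def select_soft_threshold(
    correlation: pd.DataFrame | np.ndarray,
    candidate_betas: list[int],
    r2_cut: float = 0.8,
) -> tuple[int, pd.DataFrame]:
    """Pick the smallest exponent whose scale-free fit index exceeds ``r2_cut``.

    If no candidate qualifies, the best-fitting candidate is returned with a
    warning; a single candidate is returned as given (warning iff its fit is
    below the cut), supporting a fixed, externally chosen beta.
    """
    if not candidate_betas:
        raise ValueError("candidate_betas must be non-empty")
    corr = np.asarray(correlation, dtype=float)
    rows = []
    for beta in candidate_betas:
        rows.append({"beta": beta, "fit_index": scale_free_fit_index(corr, beta)})
    fit = pd.DataFrame(rows)
    ok = fit[fit["fit_index"] > r2_cut]
    if len(ok):
        beta = int(ok["beta"].iloc[0])
    else:
        beta = int(fit.loc[fit["fit_index"].idxmax(), "beta"])
        warnings.warn(
            f"no candidate beta reaches fit index {r2_cut}; using beta={beta} "
            f"(best index {fit['fit_index'].max():.3f})",
            stacklevel=2,
        )
    return beta, fit


# ---------------------------------------------------------------------------
# Topological overlap
# ---------------------------------------------------------------------------

def tom(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency with unit diagonal.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), the
    shared-neighbour-weighted similarity; TOM_ii = 1.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency values must lie in [0, 1]")
    if not np.allclose(np.diag(a), 1.0):
        raise ValueError("adjacency diagonal must be 1")
    k = a.sum(axis=0) - 1.0  # connectivity excluding self
    prod = a @ a
    # remove the diagonal terms a_ii*a_ij and a_ij*a_jj from the neighbour sum
    shared = prod - 2.0 * a
    num = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(t, 1.0)
    return np.clip(t, 0.0, 1.0)


def consensus_tom(
    tom_stack: dict[str, np.ndarray], calibration_quantile: float = 0.95
) -> np.ndarray:
    """Quantile-calibrate per-condition TOMs and take their element-wise minimum.

    Each TOM is raised to the power log(q_ref)/log(q_c) so that its
    ``calibration_quantile`` of off-diagonal values matches the first
    (reference) condition's; the consensus keeps only overlap present in every
    condition.
    """
    conds = list(tom_stack)
    if len(conds) < 2:
        raise ValueError("need at least 2 conditions")
    n = tom_stack[conds[0]].shape[0]
    off = ~np.eye(n, dtype=bool)
    q_ref = np.quantile(tom_stack[conds[0]][off], calibration_quantile)
    if q_ref <= 0 or q_ref >= 1:
        raise ValueError("degenerate calibration quantile in reference TOM")
    calibrated = []
    for c in conds:
        t = tom_stack[c]
        q_c = np.quantile(t[off], calibration_quantile)
        if q_c <= 0 or q_c >= 1:
            raise ValueError(f"degenerate calibration quantile in condition {c!r}")
        exponent = np.log(q_ref) / np.log(q_c)
        calibrated.append(t**exponent)
    cons = np.minimum.reduce(calibrated)
    np.fill_diagonal(cons, 1.0)
    return cons


def diffcoex_tom(
    adjacency_stack: dict[str, np.ndarray], soft_power: float = 3.5
) -> np.ndarray:
    """Dissimilarity (1 - TOM) of between-condition adjacency differences.

    The difference matrix is the per-pair standard deviation of adjacency
    across conditions, rescaled to [0, 1] and soft-thresholded (raised to
    ``soft_power``, the beta/2 exponent of the original differential
    co-expression transformation) so that sampling noise in the adjacency
    differences is crushed relative to genuine condition-dependent
    co-expression; the TOM of the result groups genes whose co-expression
    changes coherently between conditions.
    """
    conds = list(adjacency_stack)
    if len(conds) < 2:
        raise ValueError("need at least 2 conditions")
    stack = np.stack([adjacency_stack[c] for c in conds])
    d = stack.std(axis=0, ddof=1)
    np.fill_diagonal(d, 0.0)
    dmax = d.max()
    if dmax > 1e-12:  # guard: identical stacks leave only float rounding
        d = (d / dmax) ** soft_power
    else:
        d[:] = 0.0
    np.fill_diagonal(d, 1.0)
    return 1.0 - tom(d)


# ---------------------------------------------------------------------------
# Module eigengenes
# ---------------------------------------------------------------------------

def module_eigengene(matrix: pd.DataFrame, module_genes: list[str], label: str = "") -> Eigengene:
    """First principal component of the gene-standardised module submatrix.

    Scores have unit variance and are sign-oriented so the mean correlation
    with the module's genes is non-negative (tie-break: positive first
    loading).
    """
    if len(module_genes) == 0:
        raise ValueError("module must be non-empty")
    sub = np.asarray(matrix.loc[module_genes], dtype=float)
    if sub.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - mu) / sd
    if len(module_genes) == 1:
        scores = z[0]
        ve = 1.0
    else:
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        scores = vt[0]
        ve = float(s[0] ** 2 / (s**2).sum())
    ssd = scores.std(ddof=0)
    if ssd > 0:
        scores = scores / ssd
    zc = z - z.mean(axis=1, keepdims=True)
    sc = scores - scores.mean()
    denom = np.sqrt((zc**2).sum(axis=1)) * np.sqrt((sc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        cors = np.where(denom > 0, (zc @ sc) / denom, 0.0)
    orient = np.mean(cors)
    if orient < 0 or (orient == 0 and scores[0] < 0):
        scores = -scores
    return Eigengene(
        module=label,
        scores=pd.Series(scores, index=matrix.columns),
        variance_explained=ve,
    )


# ---------------------------------------------------------------------------
# Dynamic branch cut and eigengene merging
# ---------------------------------------------------------------------------

def _eigengene_dissimilarity(
    panel_matrices: list[pd.DataFrame], modules: dict[str, list[str]]
) -> pd.DataFrame:
    """1 - min-over-conditions correlation between module eigengenes."""
    labels = list(modules)
    n = len(labels)
    min_cor = np.full((n, n), 1.0)
    for mat in panel_matrices:
        eig = {lab: module_eigengene(mat, modules[lab], lab).scores for lab in labels}
        E = np.stack([np.asarray(eig[lab]) for lab in labels])
        Ec = E - E.mean(axis=1, keepdims=True)
        norms = np.sqrt((Ec**2).sum(axis=1, keepdims=True))
        norms[norms == 0] = 1.0
        cor = (Ec / norms) @ (Ec / norms).T
        min_cor = np.minimum(min_cor, cor)
    return pd.DataFrame(1.0 - min_cor, index=labels, columns=labels)


def cut_modules(
    dissimilarity: pd.DataFrame,
    expression: ExpressionPanel | pd.DataFrame,
    min_module_size: int = 40,
    merge_cut_height: float = 0.25,
    cut_height_fraction: float = 0.99,
) -> ModulePartition:
    """Detect modules as dendrogram branches and merge correlated ones.

    Average-linkage clustering of the dissimilarity; branches are the clusters
    obtained by cutting at ``cut_height_fraction`` of the dendrogram height.
    Branches below ``min_module_size`` are absorbed into the nearest accepted
    branch when their mean dissimilarity to it stays below the cut, otherwise
    left unassigned. Modules whose eigengene dissimilarity (1 - correlation,
    minimum over conditions) falls below ``merge_cut_height`` are merged
    iteratively, recomputing eigengenes each round.
    """
    genes = list(dissimilarity.index)
    d = np.asarray(dissimilarity, dtype=float)
    if len(genes) < min_module_size:
        warnings.warn("fewer genes than min_module_size: all unassigned", stacklevel=2)
        return ModulePartition({g: UNASSIGNED for g in genes})
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    cut_height = cut_height_fraction * Z[:, 2].max()
    raw = fcluster(Z, t=cut_height, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    big = [c for c in sizes.index if sizes[c] >= min_module_size]
    assignment = np.full(len(genes), -1, dtype=int)
    for rank, c in enumerate(sorted(big, key=lambda c: -sizes[c])):
        assignment[raw == c] = rank
    # absorb small branches into the nearest accepted branch if close enough
    if big:
        module_idx = {m: np.where(assignment == m)[0] for m in range(len(big))}
        for i in np.where(assignment == -1)[0]:
            mean_d = {m: d[i, idx].mean() for m, idx in module_idx.items()}
            best = min(mean_d, key=mean_d.get)
            if mean_d[best] <= cut_height:
                assignment[i] = best

    modules: dict[str, list[str]] = {}
    for m in sorted(set(assignment) - {-1}):
        modules[f"M{m + 1}"] = [genes[i] for i in np.where(assignment == m)[0]]
    if not modules:
        return ModulePartition({g: UNASSIGNED for g in genes})

    if isinstance(expression, ExpressionPanel):
        mats = [expression.matrices[c] for c in expression.conditions]
    else:
        mats = [expression]

    # iterative eigengene merging
    while len(modules) > 1:
        ed = _eigengene_dissimilarity(mats, modules)
        np.fill_diagonal(ed.values, np.inf)
        i, j = np.unravel_index(np.argmin(ed.values), ed.shape)
        if ed.values[i, j] >= merge_cut_height:
            break
        a, b = ed.index[i], ed.index[j]
        logger.info("merging modules %s and %s (eigengene dissimilarity %.3f)", a, b, ed.values[i, j])
        modules[a] = modules[a] + modules[b]
        del modules[b]

    # stable relabelling by size then content
    ordered = sorted(modules.items(), key=lambda kv: (-len(kv[1]), sorted(kv[1])[0]))
    final: dict[str, str] = {g: UNASSIGNED for g in genes}
    for rank, (_, mem) in enumerate(ordered):
        for g in mem:
            final[g] = f"M{rank + 1}"
    return ModulePartition(final)


def dendrogram_newick(dissimilarity: pd.DataFrame) -> str:
    """Average-linkage dendrogram of the dissimilarity as a Newick string.

    Branch lengths are the height differences between a node's merge height
    and its children's, so cophenetic distances are preserved.
    """
    genes = list(dissimilarity.index)
    d = np.asarray(dissimilarity, dtype=float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    n = len(genes)
    label: dict[int, str] = {}
    height = {i: 0.0 for i in range(n)}
    for i in range(n):
        label[i] = genes[i]
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        node = n + k
        la = h - height[a]
        lb = h - height[b]
        label[node] = f"({label[a]}:{la:.6g},{label[b]}:{lb:.6g})"
        height[node] = h
    return label[n + len(Z) - 1] + ";"


# ---------------------------------------------------------------------------
# Panel-level drivers
# ---------------------------------------------------------------------------

def build_similarity_stack(panel: ExpressionPanel, beta: int = 7) -> SimilarityStack:
    """Compute bicor, adjacency |cor|^beta and TOM for every condition."""
    stack = SimilarityStack(
        conditions=list(panel.conditions), genes=list(panel.gene_universe), beta=beta
    )
    for cond in panel.conditions:
        corr = np.asarray(bicor_matrix(panel.matrices[cond]))
        adj = np.abs(corr) ** beta
        np.fill_diagonal(adj, 1.0)
        stack.correlation[cond] = corr
        stack.adjacency[cond] = adj
        stack.tom[cond] = tom(adj)
    return stack


def consensus_modules(
    panel: ExpressionPanel,
    beta: int = 7,
    min_module_size: int = 40,
    merge_cut_height: float = 0.25,
    calibration_quantile: float = 0.95,
    stack: SimilarityStack | None = None,
) -> ModulePartition:
    """Full consensus pipeline: bicor -> adjacency -> TOM -> consensus -> cut."""
    if stack is None:
        stack = build_similarity_stack(panel, beta=beta)
    if len(panel.conditions) == 1:
        cons = stack.tom[panel.conditions[0]]
    else:
        cons = consensus_tom(stack.tom, calibration_quantile=calibration_quantile)
    dis = pd.DataFrame(1.0 - cons, index=panel.gene_universe, columns=panel.gene_universe)
    return cut_modules(
        dis, panel, min_module_size=min_module_size, merge_cut_height=merge_cut_height
    )


def differential_modules(
    panel: ExpressionPanel,
    beta: int = 7,
    min_module_size: int = 40,
    merge_cut_height: float = 0.25,
    stack: SimilarityStack | None = None,
) -> ModulePartition:
    """DiffCoEx pipeline: adjacency differences -> TOM -> cut."""
    if stack is None:
        stack = build_similarity_stack(panel, beta=beta)
    dis = pd.DataFrame(
        diffcoex_tom(stack.adjacency),
        index=panel.gene_universe,
        columns=panel.gene_universe,
    )
    return cut_modules(
        dis, panel, min_module_size=min_module_size, merge_cut_height=merge_cut_height
    )
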