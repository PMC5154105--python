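"""Expression preprocessing: quantile normalisation, hidden-factor estimation,
covariate residualisation, EM expressed-gene filtering, orthologue mapping.

The preprocessing contract mirrors the standard microarray/RNA-seq workflow for
co-expression analysis: per-condition gene x sample matrices on a log2 scale
are quantile normalised, nuisance structure (known covariates plus hidden
batch-like factors estimated by PCA) is removed by per-gene ordinary least
squares, and a two-component Gaussian mixture fitted by EM separates
low-expressed (likely non-functional) from high-expressed genes, keeping genes
whose mean expression exceeds the 95th percentile of the low component.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)


@dataclass
class ExpressionPanel:
    """Per-condition gene x sample expression matrices over a shared gene universe.

    Attributes
    ----------
    conditions : list of condition identifiers (e.g. brain regions).
    matrices : per-condition DataFrame, genes as rows in identical order.
    gene_universe : the shared, ordered gene IDs.
    covariates : per-sample table indexed by sample ID (age, sex, batch, ...).
        Sample IDs are shared across conditions when the same individuals were
        profiled in every condition.
    """

    conditions: list[str]
    matrices: dict[str, pd.DataFrame]
    gene_universe: list[str] = field(default_factory=list)
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.gene_universe and self.conditions:
            self.gene_universe = list(self.matrices[self.conditions[0]].index)
        for cond in self.conditions:
            idx = list(self.matrices[cond].index)
            if idx != list(self.gene_universe):
                raise ValueError(f"condition {cond!r} does not share the gene ordering")
            cols = self.matrices[cond].columns
            if cols.duplicated().any():
                raise ValueError(f"duplicate sample IDs in condition {cond!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_universe)

    def map_matrices(self, fn) -> "ExpressionPanel":
        """Return a new panel with ``fn`` applied to every condition's matrix."""
        return ExpressionPanel(
            conditions=list(self.conditions),
            matrices={c: fn(self.matrices[c]) for c in self.conditions},
            gene_universe=list(self.gene_universe),
            covariates=self.covariates,
        )


@dataclass
class ExpressedGeneFilter:
    """Two-component mixture fit of per-gene mean expression and the derived
    expressed-gene threshold (low_mean + z_quantile * low_sd)."""

    threshold: float
    low_mean: float
    high_mean: float
    low_sd: float
    high_sd: float
    low_weight: float
    expressed_genes: set[str]

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "low_mean": self.low_mean,
            "high_mean": self.high_mean,
            "low_sd": self.low_sd,
            "high_sd": self.high_sd,
            "low_weight": self.low_weight,
            "n_expressed": len(self.expressed_genes),
        }


# ---------------------------------------------------------------------------
# Quantile normalisation
# ---------------------------------------------------------------------------

def quantile_normalise(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common reference distribution.

    The reference is the vector of row means of the column-sorted input; ties
    within a column receive the mean of the target values they span.
    """
    if matrix.size == 0:
        raise ValueError("empty matrix")
    x = np.asarray(matrix, dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing values not allowed")
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="mergesort")
        col = np.empty(x.shape[0])
        col[order] = ref
        # average the assigned targets over tied input values
        vals, inv = np.unique(x[:, j], return_inverse=True)
        if len(vals) < x.shape[0]:
            sums = np.bincount(inv, weights=col)
            counts = np.bincount(inv)
            col = (sums / counts)[inv]
        out[:, j] = col
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# Hidden factors (PCA surrogate for probabilistic factor estimation)
# ---------------------------------------------------------------------------

def fit_hidden_factors(matrix: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k sample-space principal-component scores of the gene-standardised
    matrix, each scaled to unit variance.

    These factors play the role of hidden nuisance variables (batch, unmodelled
    technical structure); which of them to regress out is a downstream choice.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n_samples = matrix.shape[1]
    if k >= n_samples:
        raise ValueError("k must be smaller than the number of samples")
    x = np.asarray(matrix, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    # samples x genes, columns centred per gene: scores are exactly mean-zero
    u, s, _ = np.linalg.svd(z.T, full_matrices=False)
    scores = u[:, :k] * s[:k]
    scores = scores / scores.std(axis=0, ddof=0)
    return pd.DataFrame(
        scores, index=matrix.columns, columns=[f"F{i + 1}" for i in range(k)]
    )


# ---------------------------------------------------------------------------
# Covariate residualisation
# ---------------------------------------------------------------------------

def _design_matrix(covariates: pd.DataFrame) -> np.ndarray:
    num = covariates.select_dtypes(include=[np.number])
    cat = covariates.select_dtypes(exclude=[np.number])
    blocks = [np.ones((len(covariates), 1))]
    if not num.empty:
        blocks.append(np.asarray(num, dtype=float))
    if not cat.empty:
        blocks.append(np.asarray(pd.get_dummies(cat, drop_first=True), dtype=float))
    return np.hstack(blocks)


def residualise(matrix: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Replace each gene row by its OLS residual on the covariates (with intercept).

    Categorical covariates are expanded to indicators. A rank-deficient design
    is handled by the pseudo-inverse (equivalent to dropping redundant
    columns), with a warning rather than a failure.
    """
    if list(covariates.index) != list(matrix.columns):
        covariates = covariates.loc[matrix.columns]
    X = _design_matrix(covariates)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            f"collinear covariate design (rank {rank} < {X.shape[1]} columns); "
            "redundant directions dropped",
            stacklevel=2,
        )
    proj = X @ np.linalg.pinv(X)
    resid = np.asarray(matrix, dtype=float) @ (np.eye(X.shape[0]) - proj)
    return pd.DataFrame(resid, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# EM expressed-gene filter
# ---------------------------------------------------------------------------

def _em_two_gaussians(
    x: np.ndarray, max_iter: int = 1000, tol: float = 1e-8
) -> tuple[float, float, float, float, float]:
    """Fit a two-component univariate Gaussian mixture by EM.

    Initialised by 1-D k-means (two centres from the data quartiles, Lloyd
    iterations), which is deterministic and robust for bimodal input.
    Returns (w_low, mu_low, sd_low, mu_high, sd_high) with mu_low < mu_high.
    """
    # deterministic 1-D k-means init
    c = np.array([np.quantile(x, 0.25), np.quantile(x, 0.75)])
    for _ in range(100):
        assign = np.abs(x[:, None] - c[None, :]).argmin(axis=1)
        new = np.array([x[assign == j].mean() if (assign == j).any() else c[j] for j in (0, 1)])
        if np.allclose(new, c):
            break
        c = new
    assign = np.abs(x[:, None] - c[None, :]).argmin(axis=1)
    w = np.array([(assign == 0).mean(), (assign == 1).mean()])
    mu = c.copy()
    sd = np.array([x[assign == j].std() if (assign == j).sum() > 1 else x.std() for j in (0, 1)])
    sd = np.maximum(sd, 1e-8)
    ll_old = -np.inf
    for _ in range(max_iter):
        log_comp = np.log(np.maximum(w, 1e-300)) + norm.logpdf(x[:, None], mu, sd)
        m = log_comp.max(axis=1, keepdims=True)
        log_mix = m[:, 0] + np.log(np.exp(log_comp - m).sum(axis=1))
        resp = np.exp(log_comp - log_mix[:, None])
        nk = resp.sum(axis=0)
        w = nk / len(x)
        mu = (resp * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-300)
        var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / np.maximum(nk, 1e-300)
        sd = np.sqrt(np.maximum(var, 1e-300))
        ll = log_mix.sum()
        if ll - ll_old < tol:
            break
        ll_old = ll
    lo, hi = (0, 1) if mu[0] <= mu[1] else (1, 0)
    return w[lo], mu[lo], sd[lo], mu[hi], sd[hi]


def em_expression_filter(
    mean_expression: pd.Series, quantile: float = 0.95
) -> ExpressedGeneFilter:
    """Separate low- from high-expressed genes with a two-Gaussian EM fit.

    The expressed-gene threshold is the ``quantile`` point of the fitted
    low-expression component, low_mean + z * low_sd; genes whose mean
    expression exceeds it are retained.

    Raises
    ------
    ValueError
        With message "unimodal input" when the fit degenerates (vanishing
        component weight or scale) or the two components are not separated
        (Ashman's D < 2), i.e. the input does not support two modes.
    """
    if len(mean_expression) < 50:
        raise ValueError("need at least 50 genes")
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    x = np.asarray(mean_expression, dtype=float)
    w_low, mu_low, sd_low, mu_high, sd_high = _em_two_gaussians(x)
    degenerate = (
        min(w_low, 1 - w_low) < 1e-3 or min(sd_low, sd_high) < 1e-6
    )
    ashman_d = abs(mu_high - mu_low) / np.sqrt((sd_low**2 + sd_high**2) / 2.0)
    if degenerate or ashman_d < 2.0:
        raise ValueError("unimodal input")
    threshold = mu_low + norm.ppf(quantile) * sd_low
    expressed = set(mean_expression.index[x > threshold])
    logger.info(
        "EM filter: low N(%.3f, %.3f) w=%.3f, high N(%.3f, %.3f); threshold %.3f; "
        "%d/%d expressed",
        mu_low, sd_low, w_low, mu_high, sd_high, threshold, len(expressed), len(x),
    )
    return ExpressedGeneFilter(
        threshold=float(threshold),
        low_mean=float(mu_low),
        high_mean=float(mu_high),
        low_sd=float(sd_low),
        high_sd=float(sd_high),
        low_weight=float(w_low),
        expressed_genes=expressed,
    )


# ---------------------------------------------------------------------------
# Orthologue mapping
# ---------------------------------------------------------------------------

def map_orthologues(
    table: pd.DataFrame, ortho_map: list[tuple[str, str]]
) -> pd.DataFrame:
    """Re-key a gene-indexed table through a one-to-one orthologue map.

    Only strictly bijective pairs survive: a source mapping to several targets,
    or a target hit by several sources, is dropped along with its rows.
    """
    if not ortho_map:
        raise ValueError("empty orthologue map")
    pairs = pd.DataFrame(ortho_map, columns=["source", "target"]).drop_duplicates()
    src_counts = pairs["source"].value_counts()
    tgt_counts = pairs["target"].value_counts()
    one2one = pairs[
        pairs["source"].map(src_counts).eq(1) & pairs["target"].map(tgt_counts).eq(1)
    ]
    mapping = dict(zip(one2one["source"], one2one["target"]))
    keep = table.index.isin(mapping)
    out = table.loc[keep].copy()
    out.index = [mapping[g] for g in out.index]
    logger.info(
        "orthologue mapping: %d/%d pairs one-to-one, %d/%d rows mapped",
        len(one2one), len(pairs), keep.sum(), len(table),
    )
    return out
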