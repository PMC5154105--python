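"""Independent brute-force oracles used to pin down the fast implementations."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd


def fisher_oracle(table, alternative: str = "two-sided") -> float:
    """Exact Fisher P by enumeration of all 2x2 tables with fixed margins.

    Hypergeometric probabilities are computed with exact integer binomials;
    the two-sided P sums the probabilities of tables no more likely than the
    observed one (with the conventional 1e-7 relative tie tolerance).
    """
    (a, b), (c, d) = [[int(x) for x in row] for row in table]
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = comb(n, c1)
    pmf = {k: Fraction(comb(r1, k) * comb(r2, c1 - k), denom) for k in range(lo, hi + 1)}
    if alternative == "greater":
        return float(sum(p for k, p in pmf.items() if k >= a))
    if alternative == "less":
        return float(sum(p for k, p in pmf.items() if k <= a))
    cutoff = float(pmf[a]) * (1 + 1e-7)
    return float(sum(p for p in pmf.values() if float(p) <= cutoff))


def tom_oracle(adjacency: np.ndarray) -> np.ndarray:
    """Triple-loop evaluation of the topological overlap formula."""
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            t[i, j] = (shared + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
    return t


def gsea_es_oracle(scores: pd.Series, gene_set: set, weight: float = 1.0) -> float:
    """O(N * |set|) literal walk of the GSEA running sum, signed extremum."""
    items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    hits = [g in gene_set for g, _ in items]
    n, m = len(items), sum(hits)
    wsum = sum(abs(s) ** weight for (g, s), h in zip(items, hits) if h)
    running, best = 0.0, 0.0
    for (g, s), h in zip(items, hits):
        if h:
            running += (abs(s) ** weight) / wsum if wsum > 0 else 1.0 / m
        else:
            running -= 1.0 / (n - m)
        if abs(running) > abs(best):
            best = running
    return best
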