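"""Independent reference implementations used only to check the package.

Everything here is deliberately naive (pure-Python loops, closed forms,
exhaustive enumeration) and shares no code with the library.
"""

from __future__ import annotations

import math
from statistics import median


def naive_median_polish(matrix, max_iter=10, tol=1e-6):
    """Straightforward Tukey two-way polish on a list-of-lists (None=missing).

    Sweeps row medians then column medians out of the residuals, folding
    them into the effects and re-centring the opposite effects each
    half-sweep. Returns (overall, row_effects, col_effects, residuals).
    """
    n_rows = len(matrix)
    n_cols = len(matrix[0])
    resid = [[matrix[i][j] for j in range(n_cols)] for i in range(n_rows)]
    row_eff = [0.0] * n_rows
    col_eff = [0.0] * n_cols
    overall = 0.0

    def med(values):
        vals = [v for v in values if v is not None]
        return median(vals) if vals else 0.0

    for _ in range(max_iter):
        delta = 0.0
        for i in range(n_rows):
            m = med(resid[i])
            for j in range(n_cols):
                if resid[i][j] is not None:
                    resid[i][j] -= m
            row_eff[i] += m
            delta = max(delta, abs(m))
        shift = med(col_eff)
        col_eff = [c - shift for c in col_eff]
        overall += shift
        for j in range(n_cols):
            m = med(resid[i][j] for i in range(n_rows))
            for i in range(n_rows):
                if resid[i][j] is not None:
                    resid[i][j] -= m
            col_eff[j] += m
            delta = max(delta, abs(m))
        shift = med(row_eff)
        row_eff = [r - shift for r in row_eff]
        overall += shift
        if delta < tol:
            break
    return overall, row_eff, col_eff, resid


def _lchoose(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -math.inf
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher p for [[a, b], [c, d]] by direct
    summation of the hypergeometric tail."""
    M = a + b + c + d  # population
    K = a + b  # row-1 total
    n = a + c  # column-1 total
    hi = min(K, n)
    p = 0.0
    for k in range(a, hi + 1):
        lp = _lchoose(K, k) + _lchoose(M - K, n - k) - _lchoose(M, n)
        p += math.exp(lp)
    return min(1.0, p)


def brute_force_reagent_counts(rows, threshold, direction="ge"):
    """Group-and-count oracle: rows are (gene, reagent, score) triples.

    Returns {gene: (n_total, n_passing)} over rows with a non-missing
    score.
    """
    out: dict = {}
    for gene, _reagent, score in rows:
        if score is None or (isinstance(score, float) and math.isnan(score)):
            continue
        passed = score >= threshold if direction == "ge" else score <= threshold
        tot, ok = out.get(gene, (0, 0))
        out[gene] = (tot + 1, ok + int(passed))
    return out


def brute_force_subnetwork(genes, edge_set):
    """All-pairs lookup of C(n, 2) gene pairs against a canonical edge set."""
    genes = sorted(set(genes))
    found = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            pair = (genes[i], genes[j])
            if pair in edge_set:
                found.append(pair)
    return sorted(found)
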