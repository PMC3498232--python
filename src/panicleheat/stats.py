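"""Hypergeometric enrichment statistics shared by the motif and category
over-representation analyses.

Both analyses ask the same question: given a gene universe of size ``N`` in
which ``n`` genes carry some property, is a cluster of ``M`` genes containing
``m`` carriers more than expected by chance?  The answer is the upper tail
P(X >= m) of the hypergeometric distribution, computed through log-gamma
terms so that extreme enrichments do not underflow to spurious zeros.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = ["hypergeom_upper_tail", "enrichment_ratio", "benjamini_hochberg"]

_TINY = 5e-324  # smallest positive subnormal double; p is clamped to (0, 1]


def _log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) - gammaln(
        np.asarray(n) - np.asarray(k) + 1
    )


def hypergeom_upper_tail(m: int, N: int, n: int, M: int) -> float:
    """P(X >= m) for X ~ Hypergeometric(population N, n successes, M draws).

        p = sum_{i=m}^{min(n, M)} C(n, i) C(N-n, M-i) / C(N, M)

    Parameters follow the gene-set convention: ``N`` genes in the database,
    ``n`` of which carry the property, a cluster of ``M`` genes of which
    ``m`` carry it.  The result is clamped to (0, 1].
    """
    for name, v in (("m", m), ("N", N), ("n", n), ("M", M)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if n > N or M > N:
        raise ValueError("need n <= N and M <= N")
    if m > min(n, M):
        raise ValueError(f"inconsistent counts: m={m} exceeds min(n={n}, M={M})")

    lo = max(0, n + M - N)  # support lower bound: X >= lo always
    if m <= lo:
        return 1.0
    i = np.arange(m, min(n, M) + 1)
    log_terms = _log_comb(n, i) + _log_comb(N - n, M - i) - _log_comb(N, M)
    p = float(np.exp(logsumexp(log_terms)))
    return min(max(p, _TINY), 1.0)


def enrichment_ratio(m: int, M: int, n: int, N: int) -> float:
    """Relative frequency of carriers in the cluster vs the database:
    (m / M) / (n / N).  Undefined (ValueError) when ``n`` is zero — a motif
    never seen in the database has no background frequency."""
    if M <= 0 or N <= 0:
        raise ValueError("M and N must be positive")
    if n == 0:
        raise ValueError("background count n is zero; ratio undefined")
    if m > M or n > N:
        raise ValueError("need m <= M and n <= N")
    return (m / M) / (n / N)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up FDR), optional in the
    enrichment reports and off by default."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
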