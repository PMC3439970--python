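"""Hypergeometric set-overlap significance and flat-set term enrichment.

For a universe of N transcripts of which K carry a property, and a query
set of n transcripts of which k carry it, the enrichment P-value is the
upper tail of the hypergeometric distribution including the observed
count, P(X >= k).  The linear tail is summed by a mode-anchored pmf
recurrence (near machine precision); a log-space tail is carried
alongside so that P-values far below the smallest positive double are
still reported through their log10 (the linear value underflows to 0,
matching the convention of printing "P ≈ 0").

Terms are flat sets: no ontology-graph propagation is applied, so
GO-style parent/child structure must be resolved upstream if wanted.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import AnnotationTable

__all__ = [
    "hypergeom_upper_tail",
    "log10_hypergeom_upper_tail",
    "EnrichmentResult",
    "overlap_significance",
    "term_enrichment",
]


def _check_bounds(N: int, K: int, n: int, k: int) -> None:
    if not 0 <= K <= N:
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not 0 <= n <= N:
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"need 0 <= k <= min(K, n), got k={k}, K={K}, n={n}")


def _log_pmf_terms(N: int, K: int, n: int, k: int) -> np.ndarray:
    ks = np.arange(k, min(K, n) + 1)
    return hypergeom.logpmf(ks, N, K, n)


def _log_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Natural log of P(X >= k), summed over the exact support."""
    if k <= 0:
        return 0.0
    logs = _log_pmf_terms(N, K, n, k)
    if len(logs) == 0:  # k above the support: impossible event
        return -math.inf
    return float(logsumexp(logs))


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    The tail is accumulated over the exact support: probability masses
    are generated by the pmf ratio recurrence anchored at the modal
    term (one rounding per step) and compensated-summed, which keeps
    the complement identity P(X >= k) + P(X <= k-1) = 1 accurate to
    better than 1e-12 for N up to 1e5.  Tails far below the smallest
    positive double return 0.0 — use
    :func:`log10_hypergeom_upper_tail` to resolve those.
    """
    _check_bounds(N, K, n, k)
    support_min = max(0, n + K - N)
    if k <= support_min:
        return 1.0  # the whole support is in the tail
    kmax = min(K, n)
    mode = min(max((n + 1) * (K + 1) // (N + 2), k), kmax)
    # correctly-rounded anchor from exact integer combinatorics; pmf at the
    # mode is at least 1/(support size), so it can never underflow
    anchor = float(
        Fraction(math.comb(K, mode) * math.comb(N - K, n - mode), math.comb(N, n))
    )
    terms = [anchor]
    p = anchor  # downward: pmf(i) = pmf(i+1) * (i+1)(N-K-n+i+1) / ((K-i)(n-i))
    for i in range(mode - 1, k - 1, -1):
        p *= (i + 1) * (N - K - n + i + 1) / ((K - i) * (n - i))
        terms.append(p)
    p = anchor  # upward: pmf(i+1) = pmf(i) * (K-i)(n-i) / ((i+1)(N-K-n+i+1))
    for i in range(mode, kmax):
        p *= (K - i) * (n - i) / ((i + 1) * (N - K - n + i + 1))
        terms.append(p)
    return min(float(math.fsum(terms)), 1.0)


def log10_hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """log10 P(X >= k), finite even where the linear value underflows."""
    _check_bounds(N, K, n, k)
    return _log_upper_tail(N, K, n, k) / math.log(10)


@dataclass(frozen=True)
class EnrichmentResult:
    """One hypergeometric test: counts, raw tail, and optional adjustment."""

    term_id: str
    N: int
    K: int
    n: int
    k: int
    p_raw: float
    log10_p: float
    p_adj: float | None = None


def overlap_significance(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> EnrichmentResult:
    """Significance of the overlap of two transcript sets within a universe.

    ``set_a`` plays the annotated role (K) and ``set_b`` the drawn role
    (n); the hypergeometric tail is symmetric in that choice.
    """
    universe = set(universe)
    a, b = set(set_a), set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("both sets must be subsets of the universe")
    N, K, n, k = len(universe), len(a), len(b), len(a & b)
    return EnrichmentResult(
        term_id="overlap",
        N=N,
        K=K,
        n=n,
        k=k,
        p_raw=hypergeom_upper_tail(N, K, n, k),
        log10_p=log10_hypergeom_upper_tail(N, K, n, k),
    )


def term_enrichment(
    query: Iterable[str],
    annotations: AnnotationTable,
    universe: Iterable[str] | None = None,
    adjust: str = "none",
) -> pd.DataFrame:
    """Upper-tail enrichment of every annotation term in a query set.

    The universe defaults to the annotation table's own universe (the
    low-expression-filtered background transcriptome in the standard
    pipeline).  Terms with no annotated transcript in the universe are
    not reported.  Rows are sorted by raw P ascending, ties broken by
    term id; ``adjust="benjamini_hochberg"`` adds a step-up adjusted
    column over all tested terms.
    """
    if adjust not in ("none", "benjamini_hochberg"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    universe = set(universe) if universe is not None else set(annotations.universe)
    query = set(query)
    if not query:
        raise ValueError("empty query set")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    restricted = annotations.restrict(universe)
    members = restricted.term_members()
    N, n = len(universe), len(query)
    rows = []
    for term, ids in members.items():
        K = len(ids)
        if K == 0:
            continue
        k = len(ids & query)
        rows.append(
            {
                "term_id": term,
                "N": N,
                "K": K,
                "n": n,
                "k": k,
                "p_raw": hypergeom_upper_tail(N, K, n, k),
                "log10_p": log10_hypergeom_upper_tail(N, K, n, k),
            }
        )
    out = pd.DataFrame(
        rows, columns=["term_id", "N", "K", "n", "k", "p_raw", "log10_p"]
    )
    if adjust == "benjamini_hochberg" and len(out):
        out["p_adj"] = multipletests(out["p_raw"].to_numpy(), method="fdr_bh")[1]
    else:
        out["p_adj"] = np.nan
    out = out.sort_values(["p_raw", "term_id"], kind="mergesort").reset_index(drop=True)
    return out
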