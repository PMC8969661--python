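"""Hypergeometric over-representation of a gene list with BH FDR control."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentResult:
    set_name: str
    k: int  # overlap: query ∩ set ∩ universe
    K: int  # set size within universe
    n: int  # query size within universe
    N: int  # universe size
    p_value: float  # hypergeometric upper tail P(X >= k)
    q_value: float  # BH-adjusted
    overlap: tuple[str, ...]


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_enrich(
    query: Iterable[str],
    sets: Mapping[str, set[str]],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of ``query`` in each gene set.

    Draw n = |query ∩ universe| genes from a universe of N genes of which
    K = |set ∩ universe| belong to the set; p = P(X >= k) for the observed
    overlap k.  Query members outside the universe are dropped with a
    warning.  Results are sorted by (p, set_name) and carry BH q-values
    across the supplied collection.
    """
    uni = {g.upper() for g in universe}
    if not uni:
        raise ValueError("empty universe")
    q_raw = {g.upper() for g in query}
    dropped = q_raw - uni
    if dropped:
        warnings.warn(f"{len(dropped)} query gene(s) outside universe dropped")
    q = q_raw & uni
    N, n = len(uni), len(q)

    names, pvals, rows = [], [], []
    for name in sorted(sets):
        members = {g.upper() for g in sets[name]} & uni
        K = len(members)
        overlap = tuple(sorted(q & members))
        k = len(overlap)
        # survival function at k-1 gives P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        names.append(name)
        pvals.append(min(p, 1.0))
        rows.append((name, k, K, overlap))
    qvals = bh_adjust(pvals) if pvals else np.array([])
    results = [
        EnrichmentResult(
            set_name=name, k=k, K=K, n=n, N=N,
            p_value=p, q_value=float(qv), overlap=overlap,
        )
        for (name, k, K, overlap), p, qv in zip(rows, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results
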