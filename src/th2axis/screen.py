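"""Receptor-heterodimer co-correlation screen.

Every probe on the array is correlated, within one sample group, against the
two probes encoding the subunits of a cytokine-receptor heterodimer (for the
type II IL-4 receptor: IL4R and IL13RA1).  Probes whose correlation with BOTH
subunits exceeds the sample-size critical |r| are the screen's hits; they are
categorized by sign pattern and collapsed to unique annotated gene symbols.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cohort import critical_r
from .io import ExpressionMatrix

CATEGORIES = (
    "both_positive",
    "both_negative",
    "a_only",
    "b_only",
    "discordant",
    "none",
)

# Tight-junction / desmosomal / JAK-STAT symbols highlighted by default.
DEFAULT_WATCHLIST: frozenset[str] = frozenset(
    [f"CLDN{i}" for i in range(1, 24)]
    + [f"JAM{i}" for i in (1, 2, 3)]
    + [f"DSG{i}" for i in (1, 2, 3, 4)]
    + [f"DSC{i}" for i in (1, 2, 3)]
    + ["CDH1", "CDH2", "CDH3", "CDH12"]
    + ["TJP1", "TJP2", "TJP3"]
    + ["JAK1", "JAK2", "JAK3"]
    + ["STAT1", "STAT2", "STAT3", "STAT6", "LTK", "TYK2"]
)


@dataclass
class ScreenConfig:
    subunit_a_probe: str
    subunit_b_probe: str
    group: str
    alpha: float = 0.05
    r_threshold: float | None = None  # explicit override of critical_r

    def __post_init__(self) -> None:
        if self.subunit_a_probe == self.subunit_b_probe:
            raise ValueError("subunit probes must be distinct")


@dataclass
class ScreenSummary:
    threshold: float
    n_samples: int
    probe_counts: dict[str, int]
    gene_counts: dict[str, int]
    watchlist_hits: dict[str, list[str]] = field(default_factory=dict)


def _pairwise_r_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pearson r and two-tailed t-based p on complete pairs of x, y."""
    from scipy import stats

    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        return np.nan, np.nan, n
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return np.nan, np.nan, n
    res = stats.pearsonr(xs, ys)
    return float(res.statistic), float(res.pvalue), n


def categorize(r_a: float, r_b: float, threshold: float) -> str:
    """Sign-pattern category of one probe given both subunit correlations."""
    if np.isnan(r_a) or np.isnan(r_b):
        return "none"
    sig_a, sig_b = abs(r_a) > threshold, abs(r_b) > threshold
    if sig_a and sig_b:
        if r_a > 0 and r_b > 0:
            return "both_positive"
        if r_a < 0 and r_b < 0:
            return "both_negative"
        return "discordant"
    if sig_a:
        return "a_only"
    if sig_b:
        return "b_only"
    return "none"


def screen_heterodimer(
    matrix: ExpressionMatrix,
    annot: Mapping[str, str],
    cfg: ScreenConfig,
    watchlist: Iterable[str] = DEFAULT_WATCHLIST,
) -> tuple[pd.DataFrame, ScreenSummary]:
    """Correlate every probe against both subunit probes within one group.

    Returns one record per scored probe (the two subunit probes themselves are
    excluded) with columns ``probe_id, gene_symbol, r_a, p_a, r_b, p_b,
    n_complete, category, watchlist``, plus a :class:`ScreenSummary`.
    The threshold is ``critical_r(n, alpha)`` unless ``cfg.r_threshold``
    overrides it.  Probes with fewer than 3 complete pairs against either
    subunit get category ``none`` (r/p are NaN).
    """
    for probe in (cfg.subunit_a_probe, cfg.subunit_b_probe):
        if probe not in matrix.values.index:
            raise ValueError(f"subunit probe {probe!r} absent from matrix")
    samples = matrix.group_samples(cfg.group)
    n = len(samples)
    if n < 3:
        raise ValueError(f"group {cfg.group!r} has n = {n} < 3")
    threshold = (
        cfg.r_threshold if cfg.r_threshold is not None else critical_r(n, cfg.alpha)
    )
    sub = matrix.values[samples]
    vec_a = sub.loc[cfg.subunit_a_probe].to_numpy(float)
    vec_b = sub.loc[cfg.subunit_b_probe].to_numpy(float)
    watch = {w.upper() for w in watchlist}

    rows = []
    for probe_id, row in sub.iterrows():
        if probe_id in (cfg.subunit_a_probe, cfg.subunit_b_probe):
            continue
        x = row.to_numpy(float)
        r_a, p_a, n_a = _pairwise_r_p(x, vec_a)
        r_b, p_b, n_b = _pairwise_r_p(x, vec_b)
        gene = annot.get(probe_id, "")
        rows.append(
            {
                "probe_id": probe_id,
                "gene_symbol": gene,
                "r_a": r_a,
                "p_a": p_a,
                "r_b": r_b,
                "p_b": p_b,
                "n_complete": min(n_a, n_b),
                "category": categorize(r_a, r_b, threshold),
                "watchlist": gene in watch,
            }
        )
    records = pd.DataFrame(
        rows,
        columns=[
            "probe_id", "gene_symbol", "r_a", "p_a", "r_b", "p_b",
            "n_complete", "category", "watchlist",
        ],
    )
    gene_sets = collapse_to_genes(records)
    summary = ScreenSummary(
        threshold=float(threshold),
        n_samples=n,
        probe_counts={c: int((records["category"] == c).sum()) for c in CATEGORIES},
        gene_counts={c: len(gene_sets[c]) for c in CATEGORIES},
        watchlist_hits={
            c: sorted(g for g in gene_sets[c] if g in watch) for c in CATEGORIES
        },
    )
    return records, summary


def collapse_to_genes(records: pd.DataFrame) -> dict[str, set[str]]:
    """Per-category sets of unique annotated gene symbols.

    Unannotated probes (empty symbol) are dropped; a gene belongs to a
    category as soon as one of its probes does.
    """
    out: dict[str, set[str]] = {c: set() for c in CATEGORIES}
    if records.empty:
        return out
    annotated = records[records["gene_symbol"] != ""]
    for cat, grp in annotated.groupby("category"):
        out[str(cat)] = set(grp["gene_symbol"])
    return out


def export_scatter_data(
    records: pd.DataFrame,
    path: str | Path,
) -> pd.DataFrame:
    """Write the per-probe scatter table (one row per scored probe) as TSV."""
    cols = ["probe_id", "gene_symbol", "r_a", "r_b", "category", "watchlist"]
    table = records[cols].copy()
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return table
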