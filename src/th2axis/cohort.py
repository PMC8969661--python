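"""Group-level cohort statistics.

Relative qPCR quantification by the Livak 2^-ddCt method, normality-gated
two-group comparison (Shapiro-Wilk gate choosing Welch t versus Mann-Whitney
U), Pearson correlation with its t-based p-value, and the critical |r|
threshold for a given sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DdctResult:
    """Per-subject relative expression for one target gene.

    ``fold = 2**-ddCt`` with ``dCt = Ct_target - Ct_reference`` and
    ``ddCt = dCt - calibrator``; the calibrator is the arithmetic mean of the
    control-group dCt, so control folds have geometric mean 1.
    """

    gene: str
    calibrator: float
    per_subject: pd.DataFrame  # columns: subject_id, group, dct, ddct, fold


@dataclass
class GatedTestResult:
    method: str  # "t_test" | "mann_whitney"
    statistic: float
    p_value: float
    shapiro_p_a: float
    shapiro_p_b: float
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float


@dataclass
class CorrelationStat:
    r: float
    p_value: float
    n: int


def relative_expression_ddct(
    table: pd.DataFrame,
    gene: str,
    control_group: str = "control",
) -> DdctResult:
    """Livak relative quantification for ``gene``.

    ``table`` needs columns ``subject_id``, ``group``, ``Ct_<gene>`` and
    ``Ct_ref``.  Subjects missing either Ct are dropped with a warning.
    """
    ct_col = f"Ct_{gene}"
    for col in ("subject_id", "group", ct_col, "Ct_ref"):
        if col not in table.columns:
            raise ValueError(f"cohort table lacks column {col!r}")
    sub = table[["subject_id", "group", ct_col, "Ct_ref"]].copy()
    incomplete = sub[ct_col].isna() | sub["Ct_ref"].isna()
    if incomplete.any():
        warnings.warn(
            f"{gene}: dropping {int(incomplete.sum())} subject(s) with missing Ct"
        )
        sub = sub[~incomplete]
    sub["dct"] = sub[ct_col] - sub["Ct_ref"]
    controls = sub.loc[sub["group"] == control_group, "dct"]
    if controls.empty:
        raise ValueError(f"no {control_group!r} subjects with complete Ct values")
    calibrator = float(controls.mean())
    sub["ddct"] = sub["dct"] - calibrator
    sub["fold"] = 2.0 ** (-sub["ddct"])
    out = sub[["subject_id", "group", "dct", "ddct", "fold"]].reset_index(drop=True)
    return DdctResult(gene=gene, calibrator=calibrator, per_subject=out)


def compare_groups(
    values_a,
    values_b,
    alpha_normality: float = 0.05,
    force_method: str | None = None,
) -> GatedTestResult:
    """Two-group comparison gated on Shapiro-Wilk normality.

    Both groups normal at ``alpha_normality`` -> Welch two-sample t-test;
    otherwise Mann-Whitney U (exact when sample sizes permit and there are no
    ties, normal approximation with tie correction otherwise).  A constant
    group makes the gate undefined and falls through to Mann-Whitney.
    All p-values are two-tailed.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")

    def _shapiro_p(x: np.ndarray) -> float:
        if np.ptp(x) == 0:
            warnings.warn("constant group: normality gate undefined")
            return np.nan
        return float(stats.shapiro(x).pvalue)

    sp_a, sp_b = _shapiro_p(a), _shapiro_p(b)
    normal = (sp_a >= alpha_normality) and (sp_b >= alpha_normality)
    method = force_method or ("t_test" if normal else "mann_whitney")
    if method == "t_test":
        res = stats.ttest_ind(a, b, equal_var=False)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif method == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return GatedTestResult(
        method=method,
        statistic=statistic,
        p_value=p,
        shapiro_p_a=sp_a,
        shapiro_p_b=sp_b,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
    )


def pearson_with_p(x, y) -> CorrelationStat:
    """Sample Pearson r with the two-tailed p from the t transform
    ``t = r*sqrt((n-2)/(1-r^2))`` on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationStat(r=float(res.statistic), p_value=float(res.pvalue), n=len(x))


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Smallest |r| significant two-tailed at ``alpha`` for sample size ``n``.

    Inverts the t transform on df = n - 2:  r* = t* / sqrt(t*^2 + df).
    Monotonically decreasing in n.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n - 2
    t_star = stats.t.ppf(1 - alpha / 2, df)
    return float(t_star / np.sqrt(t_star**2 + df))
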