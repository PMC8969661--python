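"""Cohort arm: group differences in serum cytokines and receptor expression.

For each serum analyte, a Shapiro-Wilk-gated two-group test (Welch t when
both groups look normal, Mann-Whitney U otherwise); for each assayed
receptor transcript, Livak 2^-ddCt relative quantification against the
control-group calibrator, followed by the same gated test on the fold
changes.  Writes results/group_tests.tsv and results/ddct_summary.tsv.

Run after analysis/01_simulate.py.
"""

import warnings
from pathlib import Path

import pandas as pd

from th2axis.cohort import compare_groups, relative_expression_ddct

DATA = Path("scratch/data")
OUT = Path("results")
OUT.mkdir(exist_ok=True)

table = pd.read_csv(DATA / "cohort.tsv", sep="\t")
case, control = "case", "control"

rows = []
analytes = [c for c in table.columns
            if c not in ("subject_id", "group") and not c.startswith("Ct_")]
for name in analytes:
    res = compare_groups(
        table.loc[table.group == case, name],
        table.loc[table.group == control, name],
    )
    rows.append({
        "analyte": name, "method": res.method, "p_value": res.p_value,
        "median_case": res.median_a,
        "median_control": res.median_b,
        "n_case": res.n_a, "n_control": res.n_b,
    })
tests = pd.DataFrame(rows)
tests.to_csv(OUT / "group_tests.tsv", sep="\t", index=False, float_format="%.4g")
print("serum analytes (case vs control):")
for _, r in tests.iterrows():
    verdict = "higher in cases" if r.median_case > r.median_control else "no shift"
    print(f"  {r.analyte:>5}: {r.method:12} p = {r.p_value:.2e}  ({verdict})")

ddct_rows = []
for col in table.columns:
    if col.startswith("Ct_") and col != "Ct_ref":
        gene = col[3:]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = relative_expression_ddct(table, gene, control_group=control)
        per = res.per_subject
        folds_case = per.loc[per.group == case, "fold"]
        folds_ctrl = per.loc[per.group == control, "fold"]
        gate = compare_groups(folds_case, folds_ctrl)
        ddct_rows.append({
            "gene": gene,
            "calibrator_dct": res.calibrator,
            "mean_fold_case": folds_case.mean(),
            "mean_fold_control": folds_ctrl.mean(),
            "method": gate.method,
            "p_value": gate.p_value,
        })
ddct = pd.DataFrame(ddct_rows)
ddct.to_csv(OUT / "ddct_summary.tsv", sep="\t", index=False, float_format="%.4g")
print("\nrelative receptor expression (2^-ddCt, control calibrator):")
for _, r in ddct.iterrows():
    print(f"  {r.gene:>8}: mean fold case {r.mean_fold_case:.2f} vs control "
          f"{r.mean_fold_control:.2f}, {r.method} p = {r.p_value:.3f}")
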