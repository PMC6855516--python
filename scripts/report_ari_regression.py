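#!/usr/bin/env python
"""Regress per-cell segmentation ARIs on missing-data covariates.

Report script for real-data analyses (not exercised by the test suite):
given a TSV with one row per (experiment, cell type) containing the ARI
of a partial-data segmentation against the full-data one plus the
missingness covariates, fit marginal (one covariate at a time) and
multiple OLS regressions and print the coefficients.

Expected columns: ari, n_cells_missing, n_lineage_missing, has_missing,
n_marks_missing.

Usage:
    python scripts/report_ari_regression.py aris.tsv
"""

import argparse

import pandas as pd
import statsmodels.api as sm

COVARIATES = ["n_cells_missing", "n_lineage_missing", "has_missing", "n_marks_missing"]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("table")
    args = ap.parse_args()
    df = pd.read_csv(args.table, sep="\t")

    print("marginal regressions:")
    for cov in COVARIATES:
        fit = sm.OLS(df["ari"], sm.add_constant(df[[cov]])).fit()
        print(f"  {cov:18s} coef {fit.params[cov]:+.4f}  p = {fit.pvalues[cov]:.3g}")

    print("multiple regression:")
    fit = sm.OLS(df["ari"], sm.add_constant(df[COVARIATES])).fit()
    for cov in COVARIATES:
        print(f"  {cov:18s} coef {fit.params[cov]:+.4f}  p = {fit.pvalues[cov]:.3g}")


if __name__ == "__main__":
    main()
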