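#!/usr/bin/env python
"""Category-balanced Wilcoxon sign tests comparing two per-gene R^2 tables.

Report script for real-data analyses (not exercised by the test suite):
given two TSV tables of per-gene prediction R^2 (columns: gene, r2) from
two segmentations and an expression table (genes x cells of log2 RPKM)
used to categorize genes, subsample every gene category to the size of
the smallest and run a Wilcoxon signed-rank test per category.

Usage:
    python scripts/report_sign_test.py r2_a.tsv r2_b.tsv expr.tsv --seed 1
"""

import argparse

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from segem.expression import categorize_genes


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("r2_a")
    ap.add_argument("r2_b")
    ap.add_argument("expr", help="TSV, genes as rows, cells as columns, log2 RPKM")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    a = pd.read_csv(args.r2_a, sep="\t").set_index("gene")["r2"]
    b = pd.read_csv(args.r2_b, sep="\t").set_index("gene")["r2"]
    expr = pd.read_csv(args.expr, sep="\t", index_col=0)
    genes = a.index.intersection(b.index).intersection(expr.index)
    cats = pd.Series(
        categorize_genes(expr.loc[genes].to_numpy().T), index=genes
    )

    rng = np.random.default_rng(args.seed)
    n_min = cats.value_counts().min()
    print(f"balanced subsample size per category: {n_min}")
    for cat, members in cats.groupby(cats):
        pick = rng.choice(members.index, size=n_min, replace=False)
        diff = (a.loc[pick] - b.loc[pick]).dropna()
        stat, p = wilcoxon(diff)
        print(f"{cat:14s} median diff {diff.median():+.4f}  p = {p:.3g}")


if __name__ == "__main__":
    main()
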