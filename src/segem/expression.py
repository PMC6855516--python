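"""Predicting expression and enhancer signals from chromatin-state occupancy.

A segmentation assigns a categorical state per bin; to use it as a
regression predictor, the state profile of a genomic region is first
summarized as the fraction of the region's bins occupied by each state
(its occupancy vector).  Regressing expression on TSS-region occupancy
across all genes and cell types yields one coefficient per state, and
the dot product of a region's occupancy with those coefficients converts
the categorical profile into a single numeric predictor, regardless of
the number of states.  For example, with coefficients 3 and -2 for two
states and occupancies 20%/80%, the region's value is
3*0.2 + (-2)*0.8 = -1.

Expression is then predicted either across genes within each cell type
or across cell types for each gene, from the TSS predictor, the distal
predictor (bins within 500 kb but beyond 2 kb of the TSS), or both;
power is summarized by R^2 and adjusted R^2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import Segmentation

__all__ = [
    "region_occupancy",
    "tss_occupancy",
    "distal_occupancy",
    "state_coefficients",
    "region_predictor",
    "predict_expression",
    "categorize_genes",
    "erna_reference",
]

TSS_FLANK = 2_000
DISTAL_FLANK = 500_000


def _tss_position(row: pd.Series) -> int:
    # BED6 convention: TSS = start on +, end-1 on -
    return int(row["start"]) if row.get("strand", "+") != "-" else int(row["end"]) - 1


def region_occupancy(
    labels: np.ndarray,
    bins: pd.DataFrame,
    regions: list[tuple[str, int, int]],
    K: int,
) -> np.ndarray:
    """Fraction of each region's bins per state, for one cell type.

    Bins are attributed to a region when their interval lies within it
    (0-based half-open coordinates); each returned row sums to 1.
    Regions covering no bin yield a NaN row.
    """
    labels = np.asarray(labels).ravel()
    starts = bins["start"].to_numpy()
    width = int((bins["end"] - bins["start"]).iloc[0])
    chroms = bins["chrom"].to_numpy()
    occ = np.full((len(regions), K), np.nan)
    for r, (chrom, s, e) in enumerate(regions):
        sel = (chroms == chrom) & (starts >= s) & (starts + width <= e)
        idx = np.flatnonzero(sel)
        if len(idx) == 0:
            continue
        occ[r] = np.bincount(labels[idx], minlength=K) / len(idx)
    return occ


def _windows(tss_table: pd.DataFrame, core: int, outer: int | None = None):
    """(chrom, start, end) windows around each TSS; distal = ring outside the core."""
    wins = []
    for _, row in tss_table.iterrows():
        t = _tss_position(row)
        if outer is None:
            wins.append((row["chrom"], max(t - core, 0), t + core))
        else:
            wins.append(
                (row["chrom"], max(t - outer, 0), t + outer, max(t - core, 0), t + core)
            )
    return wins


def tss_occupancy(
    seg: Segmentation, bins: pd.DataFrame, tss_table: pd.DataFrame, K: int,
    flank: int = TSS_FLANK,
) -> np.ndarray:
    """Occupancy over +/-`flank` TSS-centered windows; (cells, genes, K)."""
    regions = _windows(tss_table, flank)
    return np.stack(
        [region_occupancy(seg.labels[i], bins, regions, K) for i in range(seg.n_cells)]
    )


def distal_occupancy(
    seg: Segmentation, bins: pd.DataFrame, tss_table: pd.DataFrame, K: int,
    core: int = TSS_FLANK, outer: int = DISTAL_FLANK,
) -> np.ndarray:
    """Occupancy over bins within `outer` of the TSS but outside the `core` window.

    Bins are weighted uniformly across the window (bin-weighted).
    """
    labels = seg.labels
    starts = bins["start"].to_numpy()
    width = int((bins["end"] - bins["start"]).iloc[0])
    chroms = bins["chrom"].to_numpy()
    occ = np.full((seg.n_cells, len(tss_table), K), np.nan)
    for g, (_, row) in enumerate(tss_table.iterrows()):
        t = _tss_position(row)
        in_outer = (
            (chroms == row["chrom"])
            & (starts >= max(t - outer, 0))
            & (starts + width <= t + outer)
        )
        in_core = (starts >= max(t - core, 0)) & (starts + width <= t + core)
        idx = np.flatnonzero(in_outer & ~in_core)
        if len(idx) == 0:
            continue
        for i in range(seg.n_cells):
            occ[i, g] = np.bincount(labels[i][idx], minlength=K) / len(idx)
    return occ


def state_coefficients(occupancy: np.ndarray, expr: np.ndarray) -> np.ndarray:
    """Per-state coefficients from regressing expression on occupancy fractions.

    ``occupancy`` is (n_rows, K) of stacked (gene, cell) rows; ``expr``
    the matching log2 RPKM values.  Because occupancy rows sum to 1 the
    design with an intercept is rank-deficient by one; the fit uses the
    minimum-norm least-squares solution (pseudo-inverse), which resolves
    the ambiguity deterministically.  Returns the K state coefficients
    (the intercept column is dropped).
    """
    occupancy = np.asarray(occupancy, dtype=float)
    expr = np.asarray(expr, dtype=float).ravel()
    keep = np.isfinite(expr) & np.all(np.isfinite(occupancy), axis=1)
    occupancy, expr = occupancy[keep], expr[keep]
    K = occupancy.shape[1]
    if occupancy.shape[0] < K + 1:
        raise ValueError(f"need at least K+1={K + 1} (gene, cell) rows")
    X = np.column_stack([np.ones(len(expr)), occupancy])
    coef, *_ = np.linalg.lstsq(X, expr, rcond=None)
    # fold the intercept into the state coefficients (rows sum to 1)
    return coef[1:] + coef[0]


def region_predictor(occupancy: np.ndarray, coef: np.ndarray) -> np.ndarray:
    """Numeric region value: occupancy fractions dotted with state coefficients."""
    occupancy = np.atleast_2d(np.asarray(occupancy, dtype=float))
    coef = np.asarray(coef, dtype=float).ravel()
    if occupancy.shape[1] != coef.size:
        raise ValueError("coefficient length does not match number of states")
    sums = occupancy.sum(axis=1)
    ok = np.isfinite(sums)
    if np.any(np.abs(sums[ok] - 1.0) > 1e-6):
        r = int(np.flatnonzero(ok & (np.abs(sums - 1.0) > 1e-6))[0])
        raise ValueError(f"occupancy row {r} sums to {sums[r]:.6g}, not 1")
    out = occupancy @ coef
    return out if out.size > 1 else float(out[0])


def _r2(y: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    """(R^2, adjusted R^2) of an OLS fit with intercept."""
    n, k = X.shape
    Xd = np.column_stack([np.ones(n), X])
    coef, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return np.nan, np.nan
    r2 = 1.0 - float(np.sum(resid**2)) / tss
    if n - k - 1 <= 0:
        return r2, np.nan
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    return r2, adj


def predict_expression(
    tss_pred: np.ndarray,
    distal_pred: np.ndarray | None,
    expr: np.ndarray,
    axis: str = "across_genes",
) -> pd.DataFrame:
    """R^2 of predicting expression from the numeric region predictors.

    All inputs are (cells, genes) arrays (``distal_pred`` may be None for
    a TSS-only model).  ``axis="across_genes"`` fits one regression per
    cell type over genes; ``axis="across_cells"`` fits one per gene over
    cell types.  Fits with fewer than 3 finite observations give NaN.
    """
    tss_pred = np.asarray(tss_pred, dtype=float)
    expr = np.asarray(expr, dtype=float)
    if tss_pred.shape != expr.shape:
        raise ValueError("predictors are not aligned to the expression table")
    if axis == "across_cells":
        tss_pred, expr = tss_pred.T, expr.T
        distal_pred = None if distal_pred is None else np.asarray(distal_pred).T
    elif axis != "across_genes":
        raise ValueError(f"unknown axis {axis!r}")
    rows = []
    for i in range(expr.shape[0]):
        preds = [tss_pred[i]]
        if distal_pred is not None:
            preds.append(distal_pred[i])
        X = np.column_stack(preds)
        y = expr[i]
        keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
        if keep.sum() < 3:
            rows.append({"unit": i, "r2": np.nan, "adj_r2": np.nan, "n": int(keep.sum())})
            continue
        r2, adj = _r2(y[keep], X[keep])
        rows.append({"unit": i, "r2": r2, "adj_r2": adj, "n": int(keep.sum())})
    return pd.DataFrame(rows)


def categorize_genes(expr: np.ndarray) -> np.ndarray:
    """Four-way gene categories from mean/sd of log2 RPKM across cell types.

    Thresholds: mean log2 RPKM at -1 and sd at 2.  Boundary values are
    assigned to the "high" side.  Labels: ``off`` (low mean, low sd),
    ``low-variable`` (low mean, high sd), ``high-variable`` (high mean,
    high sd), ``on`` (high mean, low sd).
    """
    expr = np.asarray(expr, dtype=float)  # (cells, genes)
    mean = np.nanmean(expr, axis=0)
    sd = np.nanstd(expr, axis=0, ddof=1)
    hi_mean = mean >= -1
    hi_sd = sd >= 2
    out = np.where(
        hi_mean,
        np.where(hi_sd, "high-variable", "on"),
        np.where(hi_sd, "low-variable", "off"),
    )
    return out


def erna_reference(
    erna_tpm: np.ndarray, erna_peaks: np.ndarray, eps: float = 1e-3
) -> tuple[np.ndarray, np.ndarray]:
    """Region-level enhancer reference signals averaged over libraries.

    ``erna_tpm`` and ``erna_peaks`` are (libraries, regions) tables of TPM
    values and binary peak presence.  Returns the per-region mean of
    log2(TPM + 0.1) and the logit of the mean presence (clamped to
    [eps, 1-eps] first).
    """
    erna_tpm = np.asarray(erna_tpm, dtype=float)
    erna_peaks = np.asarray(erna_peaks, dtype=float)
    if erna_tpm.ndim != 2 or erna_peaks.ndim != 2:
        raise ValueError("library tables must be 2-d (libraries, regions)")
    log_tpm = np.log2(erna_tpm + 0.1).mean(axis=0)
    presence = np.clip(erna_peaks.mean(axis=0), eps, 1 - eps)
    return log_tpm, np.log(presence / (1 - presence))
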