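"""Segmentation comparison metrics: ARI, cell-type distances, peak recovery.

The agreement between two segmentations of the same bins is measured by
the adjusted Rand index (ARI), which corrects the pair-counting Rand
index for chance, so different state counts and unbalanced state sizes
are handled.  One minus ARI serves as a segmentation-based distance
between cell types, and the Spearman correlation of a cell's distance
vector against the full-data one measures how well cell-type
relationships are preserved under missing data.

Peak recovery: peaks of a mark are called per cell type by a z-test on
the log-scale track (null mean/sd estimated from all bins of the track)
with Benjamini-Hochberg control at FDR 0.05, and the segmentation is
scored by the area under the precision-recall curve obtained from
predicting peaks with the top-k states ranked by that mark's emission
means, k = 1..K.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import norm, spearmanr
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from .core import Segmentation, StateModel

__all__ = [
    "adjusted_rand_index",
    "segmentation_similarity",
    "cell_distance_matrix",
    "distance_concordance",
    "call_peaks",
    "pr_auc_by_state",
]


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected Rand index between two labelings of the same items."""
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError(f"label sequences differ in length: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("need at least 2 items")
    return float(adjusted_rand_score(a, b))


def segmentation_similarity(
    segA: Segmentation, segB: Segmentation, scope: str = "per_cell"
):
    """ARI between two segmentations, per cell or pooled over (cell, bin)."""
    if segA.labels.shape != segB.labels.shape:
        raise ValueError("segmentations differ in cells or bins")
    if scope == "pooled":
        return adjusted_rand_index(segA.labels.ravel(), segB.labels.ravel())
    if scope == "per_cell":
        return np.array(
            [
                adjusted_rand_index(segA.labels[i], segB.labels[i])
                for i in range(segA.n_cells)
            ]
        )
    raise ValueError(f"unknown scope {scope!r}")


def cell_distance_matrix(seg: Segmentation) -> np.ndarray:
    """Pairwise cell-type distances D[i, j] = 1 - ARI(labels_i, labels_j)."""
    n = seg.n_cells
    if n < 2:
        raise ValueError("need at least 2 cell types")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - adjusted_rand_index(seg.labels[i], seg.labels[j])
            D[i, j] = D[j, i] = d
    return D


def distance_concordance(D_partial: np.ndarray, D_full: np.ndarray) -> np.ndarray:
    """Per-cell Spearman correlation of distance vectors (diagonal excluded)."""
    D_partial = np.asarray(D_partial, dtype=float)
    D_full = np.asarray(D_full, dtype=float)
    if D_partial.shape != D_full.shape:
        raise ValueError("distance matrices differ in shape")
    n = D_partial.shape[0]
    out = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        x, y = D_partial[i, keep], D_full[i, keep]
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(
                f"constant distance row for cell {i}; concordance undefined",
                RuntimeWarning,
                stacklevel=2,
            )
            out[i] = np.nan
        else:
            out[i] = spearmanr(x, y).statistic
    return out


def call_peaks(signal: np.ndarray, fdr: float = 0.05) -> np.ndarray:
    """Call peak bins of one (cell, mark) track by a z-test at genome-wide FDR.

    The null mean and standard deviation are estimated from all bins of
    the track (the whole-genome estimate, which is deliberately
    contaminated by true peaks), one-sided upper-tail p-values are
    computed per bin, and Benjamini-Hochberg selects peaks at the given
    FDR.  See :func:`call_peaks_robust` for a median/MAD null.
    """
    return _call_peaks(signal, fdr, robust=False)


def _call_peaks(signal: np.ndarray, fdr: float = 0.05, robust: bool = False) -> np.ndarray:
    x = np.asarray(signal, dtype=float).ravel()
    if x.size < 100:
        raise ValueError("need at least 100 bins to estimate the null")
    if robust:
        mu = float(np.median(x))
        sd = 1.4826 * float(np.median(np.abs(x - mu)))
    else:
        mu = float(x.mean())
        sd = float(x.std())
    if sd == 0:
        raise ValueError("zero standard deviation: cannot form z-scores")
    p = norm.sf((x - mu) / sd)
    reject, *_ = multipletests(p, alpha=fdr, method="fdr_bh")
    return reject


def call_peaks_robust(signal: np.ndarray, fdr: float = 0.05) -> np.ndarray:
    """Peak calling with a median/MAD null, less contaminated by true peaks."""
    return _call_peaks(signal, fdr, robust=True)


def pr_auc_by_state(
    labels: np.ndarray,
    model: StateModel,
    peaks: np.ndarray,
    mark: int,
) -> float:
    """AUC of the state-ranked precision-recall curve for one cell and mark.

    States are ordered by decreasing emission mean of the mark (ties by
    state index); for each k, the bins labeled with any of the top-k
    states predict the peak set, giving one (recall, precision) point.
    The K-point curve is prepended with the recall-0 limit (precision 1)
    and integrated by the trapezoid rule over recall.
    """
    labels = np.asarray(labels).ravel()
    peaks = np.asarray(peaks, dtype=bool).ravel()
    if labels.shape != peaks.shape:
        raise ValueError("labels and peaks differ in length")
    n_pos = int(peaks.sum())
    if n_pos == 0:
        warnings.warn("no peaks: PR-AUC undefined", RuntimeWarning, stacklevel=2)
        return float("nan")
    order = np.lexsort((np.arange(model.K), -model.mean[:, mark]))
    recalls = [0.0]
    precisions = [1.0]
    pred = np.zeros_like(peaks)
    for k in order:
        pred |= labels == k
        npred = int(pred.sum())
        tp = int((pred & peaks).sum())
        precisions.append(tp / npred if npred else 1.0)
        recalls.append(tp / n_pos)
    return float(np.trapezoid(precisions, recalls))


def pr_auc_per_cell(
    seg: Segmentation, model: StateModel, peaks: np.ndarray, mark: int
) -> np.ndarray:
    """``pr_auc_by_state`` for every cell; ``peaks`` is (cells, bins) for the mark."""
    return np.array(
        [
            pr_auc_by_state(seg.labels[i], model, peaks[i], mark)
            for i in range(seg.n_cells)
        ]
    )
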