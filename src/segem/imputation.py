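"""Post-segmentation imputation of missing mark signals.

Once the genome is segmented, a missing (cell, mark, bin) value is
predicted from the emission distribution of the chromatin state at that
bin: either the state mean of the hard-assigned state (``mode="hard"``)
or the posterior-weighted average of state means (``mode="posterior"``,
the default).  Observed entries pass through unchanged.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .core import Segmentation, SignalTensor, StateModel

__all__ = ["impute_marks", "imputation_accuracy"]


def impute_marks(
    tensor: SignalTensor,
    model: StateModel,
    seg: Segmentation,
    mode: str = "posterior",
) -> SignalTensor:
    """Fill every missing (cell, mark) slice from the state emission means.

    Returns a new tensor with a full observation mask; observed entries
    are bit-identical to the input.
    """
    if mode not in ("hard", "posterior"):
        raise ValueError(f"unknown mode {mode!r}")
    if seg.labels.shape != (tensor.n_cells, tensor.n_bins):
        raise ValueError("segmentation does not cover all (cell, bin)")
    if model.p < tensor.n_marks:
        raise ValueError("model marks must be a superset of the tensor's marks")
    if mode == "posterior" and seg.posterior is None:
        raise ValueError("mode='posterior' requires a posterior matrix in the segmentation")

    values = tensor.values.copy()
    for i in range(tensor.n_cells):
        missing = np.flatnonzero(~tensor.mask[i])
        if len(missing) == 0:
            continue
        if mode == "hard":
            fill = model.mean[seg.labels[i]][:, missing]  # (n_bins, n_missing)
        else:
            fill = seg.posterior[i] @ model.mean[:, missing]
        values[i, missing, :] = fill.T
    return SignalTensor(
        values,
        np.ones_like(tensor.mask, dtype=bool),
        tensor.bins,
        list(tensor.mark_names),
        list(tensor.cell_names),
    )


def imputation_accuracy(
    imputed: SignalTensor,
    truth: SignalTensor,
    held_out: np.ndarray,
) -> pd.DataFrame:
    """Pearson, Spearman and MAE per held-out (cell, mark) slice.

    ``held_out`` is a boolean (cell, mark) matrix selecting the slices to
    score; it must be a subset of the truth tensor's observed set.
    Correlations against a zero-variance vector are undefined and reported
    as NaN with a warning.
    """
    held_out = np.asarray(held_out, dtype=bool)
    if held_out.shape != truth.mask.shape:
        raise ValueError("held_out shape does not match (cells, marks)")
    if np.any(held_out & ~truth.mask):
        raise ValueError("held_out slices must be observed in the truth tensor")
    rows = []
    for i, j in zip(*np.nonzero(held_out)):
        x = imputed.values[i, j]
        y = truth.values[i, j]
        mae = float(np.mean(np.abs(x - y)))
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(
                f"zero-variance vector for cell {truth.cell_names[i]!r}, "
                f"mark {truth.mark_names[j]!r}; correlations undefined",
                RuntimeWarning,
                stacklevel=2,
            )
            pr = sr = np.nan
        else:
            pr = float(pearsonr(x, y).statistic)
            sr = float(spearmanr(x, y).statistic)
        rows.append(
            {
                "cell": truth.cell_names[i],
                "mark": truth.mark_names[j],
                "pearson": pr,
                "spearman": sr,
                "mae": mae,
            }
        )
    return pd.DataFrame(rows, columns=["cell", "mark", "pearson", "spearman", "mae"])
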