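"""Shared domain types for multi-cell-type chromatin-state segmentation.

The central container is :class:`SignalTensor`: binned, log-transformed
chromatin-mark signal for several cell types over a common genomic bin
grid, together with a per-(cell type, mark) availability mask.  Missingness
is *block* missingness — a mark is either observed for every bin of a cell
type or absent entirely — which is what the marginal-emission model and the
sufficient-statistics EM operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SignalTensor",
    "MissingnessPattern",
    "MomentMatrix",
    "RegressionMap",
    "StateModel",
    "LocusPrior",
    "Segmentation",
    "enumerate_patterns",
    "cell_weights",
]


@dataclass
class SignalTensor:
    """Cell-type x mark x bin signal values with a block-missingness mask.

    Parameters
    ----------
    values
        Array of shape ``(n_cells, n_marks, n_bins)``.  Signal is assumed
        to already be on the log scale (``log2(x + 0.1)`` of the raw
        track values).  Entries of masked-out (cell, mark) slices are NaN.
    mask
        Boolean array of shape ``(n_cells, n_marks)``; ``True`` iff the
        mark is observed in that cell type.
    bins
        DataFrame with columns ``chrom``, ``start``, ``end`` describing the
        ordered, fixed-width genomic bins shared by all cell types.
    mark_names, cell_names
        Identifier lists; define the canonical global mark order used by
        every moment matrix.
    """

    values: np.ndarray
    mask: np.ndarray
    bins: pd.DataFrame
    mark_names: list[str]
    cell_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("values must be 3-d (cells, marks, bins)")
        n_cells, p, _ = self.values.shape
        if self.mask.shape != (n_cells, p):
            raise ValueError(
                f"mask shape {self.mask.shape} does not match values {self.values.shape[:2]}"
            )
        if len(self.mark_names) != p or len(self.cell_names) != n_cells:
            raise ValueError("mark_names/cell_names lengths do not match values")
        if len(self.bins) != self.values.shape[2]:
            raise ValueError("bins length does not match values")

    # -- basic geometry -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_marks(self) -> int:
        return self.values.shape[1]

    @property
    def n_bins(self) -> int:
        return self.values.shape[2]

    @property
    def bin_size(self) -> int:
        widths = (self.bins["end"] - self.bins["start"]).to_numpy()
        return int(widths[0]) if len(widths) else 0

    def validate(self) -> None:
        """Check the block-missingness contract.

        Observed (cell, mark) slices must be entirely finite; masked-out
        slices must carry no finite values.  A sporadic NaN inside an
        observed slice is an input error and is reported with its
        location.
        """
        widths = (self.bins["end"] - self.bins["start"]).to_numpy()
        if len(widths) and not np.all(widths == widths[0]):
            raise ValueError("bins are not of constant width")
        for i in range(self.n_cells):
            for j in range(self.n_marks):
                finite = np.isfinite(self.values[i, j])
                if self.mask[i, j]:
                    if not finite.all():
                        b = int(np.flatnonzero(~finite)[0])
                        raise ValueError(
                            f"non-finite value in observed slice: cell "
                            f"{self.cell_names[i]!r}, mark {self.mark_names[j]!r}, bin {b}"
                        )
                elif finite.any():
                    b = int(np.flatnonzero(finite)[0])
                    raise ValueError(
                        f"finite value in masked-out slice: cell "
                        f"{self.cell_names[i]!r}, mark {self.mark_names[j]!r}, bin {b}"
                    )

    # -- subsetting ------------------------------------------------------
    def subset_cells(self, idx: Sequence[int]) -> "SignalTensor":
        idx = list(idx)
        return SignalTensor(
            self.values[idx].copy(),
            self.mask[idx].copy(),
            self.bins,
            list(self.mark_names),
            [self.cell_names[i] for i in idx],
        )

    def subset_marks(self, idx: Sequence[int]) -> "SignalTensor":
        idx = list(idx)
        return SignalTensor(
            self.values[:, idx].copy(),
            self.mask[:, idx].copy(),
            self.bins,
            [self.mark_names[j] for j in idx],
            list(self.cell_names),
        )

    def copy(self) -> "SignalTensor":
        return SignalTensor(
            self.values.copy(),
            self.mask.copy(),
            self.bins.copy(),
            list(self.mark_names),
            list(self.cell_names),
        )


@dataclass(frozen=True)
class MissingnessPattern:
    """One missing-data configuration: the cells sharing an observed-mark set."""

    observed: tuple[int, ...]  # sorted mark indices, canonical global order
    cells: tuple[int, ...]  # cell indices sharing exactly this set
    n_marks: int  # total number of marks p

    @property
    def missing(self) -> tuple[int, ...]:
        obs = set(self.observed)
        return tuple(j for j in range(self.n_marks) if j not in obs)

    @property
    def is_complete(self) -> bool:
        return len(self.observed) == self.n_marks


def enumerate_patterns(tensor: SignalTensor) -> list[MissingnessPattern]:
    """Partition cell types by identical observed-mark sets.

    Patterns are returned in a stable order: by the first member cell's
    index.  A cell type with no observed marks is an error.
    """
    groups: dict[tuple[int, ...], list[int]] = {}
    order: list[tuple[int, ...]] = []
    for i in range(tensor.n_cells):
        obs = tuple(int(j) for j in np.flatnonzero(tensor.mask[i]))
        if not obs:
            raise ValueError(f"cell type has no data: {tensor.cell_names[i]!r}")
        if obs not in groups:
            groups[obs] = []
            order.append(obs)
        groups[obs].append(i)
    return [
        MissingnessPattern(obs, tuple(groups[obs]), tensor.n_marks) for obs in order
    ]


def cell_weights(tensor: SignalTensor) -> np.ndarray:
    """Per-cell-type weight w_i = (#observed marks in cell i) / p.

    Cell types with fewer marks carry proportionally less weight in the
    state-assignment counts (locus prior and state frequencies); the raw
    ratio is not renormalized across cells.  The weights do not enter the
    Gaussian parameter estimation within states.
    """
    if tensor.n_marks < 1:
        raise ValueError("need at least one mark")
    return tensor.mask.sum(axis=1) / float(tensor.n_marks)


@dataclass
class MomentMatrix:
    """Augmented sufficient-statistics matrix V for one chromatin state.

    ``V`` is ``(1+p) x (1+p)`` in canonical global mark order: ``V[0, 0]``
    is the (effective, possibly fractional) count n, ``V[0, 1:]`` the
    per-mark sums, and ``V[1:, 1:]`` the mark x mark cross-product sums.
    Gaussian mean and covariance are read off directly.
    """

    V: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        if self.V.ndim != 2 or self.V.shape[0] != self.V.shape[1]:
            raise ValueError("V must be square")

    @property
    def p(self) -> int:
        return self.V.shape[0] - 1

    @property
    def n(self) -> float:
        return float(self.V[0, 0])

    @property
    def mean(self) -> np.ndarray:
        return self.V[0, 1:] / self.V[0, 0]

    @property
    def cov(self) -> np.ndarray:
        m = self.mean
        return self.V[1:, 1:] / self.V[0, 0] - np.outer(m, m)


@dataclass
class RegressionMap:
    """Least-squares map predicting missing marks from observed marks.

    ``beta = Sigma_mo Sigma_oo^-1`` and ``alpha = mu_m - beta mu_o`` under
    the Gaussian implied by a moment matrix.  ``cond_cov`` is the
    conditional covariance ``Sigma_mm - Sigma_mo Sigma_oo^-1 Sigma_om``
    used by the corrected EM variant.
    """

    alpha: np.ndarray  # (n_missing,)
    beta: np.ndarray  # (n_missing, n_observed)
    cond_cov: np.ndarray | None = None  # (n_missing, n_missing)


@dataclass
class StateModel:
    """Per-state Gaussian emission parameters over all p marks."""

    mean: np.ndarray  # (K, p)
    cov: np.ndarray  # (K, p, p)
    state_freq: np.ndarray  # (K,), sums to 1
    mark_names: list[str] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.mean.shape[0]

    @property
    def p(self) -> int:
        return self.mean.shape[1]


@dataclass
class LocusPrior:
    """Per-bin state-propensity vectors shared across cell types.

    This is the positional component of the model: genomic positions tend
    to carry correlated chromatin states across cell types, so each bin
    keeps a propensity vector over states, estimated from the weighted
    posterior state counts of all cell types at that bin.  It is what lets
    data-rich cell types inform segmentation of data-poor ones.
    """

    propensity: np.ndarray  # (n_bins, K), rows sum to 1
    concentration: float = 1.0  # pseudocount strength used in its update


@dataclass
class Segmentation:
    """Per-cell-type, per-bin chromatin-state labels (plus optional posteriors)."""

    labels: np.ndarray  # (n_cells, n_bins) int
    posterior: np.ndarray | None = None  # (n_cells, n_bins, K)
    cell_names: list[str] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return self.labels.shape[0]

    @property
    def n_bins(self) -> int:
        return self.labels.shape[1]

    def subset_cells(self, idx: Sequence[int]) -> "Segmentation":
        idx = list(idx)
        return Segmentation(
            self.labels[idx].copy(),
            None if self.posterior is None else self.posterior[idx].copy(),
            [self.cell_names[i] for i in idx] if self.cell_names else [],
        )


def _replace(obj, **kw):
    return replace(obj, **kw)
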