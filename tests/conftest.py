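import numpy as np
import pandas as pd
import pytest

from segem.core import SignalTensor


def make_bins(n_bins: int, width: int = 200) -> pd.DataFrame:
    starts = np.arange(n_bins) * width
    return pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + width})


def make_tensor(values: np.ndarray, mask: np.ndarray | None = None) -> SignalTensor:
    """SignalTensor from a (cells, marks, bins) array; NaN-out masked slices."""
    values = np.asarray(values, dtype=float)
    n_cells, p, n_bins = values.shape
    if mask is None:
        mask = np.ones((n_cells, p), dtype=bool)
    values = values.copy()
    for i in range(n_cells):
        for j in range(p):
            if not mask[i, j]:
                values[i, j] = np.nan
    return SignalTensor(
        values,
        np.asarray(mask, dtype=bool),
        make_bins(n_bins),
        [f"mark{j + 1}" for j in range(p)],
        [f"cell{i + 1}" for i in range(n_cells)],
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
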