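"""Track readers/writers and preprocessing.

Signal tracks (bedGraph or fixed-step wig, typically -log10 Poisson
p-values) are averaged into fixed-width genomic bins (200 bp by default),
bins overlapping a blacklist are dropped, and values are variance-
stabilized with ``log2(x + 0.1)`` before modeling.  Segmentations are
written as BED9 with one itemRgb color per state and merged runs of equal
states, and round-trip losslessly through the reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Segmentation, SignalTensor, StateModel

__all__ = [
    "read_bedgraph",
    "read_fixedstep_wig",
    "read_bed3",
    "bin_signal",
    "transform_signal",
    "default_palette",
    "write_segmentation_bed",
    "read_segmentation_bed",
    "write_model_json",
    "read_model_json",
    "read_manifest",
    "load_tensor",
]

BIN_SIZE = 200


# ---------------------------------------------------------------------------
# track parsing


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph track into (chrom, start, end, value)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": int, "end": int, "value": float},
    )
    return df


def read_fixedstep_wig(path: str | Path) -> pd.DataFrame:
    """Read a fixed-step wig track into bedGraph-like intervals."""
    rows = []
    chrom, pos, step, span = None, 0, 1, None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(f.split("=") for f in line.split()[1:])
                chrom = fields["chrom"]
                pos = int(fields["start"]) - 1  # wig is 1-based
                step = int(fields.get("step", 1))
                span = int(fields.get("span", step))
                continue
            if chrom is None:
                raise ValueError("wig data line before any fixedStep header")
            rows.append((chrom, pos, pos + span, float(line)))
            pos += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def read_bed3(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={"chrom": str, "start": int, "end": int},
    )
    return df


# ---------------------------------------------------------------------------
# binning and transform


def _check_sorted(track: pd.DataFrame) -> None:
    for chrom, grp in track.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        bad = np.flatnonzero(starts[1:] < ends[:-1])
        if len(bad):
            i = grp.index[bad[0] + 1]
            raise ValueError(
                f"track intervals unsorted or overlapping at line {i}: "
                f"{chrom}:{starts[bad[0] + 1]}"
            )


def bin_signal(
    track: pd.DataFrame,
    bin_size: int = BIN_SIZE,
    blacklist: pd.DataFrame | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Coverage-weighted mean of a track per fixed-width bin.

    Bins tile each chromosome from coordinate 0; a trailing partial bin
    is dropped.  Bins with no coverage get value 0.  Bins overlapping any
    blacklist interval by at least 1 bp are removed from the output.
    Returns (chrom, start, end, value) rows in genomic order.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    _check_sorted(track)
    frames = []
    for chrom, grp in track.groupby("chrom", sort=False):
        size = (chrom_sizes or {}).get(chrom, int(grp["end"].max()))
        n_bins = size // bin_size
        if n_bins == 0:
            continue
        sums = np.zeros(n_bins)
        for s, e, v in grp[["start", "end", "value"]].itertuples(index=False):
            e = min(e, n_bins * bin_size)
            if e <= s:
                continue
            b0, b1 = s // bin_size, (e - 1) // bin_size
            if b0 == b1:
                sums[b0] += (e - s) * v
            else:
                sums[b0] += ((b0 + 1) * bin_size - s) * v
                sums[b1] += (e - b1 * bin_size) * v
                if b1 > b0 + 1:
                    sums[b0 + 1 : b1] += bin_size * v
        starts = np.arange(n_bins) * bin_size
        df = pd.DataFrame(
            {
                "chrom": chrom,
                "start": starts,
                "end": starts + bin_size,
                "value": sums / bin_size,
            }
        )
        if blacklist is not None:
            bl = blacklist[blacklist["chrom"] == chrom]
            drop = np.zeros(n_bins, dtype=bool)
            for s, e in bl[["start", "end"]].itertuples(index=False):
                lo = max(s // bin_size, 0)
                hi = min((max(e, s + 1) - 1) // bin_size, n_bins - 1)
                if lo < n_bins and hi >= 0:
                    drop[lo : hi + 1] = True
            df = df[~drop]
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "value"])
    return pd.concat(frames, ignore_index=True)


def transform_signal(x):
    """Variance-stabilizing transform log2(x + 0.1) of non-negative signal."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("signal values must be non-negative")
    out = np.log2(x + 0.1)
    return out if out.ndim else float(out)


def inverse_transform_signal(y):
    """Inverse of :func:`transform_signal`: 2**y - 0.1, clipped at 0."""
    y = np.asarray(y, dtype=float)
    out = np.clip(np.exp2(y) - 0.1, 0.0, None)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# segmentation BED9


def default_palette(K: int) -> list[str]:
    """Deterministic itemRgb color per state."""
    rng = np.random.default_rng(12345)
    cols = rng.integers(0, 256, size=(max(K, 1), 3))
    return [f"{r},{g},{b}" for r, g, b in cols]


def write_segmentation_bed(
    seg: Segmentation,
    bins: pd.DataFrame,
    out_dir: str | Path,
    palette: list[str] | None = None,
    prefix: str = "seg",
) -> list[Path]:
    """One BED9 file per cell type with adjacent equal-state bins merged."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    K = int(seg.labels.max()) + 1 if seg.labels.size else 1
    palette = palette or default_palette(K)
    chroms = bins["chrom"].to_numpy()
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    paths = []
    names = seg.cell_names or [f"cell{i + 1}" for i in range(seg.n_cells)]
    for i in range(seg.n_cells):
        lab = seg.labels[i]
        path = out_dir / f"{prefix}_{names[i]}.bed"
        with open(path, "w") as fh:
            run_start = 0
            for b in range(1, len(lab) + 1):
                boundary = (
                    b == len(lab)
                    or lab[b] != lab[run_start]
                    or chroms[b] != chroms[run_start]
                    or starts[b] != ends[b - 1]
                )
                if boundary:
                    s, e = starts[run_start], ends[b - 1]
                    k = int(lab[run_start])
                    fh.write(
                        f"{chroms[run_start]}\t{s}\t{e}\tS{k}\t0\t.\t{s}\t{e}\t{palette[k]}\n"
                    )
                    run_start = b
        paths.append(path)
    return paths


def read_segmentation_bed(paths: list[str | Path], bins: pd.DataFrame) -> Segmentation:
    """Read BED9 segmentations back onto a bin grid (inverse of the writer)."""
    width = int((bins["end"] - bins["start"]).iloc[0])
    key = {
        (c, s): idx
        for idx, (c, s) in enumerate(zip(bins["chrom"], bins["start"]))
    }
    labels = np.zeros((len(paths), len(bins)), dtype=int)
    names = []
    for i, path in enumerate(paths):
        names.append(Path(path).stem)
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score", "strand",
                   "thickStart", "thickEnd", "itemRgb"],
        )
        for chrom, s, e, name in df[["chrom", "start", "end", "name"]].itertuples(index=False):
            k = int(str(name).lstrip("S"))
            for pos in range(int(s), int(e), width):
                idx = key.get((chrom, pos))
                if idx is not None:
                    labels[i, idx] = k
    return Segmentation(labels=labels, cell_names=names)


# ---------------------------------------------------------------------------
# model JSON


def write_model_json(model: StateModel, path: str | Path) -> None:
    payload = {
        "K": model.K,
        "mark_names": model.mark_names,
        "mean": model.mean.tolist(),
        "cov": model.cov.tolist(),
        "state_freq": model.state_freq.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_model_json(path: str | Path) -> StateModel:
    payload = json.loads(Path(path).read_text())
    return StateModel(
        mean=np.asarray(payload["mean"], dtype=float),
        cov=np.asarray(payload["cov"], dtype=float),
        state_freq=np.asarray(payload["state_freq"], dtype=float),
        mark_names=list(payload["mark_names"]),
    )


# ---------------------------------------------------------------------------
# manifest -> SignalTensor


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Manifest TSV with columns (cell, mark, path)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"cell", "mark", "path"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns {sorted(missing)}")
    return df


def load_tensor(
    manifest: pd.DataFrame,
    bin_size: int = BIN_SIZE,
    blacklist: pd.DataFrame | None = None,
    transform: bool = True,
) -> SignalTensor:
    """Bin every listed track and assemble the (cell, mark, bin) tensor.

    All tracks are binned on the common grid implied by the union of
    chromosome extents; a (cell, mark) pair absent from the manifest is
    treated as missing.  ``transform`` applies log2(x + 0.1).
    """
    cells = list(dict.fromkeys(manifest["cell"]))
    marks = list(dict.fromkeys(manifest["mark"]))
    binned: dict[tuple[str, str], pd.DataFrame] = {}
    sizes: dict[str, int] = {}
    tracks: dict[tuple[str, str], pd.DataFrame] = {}
    for cell, mark, p in manifest[["cell", "mark", "path"]].itertuples(index=False):
        track = (
            read_fixedstep_wig(p)
            if str(p).endswith((".wig", ".wig.txt"))
            else read_bedgraph(p)
        )
        tracks[(cell, mark)] = track
        for chrom, grp in track.groupby("chrom"):
            sizes[chrom] = max(sizes.get(chrom, 0), int(grp["end"].max()))
    for key, track in tracks.items():
        binned[key] = bin_signal(track, bin_size, blacklist, chrom_sizes=sizes)

    grid = next(iter(binned.values()))[["chrom", "start", "end"]].reset_index(drop=True)
    n_bins = len(grid)
    values = np.full((len(cells), len(marks), n_bins), np.nan)
    mask = np.zeros((len(cells), len(marks)), dtype=bool)
    for (cell, mark), df in binned.items():
        if len(df) != n_bins:
            raise ValueError(f"track for ({cell}, {mark}) does not match the bin grid")
        i, j = cells.index(cell), marks.index(mark)
        vals = df["value"].to_numpy()
        values[i, j] = transform_signal(vals) if transform else vals
        mask[i, j] = True
    tensor = SignalTensor(values, mask, grid, marks, cells)
    tensor.validate()
    return tensor
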