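"""Genome window tiling and per-window signal tracks.

All downstream scoring operates on a fixed tiling of the genome into
overlapping windows (default 500 bp with 50 bp shifts).  This module defines
the tiling (:class:`WindowGrid`), per-window value vectors
(:class:`WindowTrack`), raw per-base signal (:class:`BaseTrack`, bedGraph
semantics), and top-fraction accessibility masks used to restrict motif
scores to open chromatin.

Coordinates are 0-based, half-open throughout (BED convention).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WindowGrid",
    "WindowTrack",
    "BaseTrack",
    "AccessibilityMask",
    "GridMismatchError",
    "tile_genome",
    "aggregate_base_track",
    "top_fraction_mask",
    "apply_mask",
    "read_chrom_sizes",
    "read_bedgraph",
    "write_window_track_tsv",
    "write_window_track_bedgraph",
    "write_mask_bed",
]


class GridMismatchError(ValueError):
    """Raised when two objects refer to different window grids."""


class WindowGrid:
    """A deterministic tiling of a genome into fixed-length windows.

    Windows on each chromosome start at ``0, stride, 2*stride, ...`` while
    ``start + window_length <= L``; chromosomes shorter than one window
    contribute no windows.  The flattened window order is by chromosome
    (input order), then start.
    """

    def __init__(
        self,
        chrom_sizes: Mapping[str, int],
        window_length: int = 500,
        stride: int = 50,
    ):
        if window_length <= 0 or stride <= 0:
            raise ValueError("window_length and stride must be positive")
        if window_length % stride != 0:
            raise ValueError("window_length must be a multiple of stride")
        for name, size in chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"non-positive size for chromosome {name!r}")
        self.chrom_sizes = dict(chrom_sizes)
        self.window_length = int(window_length)
        self.stride = int(stride)
        self.chroms: list[str] = list(self.chrom_sizes)

        counts = []
        for name in self.chroms:
            L = self.chrom_sizes[name]
            counts.append((L - window_length) // stride + 1 if L >= window_length else 0)
        self._counts = np.asarray(counts, dtype=np.int64)
        # offset of each chromosome's first window in the flattened order
        self._offsets = np.concatenate([[0], np.cumsum(self._counts)])
        self.n_windows = int(self._offsets[-1])
        self.chrom_index = np.repeat(
            np.arange(len(self.chroms), dtype=np.int32), self._counts
        )
        self.starts = np.concatenate(
            [np.arange(c, dtype=np.int64) * stride for c in self._counts]
        ) if self.n_windows else np.empty(0, dtype=np.int64)

    def __len__(self) -> int:
        return self.n_windows

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, WindowGrid)
            and self.chrom_sizes == other.chrom_sizes
            and self.window_length == other.window_length
            and self.stride == other.stride
        )

    def __hash__(self):
        return hash((tuple(self.chrom_sizes.items()), self.window_length, self.stride))

    def n_windows_chrom(self, chrom: str) -> int:
        return int(self._counts[self.chroms.index(chrom)])

    def chrom_slice(self, chrom: str) -> slice:
        """Flattened-index slice of all windows on one chromosome."""
        i = self.chroms.index(chrom)
        return slice(int(self._offsets[i]), int(self._offsets[i + 1]))

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.window_length

    def windows(self) -> Iterator[tuple[str, int, int]]:
        for ci, s in zip(self.chrom_index, self.starts):
            yield self.chroms[ci], int(s), int(s) + self.window_length

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": np.asarray(self.chroms, dtype=object)[self.chrom_index],
                "start": self.starts,
                "end": self.ends,
            }
        )

    def overlapping_windows(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Flattened indices of windows overlapping [start, end) by >= 1 bp."""
        if chrom not in self.chrom_sizes:
            return np.empty(0, dtype=np.int64)
        sl = self.chrom_slice(chrom)
        n = sl.stop - sl.start
        if n == 0 or end <= start:
            return np.empty(0, dtype=np.int64)
        # window k overlaps iff k*stride < end and k*stride + wl > start
        lo = max(0, -(-(start - self.window_length + 1) // self.stride))
        hi = min(n, -(-end // self.stride))
        if hi <= lo:
            return np.empty(0, dtype=np.int64)
        return np.arange(sl.start + lo, sl.start + hi, dtype=np.int64)


def tile_genome(
    chrom_sizes: Mapping[str, int], window_length: int = 500, stride: int = 50
) -> WindowGrid:
    """Tile a genome into overlapping fixed-length windows."""
    return WindowGrid(chrom_sizes, window_length=window_length, stride=stride)


@dataclass
class WindowTrack:
    """One real value per window of a :class:`WindowGrid` (NaN = missing)."""

    grid: WindowGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.grid.n_windows,):
            raise ValueError(
                f"track has {self.values.size} values for {self.grid.n_windows} windows"
            )

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        df["value"] = self.values
        return df


@dataclass
class BaseTrack:
    """Per-base signal with bedGraph semantics; uncovered bases are 0.

    ``intervals`` maps chromosome name to ``(starts, ends, values)`` arrays
    sorted by start, non-overlapping within a chromosome.
    """

    intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    def __post_init__(self):
        clean = {}
        for chrom, (s, e, v) in self.intervals.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=np.float64)
            order = np.argsort(s, kind="stable")
            s, e, v = s[order], e[order], v[order]
            if np.any(e[:-1] > s[1:]):
                raise ValueError(f"overlapping intervals on {chrom}")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite values on {chrom}")
            clean[chrom] = (s, e, v)
        self.intervals = clean

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BaseTrack":
        out = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            out[str(chrom)] = (
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                sub["value"].to_numpy(),
            )
        return cls(out)

    def dense(self, chrom: str, length: int) -> np.ndarray:
        """Materialize the per-base signal for one chromosome."""
        arr = np.zeros(length, dtype=np.float64)
        if chrom in self.intervals:
            s, e, v = self.intervals[chrom]
            for si, ei, vi in zip(s, e, v):
                arr[max(si, 0) : min(ei, length)] = vi
        return arr


@dataclass
class AccessibilityMask:
    """Boolean accessibility call per window for one developmental stage."""

    grid: WindowGrid
    values: np.ndarray
    stage: str
    fraction: float = 0.10

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != (self.grid.n_windows,):
            raise ValueError("mask length does not match grid")


def aggregate_base_track(track: BaseTrack, grid: WindowGrid) -> WindowTrack:
    """Window value = mean over stride-length subsegments of the max base value.

    A 500 bp window with 50 bp stride is summarized by averaging the maximum
    signal within each of its ten 50 bp subsegments; uncovered bases count
    as 0.  Track chromosomes absent from the grid are skipped with a warning.
    """
    nseg_per_win = grid.window_length // grid.stride
    values = np.zeros(grid.n_windows, dtype=np.float64)
    for chrom in track.intervals:
        if chrom not in grid.chrom_sizes:
            logger.warning("chromosome %r in track but not in grid; skipped", chrom)
    for chrom in grid.chroms:
        sl = grid.chrom_slice(chrom)
        nwin = sl.stop - sl.start
        if nwin == 0:
            continue
        L = grid.chrom_sizes[chrom]
        dense = track.dense(chrom, L)
        nseg = L // grid.stride
        seg_max = dense[: nseg * grid.stride].reshape(nseg, grid.stride).max(axis=1)
        csum = np.concatenate([[0.0], np.cumsum(seg_max)])
        idx = np.arange(nwin)
        values[sl] = (csum[idx + nseg_per_win] - csum[idx]) / nseg_per_win
    return WindowTrack(grid, values)


def top_fraction_mask(
    track: WindowTrack, fraction: float = 0.10, stage: str = ""
) -> AccessibilityMask:
    """Mark exactly ``floor(fraction * N)`` windows with the highest values.

    Ties at the cut are broken by ascending genomic order (chrom, start) so
    the selected set is a deterministic function of the values alone.
    Missing (NaN) values are never selected.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    vals = track.values
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("all window values are missing")
    n = track.grid.n_windows
    m = math.floor(fraction * n)
    if m > int(finite.sum()):
        raise ValueError(
            f"cannot select {m} windows: only {int(finite.sum())} non-missing"
        )
    # primary key: descending value; tie-break: ascending flattened index
    # (flattened order is genomic order).  NaNs pushed to the end.
    key = np.where(finite, -vals, np.inf)
    order = np.argsort(key, kind="stable")
    mask = np.zeros(n, dtype=bool)
    mask[order[:m]] = True
    return AccessibilityMask(track.grid, mask, stage=stage, fraction=fraction)


def apply_mask(
    track: WindowTrack, mask: AccessibilityMask, fill: float = 0.0
) -> WindowTrack:
    """Keep values where the mask is true; set masked-out windows to ``fill``."""
    if track.grid != mask.grid:
        raise GridMismatchError("track and mask are on different grids")
    return WindowTrack(track.grid, np.where(mask.values, track.values, fill))


# ---------------------------------------------------------------------------
# I/O helpers


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def read_bedgraph(path) -> BaseTrack:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "value"],
        comment="#",
        dtype={"chrom": str},
    )
    df = df[~df["chrom"].str.startswith("track")]
    return BaseTrack.from_frame(df)


def write_window_track_tsv(track: WindowTrack, path) -> None:
    track.to_frame().to_csv(path, sep="\t", index=False)


def write_window_track_bedgraph(track: WindowTrack, path) -> None:
    track.to_frame().to_csv(path, sep="\t", index=False, header=False)


def write_mask_bed(mask: AccessibilityMask, path) -> None:
    df = mask.grid.to_frame()[mask.values]
    df["name"] = mask.stage
    df.to_csv(path, sep="\t", index=False, header=False)
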