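"""Evaluation protocol for predicted TF binding profiles.

Predicted motif tracks are compared against occupancy-style tracks (ChIP or
accessibility) over an evaluation set of windows: the strongest non-coding
accessible peaks of the target track plus an equal-sized random draw of
non-coding accessible windows.  Agreement is quantified by Pearson/Spearman
correlation with a t-transform p-value, by AUROC (Mann-Whitney with
half-credit ties), and by cross-correlation matrices that rank each target's
own motif among all motifs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from regmap.core_tracks import AccessibilityMask, GridMismatchError, WindowTrack

__all__ = [
    "EvalWindowSet",
    "CorrelationReport",
    "select_eval_windows",
    "correlation",
    "roc_auc",
    "cross_correlation_matrix",
]


@dataclass
class EvalWindowSet:
    """Peak and random window indices selected under the declared filters."""

    positives: np.ndarray  # flattened grid indices, top peaks
    randoms: np.ndarray
    seed: int
    filters: tuple[str, ...] = ("non-coding", "accessible")

    def __post_init__(self):
        if np.intersect1d(self.positives, self.randoms).size:
            raise ValueError("positive and random sets must be disjoint")

    @property
    def indices(self) -> np.ndarray:
        return np.concatenate([self.positives, self.randoms])

    @property
    def labels(self) -> np.ndarray:
        """True for peak windows, False for random windows."""
        return np.concatenate(
            [np.ones(len(self.positives), bool), np.zeros(len(self.randoms), bool)]
        )


@dataclass
class CorrelationReport:
    method: str
    r: float
    n: int
    p_value: float
    df: int


def _coding_window_mask(grid, coding: Sequence[tuple[str, int, int]]) -> np.ndarray:
    """Boolean per window: overlaps (>= 1 bp) some coding interval."""
    out = np.zeros(grid.n_windows, dtype=bool)
    for chrom, start, end in coding:
        out[grid.overlapping_windows(chrom, start, end)] = True
    return out


def select_eval_windows(
    peak_track: WindowTrack,
    mask: AccessibilityMask,
    coding: Sequence[tuple[str, int, int]],
    n_pos: int = 1000,
    n_rand: int = 1000,
    seed: int = 0,
) -> EvalWindowSet:
    """Top accessible non-coding peaks plus a seeded random background draw.

    Eligible windows are accessible (mask true) and overlap no coding
    interval.  Positives are the ``n_pos`` highest-valued eligible windows
    (ties broken by genomic order); randoms are drawn uniformly without
    replacement from the remaining eligible windows.
    """
    grid = peak_track.grid
    if grid != mask.grid:
        raise GridMismatchError("peak track and mask are on different grids")
    eligible = mask.values & ~_coding_window_mask(grid, coding)
    eligible &= np.isfinite(peak_track.values)
    n_eligible = int(eligible.sum())
    if n_eligible < n_pos + n_rand:
        raise ValueError(
            f"need {n_pos + n_rand} eligible windows, only {n_eligible} available"
        )
    idx = np.flatnonzero(eligible)
    order = np.argsort(-peak_track.values[idx], kind="stable")
    positives = np.sort(idx[order[:n_pos]])
    rest = np.setdiff1d(idx, positives, assume_unique=True)
    rng = np.random.default_rng(seed)
    randoms = np.sort(rng.choice(rest, size=n_rand, replace=False))
    return EvalWindowSet(positives=positives, randoms=randoms, seed=seed)


def correlation(x, y, method: str = "pearson") -> CorrelationReport:
    """Correlation with a two-sided t-transform p-value.

    ``t = r * sqrt((n-2) / (1-r^2))`` on ``n-2`` degrees of freedom; for
    Spearman the transform is applied to the midrank rho (large-n
    approximation).  |r| = 1 is reported with p = 0.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    method = method.lower()
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationReport(method=method, r=r, n=n, p_value=p, df=df)


def roc_auc(scores, labels) -> tuple[float, np.ndarray]:
    """AUROC as the Mann-Whitney statistic (ties get half credit).

    Returns the area and the (fpr, tpr) curve from a descending-score
    threshold sweep.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    # threshold sweep over distinct scores, descending
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_labels)
    fps = np.cumsum(~sorted_labels)
    distinct = np.concatenate([sorted_scores[1:] != sorted_scores[:-1], [True]])
    tpr = np.concatenate([[0.0], tps[distinct] / n_pos])
    fpr = np.concatenate([[0.0], fps[distinct] / n_neg])
    curve = np.column_stack([fpr, tpr])
    return float(auc), curve


def cross_correlation_matrix(
    motif_tracks: Sequence[WindowTrack],
    target_tracks: Sequence[WindowTrack],
    eval_set: EvalWindowSet,
    matched: Sequence[tuple[int, int]],
    method: str = "pearson",
) -> tuple[np.ndarray, dict[int, float]]:
    """Correlations of every motif track with every target over eval windows.

    ``matched`` declares (motif_index, target_index) pairs; for each matched
    target the rank (1 = best, average rank on ties) of its own motif among
    all motifs by descending correlation is returned.
    """
    grids = {t.grid for t in motif_tracks} | {t.grid for t in target_tracks}
    if len(grids) != 1:
        raise GridMismatchError("all tracks must share one grid")
    idx = eval_set.indices
    mat = np.empty((len(motif_tracks), len(target_tracks)))
    for i, mt in enumerate(motif_tracks):
        for j, tt in enumerate(target_tracks):
            mat[i, j] = correlation(mt.values[idx], tt.values[idx], method).r
    ranks: dict[int, float] = {}
    for mi, tj in matched:
        col_ranks = stats.rankdata(-mat[:, tj], method="average")
        ranks[tj] = float(col_ranks[mi])
    return mat, ranks
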