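"""Co-localization of a query peak set (e.g. H3K4me3) against an anchor
peak set (e.g. WDR5) and the HMd density statistic.

Each query peak is assigned to its single nearest anchor center on the
same chromosome. Queries are counted cumulatively within a ladder of
distance thresholds X_i, and the per-annulus density is

    HMd_i = (Y_i - Y_{i-1}) * 100 / ((X_i - X_{i-1})_kb * M)

with implicit (X_0, Y_0) = (0, 0), M the number of anchors, and X
converted bp -> kb so the unit is query peaks per 100 anchor peaks
per kb. The identity sum_i HMd_i * dX_i(kb) * M / 100 = Y_last holds
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .peak_io import Peak, peak_center

__all__ = [
    "DEFAULT_BINS",
    "ColocalizationProfile",
    "center_distances",
    "cumulative_counts",
    "hmd_density",
    "colocalization_profile",
]

#: distance-threshold ladder (bp): 50 bp .. 5 kb
DEFAULT_BINS: tuple[int, ...] = (50, 100, 200, 500, 1000, 2000, 3000, 4000, 5000)


@dataclass(frozen=True)
class ColocalizationProfile:
    """Distance thresholds X (bp), cumulative counts Y, anchor count M,
    per-annulus increments, and HMd densities (per 100 anchors per kb)."""

    X: np.ndarray
    Y: np.ndarray
    M: int
    increments: np.ndarray
    hmd: np.ndarray

    @property
    def n_binned(self) -> int:
        """Queries within the outermost threshold."""
        return int(self.Y[-1])


def center_distances(
    anchors: Sequence[Peak],
    queries: Sequence[Peak],
    center_mode: str = "midpoint",
) -> np.ndarray:
    """Absolute center-to-center distance from each query to its nearest
    anchor on the same chromosome; inf for queries on anchor-free
    chromosomes (they are never binned)."""
    if not anchors:
        raise ValueError("center_distances requires at least one anchor peak")
    anchor_centers: dict[str, np.ndarray] = {}
    for chrom in {a.chrom for a in anchors}:
        centers = [peak_center(a, center_mode) for a in anchors if a.chrom == chrom]
        anchor_centers[chrom] = np.sort(np.array(centers, dtype=np.int64))

    out = np.full(len(queries), np.inf)
    for qi, q in enumerate(queries):
        centers = anchor_centers.get(q.chrom)
        if centers is None:
            continue
        c = peak_center(q, center_mode)
        i = np.searchsorted(centers, c)
        best = np.inf
        if i > 0:
            best = min(best, c - centers[i - 1])
        if i < len(centers):
            best = min(best, centers[i] - c)
        out[qi] = best
    return out


def cumulative_counts(
    distances: np.ndarray | Sequence[float], X: Sequence[int] = DEFAULT_BINS
) -> np.ndarray:
    """Y_i = number of distances <= X_i (cumulative across thresholds)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 1 or len(X) == 0 or X[0] <= 0 or np.any(np.diff(X) <= 0):
        raise ValueError("thresholds X must be strictly increasing and positive")
    d = np.sort(np.asarray(distances, dtype=float))
    d = d[np.isfinite(d)]
    return np.searchsorted(d, X, side="right").astype(np.int64)


def hmd_density(
    Y: np.ndarray | Sequence[int],
    X: Sequence[int] = DEFAULT_BINS,
    M: int = 1,
) -> np.ndarray:
    """Per-annulus query density: (Y_i - Y_{i-1}) * 100 / (dX_kb * M)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if len(X) != len(Y):
        raise ValueError("X and Y must have the same length")
    if X[0] <= 0 or np.any(np.diff(X) <= 0):
        raise ValueError("thresholds X must be strictly increasing and positive")
    if M < 1:
        raise ValueError("anchor count M must be >= 1")
    dY = np.diff(Y, prepend=0.0)
    if np.any(dY < 0):
        raise ValueError("cumulative counts Y must be non-decreasing")
    dX_kb = np.diff(X, prepend=0.0) / 1000.0
    return dY * 100.0 / (dX_kb * M)


def colocalization_profile(
    anchors: Sequence[Peak],
    queries: Sequence[Peak],
    X: Sequence[int] = DEFAULT_BINS,
    center_mode: str = "midpoint",
) -> ColocalizationProfile:
    """Full pipeline: nearest-anchor distances -> cumulative counts -> HMd."""
    distances = center_distances(anchors, queries, center_mode)
    Y = cumulative_counts(distances, X)
    M = len(anchors)
    hmd = hmd_density(Y, X, M)
    return ColocalizationProfile(
        X=np.asarray(X, dtype=np.int64),
        Y=Y,
        M=M,
        increments=np.diff(Y, prepend=0),
        hmd=hmd,
    )
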