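"""Separation-line placement and 16-cluster classification.

An amplitude-coded 4-plex puts two targets in each fluorescence channel at
distinct amplitude levels, so each channel axis splits into four bands —

    0 negative, 1 low-amplitude target, 2 high-amplitude target,
    3 double positive (both same-channel targets, amplitudes add) —

and the two-channel amplitude plane splits into a 4x4 grid of up to 16
droplet clusters. Three separation lines per axis realise the split. Lines
are proposed automatically from the 1-D amplitude distribution of each axis
and can be overridden programmatically (:func:`set_line`), mirroring the
workflow of setting a threshold "in the middle between the clusters".

Automatic placement: a Gaussian-kernel density estimate (Silverman
bandwidth, 512-point grid) is searched for exactly the expected number of
modes; if found, each line goes at the density minimum between consecutive
modes. Otherwise a deterministic 1-D k-means partitions the axis and lines
go at midpoints between consecutive sorted centers. Either way the result
is rejected — with a pointer to manual placement — when adjacent clusters
are not separated by a configurable multiple of their spreads.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .io import DropletSet

__all__ = [
    "SeparationGrid",
    "ClusterGrid",
    "InsufficientClusterStructureError",
    "band_of",
    "propose_lines_1d",
    "propose_grid",
    "set_line",
    "classify",
]


class InsufficientClusterStructureError(ValueError):
    """The amplitude distribution does not resolve the expected clusters.

    Raised when automatic placement cannot find the expected band structure;
    the remedy is to set separation lines manually (``set_line`` or the
    run-configuration line positions), typically from a positive control.
    """


@dataclass(frozen=True)
class SeparationGrid:
    """Separation-line positions for both channel axes.

    ``ch1_lines``/``ch2_lines`` are strictly ascending amplitudes; a channel
    carrying two targets has 3 lines (4 bands), one target has 1 line, an
    unused channel has none. ``provenance`` records whether the lines were
    placed automatically, manually, or mixed.
    """

    ch1_lines: tuple[float, ...]
    ch2_lines: tuple[float, ...]
    provenance: str = "automatic"

    def __post_init__(self) -> None:
        for name, lines in (("ch1", self.ch1_lines), ("ch2", self.ch2_lines)):
            arr = np.asarray(lines, dtype=float)
            if arr.size and not np.isfinite(arr).all():
                raise ValueError(f"{name} lines must be finite")
            if arr.size > 1 and not (np.diff(arr) > 0).all():
                raise ValueError(f"{name} lines must be strictly ascending: {lines}")
        if self.provenance not in ("automatic", "manual", "mixed"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        object.__setattr__(self, "ch1_lines", tuple(float(x) for x in self.ch1_lines))
        object.__setattr__(self, "ch2_lines", tuple(float(x) for x in self.ch2_lines))

    def lines(self, channel: int) -> tuple[float, ...]:
        if channel == 1:
            return self.ch1_lines
        if channel == 2:
            return self.ch2_lines
        raise ValueError(f"channel must be 1 or 2, got {channel}")


@dataclass(frozen=True)
class ClusterGrid:
    """Droplet counts per (channel-1 band, channel-2 band) cell."""

    counts: np.ndarray
    total: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D table")
        if (counts < 0).any():
            raise ValueError("cluster counts must be non-negative")
        if counts.sum() != self.total:
            raise ValueError(
                f"cell counts sum to {counts.sum()} but total is {self.total}"
            )
        object.__setattr__(self, "counts", counts)


def band_of(amplitude, lines: Sequence[float]):
    """Band index of an amplitude given ascending separation lines.

    Returns the number of lines at or below the amplitude, so a droplet
    sitting exactly on a line belongs to the upper band. Works on scalars
    and arrays alike.
    """
    lines = np.asarray(lines, dtype=float)
    if lines.size > 1 and not (np.diff(lines) > 0).all():
        raise ValueError("lines must be strictly ascending")
    out = np.searchsorted(lines, amplitude, side="right")
    if np.isscalar(amplitude):
        return int(out)
    return out


def _silverman_bandwidth(x: np.ndarray) -> float:
    sd = float(np.std(x, ddof=1))
    q1, q3 = np.percentile(x, [25, 75])
    iqr = float(q3 - q1)
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * scale * x.size ** (-0.2)


def _kde_valley_lines(x: np.ndarray, n_bands: int, grid_points: int) -> np.ndarray | None:
    """Lines at density minima between modes, or None if the mode count is off."""
    lo, hi = float(x.min()), float(x.max())
    bw = _silverman_bandwidth(x)
    if bw <= 0:
        return None
    hist, edges = np.histogram(x, bins=grid_points, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    spacing = edges[1] - edges[0]
    density = gaussian_filter1d(hist.astype(float), sigma=bw / spacing, mode="constant")
    peaks, _ = find_peaks(density)
    if peaks.size != n_bands:
        return None
    lines = np.empty(n_bands - 1)
    for k in range(n_bands - 1):
        seg = slice(peaks[k], peaks[k + 1] + 1)
        lines[k] = centers[peaks[k] + int(np.argmin(density[seg]))]
    return lines


def _kmeans_1d(x: np.ndarray, k: int, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic 1-D Lloyd's algorithm.

    Initial centers sit at the k inner quantiles; if the quantiles collapse
    (heavily unbalanced data, e.g. >90% negative droplets) the init falls
    back to centers evenly spread over the amplitude span. Empty clusters
    keep their previous (stale) center instead of being relocated.
    Returns (sorted centers, labels).
    """
    qs = (np.arange(k) + 0.5) / k
    centers = np.quantile(x, qs)
    span = float(x.max() - x.min())
    if np.min(np.diff(centers)) < span / (4 * k):
        centers = x.min() + span * qs
    for _ in range(max_iter):
        bounds = 0.5 * (centers[:-1] + centers[1:])
        labels = np.searchsorted(bounds, x, side="right")
        new = centers.copy()
        for j in range(k):
            pts = x[labels == j]
            if pts.size:
                new[j] = pts.mean()
        new.sort()
        if np.allclose(new, centers):
            centers = new
            break
        centers = new
    bounds = 0.5 * (centers[:-1] + centers[1:])
    labels = np.searchsorted(bounds, x, side="right")
    return centers, labels


def _cluster_stats(x: np.ndarray, labels: np.ndarray, k: int):
    stats = []
    for j in range(k):
        pts = x[labels == j]
        if pts.size == 0:
            return None
        sd = float(pts.std(ddof=1)) if pts.size > 1 else 0.0
        stats.append((float(pts.mean()), sd))
    return stats


def _separated(stats, min_separation: float) -> bool:
    return all(
        (m2 - m1) >= min_separation * (s1 + s2)
        for (m1, s1), (m2, s2) in zip(stats, stats[1:])
    )


def _try_kmeans(x: np.ndarray, k: int, min_separation: float) -> np.ndarray | None:
    """Sorted k-means centers if all k clusters are occupied and separated."""
    centers, labels = _kmeans_1d(x, k)
    stats = _cluster_stats(x, labels, k)
    if stats is None or not _separated(stats, min_separation):
        return None
    return centers


def _check_band_separation(
    x: np.ndarray, lines: np.ndarray, min_separation: float
) -> None:
    """Require adjacent occupied bands to be apart by min_separation x spreads."""
    bands = np.searchsorted(lines, x, side="right")
    stats = []
    for b in range(lines.size + 1):
        pts = x[bands == b]
        if pts.size:
            sd = float(pts.std(ddof=1)) if pts.size > 1 else 0.0
            stats.append((float(pts.mean()), sd))
    if not _separated(stats, min_separation):
        raise InsufficientClusterStructureError(
            "adjacent clusters are not separated by "
            f"{min_separation} x their combined spreads; set lines manually"
        )


def propose_lines_1d(
    amplitudes,
    n_bands: int = 4,
    *,
    min_spread: float = 1.0,
    grid_points: int = 512,
    min_separation: float = 3.0,
) -> tuple[float, ...]:
    """Propose ``n_bands - 1`` ascending separation lines for one axis.

    Primary method: Gaussian-kernel density estimate (Silverman bandwidth,
    ``grid_points`` evaluation grid); if exactly ``n_bands`` modes appear,
    lines go at the density minima between consecutive modes. Otherwise a
    deterministic 1-D k-means with ``k = n_bands`` is run and lines go at
    midpoints between consecutive sorted centers. When that fails on a
    4-band axis, the double-positive band may simply hold no droplets (rare
    co-occupancy at low concentration): a 3-cluster solution is tried and,
    if separated, the top line is placed just above the data.

    Raises
    ------
    InsufficientClusterStructureError
        If the amplitude spread is below ``min_spread``, if fewer than
        ``n_bands - 1`` distinct clusters exist, or if adjacent clusters are
        closer than ``min_separation`` times their combined standard
        deviations.
    """
    x = np.asarray(amplitudes, dtype=float)
    if x.size < 50:
        raise ValueError(f"need at least 50 amplitudes, got {x.size}")
    if n_bands < 2:
        raise ValueError("n_bands must be at least 2")
    span = float(x.max() - x.min())
    if span < min_spread:
        raise InsufficientClusterStructureError(
            f"amplitude spread {span:.3g} is below the resolution floor "
            f"{min_spread:.3g}; all droplets form one cluster — set lines manually"
        )

    lines = _kde_valley_lines(x, n_bands, grid_points)
    if lines is not None:
        _check_band_separation(x, lines, min_separation)
    else:
        centers = _try_kmeans(x, n_bands, min_separation)
        if centers is not None:
            lines = 0.5 * (centers[:-1] + centers[1:])
        elif n_bands == 4:
            # a rare pair of same-channel targets can leave the double-positive
            # band empty: look for the three remaining clusters and put the top
            # line above the data
            centers = _try_kmeans(x, 3, min_separation)
            if centers is None:
                raise InsufficientClusterStructureError(
                    f"could not resolve {n_bands} amplitude bands (nor {n_bands - 1} "
                    "with an empty double-positive band); set lines manually"
                )
            mids = 0.5 * (centers[:-1] + centers[1:])
            lines = np.append(mids, float(x.max()) + 0.01 * span)
        else:
            raise InsufficientClusterStructureError(
                f"could not resolve {n_bands} amplitude bands; set lines manually"
            )
    lines = np.asarray(lines, dtype=float)
    if not (np.diff(lines) > 0).all():
        raise InsufficientClusterStructureError(
            "proposed lines are not strictly ascending; set lines manually"
        )
    return tuple(float(v) for v in lines)


def propose_grid(droplets: DropletSet, layout, **kwargs) -> SeparationGrid:
    """Propose separation lines for both axes of a well.

    The assay layout decides the line count per axis: two targets on a
    channel need 3 lines, one target 1 line, an unused channel none.
    Keyword arguments are passed through to :func:`propose_lines_1d`.
    """
    if droplets.n_accepted == 0:
        raise ValueError("droplet set is empty")
    per_axis: dict[int, tuple[float, ...]] = {}
    for channel, amplitudes in ((1, droplets.ch1), (2, droplets.ch2)):
        n_targets = len(layout.targets_on_channel(channel))
        if n_targets == 0:
            per_axis[channel] = ()
            continue
        n_bands = 4 if n_targets == 2 else 2
        try:
            per_axis[channel] = propose_lines_1d(amplitudes, n_bands, **kwargs)
        except InsufficientClusterStructureError as err:
            raise InsufficientClusterStructureError(
                f"channel {channel}: {err}"
            ) from err
    return SeparationGrid(per_axis[1], per_axis[2], provenance="automatic")


def set_line(
    grid: SeparationGrid, channel: int, index: int, position: float
) -> SeparationGrid:
    """Return a copy of the grid with one separation line moved.

    The moved line must keep the axis strictly ascending. Provenance becomes
    ``manual`` if the grid was already manual, otherwise ``mixed``.
    """
    lines = list(grid.lines(channel))
    if not 0 <= index < len(lines):
        raise IndexError(f"channel {channel} has {len(lines)} lines, no index {index}")
    if index > 0 and position <= lines[index - 1]:
        raise ValueError(
            f"position {position} conflicts with lower neighbor line at {lines[index - 1]}"
        )
    if index < len(lines) - 1 and position >= lines[index + 1]:
        raise ValueError(
            f"position {position} conflicts with upper neighbor line at {lines[index + 1]}"
        )
    lines[index] = float(position)
    provenance = "manual" if grid.provenance == "manual" else "mixed"
    if channel == 1:
        return replace(grid, ch1_lines=tuple(lines), provenance=provenance)
    return replace(grid, ch2_lines=tuple(lines), provenance=provenance)


def classify(droplets: DropletSet, grid: SeparationGrid) -> ClusterGrid:
    """Assign every droplet to a grid cell and tabulate the counts.

    The result is order-invariant and the cell counts sum to the number of
    accepted droplets.
    """
    b1 = band_of(droplets.ch1, grid.ch1_lines)
    b2 = band_of(droplets.ch2, grid.ch2_lines)
    nb1 = len(grid.ch1_lines) + 1
    nb2 = len(grid.ch2_lines) + 1
    counts = np.zeros((nb1, nb2), dtype=int)
    np.add.at(counts, (b1, b2), 1)
    return ClusterGrid(counts=counts, total=droplets.n_accepted)
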