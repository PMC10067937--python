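"""Windowed nearest-neighbour distances between two particle channels.

For each query punctum (e.g. PIEZO1) the candidate reference puncta
(e.g. PECAM1) are those within a per-axis window — |Δx| ≤ w AND
|Δy| ≤ w, a square window, default w = 0.5 µm — and the minimum
Euclidean distance among candidates is recorded.  Queries with no
candidate in the window are counted, not silently dropped.  The
resulting sample is binned into a density-normalised histogram, the
target of the distance-distribution fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["DistanceSample", "DistanceHistogram",
           "nearest_neighbour_distances", "build_histogram"]


@dataclass
class DistanceSample:
    """Nearest-neighbour distances (µm) with window bookkeeping.

    ``n_query = len(distances) + n_excluded``; with a finite window every
    distance is ≤ window·√2 (the square-window diagonal).
    """

    distances: np.ndarray
    window_um: float
    n_query: int
    n_excluded: int

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(self.distances < 0):
            raise ValueError("distances must be >= 0")
        if self.n_query != len(self.distances) + self.n_excluded:
            raise ValueError("n_query must equal len(distances) + n_excluded")

    def __len__(self) -> int:
        return len(self.distances)

    def summary(self) -> dict:
        return {
            "n_query": int(self.n_query),
            "n_distances": int(len(self.distances)),
            "n_excluded": int(self.n_excluded),
            "window_um": float(self.window_um),
        }


@dataclass
class DistanceHistogram:
    """Density-normalised distance histogram (per-µm values)."""

    bin_edges: np.ndarray
    density: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if len(self.bin_edges) != len(self.density) + 1:
            raise ValueError("need len(bin_edges) == len(density) + 1")

    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _coords(particles) -> np.ndarray:
    """Accept a ParticleSet, an (n, 2) array, or anything array-like."""
    if hasattr(particles, "coords"):
        return np.asarray(particles.coords(), dtype=float)
    arr = np.asarray(particles, dtype=float)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of (x, y) coordinates in µm")
    return arr


def nearest_neighbour_distances(query, reference,
                                window_um: float = 0.5) -> DistanceSample:
    """Windowed nearest-neighbour distance from each query to the reference set.

    Candidates must satisfy |Δx| ≤ window AND |Δy| ≤ window (an L∞ ball);
    among candidates the minimum Euclidean distance is recorded.  Queries
    with no candidate contribute to ``n_excluded``.  Many-to-one matching
    is allowed: several queries may share one nearest reference.
    """
    q = _coords(query)
    ref = _coords(reference)
    if not window_um > 0:
        raise ValueError("window_um must be > 0")
    if len(q) == 0:
        return DistanceSample(np.empty(0), window_um, 0, 0)
    if len(ref) == 0:
        return DistanceSample(np.empty(0), window_um, len(q), len(q))

    distances = []
    n_excluded = 0
    if np.isinf(window_um):
        tree = cKDTree(ref)
        d, _ = tree.query(q, k=1)
        return DistanceSample(np.asarray(d, dtype=float), window_um, len(q), 0)

    tree = cKDTree(ref)
    # L-infinity range query implements the square per-axis window exactly
    neighbour_lists = tree.query_ball_point(q, r=window_um, p=np.inf)
    for qi, idx in zip(q, neighbour_lists):
        if not idx:
            n_excluded += 1
            continue
        diffs = ref[idx] - qi
        distances.append(float(np.min(np.hypot(diffs[:, 0], diffs[:, 1]))))
    return DistanceSample(np.asarray(distances), window_um, len(q), n_excluded)


def build_histogram(sample: DistanceSample, bin_width_um: float = 0.01) -> DistanceHistogram:
    """Bin a distance sample into right-open, density-normalised bins.

    Bins run from 0 to ceil(max/bin_width)·bin_width; density is
    counts / (n · bin_width) so the histogram integrates to 1 over its
    support.
    """
    if not bin_width_um > 0:
        raise ValueError("bin_width_um must be > 0")
    d = sample.distances
    if len(d) == 0:
        raise ValueError(
            "empty distance sample: no query had a reference inside the window "
            f"(n_excluded={sample.n_excluded}); widen the window or check inputs"
        )
    n_bins = max(1, math.ceil(float(np.max(d)) / bin_width_um))
    # guard against a max exactly on an edge falling out of the last right-open bin
    if np.max(d) >= n_bins * bin_width_um:
        n_bins += 1
    edges = np.arange(n_bins + 1) * bin_width_um
    counts = np.zeros(n_bins, dtype=float)
    idx = np.floor(d / bin_width_um).astype(int)
    np.add.at(counts, idx, 1.0)
    density = counts / (len(d) * bin_width_um)
    return DistanceHistogram(bin_edges=edges, density=density, n=len(d))
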