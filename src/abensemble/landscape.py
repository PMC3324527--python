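"""2D potential of mean force and representative-conformation selection.

The PMF over two reaction coordinates is the Boltzmann inversion of the
empirical 2D histogram: ``pmf_i = -ln(N_i / N)`` in kT, with the finite
minimum shifted to 0 for reporting and empty bins masked (NaN) rather than
assigned a large finite value, which would fake barriers.

Representative conformations come from the lowest-PMF basin: frames within
a depth of the global minimum are clustered on pairwise C-alpha RMSD with
the iterative neighbor-count (GROMOS/Daura) algorithm, and the centroid of
the largest cluster is the representative.  Tie-breaks (equal neighbor
counts, equal cluster sizes) resolve to the lowest frame index, making the
result invariant to input frame permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Conformation
from .superpose import kabsch_rmsd

__all__ = [
    "DEFAULT_PMF_BINS",
    "DEFAULT_CLUSTER_CUTOFF_NM",
    "PMFGrid",
    "compute_pmf",
    "lowest_basin_frames",
    "pairwise_rmsd",
    "ClusterResult",
    "gromos_cluster",
]

DEFAULT_PMF_BINS = 40
DEFAULT_CLUSTER_CUTOFF_NM = 0.3


@dataclass
class PMFGrid:
    """2D binned occupancy with PMF values in kT and bin->frame mapping."""

    x_name: str
    y_name: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray               # (nx, ny) int
    pmf: np.ndarray                  # (nx, ny) float, NaN where unsampled
    frame_index: dict[tuple[int, int], list[int]]
    n_total: int

    @property
    def minimum_bin(self) -> tuple[int, int]:
        masked = np.where(np.isnan(self.pmf), np.inf, self.pmf)
        return tuple(np.unravel_index(np.argmin(masked), self.pmf.shape))


def _digitize(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin index per value; the last bin is right-closed."""
    idx = np.searchsorted(edges, values, side="right") - 1
    idx[values == edges[-1]] = len(edges) - 2
    return idx


def compute_pmf(x: np.ndarray, y: np.ndarray,
                n_bins: int = DEFAULT_PMF_BINS,
                x_name: str = "x", y_name: str = "y") -> PMFGrid:
    """Boltzmann-inverted 2D histogram of two reaction coordinates."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size == 0:
        raise ValueError("zero frames")
    def edges_of(v: np.ndarray) -> np.ndarray:
        if v.min() == v.max():
            return np.linspace(v.min() - 0.5, v.min() + 0.5, n_bins + 1)
        return np.linspace(v.min(), v.max(), n_bins + 1)

    x_edges = edges_of(x)
    y_edges = edges_of(y)
    ix = _digitize(x, x_edges)
    iy = _digitize(y, y_edges)
    counts = np.zeros((n_bins, n_bins), dtype=int)
    np.add.at(counts, (ix, iy), 1)
    n_total = int(x.size)
    with np.errstate(divide="ignore"):
        pmf = -np.log(counts / n_total)
    pmf[counts == 0] = np.nan
    pmf -= np.nanmin(pmf)  # relative free energy: global minimum at 0 kT
    frame_index: dict[tuple[int, int], list[int]] = {}
    for k, (i, j) in enumerate(zip(ix.tolist(), iy.tolist())):
        frame_index.setdefault((i, j), []).append(k)
    return PMFGrid(x_name, y_name, x_edges, y_edges, counts, pmf,
                   frame_index, n_total)


def lowest_basin_frames(grid: PMFGrid, depth: float = 0.5) -> list[int]:
    """Frames in bins within ``depth`` kT of the global PMF minimum."""
    if not np.isfinite(grid.pmf).any():
        raise ValueError("grid has no finite bin")
    sel = np.argwhere(np.where(np.isnan(grid.pmf), np.inf, grid.pmf) <= depth)
    frames: list[int] = []
    for i, j in sel:
        frames.extend(grid.frame_index.get((int(i), int(j)), []))
    return sorted(frames)


def pairwise_rmsd(a: Conformation, b: Conformation,
                  selection=None) -> float:
    """Minimal C-alpha RMSD between two conformations, in nm.

    ``selection`` is an atom-predicate overriding the C-alpha default; both
    conformations must yield matched selections.
    """
    if selection is None:
        xa, xb = a.ca_coords(), b.ca_coords()
    else:
        xa, xb = a.coords[selection(a)], b.coords[selection(b)]
    return kabsch_rmsd(xa, xb) * 0.1  # Angstrom -> nm


@dataclass
class ClusterResult:
    """Partition of frames into RMSD clusters, ordered by decreasing size."""

    clusters: list[list[int]]
    centroids: list[int]
    cutoff: float  # nm

    @property
    def largest_cluster_centroid(self) -> int:
        return self.centroids[0]


def gromos_cluster(frames: list[Conformation],
                   cutoff: float = DEFAULT_CLUSTER_CUTOFF_NM,
                   selection=None) -> ClusterResult:
    """Iterative neighbor-count clustering on pairwise C-alpha RMSD.

    The frame with the most neighbors within ``cutoff`` (nm) becomes a
    centroid; it and its neighbors are removed; repeat until no frames
    remain.  Equal neighbor counts resolve to the lowest frame index.
    Clusters are reported largest-first (ties again by lowest centroid
    index).
    """
    n = len(frames)
    if n == 0:
        raise ValueError("no frames to cluster")
    rmsd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rmsd[i, j] = rmsd[j, i] = pairwise_rmsd(frames[i], frames[j],
                                                    selection)
    neighbor = rmsd <= cutoff  # includes self
    remaining = np.ones(n, dtype=bool)
    clusters: list[list[int]] = []
    centroids: list[int] = []
    while remaining.any():
        counts = (neighbor & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbor[center] & remaining)
        clusters.append(members.tolist())
        centroids.append(center)
        remaining[members] = False
    order = sorted(range(len(clusters)),
                   key=lambda k: (-len(clusters[k]), centroids[k]))
    return ClusterResult(
        clusters=[clusters[k] for k in order],
        centroids=[centroids[k] for k in order],
        cutoff=cutoff,
    )
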