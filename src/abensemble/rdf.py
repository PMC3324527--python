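"""Per-residue water radial distributions and first-shell occupancy.

For each frame, the distance from every water oxygen to the *nearest heavy
atom of the residue* is histogrammed in shells of width ``dr`` out to
``r_max``.  The raw shell counts are normalized by the ideal-uniform
expectation, with the bulk density estimated from the outer 20% of the
radial range (tolerant of irregular solvation shells, unlike a box-volume
normalization).  Means are over frames; SEMs across trajectories.

The first solvation shell is integrated out to the first local minimum of
g(r) after its first maximum; profiles with no shell structure fall back
to a default 3.5 Angstrom radius and are flagged.

Differences between two alloforms' profiles at the first-shell peak are
classified by SEM overlap: well-separated ("**"), touching ("*"), or none.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .core import Conformation, Ensemble

__all__ = [
    "RDFProfile",
    "water_rdf",
    "first_shell_count",
    "classify_difference",
    "FALLBACK_SHELL_RADIUS",
]

FALLBACK_SHELL_RADIUS = 3.5  # Angstrom; used when g(r) has no shell structure


@dataclass
class RDFProfile:
    """Radial distribution of water around one residue."""

    residue: int
    residue_code: str
    r_edges: np.ndarray
    g: np.ndarray
    sem: np.ndarray
    raw_counts: np.ndarray           # mean waters per shell per frame
    bulk_density_norm: float         # mean waters per shell expected at bulk

    def __post_init__(self) -> None:
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])


def _residue_water_distances(frame: Conformation, waters: np.ndarray,
                             residue: int) -> np.ndarray:
    mask = (frame.residue_index == residue) & frame.heavy_mask()
    ref = frame.coords[mask]
    if len(ref) == 0:
        raise ValueError(f"residue {residue} has no heavy atoms")
    return cdist(np.asarray(waters, dtype=float), ref).min(axis=1)


def _shell_counts(frame: Conformation, waters: np.ndarray, residue: int,
                  edges: np.ndarray) -> np.ndarray:
    d = _residue_water_distances(frame, waters, residue)
    counts, _ = np.histogram(d, bins=edges)
    return counts.astype(float)


def water_rdf(ensemble: Ensemble,
              waters: Sequence[Sequence[np.ndarray]],
              residue: int,
              r_max: float = 10.0,
              dr: float = 0.25) -> RDFProfile:
    """Radial distribution of water oxygens around one residue.

    ``waters`` mirrors the ensemble layout: one list of per-frame (Nw, 3)
    oxygen coordinate arrays per trajectory.
    """
    if ensemble.is_empty:
        raise ValueError("empty ensemble")
    if len(waters) != ensemble.n_trajectories:
        raise ValueError("waters layout must mirror the ensemble trajectories")
    edges = np.arange(0.0, r_max + dr / 2, dr)
    per_traj_counts = []
    for traj, wtraj in zip(ensemble.trajectories, waters):
        if len(wtraj) != len(traj):
            raise ValueError("per-frame water list length mismatch")
        if any(len(w) == 0 for w in wtraj):
            raise ValueError("frame without water coordinates")
        frames = np.stack([
            _shell_counts(f, w, residue, edges) for f, w in zip(traj, wtraj)
        ])
        per_traj_counts.append(frames.mean(axis=0))
    counts = np.stack(per_traj_counts)            # (n_traj, n_shells)
    mean_counts = counts.mean(axis=0)

    # Bulk normalization from the outer 20% of the radial range: expected
    # waters per shell = rho_bulk * shell volume (spherical shells).
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    outer = centers >= 0.8 * r_max
    if mean_counts[outer].sum() == 0:
        # r_max extends beyond the data (e.g. past the box); estimate the
        # bulk from the outer 20% of the populated radial range instead.
        populated = np.flatnonzero(mean_counts > 0)
        if populated.size == 0:
            raise ValueError("no waters in any shell")
        outer = (centers >= 0.8 * centers[populated[-1]]) \
            & (centers <= centers[populated[-1]])
    rho_bulk = mean_counts[outer].sum() / shell_vol[outer].sum()
    if rho_bulk <= 0:
        raise ValueError("no waters in the normalization tail")
    expected = rho_bulk * shell_vol
    g_by_traj = counts / expected[None, :]
    g = g_by_traj.mean(axis=0)
    if len(waters) >= 2:
        sem = g_by_traj.std(axis=0, ddof=1) / np.sqrt(len(waters))
    else:
        sem = np.zeros_like(g)
    code_arr = ensemble.frames_flat()[0]
    code = str(code_arr.residue_code[code_arr.residue_index == residue][0])
    return RDFProfile(residue=residue, residue_code=code, r_edges=edges,
                      g=g, sem=sem, raw_counts=mean_counts,
                      bulk_density_norm=float(rho_bulk))


def _first_minimum_index(g: np.ndarray) -> int | None:
    """Index of the first local minimum after the first local maximum."""
    peak = None
    for i in range(1, len(g) - 1):
        if peak is None:
            if g[i] > g[i - 1] and g[i] >= g[i + 1] and g[i] > 0:
                peak = i
        else:
            if g[i] < g[i - 1] and g[i] <= g[i + 1]:
                return i
    return None


def first_shell_count(profile: RDFProfile) -> tuple[float, bool]:
    """Mean waters in the first solvation shell; flag True if the fallback
    radius was used (no detectable shell structure)."""
    idx = _first_minimum_index(profile.g)
    if idx is None:
        r_cut = FALLBACK_SHELL_RADIUS
        fallback = True
    else:
        r_cut = profile.r_centers[idx]
        fallback = False
    sel = profile.r_centers <= r_cut
    return float(profile.raw_counts[sel].sum()), fallback


def classify_difference(a: RDFProfile, b: RDFProfile) -> str:
    """SEM-overlap classification at the first-shell peak bin.

    Returns "**" for well-separated profiles (difference beyond the summed
    SEMs by more than 10%), "*" for touching profiles (difference within
    10% above the summed SEMs), and "" otherwise.  Symmetric in (a, b).
    """
    if a.r_edges.shape != b.r_edges.shape or not np.allclose(a.r_edges, b.r_edges):
        raise ValueError("profiles must share one binning")
    peak = int(np.argmax(a.g + b.g))
    delta = abs(a.g[peak] - b.g[peak])
    s = a.sem[peak] + b.sem[peak]
    if s < delta <= 1.1 * s:
        return "*"
    if delta > 1.1 * s:
        return "**"
    return ""
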