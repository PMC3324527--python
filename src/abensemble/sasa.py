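"""Solvent accessible surface area and normalized distributions.

SASA is computed with a deterministic Shrake-Rupley scheme: each atom's
sphere (vdW radius + probe, default probe 1.4 Angstrom) is sampled with a
fixed 960-point Fibonacci point set; a point is exposed if it lies outside
every other atom's expanded sphere, and the atom's exposed area is the
exposed fraction times the sphere area.  Per-residue SASA sums the atom
areas within the residue; occlusion considers all atoms of the assembly.
Areas are reported in nm^2 (the reaction-coordinate unit) while
coordinates stay in Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import AlloformSpec, Conformation, PerResidueProfile, Ensemble
from .stats import mean_sem

__all__ = [
    "PROBE_RADIUS",
    "N_SPHERE_POINTS",
    "sasa_per_atom",
    "sasa_per_residue",
    "hydrophobic_sasa",
    "Histogram1D",
    "distribution",
]

PROBE_RADIUS = 1.4      # Angstrom
N_SPHERE_POINTS = 960   # deterministic Fibonacci sampling resolution

_A2_TO_NM2 = 0.01


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


_SPHERE_CACHE: dict[int, np.ndarray] = {}


def _sphere_points(n: int) -> np.ndarray:
    if n not in _SPHERE_CACHE:
        _SPHERE_CACHE[n] = _fibonacci_sphere(n)
    return _SPHERE_CACHE[n]


def sasa_per_atom(conf: Conformation, probe: float = PROBE_RADIUS,
                  n_points: int = N_SPHERE_POINTS) -> np.ndarray:
    """Per-atom solvent accessible surface area in Angstrom^2."""
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    pts = _sphere_points(n_points)
    radii = conf.vdw_radius + probe
    coords = conf.coords
    n = conf.n_atoms
    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.empty(n)
    for i in range(n):
        ri = radii[i]
        surface = coords[i] + ri * pts
        # Neighbors whose expanded sphere can reach atom i's surface.
        nbr = tree.query_ball_point(coords[i], ri + max_r)
        nbr = [j for j in nbr if j != i]
        if nbr:
            d = np.linalg.norm(surface[:, None, :] - coords[nbr][None, :, :],
                               axis=2)
            buried = (d < radii[nbr][None, :]).any(axis=1)
            exposed_frac = 1.0 - buried.mean()
        else:
            exposed_frac = 1.0
        areas[i] = exposed_frac * 4.0 * np.pi * ri * ri
    return areas


def sasa_per_residue(conf: Conformation, probe: float = PROBE_RADIUS,
                     n_points: int = N_SPHERE_POINTS) -> dict[tuple[int, int], float]:
    """Per-residue SASA in nm^2 keyed by (peptide, residue index)."""
    atom_areas = sasa_per_atom(conf, probe, n_points)
    out: dict[tuple[int, int], float] = {}
    for p in conf.peptides:
        for r in np.unique(conf.residue_index[conf.peptide_id == p]):
            mask = (conf.peptide_id == p) & (conf.residue_index == r)
            out[(int(p), int(r))] = float(atom_areas[mask].sum()) * _A2_TO_NM2
    return out


def sasa_profile(ensemble: Ensemble, probe: float = PROBE_RADIUS,
                 n_points: int = N_SPHERE_POINTS) -> PerResidueProfile:
    """Mean per-residue SASA over an ensemble (peptides pooled), nm^2."""
    if ensemble.is_empty:
        raise ValueError("empty ensemble")
    first = next(ensemble.frames())
    n_res = first.n_residues(1)

    def frame_values(f: Conformation) -> np.ndarray:
        per = sasa_per_residue(f, probe, n_points)
        vals = np.zeros(n_res)
        counts = np.zeros(n_res)
        for (p, r), a in per.items():
            vals[r - 1] += a
            counts[r - 1] += 1
        return vals / np.maximum(counts, 1)

    mean, sem = mean_sem(ensemble.map_by_trajectory(frame_values))
    return PerResidueProfile("sasa_per_residue", mean, sem, units="nm^2")


def hydrophobic_sasa(conf: Conformation, spec: AlloformSpec,
                     probe: float = PROBE_RADIUS,
                     n_points: int = N_SPHERE_POINTS) -> float:
    """Combined SASA of all hydrophobic residues across all peptides (nm^2)."""
    per = sasa_per_residue(conf, probe, n_points)
    return float(sum(
        a for (p, r), a in per.items() if r in spec.hydrophobic_residues
    ))


@dataclass
class Histogram1D:
    """Density-normalized histogram with per-bin SEM across trajectories."""

    bin_edges: np.ndarray
    density: np.ndarray
    sem: np.ndarray

    def __post_init__(self) -> None:
        widths = np.diff(self.bin_edges)
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        total = float(np.sum(self.density * widths))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"density does not integrate to 1 ({total})")


def distribution(values: Sequence[float] | Sequence[np.ndarray],
                 n_bins: int,
                 by_trajectory: bool = False) -> Histogram1D:
    """Normalized probability distribution of a reaction coordinate.

    With ``by_trajectory=True``, ``values`` holds one sample array per
    trajectory; the density is computed from the pooled samples and the
    per-bin SEM across per-trajectory densities (all on the pooled bin
    grid).  Otherwise SEM is zero only when a single sample value repeats.
    """
    if by_trajectory:
        groups = [np.asarray(v, dtype=float) for v in values]
        pooled = np.concatenate(groups)
    else:
        pooled = np.asarray(values, dtype=float)
        groups = None
    if pooled.size < 2:
        raise ValueError("need at least two samples")
    edges = np.histogram_bin_edges(pooled, bins=n_bins)
    if edges[0] == edges[-1]:  # constant samples: one occupied bin
        edges = np.linspace(edges[0] - 0.5, edges[0] + 0.5, n_bins + 1)
    density, _ = np.histogram(pooled, bins=edges, density=True)
    if groups is not None and len(groups) >= 2:
        per = np.stack([
            np.histogram(g, bins=edges, density=True)[0] for g in groups
        ])
        sem = per.std(axis=0, ddof=1) / np.sqrt(len(groups))
    else:
        sem = np.zeros_like(density)
    return Histogram1D(bin_edges=edges, density=density, sem=sem)
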