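"""Center-of-mass geometry, contact numbers, and contact maps.

Contacts follow the C-alpha convention: two residues are in contact when
their C-alpha atoms lie strictly below the cutoff (default 7.5 Angstrom;
ties at exactly the cutoff count as non-contact).  The contact number
counts interpeptide residue pairs of a dimer and serves as a proxy for the
interface area; the NT-CM distance (N-terminal C-alpha to assembly center
of mass) serves as an effective radius of a quasi-spherical conformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core import AtomPredicate, Conformation, Ensemble, PerResidueProfile
from .stats import mean_sem

__all__ = [
    "DEFAULT_CONTACT_CUTOFF",
    "center_of_mass",
    "radius_of_gyration",
    "residue_cm_distances",
    "nt_cm_distance",
    "contact_number",
    "ContactMap",
    "contact_map",
]

#: Default C-alpha contact cutoff (Angstrom); the second value of the
#: two-cutoff robustness check is 8.0.
DEFAULT_CONTACT_CUTOFF = 7.5


def center_of_mass(conf: Conformation,
                   selection: AtomPredicate | np.ndarray | None = None
                   ) -> np.ndarray:
    """Mass-weighted mean position of the selected atoms (Angstrom).

    The default selection is every peptide atom (waters/ions never enter a
    Conformation); an empty selection is an error.
    """
    if selection is None:
        mask = np.ones(conf.n_atoms, dtype=bool)
    elif callable(selection):
        mask = selection(conf)
    else:
        mask = np.asarray(selection, dtype=bool)
    if not mask.any():
        raise ValueError("empty selection for center of mass")
    w = conf.mass[mask]
    return (conf.coords[mask] * w[:, None]).sum(axis=0) / w.sum()


def radius_of_gyration(conf: Conformation) -> float:
    """sqrt(sum m_i |r_i - r_cm|^2 / sum m_i) in Angstrom."""
    cm = center_of_mass(conf)
    d2 = np.sum((conf.coords - cm) ** 2, axis=1)
    return float(np.sqrt(np.sum(conf.mass * d2) / conf.mass.sum()))


def _frame_cm_distances(conf: Conformation, n_res: int) -> np.ndarray:
    """Per-residue |CA_i - CM| of one frame; dimer peptides pooled (mean)."""
    cm = center_of_mass(conf)
    out = np.full((len(conf.peptides), n_res), np.nan)
    for k, p in enumerate(conf.peptides):
        mask = conf.ca_mask(int(p))
        idx = conf.residue_index[mask] - 1
        out[k, idx] = np.linalg.norm(conf.coords[mask] - cm, axis=1)
    return np.nanmean(out, axis=0)


def residue_cm_distances(ensemble: Ensemble) -> PerResidueProfile:
    """Mean distance of each residue's C-alpha from the frame CM.

    Averaged over all frames; SEM across trajectories.  For dimers both
    peptides contribute samples.
    """
    if ensemble.is_empty:
        raise ValueError("empty ensemble")
    first = next(ensemble.frames())
    n_res = first.n_residues(1)
    per_traj = ensemble.map_by_trajectory(
        lambda f: _frame_cm_distances(f, n_res))
    mean, sem = mean_sem(per_traj)
    return PerResidueProfile("distance_from_cm", mean, sem, units="Angstrom")


def nt_cm_distance(conf: Conformation) -> np.ndarray:
    """|CA(D1, peptide k) - CM(assembly)| for each peptide (Angstrom)."""
    cm = center_of_mass(conf)
    out = []
    for p in conf.peptides:
        mask = conf.ca_mask(int(p)) & (conf.residue_index == 1)
        if not mask.any():
            raise ValueError(f"peptide {p}: residue 1 C-alpha missing")
        out.append(float(np.linalg.norm(conf.coords[mask][0] - cm)))
    return np.array(out)


def _cross_ca_distances(conf: Conformation) -> np.ndarray:
    """Interpeptide CA-CA distance matrix, rows/cols ordered by residue."""
    if not conf.is_dimer:
        raise ValueError("contact number requires a dimer conformation")
    a = conf.ca_coords(1)
    b = conf.ca_coords(2)
    return cdist(a, b)


def contact_number(conf: Conformation,
                   cutoff: float = DEFAULT_CONTACT_CUTOFF) -> int:
    """Number of interpeptide residue pairs with CA-CA distance < cutoff."""
    return int(np.count_nonzero(_cross_ca_distances(conf) < cutoff))


@dataclass
class ContactMap:
    """Residue-residue mean contact probability with SEM.

    ``kind="intra"`` averages tertiary contacts (both peptides of a dimer
    pooled); ``kind="inter"`` averages quaternary contacts, symmetrized
    over peptide labeling so the result is invariant to chain order.
    """

    kind: str
    matrix: np.ndarray
    sem: np.ndarray
    cutoff: float
    n_conformations: int

    def __post_init__(self) -> None:
        finite = self.matrix[np.isfinite(self.matrix)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("contact probabilities must lie in [0, 1]")


def _frame_contact_matrix(conf: Conformation, cutoff: float,
                          kind: str) -> np.ndarray:
    if kind == "intra":
        mats = []
        for p in conf.peptides:
            ca = conf.ca_coords(int(p))
            mats.append((cdist(ca, ca) < cutoff).astype(float))
        return np.mean(mats, axis=0)
    if kind == "inter":
        d = _cross_ca_distances(conf)
        m = (d < cutoff).astype(float)
        return 0.5 * (m + m.T)
    raise ValueError(f"unknown contact map kind {kind!r}")


def contact_map(ensemble: Ensemble, cutoff: float = DEFAULT_CONTACT_CUTOFF,
                kind: str = "intra") -> ContactMap:
    """Per-pair contact probability averaged over all frames, SEM across
    trajectories."""
    if ensemble.is_empty:
        raise ValueError("empty ensemble")
    per_traj = ensemble.map_by_trajectory(
        lambda f: _frame_contact_matrix(f, cutoff, kind))
    mean, sem = mean_sem(per_traj)
    return ContactMap(kind=kind, matrix=mean, sem=sem, cutoff=cutoff,
                      n_conformations=ensemble.n_frames)
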