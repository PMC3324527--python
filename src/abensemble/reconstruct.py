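"""Four-bead to united-atom reconstruction.

Coarse-grained chains carry four beads per residue (N, C-alpha, C', one
side-chain bead; Gly has none).  Reconstruction proceeds in two stages:

1.  **Template grafting** — backbone heavy atoms are taken from the N /
    C-alpha / C' beads (the carbonyl O is added at ideal geometry), and a
    rigid united-atom side-chain template replaces the single side-chain
    bead, centered on the bead position with a deterministic initial
    orientation (template principal axis along C-alpha -> bead).

2.  **Monte Carlo clash relief** — Metropolis moves (rigid side-chain
    rotations/displacements first, then small backbone moves) minimize a
    soft-sphere clash energy ``E = sum max(0, sigma_ij - d_ij)^2`` with
    ``sigma_ij = 0.9 (r_i + r_j)`` over non-bonded pairs.  Any move taking
    the mapped bead positions beyond ``max_cg_rmsd`` from the source beads
    (no re-superposition) is rejected outright, so the output always
    honors the bead-RMSD bound, and the best-so-far energy never
    increases.

Hydrogens are not placed (delegated to external tools); the united-atom
description is heavy atoms only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core import Conformation, ELEMENT_MASSES, ELEMENT_VDW_RADII
from .superpose import raw_rmsd

__all__ = [
    "SIDECHAIN_TEMPLATES",
    "DEFAULT_MAX_CG_RMSD",
    "DEFAULT_SCHEDULE",
    "graft_side_chains",
    "map_to_beads",
    "clash_energy",
    "relax_clashes",
    "reconstruct",
    "ReconstructionReport",
    "heavy_atom_count",
]

DEFAULT_MAX_CG_RMSD = 2.0    # Angstrom; bead-RMSD hard bound
DEFAULT_SCHEDULE = 2000      # proposed moves per phase
HARD_RADIUS_SCALE = 0.9      # sigma_ij = 0.9 * (vdW_i + vdW_j)

# United-atom side-chain heavy atoms (name, element) per residue type.
SIDECHAIN_TEMPLATES: dict[str, list[tuple[str, str]]] = {
    "G": [],
    "A": [("CB", "C")],
    "S": [("CB", "C"), ("OG", "O")],
    "C": [("CB", "C"), ("SG", "S")],
    "T": [("CB", "C"), ("OG1", "O"), ("CG2", "C")],
    "V": [("CB", "C"), ("CG1", "C"), ("CG2", "C")],
    "L": [("CB", "C"), ("CG", "C"), ("CD1", "C"), ("CD2", "C")],
    "I": [("CB", "C"), ("CG1", "C"), ("CG2", "C"), ("CD1", "C")],
    "M": [("CB", "C"), ("CG", "C"), ("SD", "S"), ("CE", "C")],
    "P": [("CB", "C"), ("CG", "C"), ("CD", "C")],
    "F": [("CB", "C"), ("CG", "C"), ("CD1", "C"), ("CD2", "C"),
          ("CE1", "C"), ("CE2", "C"), ("CZ", "C")],
    "Y": [("CB", "C"), ("CG", "C"), ("CD1", "C"), ("CD2", "C"),
          ("CE1", "C"), ("CE2", "C"), ("CZ", "C"), ("OH", "O")],
    "W": [("CB", "C"), ("CG", "C"), ("CD1", "C"), ("CD2", "C"),
          ("NE1", "N"), ("CE2", "C"), ("CE3", "C"), ("CZ2", "C"),
          ("CZ3", "C"), ("CH2", "C")],
    "D": [("CB", "C"), ("CG", "C"), ("OD1", "O"), ("OD2", "O")],
    "E": [("CB", "C"), ("CG", "C"), ("CD", "C"), ("OE1", "O"), ("OE2", "O")],
    "N": [("CB", "C"), ("CG", "C"), ("OD1", "O"), ("ND2", "N")],
    "Q": [("CB", "C"), ("CG", "C"), ("CD", "C"), ("OE1", "O"), ("NE2", "N")],
    "K": [("CB", "C"), ("CG", "C"), ("CD", "C"), ("CE", "C"), ("NZ", "N")],
    "R": [("CB", "C"), ("CG", "C"), ("CD", "C"), ("NE", "N"), ("CZ", "C"),
          ("NH1", "N"), ("NH2", "N")],
    "H": [("CB", "C"), ("CG", "C"), ("ND1", "N"), ("CD2", "C"),
          ("CE1", "C"), ("NE2", "N")],
}

_BACKBONE_HEAVY = 4  # N, CA, C, O


def heavy_atom_count(code: str) -> int:
    """United-atom heavy atoms of one residue (backbone + side chain)."""
    return _BACKBONE_HEAVY + len(SIDECHAIN_TEMPLATES[code])


def _template_local_coords(code: str) -> np.ndarray:
    """Deterministic idealized template geometry, centered on its centroid.

    Atoms are laid out along a zigzag chain with 1.5 Angstrom spacing --
    a surrogate for real rotamer geometry sufficient for clash relief.
    """
    n = len(SIDECHAIN_TEMPLATES[code])
    if n == 0:
        return np.empty((0, 3))
    pts = np.array([
        [1.25 * k, 0.75 * (k % 2), 0.0] for k in range(n)
    ])
    return pts - pts.mean(axis=0)


def _orient_template(local: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Rotate the template so its long axis follows ``axis``."""
    if len(local) < 2:
        return local
    axis = axis / max(np.linalg.norm(axis), 1e-12)
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(x, axis)
    c = float(np.dot(x, axis))
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([-1.0, -1.0, 1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
    return local @ rot.T


def _bead_positions(cg: Conformation) -> dict[tuple[int, str], np.ndarray]:
    out = {}
    for name in ("N", "CA", "C", "CB"):
        mask = cg.atom_name == name
        for r, xyz in zip(cg.residue_index[mask], cg.coords[mask]):
            out[(int(r), name)] = xyz
    return out


def graft_side_chains(cg: Conformation) -> Conformation:
    """Replace side-chain beads by rigid united-atom templates.

    Backbone N/C-alpha/C' positions are taken from the beads unchanged; the
    carbonyl O is added at ideal geometry in the local backbone frame.
    """
    beads = _bead_positions(cg)
    n_res = cg.n_residues(1)
    records = []
    coords = []
    for r in range(1, n_res + 1):
        sel = cg.residue_index == r
        if not sel.any():
            raise ValueError(f"residue {r} missing from the chain")
        code = str(cg.residue_code[sel][0])
        if code not in SIDECHAIN_TEMPLATES:
            raise ValueError(f"no side-chain template for residue {code!r}")
        for name in ("N", "CA", "C"):
            if (r, name) not in beads:
                raise ValueError(f"residue {code}{r}: missing {name} bead")
        n_xyz, ca_xyz, c_xyz = (beads[(r, n)] for n in ("N", "CA", "C"))
        records += [(1, r, code, "N", "N"), (1, r, code, "CA", "C"),
                    (1, r, code, "C", "C")]
        coords += [n_xyz, ca_xyz, c_xyz]
        # Carbonyl O: 1.23 A from C', bisecting away from CA and next N.
        d1 = c_xyz - ca_xyz
        d1 /= max(np.linalg.norm(d1), 1e-12)
        if (r + 1, "N") in beads:
            d2 = c_xyz - beads[(r + 1, "N")]
            d2 /= max(np.linalg.norm(d2), 1e-12)
            o_dir = d1 + d2
        else:
            o_dir = d1
        o_dir /= max(np.linalg.norm(o_dir), 1e-12)
        records.append((1, r, code, "O", "O"))
        coords.append(c_xyz + 1.23 * o_dir)
        template = SIDECHAIN_TEMPLATES[code]
        if template:
            if (r, "CB") not in beads:
                raise ValueError(f"residue {code}{r}: missing side-chain bead")
            bead = beads[(r, "CB")]
            local = _orient_template(_template_local_coords(code),
                                     bead - ca_xyz)
            for (name, elem), xyz in zip(template, bead + local):
                records.append((1, r, code, name, elem))
                coords.append(xyz)
    elements = np.array([rec[4] for rec in records])
    return Conformation(
        peptide_id=np.array([rec[0] for rec in records], dtype=int),
        residue_index=np.array([rec[1] for rec in records], dtype=int),
        residue_code=np.array([rec[2] for rec in records], dtype="<U1"),
        atom_name=np.array([rec[3] for rec in records], dtype="<U6"),
        element=elements,
        vdw_radius=np.array([ELEMENT_VDW_RADII[e] for e in elements]),
        mass=np.array([ELEMENT_MASSES[e] for e in elements]),
        coords=np.array(coords),
        frame_time=cg.frame_time,
    )


def map_to_beads(conf: Conformation) -> Conformation:
    """Map a united-atom chain back to its four-bead representation.

    N/C-alpha/C' map directly; the side-chain bead is the centroid of the
    side-chain heavy atoms.
    """
    records = []
    coords = []
    n_res = conf.n_residues(1)
    backbone = {"N", "CA", "C", "O"}
    for r in range(1, n_res + 1):
        sel = conf.residue_index == r
        code = str(conf.residue_code[sel][0])
        for name in ("N", "CA", "C"):
            mask = sel & (conf.atom_name == name)
            records.append((1, r, code, name, "N" if name == "N" else "C"))
            coords.append(conf.coords[mask][0])
        side = sel & ~np.isin(conf.atom_name, list(backbone))
        if side.any():
            records.append((1, r, code, "CB", "C"))
            coords.append(conf.coords[side].mean(axis=0))
    elements = np.array([rec[4] for rec in records])
    return Conformation(
        peptide_id=np.array([rec[0] for rec in records], dtype=int),
        residue_index=np.array([rec[1] for rec in records], dtype=int),
        residue_code=np.array([rec[2] for rec in records], dtype="<U1"),
        atom_name=np.array([rec[3] for rec in records], dtype="<U6"),
        element=elements,
        vdw_radius=np.array([ELEMENT_VDW_RADII[e] for e in elements]),
        mass=np.array([ELEMENT_MASSES[e] for e in elements]),
        coords=np.array(coords),
        frame_time=conf.frame_time,
    )


def _bead_rmsd(conf: Conformation, source_beads: Conformation) -> float:
    """RMSD of the mapped beads against the source beads, no superposition."""
    mapped = map_to_beads(conf)
    return raw_rmsd(mapped.coords, source_beads.coords)


def _pair_mask(conf: Conformation) -> np.ndarray:
    """Non-bonded pair mask for the clash energy.

    Excluded: pairs within one residue, and backbone-backbone pairs of
    adjacent residues (covers the peptide bond and its 1-3/1-4 geometry).
    """
    n = conf.n_atoms
    res = conf.residue_index
    same = res[:, None] == res[None, :]
    adjacent = np.abs(res[:, None] - res[None, :]) == 1
    backbone = np.isin(conf.atom_name, ["N", "CA", "C", "O"])
    bb_pair = backbone[:, None] & backbone[None, :]
    mask = ~(same | (adjacent & bb_pair))
    mask &= ~np.eye(n, dtype=bool)
    return np.triu(mask)


def clash_energy(conf: Conformation,
                 pair_mask: np.ndarray | None = None) -> float:
    """Soft-sphere clash energy: sum over non-bonded pairs of
    ``max(0, sigma_ij - d_ij)^2`` with sigma = 0.9 (r_i + r_j)."""
    if pair_mask is None:
        pair_mask = _pair_mask(conf)
    d = cdist(conf.coords, conf.coords)
    sigma = HARD_RADIUS_SCALE * (
        conf.vdw_radius[:, None] + conf.vdw_radius[None, :])
    overlap = np.maximum(0.0, sigma - d)
    return float((overlap[pair_mask] ** 2).sum())


def _partial_energy(coords: np.ndarray, vdw: np.ndarray,
                    moved: np.ndarray, pair_mask: np.ndarray) -> float:
    """Clash energy restricted to pairs involving the moved atoms."""
    sub_mask = pair_mask[moved][:, :] | pair_mask[:, moved].T
    d = cdist(coords[moved], coords)
    sigma = HARD_RADIUS_SCALE * (vdw[moved][:, None] + vdw[None, :])
    overlap = np.maximum(0.0, sigma - d)
    return float((overlap[sub_mask] ** 2).sum())


def _random_rotation(rng: np.random.Generator, max_angle: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-max_angle, max_angle)
    vx = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                   [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * vx + (1 - np.cos(angle)) * vx @ vx


@dataclass
class ReconstructionReport:
    initial_energy: float
    final_energy: float
    bead_rmsd: float
    accepted_moves: int
    proposed_moves: int


def relax_clashes(conf: Conformation, cg: Conformation,
                  max_cg_rmsd: float = DEFAULT_MAX_CG_RMSD,
                  seed: int = 0,
                  schedule: int = DEFAULT_SCHEDULE,
                  temperature: float = 0.05,
                  ) -> tuple[Conformation, ReconstructionReport]:
    """Metropolis Monte Carlo clash relief under the bead-RMSD bound.

    Phase 1 applies rigid rotations/small displacements to side chains;
    phase 2 small backbone displacements — mirroring the separate
    optimization of side-chain and backbone atoms.  The best-so-far energy
    is monotone non-increasing and the returned structure is the best one
    observed, so the final energy never exceeds the initial energy.
    """
    if schedule <= 0:
        raise ValueError("schedule length must be positive")
    pair_mask_full = _pair_mask(conf)
    pair_mask = pair_mask_full | pair_mask_full.T
    coords = conf.coords.copy()
    vdw = conf.vdw_radius
    e0 = clash_energy(conf, pair_mask_full)
    if e0 == 0.0:
        report = ReconstructionReport(e0, e0, _bead_rmsd(conf, cg), 0, 0)
        return conf.with_coords(coords), report
    rng = np.random.default_rng(seed)
    n_res = conf.n_residues(1)
    backbone_names = ["N", "CA", "C", "O"]
    side_groups = []
    back_groups = []
    for r in range(1, n_res + 1):
        sel = conf.residue_index == r
        side = np.flatnonzero(sel & ~np.isin(conf.atom_name, backbone_names))
        if side.size:
            side_groups.append((r, side))
        back_groups.append((r, np.flatnonzero(
            sel & np.isin(conf.atom_name, backbone_names))))

    # Incremental bead-RMSD bookkeeping: mapped bead rows aligned with the
    # source bead order (N, CA, C, [CB] per residue).
    src_beads = cg.coords
    bead_rows: dict[tuple[int, str], int] = {}
    row = 0
    for r, name in zip(cg.residue_index, cg.atom_name):
        bead_rows[(int(r), str(name))] = row
        row += 1
    n_beads = len(src_beads)
    mapped = np.empty_like(src_beads)
    atom_row: dict[tuple[int, str], int] = {}
    for i, (r, name) in enumerate(zip(conf.residue_index, conf.atom_name)):
        atom_row[(int(r), str(name))] = i
    for (r, name), b in bead_rows.items():
        if name == "CB":
            _, side = next(g for g in side_groups if g[0] == r)
            mapped[b] = coords[side].mean(axis=0)
        else:
            mapped[b] = coords[atom_row[(r, name)]]
    sq_dev = float(np.sum((mapped - src_beads) ** 2))
    max_sq = max_cg_rmsd ** 2 * n_beads

    def bead_update(r: int, kind: str) -> tuple[list[int], np.ndarray]:
        """New bead rows for residue r after a move of ``kind``."""
        if kind == "side":
            b = bead_rows[(r, "CB")]
            _, side = next(g for g in side_groups if g[0] == r)
            return [b], coords[side].mean(axis=0)[None, :]
        rows = [bead_rows[(r, n)] for n in ("N", "CA", "C")]
        return rows, np.stack([coords[atom_row[(r, n)]]
                               for n in ("N", "CA", "C")])

    best_coords = coords.copy()
    best_energy = current_energy = e0
    accepted = proposed = 0

    def try_move(r: int, kind: str, moved: np.ndarray,
                 new_xyz: np.ndarray) -> None:
        nonlocal current_energy, best_energy, best_coords, accepted, sq_dev
        old_xyz = coords[moved].copy()
        e_old = _partial_energy(coords, vdw, moved, pair_mask)
        coords[moved] = new_xyz
        e_new = _partial_energy(coords, vdw, moved, pair_mask)
        delta = e_new - e_old
        rows, new_beads = bead_update(r, kind)
        old_beads = mapped[rows].copy()
        new_sq = sq_dev \
            - float(np.sum((old_beads - src_beads[rows]) ** 2)) \
            + float(np.sum((new_beads - src_beads[rows]) ** 2))
        if new_sq > max_sq or (
                delta > 0 and rng.random() >= np.exp(-delta / temperature)):
            coords[moved] = old_xyz
            return
        mapped[rows] = new_beads
        sq_dev = new_sq
        accepted += 1
        current_energy += delta
        if current_energy < best_energy:
            best_energy = current_energy
            best_coords = coords.copy()

    # Phase 1: side chains (rigid rotation about the C-alpha + jitter).
    for _ in range(schedule):
        if not side_groups:
            break
        proposed += 1
        r, idx = side_groups[rng.integers(len(side_groups))]
        ca = coords[atom_row[(r, "CA")]]
        rot = _random_rotation(rng, max_angle=0.5)
        new = (coords[idx] - ca) @ rot.T + ca \
            + rng.normal(scale=0.1, size=3)
        try_move(r, "side", idx, new)
    # Phase 2: backbone (small rigid displacement per residue).
    for _ in range(schedule):
        proposed += 1
        r, idx = back_groups[rng.integers(len(back_groups))]
        new = coords[idx] + rng.normal(scale=0.05, size=3)
        try_move(r, "back", idx, new)

    final = conf.with_coords(best_coords)
    report = ReconstructionReport(
        initial_energy=e0,
        final_energy=clash_energy(final, pair_mask_full),
        bead_rmsd=_bead_rmsd(final, cg),
        accepted_moves=accepted,
        proposed_moves=proposed,
    )
    return final, report


def reconstruct(cg: Conformation,
                max_cg_rmsd: float = DEFAULT_MAX_CG_RMSD,
                seed: int = 0,
                schedule: int = DEFAULT_SCHEDULE,
                ) -> tuple[Conformation, ReconstructionReport]:
    """Graft united-atom side chains onto a four-bead chain and relax."""
    grafted = graft_side_chains(cg)
    return relax_clashes(grafted, cg, max_cg_rmsd=max_cg_rmsd, seed=seed,
                         schedule=schedule)
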