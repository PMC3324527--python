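"""Shared fixtures: alloform specs, small synthetic ensembles, builders."""

from __future__ import annotations

import numpy as np
import pytest

from abensemble.core import (
    AlloformSpec,
    Conformation,
    ELEMENT_MASSES,
    ELEMENT_VDW_RADII,
    alloform,
)
from abensemble.synthetic import (
    GeneratorConfig,
    gen_dimer_ensemble,
    gen_monomer_ensemble,
)


@pytest.fixture(scope="session")
def ab40() -> AlloformSpec:
    return alloform("Ab40")


@pytest.fixture(scope="session")
def ab42() -> AlloformSpec:
    return alloform("Ab42")


def make_conformation(coords,
                      atom_name=None,
                      element=None,
                      residue_index=None,
                      peptide_id=None,
                      residue_code=None,
                      mass=None,
                      frame_time=0.0) -> Conformation:
    """Build an ad-hoc Conformation with sensible defaults (all-CA chain)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    atom_name = np.asarray(atom_name if atom_name is not None else ["CA"] * n)
    element = np.asarray(element if element is not None else ["C"] * n)
    residue_index = np.asarray(
        residue_index if residue_index is not None else np.arange(1, n + 1),
        dtype=int)
    peptide_id = np.asarray(
        peptide_id if peptide_id is not None else np.ones(n, dtype=int))
    residue_code = np.asarray(
        residue_code if residue_code is not None else ["G"] * n)
    vdw = np.array([ELEMENT_VDW_RADII[e] for e in element])
    m = np.asarray(mass) if mass is not None \
        else np.array([ELEMENT_MASSES[e] for e in element])
    return Conformation(
        peptide_id=peptide_id, residue_index=residue_index,
        residue_code=residue_code, atom_name=atom_name, element=element,
        vdw_radius=vdw, mass=m, coords=coords, frame_time=frame_time)


def random_rigid_motion(rng: np.random.Generator):
    """A random rotation matrix and translation vector."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    trans = rng.normal(scale=20.0, size=3)
    return rot, trans


def quaternion_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Independent optimal-superposition RMSD via the quaternion
    eigenvalue method (Kearsley/Theobald formulation)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    m = bc.T @ ac
    ga = float(np.sum(ac * ac))
    gb = float(np.sum(bc * bc))
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = float(np.linalg.eigvalsh(key)[-1])
    msd = max(0.0, (ga + gb - 2.0 * lam)) / len(a)
    return float(np.sqrt(msd))


@pytest.fixture(scope="session")
def small_dimer_ensemble(ab40):
    """3 trajectories x 10 frames of compact Ab40 dimers, contact target 15."""
    cfg = GeneratorConfig(seed=11, n_trajectories=3, frames_per_trajectory=10,
                          compactness=10.0, target_contact_number=15)
    return gen_dimer_ensemble(cfg, ab40)


@pytest.fixture(scope="session")
def small_monomer_ensemble(ab42):
    """3 trajectories x 10 frames of Ab42 monomers, Rg 10 A."""
    cfg = GeneratorConfig(seed=13, n_trajectories=3, frames_per_trajectory=10,
                          compactness=10.0)
    return gen_monomer_ensemble(cfg, ab42)
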