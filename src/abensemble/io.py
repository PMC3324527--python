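"""Readers and writers for structures, trajectories, and run configs.

PDB parsing/writing delegates to biotite; this module maps biotite's
``AtomArray`` onto the package's :class:`~abensemble.core.Conformation`
(chains -> peptide ids, 3-letter -> 1-letter residue codes, element-derived
van der Waals radii and masses from the internal table).  Malformed ATOM
records are reported with their line number before biotite ever sees them.

Trajectories are consumed through a pluggable reader contract: multi-model
PDB is read natively; ``.xtc``/``.dcd`` delegate to mdtraj if available.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import yaml
import biotite.structure as struc
from biotite.structure.io import pdb as _pdb
from biotite.sequence import ProteinSequence

from .core import (
    AlloformSpec,
    Conformation,
    ELEMENT_MASSES,
    ELEMENT_VDW_RADII,
    Ensemble,
)

__all__ = [
    "ParseError",
    "load_structure",
    "write_structure",
    "load_ensemble",
    "write_ensemble",
    "load_config",
]


class ParseError(ValueError):
    """Malformed structure file; carries the offending line number."""


def _prescan_pdb(path: str) -> None:
    """Validate ATOM/HETATM record geometry columns, with line numbers."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"{path}:{lineno}: truncated ATOM record")
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: unparseable coordinate field "
                        f"{line[lo:hi]!r}"
                    ) from None


def _element_of(atom_name: str, element: str) -> str:
    if element and element.strip():
        return element.strip().upper().capitalize().upper()[:2].strip()
    # Derive from the atom name: strip digits, first letter is the element
    # for the organic set handled here (C/N/O/S/H).
    stripped = "".join(c for c in atom_name if c.isalpha())
    if not stripped:
        raise ParseError(f"cannot derive element from atom name {atom_name!r}")
    return stripped[0].upper()


def _atoms_to_conformation(arr: struc.AtomArray,
                           spec: AlloformSpec | None,
                           frame_time: float = 0.0) -> Conformation:
    chains = sorted(set(arr.chain_id.tolist()))
    if len(chains) > 2:
        raise ParseError(f"expected 1 or 2 chains, found {len(chains)}")
    chain_to_pid = {c: i + 1 for i, c in enumerate(chains)}

    n = arr.array_length()
    peptide_id = np.array([chain_to_pid[c] for c in arr.chain_id], dtype=int)
    codes = np.empty(n, dtype="<U1")
    for i, res3 in enumerate(arr.res_name):
        try:
            codes[i] = ProteinSequence.convert_letter_3to1(res3.capitalize())
        except Exception:
            raise ParseError(f"unknown residue name {res3!r}") from None

    elements = np.array(
        [_element_of(an, el) for an, el in zip(arr.atom_name, arr.element)]
    )
    unknown = sorted(set(elements) - set(ELEMENT_VDW_RADII))
    if unknown:
        raise ParseError(f"elements outside the internal table: {unknown}")
    vdw = np.array([ELEMENT_VDW_RADII[e] for e in elements])
    mass = np.array([ELEMENT_MASSES[e] for e in elements])

    conf = Conformation(
        peptide_id=peptide_id,
        residue_index=np.asarray(arr.res_id, dtype=int),
        residue_code=codes,
        atom_name=np.asarray(arr.atom_name, dtype="<U6"),
        element=elements,
        vdw_radius=vdw,
        mass=mass,
        coords=np.asarray(arr.coord, dtype=float),
        frame_time=frame_time,
    )
    conf.validate(spec)
    return conf


def load_structure(path: str, spec: AlloformSpec | None = None) -> Conformation:
    """Read a single-model PDB file into a Conformation.

    Chain identifiers map to peptide ids in sorted order; residue codes are
    validated against ``spec`` when one is supplied.
    """
    _prescan_pdb(path)
    pdb_file = _pdb.PDBFile.read(path)
    arr = pdb_file.get_structure(model=1)
    return _atoms_to_conformation(arr, spec)


def _conformation_to_atoms(conf: Conformation) -> struc.AtomArray:
    n = conf.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(conf.coords, dtype=np.float32)
    chain_letters = {1: "A", 2: "B"}
    arr.chain_id = np.array([chain_letters[int(p)] for p in conf.peptide_id])
    arr.res_id = np.asarray(conf.residue_index, dtype=int)
    arr.res_name = np.array(
        [ProteinSequence.convert_letter_1to3(c).upper() for c in conf.residue_code]
    )
    arr.atom_name = np.asarray(conf.atom_name, dtype="<U6")
    arr.element = np.asarray(conf.element, dtype="<U2")
    return arr


def write_structure(conf: Conformation, path: str) -> None:
    """Write a Conformation as a single-model PDB file."""
    pdb_file = _pdb.PDBFile()
    pdb_file.set_structure(_conformation_to_atoms(conf))
    pdb_file.write(path)


def write_ensemble(ensemble: Ensemble, path: str) -> None:
    """Write all frames of a (single-trajectory) ensemble as multi-model PDB."""
    frames = ensemble.frames_flat()
    if not frames:
        raise ValueError("cannot write an empty ensemble")
    stack = struc.stack([_conformation_to_atoms(f) for f in frames])
    pdb_file = _pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(path)


def _read_frames_pdb(topology: Conformation, path: str,
                     interval: float) -> list[Conformation]:
    _prescan_pdb(path)
    pdb_file = _pdb.PDBFile.read(path)
    n_models = pdb_file.get_model_count()
    frames = []
    for m in range(1, n_models + 1):
        arr = pdb_file.get_structure(model=m)
        frames.append(topology.with_coords(np.asarray(arr.coord, dtype=float),
                                           frame_time=m * interval))
    return frames


def _read_frames_mdtraj(topology: Conformation, path: str, top_path: str,
                        interval: float) -> list[Conformation]:
    import mdtraj  # optional reader backend

    traj = mdtraj.load(path, top=top_path)
    coords = np.asarray(traj.xyz, dtype=float) * 10.0  # nm -> Angstrom
    return [
        topology.with_coords(coords[k], frame_time=(k + 1) * interval)
        for k in range(len(coords))
    ]


def load_ensemble(topology: str,
                  trajectories: str | Sequence[str],
                  window: tuple[float, float],
                  interval: float,
                  spec: AlloformSpec | None = None) -> Ensemble:
    """Load trajectories against a PDB topology and apply the analysis window.

    Frame k of each trajectory is stamped at time ``k * interval`` ps
    (k = 1..M, matching a recording interval of one frame every ``interval``
    ps); only frames with ``t_start < t <= t_end`` are retained.
    """
    if isinstance(trajectories, (str, os.PathLike)):
        trajectories = [trajectories]
    top = load_structure(topology, spec)
    t0, t1 = window
    if t1 < t0:
        raise ValueError(f"invalid window {window}")
    all_trajs: list[list[Conformation]] = []
    for path in trajectories:
        ext = os.path.splitext(str(path))[1].lower()
        if ext == ".pdb":
            frames = _read_frames_pdb(top, str(path), interval)
        elif ext in (".xtc", ".dcd"):
            frames = _read_frames_mdtraj(top, str(path), topology, interval)
        else:
            raise ValueError(f"unsupported trajectory format {ext!r}")
        span = frames[-1].frame_time if frames else 0.0
        if t0 > span:
            raise ValueError(
                f"analysis window {window} starts beyond trajectory span "
                f"({span} ps) in {path}"
            )
        all_trajs.append([f for f in frames if t0 < f.frame_time <= t1])
    return Ensemble(all_trajs, recording_interval=interval,
                    analysis_window=(t0, t1))


def load_config(path: str) -> dict:
    """Read a YAML run configuration into a flat dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg
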