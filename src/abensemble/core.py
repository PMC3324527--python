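"""Core domain types for conformational-ensemble analysis of amyloid-beta.

The analyses in this package operate on three containers:

``Conformation``
    One frame: per-atom topology (peptide id, residue index/code, atom name,
    element, van der Waals radius, mass) plus Cartesian coordinates in
    Angstrom and a frame time in picoseconds.

``Ensemble``
    An ordered collection of trajectories, each a sequence of frames sharing
    one topology, together with the recording interval and the analysis
    window.  Statistics downstream treat trajectories as the independent
    sampling unit.

``AlloformSpec``
    The sequence and charge registry of one amyloid-beta alloform (Ab40 or
    Ab42): positively charged residues R5/K16/K28, the six negatively
    charged residues D1/E3/D7/E11/E22/D23, and the hydrophobic set used for
    the hydrophobic-SASA reaction coordinate.

Length unit is Angstrom throughout; reporting layers may convert to nm.
Residue indexing is 1-based (D1 ... A42).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Sequence

import numpy as np

__all__ = [
    "Conformation",
    "Ensemble",
    "AlloformSpec",
    "alloform",
    "ELEMENT_VDW_RADII",
    "ELEMENT_MASSES",
    "AB42_SEQUENCE",
    "AB40_SEQUENCE",
    "HYDROPHOBIC_DEFAULT",
]

# Fixed internal element table (Bondi vdW radii, standard atomic weights) so
# results do not depend on the installation.  United-atom analyses only ever
# see H, C, N, O, S.
ELEMENT_VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
}
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
}

AB42_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"
AB40_SEQUENCE = AB42_SEQUENCE[:-2]

#: Default hydrophobic residue types for the combined-SASA reaction
#: coordinate; conservative standard choice (G and Y excluded).
HYDROPHOBIC_DEFAULT = frozenset("AVLIMF")

POSITIVE_RESIDUES = frozenset({5, 16, 28})       # R5, K16, K28
NEGATIVE_RESIDUES = frozenset({1, 3, 7, 11, 22, 23})  # D1, E3, D7, E11, E22, D23


class TopologyError(ValueError):
    """Raised when a structure violates a topology invariant."""


@dataclass(frozen=True)
class AlloformSpec:
    """Sequence and charge registry for one amyloid-beta alloform."""

    name: str
    sequence: str
    positive_residues: frozenset[int]
    negative_residues: frozenset[int]
    hydrophobic_residues: frozenset[int]

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def residue_code(self, index: int) -> str:
        """1-letter code of residue ``index`` (1-based)."""
        return self.sequence[index - 1]


def _make_spec(name: str, sequence: str) -> AlloformSpec:
    hydrophobic = frozenset(
        i + 1 for i, aa in enumerate(sequence) if aa in HYDROPHOBIC_DEFAULT
    )
    return AlloformSpec(
        name=name,
        sequence=sequence,
        positive_residues=POSITIVE_RESIDUES,
        negative_residues=NEGATIVE_RESIDUES,
        hydrophobic_residues=hydrophobic,
    )


_REGISTRY: dict[str, AlloformSpec] = {
    "Ab40": _make_spec("Ab40", AB40_SEQUENCE),
    "Ab42": _make_spec("Ab42", AB42_SEQUENCE),
}


def alloform(name: str) -> AlloformSpec:
    """Return the registry entry for ``name`` ("Ab40" or "Ab42")."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown alloform {name!r}; known: {sorted(_REGISTRY)}"
        ) from None


@dataclass
class Conformation:
    """A single frame: atom topology plus coordinates (Angstrom).

    All per-atom fields are parallel numpy arrays of length ``n_atoms``.
    ``peptide_id`` is 1 for monomers and 1/2 for dimers; ``residue_index``
    is 1-based within each peptide.
    """

    peptide_id: np.ndarray          # int
    residue_index: np.ndarray       # int, 1-based
    residue_code: np.ndarray        # '<U1'
    atom_name: np.ndarray           # str
    element: np.ndarray             # str
    vdw_radius: np.ndarray          # float, Angstrom
    mass: np.ndarray                # float, amu
    coords: np.ndarray              # (n_atoms, 3) float, Angstrom
    frame_time: float = 0.0         # ps

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise TopologyError("coords must have shape (n_atoms, 3)")
        n = len(self.coords)
        for name in ("peptide_id", "residue_index", "residue_code",
                     "atom_name", "element", "vdw_radius", "mass"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise TopologyError(f"{name} length {len(arr)} != {n} atoms")
            setattr(self, name, arr)

    # -- basic views ------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def peptides(self) -> np.ndarray:
        return np.unique(self.peptide_id)

    @property
    def is_dimer(self) -> bool:
        return len(self.peptides) == 2

    def ca_mask(self, peptide: int | None = None) -> np.ndarray:
        mask = self.atom_name == "CA"
        if peptide is not None:
            mask &= self.peptide_id == peptide
        return mask

    def heavy_mask(self) -> np.ndarray:
        return self.element != "H"

    def select(self, mask: np.ndarray) -> "Conformation":
        """Sub-conformation of the atoms where ``mask`` is True."""
        return Conformation(
            peptide_id=self.peptide_id[mask],
            residue_index=self.residue_index[mask],
            residue_code=self.residue_code[mask],
            atom_name=self.atom_name[mask],
            element=self.element[mask],
            vdw_radius=self.vdw_radius[mask],
            mass=self.mass[mask],
            coords=self.coords[mask],
            frame_time=self.frame_time,
        )

    def with_coords(self, coords: np.ndarray,
                    frame_time: float | None = None) -> "Conformation":
        """Copy sharing topology arrays but with new coordinates."""
        return replace(
            self,
            coords=np.array(coords, dtype=float),
            frame_time=self.frame_time if frame_time is None else frame_time,
        )

    def ca_coords(self, peptide: int | None = None) -> np.ndarray:
        return self.coords[self.ca_mask(peptide)]

    def n_residues(self, peptide: int = 1) -> int:
        sel = self.peptide_id == peptide
        return int(self.residue_index[sel].max()) if sel.any() else 0

    # -- validation -------------------------------------------------------

    def validate(self, spec: AlloformSpec | None = None) -> None:
        """Check the Conformation invariants; raise TopologyError on failure."""
        if not np.all(np.isfinite(self.coords)):
            raise TopologyError("non-finite coordinates")
        peps = set(int(p) for p in self.peptides)
        if peps not in ({1}, {1, 2}):
            raise TopologyError(f"peptide ids must be {{1}} or {{1,2}}, got {peps}")
        if self.residue_index.min() < 1 or self.residue_index.max() > 42:
            raise TopologyError("residue indices must lie in 1..42")
        for p in peps:
            sel = self.peptide_id == p
            residues = np.unique(self.residue_index[sel])
            ca_res = np.unique(self.residue_index[sel & (self.atom_name == "CA")])
            missing = set(residues.tolist()) - set(ca_res.tolist())
            if missing:
                raise TopologyError(
                    f"peptide {p}: residues without CA atom: {sorted(missing)}"
                )
            if spec is not None:
                for r in residues:
                    codes = np.unique(
                        self.residue_code[sel & (self.residue_index == r)]
                    )
                    expected = spec.residue_code(int(r))
                    if any(c != expected for c in codes):
                        raise TopologyError(
                            f"peptide {p} residue {r}: code {codes} does not "
                            f"match {spec.name} sequence ({expected})"
                        )


AtomPredicate = Callable[[Conformation], np.ndarray]


@dataclass
class Ensemble:
    """Ordered frames grouped by trajectory, with an analysis window.

    ``analysis_window`` is half-open at the start: a frame at time t belongs
    to the window iff ``t_start < t <= t_end`` (in ps).  All trajectories
    share one topology.
    """

    trajectories: list[list[Conformation]]
    recording_interval: float                 # ps
    analysis_window: tuple[float, float]      # (t_start, t_end], ps

    def __post_init__(self) -> None:
        for k, traj in enumerate(self.trajectories):
            times = [f.frame_time for f in traj]
            if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
                raise ValueError(
                    f"trajectory {k}: frame times not strictly increasing"
                )

    @property
    def n_trajectories(self) -> int:
        return len(self.trajectories)

    @property
    def n_frames(self) -> int:
        return sum(len(t) for t in self.trajectories)

    @property
    def is_empty(self) -> bool:
        return self.n_frames == 0

    def frames(self) -> Iterator[Conformation]:
        for traj in self.trajectories:
            yield from traj

    def frames_flat(self) -> list[Conformation]:
        return [f for t in self.trajectories for f in t]

    def apply_window(self) -> "Ensemble":
        """Restrict every trajectory to frames inside the analysis window.

        Idempotent: applying the window twice equals applying it once.
        """
        t0, t1 = self.analysis_window
        kept = [
            [f for f in traj if t0 < f.frame_time <= t1]
            for traj in self.trajectories
        ]
        return Ensemble(kept, self.recording_interval, self.analysis_window)

    def subset(self, trajectory_indices: Sequence[int]) -> "Ensemble":
        return Ensemble(
            [self.trajectories[i] for i in trajectory_indices],
            self.recording_interval,
            self.analysis_window,
        )

    def map_by_trajectory(self, fn: Callable[[Conformation], float | np.ndarray]
                          ) -> list[np.ndarray]:
        """Evaluate ``fn`` on every frame, grouped by trajectory."""
        return [np.asarray([fn(f) for f in traj]) for traj in self.trajectories]


@dataclass
class PerResidueProfile:
    """Per-residue statistic with mean and SEM across trajectories."""

    statistic_name: str
    values: np.ndarray
    sem: np.ndarray
    units: str = ""
    residue_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if self.values.shape != self.sem.shape:
            raise ValueError("values and sem must have the same shape")
        if self.residue_index is None:
            self.residue_index = np.arange(1, len(self.values) + 1)
        finite = self.sem[np.isfinite(self.sem)]
        if np.any(finite < 0):
            raise ValueError("SEM must be non-negative")

    def __len__(self) -> int:
        return len(self.values)
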