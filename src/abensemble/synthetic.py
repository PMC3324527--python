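"""Synthetic conformational ensembles with the statistical structure the
analyses assume.

Real explicit-solvent trajectories of amyloid-beta monomers and dimers are
too expensive to regenerate, so every downstream stage is exercised on
seeded synthetic ensembles that emulate the features the analyses measure:

* disordered monomers of tunable compactness (self-avoiding C-alpha walks
  with one pseudo side-chain atom per non-Gly residue, Gaussian frame
  jitter, radius-of-gyration rescaling);
* two-peptide quasi-spherical dimers with a prescribed interpeptide
  contact number, buried hydrophobic C-termini and solvent-exposed
  N-termini;
* two-state (telegraph) salt-bridge formation/breaking with prescribed
  stationary occupancy and mean dwell time;
* uniform-density water shells around a solute;
* four-bead (N, C-alpha, C', side-chain bead) chains for the
  coarse-grained reconstruction stage.

All generators are deterministic for a fixed seed; one generator instance
is derived per trajectory (seed + trajectory index) so trajectory subsets
are reproducible.  Pseudo side-chain atoms of charged residues carry the
side-chain N/O names the salt-bridge detector expects, so detection code
runs unmodified on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .core import (
    AlloformSpec,
    Conformation,
    ELEMENT_MASSES,
    ELEMENT_VDW_RADII,
    Ensemble,
)
from .geometry import center_of_mass, radius_of_gyration
from .saltbridges import DEFAULT_SALTBRIDGE_CUTOFF

__all__ = [
    "GeneratorConfig",
    "SaltBridgePairSpec",
    "gen_monomer_ensemble",
    "gen_dimer_ensemble",
    "gen_saltbridge_telegraph",
    "gen_water_shell",
    "gen_cg_conformer",
]

# Pseudo side-chain atom name per residue type: charged residues carry the
# N/O labels used by salt-bridge detection; everything else gets a CB.
_PSEUDO_SIDECHAIN = {"R": ("NH1", "N"), "K": ("NZ", "N"),
                     "D": ("OD1", "O"), "E": ("OE1", "O")}

_MIN_CA_SEPARATION = 4.0  # Angstrom, non-bonded C-alpha pairs


@dataclass(frozen=True)
class SaltBridgePairSpec:
    """Telegraph specification for one (positive, negative) residue pair."""

    positive: int
    negative: int
    occupancy: float          # stationary probability of the ON state
    mean_dwell: float = 5.0   # mean ON dwell, frames

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic-ensemble generators."""

    seed: int = 0
    n_trajectories: int = 10
    frames_per_trajectory: int = 600
    recording_interval: float = 50.0      # ps
    bond_length: float = 3.8              # C-alpha - C-alpha, Angstrom
    compactness: float | None = None      # target Rg, Angstrom; None = free
    jitter: float = 0.3                   # per-frame Gaussian sigma, Angstrom
    target_contact_number: int = 10       # dimers
    contact_cutoff: float = 7.5           # Angstrom
    cutoff_gap: tuple[float, float] | None = None  # keep pairs out of gap
    nt_exposure_bias: bool = True         # dimers: N-term out, C-term in
    saltbridge_spec: list[SaltBridgePairSpec] = field(default_factory=list)
    water_density: float = 0.0            # molecules / Angstrom^3
    box_radius: float = 30.0              # Angstrom (cubic half-width)

    def __post_init__(self) -> None:
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")


# ---------------------------------------------------------------------------
# chain construction

def _self_avoiding_walk(n: int, bond: float, rng: np.random.Generator,
                        max_tries: int = 500) -> np.ndarray:
    """C-alpha positions of a self-avoiding random walk."""
    pos = np.zeros((n, 3))
    i = 1
    tries = 0
    while i < n:
        step = rng.normal(size=3)
        step *= bond / np.linalg.norm(step)
        cand = pos[i - 1] + step
        prior = pos[: max(i - 1, 0)]
        if len(prior) == 0 or np.linalg.norm(
                prior - cand, axis=1).min() >= _MIN_CA_SEPARATION:
            pos[i] = cand
            i += 1
            tries = 0
        else:
            tries += 1
            if tries > max_tries:  # backtrack one step
                i = max(1, i - 1)
                tries = 0
    return pos


def _chain_topology(spec: AlloformSpec, peptide: int
                    ) -> tuple[list[tuple], np.ndarray]:
    """Atom records (peptide, res, code, name, element) for one chain."""
    records = []
    for r in range(1, spec.n_residues + 1):
        code = spec.residue_code(r)
        records.append((peptide, r, code, "CA", "C"))
        if code != "G":
            name, elem = _PSEUDO_SIDECHAIN.get(code, ("CB", "C"))
            records.append((peptide, r, code, name, elem))
    return records, np.array([rec[1] for rec in records])


def _assemble(records: list[tuple], coords: np.ndarray,
              frame_time: float = 0.0) -> Conformation:
    elements = np.array([r[4] for r in records])
    return Conformation(
        peptide_id=np.array([r[0] for r in records], dtype=int),
        residue_index=np.array([r[1] for r in records], dtype=int),
        residue_code=np.array([r[2] for r in records], dtype="<U1"),
        atom_name=np.array([r[3] for r in records], dtype="<U6"),
        element=elements,
        vdw_radius=np.array([ELEMENT_VDW_RADII[e] for e in elements]),
        mass=np.array([ELEMENT_MASSES[e] for e in elements]),
        coords=coords,
        frame_time=frame_time,
    )


def _sidechain_direction(ca: np.ndarray, i: int,
                         rng: np.random.Generator) -> np.ndarray:
    lo, hi = max(i - 1, 0), min(i + 1, len(ca) - 1)
    v = ca[i] - 0.5 * (ca[lo] + ca[hi])
    if np.linalg.norm(v) < 1e-6:
        v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _chain_coords(spec: AlloformSpec, ca: np.ndarray,
                  rng: np.random.Generator,
                  sidechain_distance: float = 2.0) -> np.ndarray:
    """Full pseudo-atom coordinates from C-alpha positions."""
    coords = []
    for i in range(spec.n_residues):
        coords.append(ca[i])
        if spec.residue_code(i + 1) != "G":
            d = _sidechain_direction(ca, i, rng)
            coords.append(ca[i] + sidechain_distance * d)
    return np.array(coords)


def _min_feasible_rg(n: int) -> float:
    # Close packing of n spheres at the 4 A self-avoidance spacing: uniform
    # sphere of radius 2 n^(1/3); Rg of a uniform ball is sqrt(3/5) R.
    return float(np.sqrt(3.0 / 5.0) * 2.0 * n ** (1.0 / 3.0))


def _rescale_to_rg(conf: Conformation, target: float) -> Conformation:
    cm = center_of_mass(conf)
    rg = radius_of_gyration(conf)
    return conf.with_coords(cm + (conf.coords - cm) * (target / rg))


# ---------------------------------------------------------------------------
# monomers

def gen_monomer_ensemble(cfg: GeneratorConfig,
                         spec: AlloformSpec) -> Ensemble:
    """Disordered monomer ensemble of tunable compactness."""
    if cfg.frames_per_trajectory < 1:
        raise ValueError("need at least one frame per trajectory")
    if cfg.compactness is not None and np.isfinite(cfg.compactness):
        if cfg.compactness < _min_feasible_rg(spec.n_residues):
            raise ValueError(
                f"target Rg {cfg.compactness} below close packing "
                f"({_min_feasible_rg(spec.n_residues):.2f} A)"
            )
    records, _ = _chain_topology(spec, peptide=1)
    trajectories = []
    for t in range(cfg.n_trajectories):
        rng = np.random.default_rng(cfg.seed + t)
        ca = _self_avoiding_walk(spec.n_residues, cfg.bond_length, rng)
        base = _chain_coords(spec, ca, rng)
        frames = []
        for k in range(cfg.frames_per_trajectory):
            coords = base + rng.normal(scale=cfg.jitter, size=base.shape) \
                if cfg.jitter > 0 else base.copy()
            conf = _assemble(records, coords,
                             frame_time=(k + 1) * cfg.recording_interval)
            if cfg.compactness is not None and np.isfinite(cfg.compactness):
                conf = _rescale_to_rg(conf, cfg.compactness)
            frames.append(conf)
        trajectories.append(frames)
    window = (0.0, cfg.frames_per_trajectory * cfg.recording_interval)
    return Ensemble(trajectories, cfg.recording_interval, window)


# ---------------------------------------------------------------------------
# dimers

def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a to unit vector b (Rodrigues)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180 degrees: rotate about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return -np.eye(3) + 2.0 * np.outer(axis, axis)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _bias_chain(spec: AlloformSpec, coords: np.ndarray,
                residue_of_atom: np.ndarray) -> np.ndarray:
    """Radially rescale residues about the chain centroid: N-terminal
    residues 1-5 pushed outward, residues 30..C-terminus pulled inward."""
    n_res = spec.n_residues
    factors = np.ones(n_res)
    factors[:5] = 1.4
    start = 29  # residue 30 onward
    factors[start:] = 0.7
    ramp = np.linspace(1.4, 0.7, start - 5 + 2)[1:-1]
    factors[5:start] = ramp
    centroid = coords.mean(axis=0)
    out = coords.copy()
    for r in range(1, n_res + 1):
        mask = residue_of_atom == r
        out[mask] = centroid + (coords[mask] - centroid) * factors[r - 1]
    return out


def _orient_nt_outward(coords: np.ndarray, residue_of_atom: np.ndarray,
                       outward: np.ndarray) -> np.ndarray:
    """Rotate the chain so its N-terminal direction points along
    ``outward``."""
    centroid = coords.mean(axis=0)
    nt = coords[residue_of_atom == 1].mean(axis=0) - centroid
    if np.linalg.norm(nt) < 1e-9:
        return coords
    rot = _rotation_between(nt, outward)
    return centroid + (coords - centroid) @ rot.T


def _contact_count(ca1: np.ndarray, ca2: np.ndarray, sep: float,
                   cutoff: float) -> int:
    return int(np.count_nonzero(
        cdist(ca1, ca2 + np.array([sep, 0.0, 0.0])) < cutoff))


def _place_dimer(cfg: GeneratorConfig, ca1: np.ndarray, ca2: np.ndarray
                 ) -> float | None:
    """Separation along x giving the target contact number (within +/- 2),
    preferring separations with no cross pair inside the cutoff gap."""
    target = cfg.target_contact_number
    cutoff = cfg.contact_cutoff
    if target == 0:
        spread = (np.abs(ca1[:, 0]).max() + np.abs(ca2[:, 0]).max())
        return float(spread + 3.0 * cutoff)
    lo, hi = 0.0, 200.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        c = _contact_count(ca1, ca2, mid, cutoff)
        if c > target:
            lo = mid
        else:
            hi = mid
    for sep in np.arange(max(lo - 2.0, 0.0), hi + 2.0, 0.1):
        c = _contact_count(ca1, ca2, sep, cutoff)
        if abs(c - target) <= 2:
            return float(sep)
    return None


def _repair_gap(c1: np.ndarray, c2: np.ndarray,
                ca_mask1: np.ndarray, ca_mask2: np.ndarray,
                res2: np.ndarray, gap: tuple[float, float],
                max_iter: int = 200) -> np.ndarray:
    """Nudge chain-2 residues until no cross-peptide C-alpha pair lies
    inside the cutoff gap [g0, g1)."""
    g0, g1 = gap
    c2 = c2.copy()
    ca2_rows = np.flatnonzero(ca_mask2)
    for _ in range(max_iter):
        ca1 = c1[ca_mask1]
        ca2 = c2[ca_mask2]
        d = cdist(ca1, ca2)
        in_gap = (d >= g0) & (d < g1)
        if not in_gap.any():
            return c2
        # Move the chain-2 residue involved in the most gap pairs away from
        # its nearest gap partner, just past the outer gap edge.
        j = int(np.argmax(in_gap.sum(axis=0)))
        i = int(np.argmin(np.where(in_gap[:, j], d[:, j], np.inf)))
        direction = ca2[j] - ca1[i]
        norm = np.linalg.norm(direction)
        shift = (g1 + 0.05 - norm) * direction / norm
        res_atoms = res2 == res2[ca2_rows[j]]
        c2[res_atoms] += shift
    raise ValueError("could not clear the contact-cutoff gap")


def gen_dimer_ensemble(cfg: GeneratorConfig, spec: AlloformSpec) -> Ensemble:
    """Quasi-spherical dimers with a prescribed interpeptide contact number,
    buried C-termini and solvent-exposed N-termini."""
    n = spec.n_residues
    if cfg.target_contact_number < 0:
        raise ValueError("target_contact_number must be >= 0")
    if cfg.target_contact_number > n * n:
        raise ValueError(
            f"contact target {cfg.target_contact_number} infeasible for "
            f"chain length {n}"
        )
    rec1, res1 = _chain_topology(spec, peptide=1)
    rec2, res2 = _chain_topology(spec, peptide=2)
    records = rec1 + rec2
    trajectories = []
    for t in range(cfg.n_trajectories):
        rng = np.random.default_rng(cfg.seed + t)
        chains = []
        for pep, res_of in ((1, res1), (2, res2)):
            ca = _self_avoiding_walk(n, cfg.bond_length, rng)
            coords = _chain_coords(spec, ca, rng)
            if cfg.compactness is not None and np.isfinite(cfg.compactness):
                centroid = coords.mean(axis=0)
                rg = np.sqrt(np.mean(np.sum((coords - centroid) ** 2, axis=1)))
                coords = centroid + (coords - centroid) * (cfg.compactness / rg)
            if cfg.nt_exposure_bias:
                coords = _bias_chain(spec, coords, res_of)
                outward = np.array([-1.0, 0.0, 0.0]) if pep == 1 \
                    else np.array([1.0, 0.0, 0.0])
                coords = _orient_nt_outward(coords, res_of, outward)
            coords -= coords.mean(axis=0)
            chains.append(coords)
        frames = []
        for k in range(cfg.frames_per_trajectory):
            c1 = chains[0] + rng.normal(scale=cfg.jitter, size=chains[0].shape) \
                if cfg.jitter > 0 else chains[0].copy()
            c2 = chains[1] + rng.normal(scale=cfg.jitter, size=chains[1].shape) \
                if cfg.jitter > 0 else chains[1].copy()
            ca_mask1 = np.array([r[3] == "CA" for r in rec1])
            ca_mask2 = np.array([r[3] == "CA" for r in rec2])
            sep = _place_dimer(cfg, c1[ca_mask1], c2[ca_mask2])
            if sep is None:
                raise ValueError(
                    f"could not realize contact target "
                    f"{cfg.target_contact_number} (trajectory {t}, frame {k})"
                )
            c2 = c2 + np.array([sep, 0.0, 0.0])
            if cfg.cutoff_gap is not None:
                c2 = _repair_gap(c1, c2, ca_mask1, ca_mask2, res2,
                                 cfg.cutoff_gap)
            coords = np.vstack([c1, c2])
            frames.append(_assemble(
                records, coords,
                frame_time=(k + 1) * cfg.recording_interval))
        trajectories.append(frames)
    window = (0.0, cfg.frames_per_trajectory * cfg.recording_interval)
    return Ensemble(trajectories, cfg.recording_interval, window)


# ---------------------------------------------------------------------------
# telegraph salt bridges

def _telegraph_states(p: float, dwell: float, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Two-state Markov chain with stationary occupancy p and mean ON dwell."""
    if p <= 0.0:
        return np.zeros(n, dtype=bool)
    if p >= 1.0:
        return np.ones(n, dtype=bool)
    dwell_on = max(dwell, 1.0)
    dwell_off = max(dwell_on * (1.0 - p) / p, 1.0)
    # Adjust the ON dwell if the OFF dwell clamps, preserving stationarity.
    if dwell_off == 1.0:
        dwell_on = p / (1.0 - p)
        dwell_on = max(dwell_on, 1.0)
    p_leave_on = 1.0 / dwell_on
    p_leave_off = 1.0 / dwell_off
    states = np.empty(n, dtype=bool)
    s = bool(rng.random() < p)
    for i in range(n):
        states[i] = s
        if s:
            s = not (rng.random() < p_leave_on)
        else:
            s = rng.random() < p_leave_off
    return states


def gen_saltbridge_telegraph(cfg: GeneratorConfig, base: Ensemble,
                             cutoff: float = DEFAULT_SALTBRIDGE_CUTOFF
                             ) -> Ensemble:
    """Impose two-state salt-bridge dynamics on a base ensemble.

    For each pair in ``cfg.saltbridge_spec``, a telegraph process sets the
    minimal side-chain N-O distance to ``cutoff - 1`` in the ON state and
    ``cutoff + 3`` in the OFF state (the same state applied to every
    peptide, so pooled intrapeptide propensity equals the occupancy).
    """
    new_trajectories = []
    for t, traj in enumerate(base.trajectories):
        rng = np.random.default_rng(cfg.seed + 7919 * (t + 1))
        states = {
            id(ps): _telegraph_states(ps.occupancy, ps.mean_dwell,
                                      len(traj), rng)
            for ps in cfg.saltbridge_spec
        }
        frames = []
        for k, frame in enumerate(traj):
            coords = frame.coords.copy()
            for ps in cfg.saltbridge_spec:
                on = states[id(ps)][k]
                dist = cutoff - 1.0 if on else cutoff + 3.0
                for pep in frame.peptides:
                    n_mask = ((frame.peptide_id == pep)
                              & (frame.residue_index == ps.positive)
                              & (frame.element == "N"))
                    o_mask = ((frame.peptide_id == pep)
                              & (frame.residue_index == ps.negative)
                              & (frame.element == "O"))
                    if not n_mask.any() or not o_mask.any():
                        raise ValueError(
                            f"pair {ps.positive}-{ps.negative}: side-chain "
                            f"N/O pseudo-atoms missing on peptide {pep}"
                        )
                    o = coords[o_mask][0]
                    nvec = coords[n_mask][0] - o
                    norm = np.linalg.norm(nvec)
                    if norm < 1e-9:
                        nvec, norm = np.array([1.0, 0.0, 0.0]), 1.0
                    coords[np.flatnonzero(n_mask)[0]] = o + nvec / norm * dist
            frames.append(frame.with_coords(coords))
        new_trajectories.append(frames)
    return Ensemble(new_trajectories, base.recording_interval,
                    base.analysis_window)


# ---------------------------------------------------------------------------
# water shells

def gen_water_shell(cfg: GeneratorConfig, solute: Conformation | None,
                    rng: np.random.Generator | None = None,
                    exclusion: float = 2.6) -> np.ndarray:
    """Uniform-density water oxygens in a cubic box, excluded from the
    solute.

    The box is a cube of half-width ``box_radius`` centered on the solute
    CM (the origin if no solute).  Positions within ``exclusion`` Angstrom
    of any solute heavy atom are rejected, so the realized count follows
    the Poisson expectation over the accessible volume.
    """
    if cfg.water_density < 0:
        raise ValueError("water_density must be non-negative")
    if cfg.water_density == 0:
        return np.empty((0, 3))
    rng = rng or np.random.default_rng(cfg.seed)
    volume = (2.0 * cfg.box_radius) ** 3
    expected = cfg.water_density * volume
    if expected > 2e6:
        raise ValueError(
            f"water_density {cfg.water_density} would require ~{expected:.0f} "
            f"placement attempts; refusing unbounded rejection sampling"
        )
    n = rng.poisson(expected)
    center = center_of_mass(solute) if solute is not None else np.zeros(3)
    pts = center + rng.uniform(-cfg.box_radius, cfg.box_radius, size=(n, 3))
    if solute is not None and solute.n_atoms:
        heavy = solute.coords[solute.heavy_mask()]
        d = cdist(pts, heavy).min(axis=1)
        pts = pts[d >= exclusion]
    return pts


# ---------------------------------------------------------------------------
# four-bead chains

def gen_cg_conformer(cfg: GeneratorConfig, spec: AlloformSpec,
                     rng: np.random.Generator | None = None) -> Conformation:
    """Four-bead chain: N, C-alpha, C' backbone beads with idealized
    geometry plus one side-chain bead per non-Gly residue."""
    rng = rng or np.random.default_rng(cfg.seed)
    n = spec.n_residues
    ca = _self_avoiding_walk(n, cfg.bond_length, rng)
    records = []
    coords = []
    for i in range(n):
        r = i + 1
        code = spec.residue_code(r)
        prev_dir = (ca[i - 1] - ca[i]) if i > 0 else None
        next_dir = (ca[i + 1] - ca[i]) if i < n - 1 else None
        if prev_dir is None:
            prev_dir = -next_dir
        if next_dir is None:
            next_dir = -prev_dir
        n_pos = ca[i] + 1.46 * prev_dir / np.linalg.norm(prev_dir)
        c_pos = ca[i] + 1.52 * next_dir / np.linalg.norm(next_dir)
        records.append((1, r, code, "N", "N"))
        coords.append(n_pos)
        records.append((1, r, code, "CA", "C"))
        coords.append(ca[i])
        records.append((1, r, code, "C", "C"))
        coords.append(c_pos)
        if code != "G":
            d = _sidechain_direction(ca, i, rng)
            dist = rng.uniform(1.5, 2.5)
            records.append((1, r, code, "CB", "C"))
            coords.append(ca[i] + dist * d)
    return _assemble(records, np.array(coords))
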