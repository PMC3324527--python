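"""Salt-bridge detection, propensities, and propensity-table assembly.

A salt bridge between a positively charged residue (R5, K16, K28) and a
negatively charged residue (D1, E3, D7, E11, E22, D23) is present in a
frame whenever any side-chain nitrogen of the positive residue lies within
the cutoff distance of any side-chain oxygen of the negative residue.
Backbone N/O and the charged termini are excluded: the tables enumerate
side-chain pairs only.

Propensity is the percentage of analysis-window frames in which a bridge is
present, computed per trajectory and then averaged across trajectories
(SEM by the trajectory convention).  For dimers, occurrences on either
peptide pool into one intrapeptide statistic; interpeptide bridges are
counted when the partners sit on different peptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import AlloformSpec, Conformation, Ensemble
from .stats import mean_sem

__all__ = [
    "DEFAULT_SALTBRIDGE_CUTOFF",
    "BridgeKey",
    "detect_salt_bridges",
    "PairPropensity",
    "saltbridge_propensity",
    "SaltBridgeTable",
    "aggregate_table",
    "round_half_up",
]

#: Default side-chain N-O distance cutoff (Angstrom); a standard
#: salt-bridge criterion, configurable.
DEFAULT_SALTBRIDGE_CUTOFF = 4.0

# Side-chain nitrogen names of R/K and side-chain oxygen names of D/E.
SIDECHAIN_N = {
    "R": ("NE", "NH1", "NH2"),
    "K": ("NZ",),
}
SIDECHAIN_O = {
    "D": ("OD1", "OD2"),
    "E": ("OE1", "OE2"),
}

BridgeKey = tuple[int, int, int, int]  # (pos_res, neg_res, pos_pep, neg_pep)


def _sidechain_atoms(conf: Conformation, residue: int, peptide: int,
                     names: tuple[str, ...]) -> np.ndarray:
    mask = (
        (conf.peptide_id == peptide)
        & (conf.residue_index == residue)
        & np.isin(conf.atom_name, names)
    )
    return conf.coords[mask]


def detect_salt_bridges(conf: Conformation,
                        cutoff: float = DEFAULT_SALTBRIDGE_CUTOFF,
                        spec: AlloformSpec | None = None,
                        ) -> set[BridgeKey]:
    """Frame-level salt-bridge detection.

    Returns the set of (positive residue, negative residue, positive
    peptide, negative peptide) tuples whose minimal side-chain N-O distance
    is strictly below the cutoff.  Missing side-chain atoms for a charged
    residue raise an error naming the residue.
    """
    from .core import alloform

    spec = spec or alloform("Ab42" if conf.n_residues(1) == 42 else "Ab40")
    present: set[BridgeKey] = set()
    peptides = [int(p) for p in conf.peptides]
    for pos in sorted(spec.positive_residues):
        pos_code = spec.residue_code(pos)
        n_names = SIDECHAIN_N.get(pos_code)
        if n_names is None:
            raise ValueError(f"residue {pos_code}{pos} is not R/K")
        for pp in peptides:
            n_xyz = _sidechain_atoms(conf, pos, pp, n_names)
            if len(n_xyz) == 0:
                raise ValueError(
                    f"missing side-chain N atoms for {pos_code}{pos} "
                    f"(peptide {pp})"
                )
            for neg in sorted(spec.negative_residues):
                neg_code = spec.residue_code(neg)
                o_names = SIDECHAIN_O.get(neg_code)
                if o_names is None:
                    raise ValueError(f"residue {neg_code}{neg} is not D/E")
                for np_ in peptides:
                    o_xyz = _sidechain_atoms(conf, neg, np_, o_names)
                    if len(o_xyz) == 0:
                        raise ValueError(
                            f"missing side-chain O atoms for {neg_code}{neg} "
                            f"(peptide {np_})"
                        )
                    if cdist(n_xyz, o_xyz).min() < cutoff:
                        present.add((pos, neg, pp, np_))
    return present


@dataclass
class PairPropensity:
    """Propensity (%) of one (positive, negative) residue pair."""

    positive: int
    negative: int
    intra: float
    intra_sem: float
    inter: float | None = None      # None for monomers (not applicable)
    inter_sem: float | None = None

    @property
    def total(self) -> float:
        return self.intra + (self.inter or 0.0)


def saltbridge_propensity(ensemble: Ensemble,
                          cutoff: float = DEFAULT_SALTBRIDGE_CUTOFF,
                          spec: AlloformSpec | None = None,
                          ) -> list[PairPropensity]:
    """Per-pair salt-bridge propensities of an ensemble, split intra/inter.

    For monomer ensembles the interpeptide statistic is structurally absent
    and reported as None (not 0).
    """
    if ensemble.is_empty:
        raise ValueError("empty ensemble")
    first = next(ensemble.frames())
    is_dimer = first.is_dimer
    from .core import alloform

    spec = spec or alloform("Ab42" if first.n_residues(1) == 42 else "Ab40")

    pairs = [
        (p, n)
        for p in sorted(spec.positive_residues)
        for n in sorted(spec.negative_residues)
    ]
    # Per trajectory: fraction of frames each pair is present, intra/inter.
    intra_by_traj: dict[tuple[int, int], list[float]] = {p: [] for p in pairs}
    inter_by_traj: dict[tuple[int, int], list[float]] = {p: [] for p in pairs}
    for traj in ensemble.trajectories:
        intra_counts = dict.fromkeys(pairs, 0)
        inter_counts = dict.fromkeys(pairs, 0)
        for frame in traj:
            found = detect_salt_bridges(frame, cutoff, spec)
            for pair in pairs:
                keys_intra = any(
                    (pos, neg, pp, np_) in found
                    for (pos, neg) in (pair,)
                    for pp in (1, 2)
                    for np_ in (pp,)
                )
                if keys_intra:
                    intra_counts[pair] += 1
                if is_dimer:
                    keys_inter = any(
                        (pair[0], pair[1], pp, np_) in found
                        for pp, np_ in ((1, 2), (2, 1))
                    )
                    if keys_inter:
                        inter_counts[pair] += 1
        n = len(traj)
        for pair in pairs:
            intra_by_traj[pair].append(100.0 * intra_counts[pair] / n)
            if is_dimer:
                inter_by_traj[pair].append(100.0 * inter_counts[pair] / n)

    out: list[PairPropensity] = []
    for pair in pairs:
        m, s = mean_sem([np.array([v]) for v in intra_by_traj[pair]])
        pp = PairPropensity(pair[0], pair[1], float(m), float(s))
        if is_dimer:
            mi, si = mean_sem([np.array([v]) for v in inter_by_traj[pair]])
            pp.inter, pp.inter_sem = float(mi), float(si)
        out.append(pp)
    return out


def round_half_up(x: float) -> int:
    """Integer reporting convention: round half away from zero upward."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), ROUND_HALF_UP))


@dataclass
class SaltBridgeTable:
    """One column of the propensity tables: six pair rows per positive
    residue plus TOTAL and Average TOTAL aggregates.

    TOTAL(pos) is the sum of that residue's six pair propensities (it may
    exceed 100 because distinct bridges coexist); Average TOTAL is the mean
    of the three TOTAL values.  Aggregates are computed from unrounded pair
    values; ``rounded()`` applies the display convention (round half up).
    """

    condition: str
    pairs: dict[tuple[int, int], float]
    totals: dict[int, float] = field(init=False)
    average_total: float = field(init=False)

    def __post_init__(self) -> None:
        positives = sorted({p for p, _ in self.pairs})
        for p in positives:
            if len([1 for q, _ in self.pairs if q == p]) != 6:
                raise ValueError(
                    f"positive residue {p} must have exactly six negative "
                    f"partners"
                )
        self.totals = {
            p: float(sum(v for (q, _), v in self.pairs.items() if q == p))
            for p in positives
        }
        self.average_total = float(np.mean(list(self.totals.values())))

    def rounded(self) -> dict[str, int]:
        out = {
            f"TOTAL_{pos}": round_half_up(tot)
            for pos, tot in self.totals.items()
        }
        out["Average_TOTAL"] = round_half_up(self.average_total)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"pair": f"{p}-{n}", "propensity": v}
            for (p, n), v in self.pairs.items()
        ]
        for pos, tot in self.totals.items():
            rows.append({"pair": f"TOTAL_{pos}", "propensity": tot})
        rows.append({"pair": "Average_TOTAL", "propensity": self.average_total})
        return pd.DataFrame(rows)


def aggregate_table(per_pair: dict[tuple[int, int], float],
                    condition: str = "") -> SaltBridgeTable:
    """Assemble the TOTAL / Average TOTAL aggregates from per-pair values."""
    return SaltBridgeTable(condition=condition, pairs=dict(per_pair))
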