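"""Reference numeric inputs for the amyloid-beta monomer/dimer study.

Two kinds of published inputs drive the bookkeeping and aggregation
operators:

* the trajectory census — how many 50 ns explicit-solvent trajectories
  were acquired per alloform (Ab40/Ab42), assembly state (monomer/dimer)
  and water model (SPCE/TIP3P); and
* the per-pair salt-bridge propensity tables (percent) for monomers
  (intrapeptide only) and dimers (intrapeptide / interpeptide / total
  blocks), from which the TOTAL and Average TOTAL aggregate rows are
  recomputed.

Pairs are keyed (positive residue, negative residue) with the positive
residues R5/K16/K28 and negative residues D1/E3/D7/E11/E22/D23.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "TRAJECTORY_COUNTS",
    "TRAJECTORY_LENGTH_NS",
    "RECORDING_INTERVAL_PS",
    "ANALYSIS_WINDOW_PS",
    "MONOMER_PAIR_TABLE",
    "DIMER_PAIR_TABLE",
    "frames_in_window",
    "census",
]

TRAJECTORY_LENGTH_NS = 50.0
RECORDING_INTERVAL_PS = 50.0
ANALYSIS_WINDOW_PS = (20_000.0, 50_000.0)   # (20, 50] ns

#: Acquired trajectory counts per (assembly, alloform, water model).
TRAJECTORY_COUNTS: dict[tuple[str, str, str], int] = {
    ("monomer", "Ab40", "SPCE"): 44,
    ("monomer", "Ab40", "TIP3P"): 41,
    ("monomer", "Ab42", "SPCE"): 45,
    ("monomer", "Ab42", "TIP3P"): 39,
    ("dimer", "Ab40", "SPCE"): 49,
    ("dimer", "Ab40", "TIP3P"): 42,
    ("dimer", "Ab42", "SPCE"): 42,
    ("dimer", "Ab42", "TIP3P"): 41,
}

_PAIRS = [(p, n) for p in (5, 16, 28) for n in (1, 3, 7, 11, 22, 23)]


def _table(rows: list[int]) -> dict[tuple[int, int], float]:
    assert len(rows) == 18
    return {pair: float(v) for pair, v in zip(_PAIRS, rows)}


#: Monomer intrapeptide propensities (%), keyed (alloform, water model).
MONOMER_PAIR_TABLE: dict[tuple[str, str], dict[tuple[int, int], float]] = {
    ("Ab40", "SPCE"): _table([8, 17, 19, 11, 8, 2,
                              1, 2, 3, 7, 3, 5,
                              10, 6, 0, 1, 12, 9]),
    ("Ab40", "TIP3P"): _table([27, 24, 11, 18, 12, 4,
                               3, 2, 3, 7, 6, 2,
                               9, 3, 3, 5, 12, 14]),
    ("Ab42", "SPCE"): _table([36, 28, 4, 3, 7, 7,
                              5, 2, 3, 9, 3, 4,
                              0, 3, 4, 5, 10, 8]),
    ("Ab42", "TIP3P"): _table([37, 32, 6, 14, 12, 2,
                               2, 5, 10, 8, 4, 5,
                               6, 9, 2, 6, 15, 14]),
}

#: Dimer propensities (%), keyed (alloform, water model, block) with block
#: in {"intra", "inter", "total"}.
DIMER_PAIR_TABLE: dict[tuple[str, str, str], dict[tuple[int, int], float]] = {
    ("Ab40", "SPCE", "intra"): _table([11, 18, 14, 8, 7, 4,
                                       3, 2, 4, 4, 1, 1,
                                       3, 1, 3, 2, 9, 15]),
    ("Ab40", "TIP3P", "intra"): _table([9, 32, 12, 6, 8, 3,
                                        7, 4, 4, 9, 3, 2,
                                        4, 3, 4, 2, 11, 17]),
    ("Ab42", "SPCE", "intra"): _table([27, 27, 13, 3, 6, 1,
                                       1, 2, 3, 5, 1, 1,
                                       4, 1, 2, 2, 4, 5]),
    ("Ab42", "TIP3P", "intra"): _table([26, 36, 16, 6, 5, 1,
                                        2, 4, 1, 4, 2, 1,
                                        5, 2, 2, 2, 8, 9]),
    ("Ab40", "SPCE", "inter"): _table([2, 3, 1, 1, 3, 4,
                                       7, 6, 1, 1, 1, 3,
                                       5, 3, 2, 0, 0, 2]),
    ("Ab40", "TIP3P", "inter"): _table([1, 0, 0, 5, 5, 2,
                                        2, 2, 0, 0, 2, 1,
                                        3, 5, 0, 1, 5, 3]),
    ("Ab42", "SPCE", "inter"): _table([3, 2, 1, 2, 2, 2,
                                       1, 1, 3, 2, 0, 3,
                                       1, 1, 1, 3, 0, 1]),
    ("Ab42", "TIP3P", "inter"): _table([0, 1, 0, 1, 5, 3,
                                        2, 3, 1, 4, 2, 3,
                                        1, 0, 3, 3, 4, 3]),
    ("Ab40", "SPCE", "total"): _table([13, 21, 15, 9, 10, 8,
                                       10, 8, 5, 5, 2, 4,
                                       7, 4, 6, 2, 9, 17]),
    ("Ab40", "TIP3P", "total"): _table([10, 32, 12, 11, 13, 5,
                                        9, 6, 4, 9, 5, 4,
                                        7, 8, 5, 4, 15, 20]),
    ("Ab42", "SPCE", "total"): _table([30, 28, 14, 6, 8, 3,
                                       1, 4, 6, 7, 1, 5,
                                       5, 2, 4, 5, 4, 6]),
    ("Ab42", "TIP3P", "total"): _table([27, 36, 16, 8, 10, 4,
                                        4, 6, 2, 9, 4, 4,
                                        6, 2, 4, 5, 13, 13]),
}


def frames_in_window(trajectory_length_ps: float,
                     interval_ps: float,
                     window: tuple[float, float]) -> int:
    """Number of recorded frames falling inside a (t0, t1] window.

    Frames are recorded at k * interval for k = 1..M; the same predicate
    the Ensemble windowing applies.
    """
    times = np.arange(interval_ps, trajectory_length_ps + interval_ps / 2,
                      interval_ps)
    t0, t1 = window
    return int(np.count_nonzero((times > t0) & (times <= t1)))


def census(counts: dict[tuple[str, str, str], int] | None = None,
           trajectory_length_ns: float = TRAJECTORY_LENGTH_NS,
           interval_ps: float = RECORDING_INTERVAL_PS,
           window: tuple[float, float] = ANALYSIS_WINDOW_PS) -> dict:
    """Trajectory bookkeeping: totals and per-condition conformation counts."""
    counts = counts or TRAJECTORY_COUNTS
    per_traj = frames_in_window(trajectory_length_ns * 1000.0, interval_ps,
                                window)
    conformations = {k: n * per_traj for k, n in counts.items()}
    total_traj = sum(counts.values())
    return {
        "total_trajectories": total_traj,
        "total_time_us": total_traj * trajectory_length_ns / 1000.0,
        "frames_per_trajectory": per_traj,
        "conformations": conformations,
        "total_conformations": sum(conformations.values()),
    }
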