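"""Ensemble statistics: SEM conventions, RMSD series, convergence checks,
and secondary-structure propensity aggregation.

The single statistical convention of this package: the independent sampling
unit is the trajectory.  Every reported mean is a mean of per-trajectory
means, and every SEM is ``std(trajectory means, ddof=1)/sqrt(n_traj)``.
Frames within a trajectory are autocorrelated and never treated as
independent samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .core import Conformation, Ensemble, PerResidueProfile
from .superpose import kabsch_rmsd

__all__ = [
    "mean_sem",
    "rmsd_series",
    "select_extreme_trajectories",
    "ConvergenceReport",
    "convergence_check",
    "ss_propensity",
    "read_label_stream",
    "SS_CLASSES",
]

SS_CLASSES = ("T", "E", "H", "C")  # turn, beta-strand, helix, coil


def mean_sem(samples_by_trajectory: Sequence[np.ndarray]
             ) -> tuple[np.ndarray, np.ndarray]:
    """Trajectory-level mean and SEM.

    ``samples_by_trajectory`` holds one array of samples per trajectory
    (scalars or per-residue vectors along the last axis).  Trajectory means
    are computed first; the reported mean is their mean and the SEM their
    standard deviation over sqrt(n).  With a single trajectory the SEM is
    returned as NaN (flagged unavailable).
    """
    if len(samples_by_trajectory) == 0:
        raise ValueError("need at least one trajectory")
    traj_means = np.stack(
        [np.mean(np.asarray(s, dtype=float), axis=0) for s in samples_by_trajectory]
    )
    mean = traj_means.mean(axis=0)
    if len(traj_means) < 2:
        sem = np.full_like(np.asarray(mean, dtype=float), np.nan)
    else:
        sem = traj_means.std(axis=0, ddof=1) / np.sqrt(len(traj_means))
    return mean, sem


def rmsd_series(trajectory: Sequence[Conformation],
                reference: Conformation | None = None) -> np.ndarray:
    """Optimal-superposition C-alpha RMSD of each frame against a reference.

    The reference defaults to the first frame.  Returned in Angstrom.
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    ref = reference if reference is not None else trajectory[0]
    ref_ca = ref.ca_coords()
    return np.array([kabsch_rmsd(ref_ca, f.ca_coords()) for f in trajectory])


def select_extreme_trajectories(ensemble: Ensemble, k: int) -> list[int]:
    """Indices of the trajectories with extreme time-averaged RMSD.

    Trajectories are ranked by their mean C-alpha RMSD (each frame against
    its own first frame) over the analysis window; the ceil(k/2) highest and
    floor(k/2) lowest indices are returned (k=1 returns the single highest).
    """
    if k > ensemble.n_trajectories:
        raise ValueError("k exceeds the number of trajectories")
    windowed = ensemble.apply_window()
    means = np.array([
        rmsd_series(traj).mean() if traj else np.nan
        for traj in windowed.trajectories
    ])
    order = np.argsort(means)  # ascending
    n_high = (k + 1) // 2
    n_low = k // 2
    high = order[::-1][:n_high].tolist()
    low = order[:n_low].tolist()
    return sorted(set(high + low))


@dataclass
class ConvergenceReport:
    """Profiles of one statistic at increasing data levels, plus the verdict.

    ``converged`` is True iff the max absolute per-residue difference
    between the last two levels is below the tolerance; with a single level
    it is None (undefined, flagged).
    """

    statistic: str
    mode: str                       # "time_windows" | "trajectory_counts"
    levels: list
    curves: list[PerResidueProfile]
    max_abs_delta: list[float]
    tolerance: float
    converged: bool | None


def convergence_check(ensemble: Ensemble,
                      statistic: Callable[[Ensemble], PerResidueProfile],
                      mode: str,
                      levels: Sequence,
                      tolerance: float = 0.5,
                      statistic_name: str = "statistic") -> ConvergenceReport:
    """Evaluate a per-residue statistic at increasing data levels.

    ``mode="time_windows"`` evaluates over (t0, t1] sub-windows; levels are
    (t_start, t_end) pairs.  ``mode="trajectory_counts"`` evaluates over the
    first n trajectories; levels are trajectory counts.  Converged iff the
    last successive pair of curves differs by less than ``tolerance``
    everywhere.
    """
    curves: list[PerResidueProfile] = []
    for level in levels:
        if mode == "time_windows":
            t0, t1 = level
            sub = Ensemble(ensemble.trajectories, ensemble.recording_interval,
                           (float(t0), float(t1))).apply_window()
        elif mode == "trajectory_counts":
            n = int(level)
            if n > ensemble.n_trajectories:
                raise ValueError(f"level {n} exceeds ensemble extent")
            sub = ensemble.subset(range(n)).apply_window()
        else:
            raise ValueError(f"unknown mode {mode!r}")
        curves.append(statistic(sub))
    deltas = [
        float(np.max(np.abs(b.values - a.values)))
        for a, b in zip(curves, curves[1:])
    ]
    converged: bool | None
    if len(curves) < 2:
        converged = None
    else:
        converged = deltas[-1] < tolerance
    return ConvergenceReport(
        statistic=statistic_name, mode=mode, levels=list(levels),
        curves=curves, max_abs_delta=deltas, tolerance=tolerance,
        converged=converged,
    )


def read_label_stream(path: str) -> np.ndarray:
    """Read a secondary-structure label stream.

    One line per frame, one single-letter class (T/E/H/C) per residue,
    whitespace-delimited or contiguous.  Returns an (n_frames, n_residues)
    array of single characters.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            tokens = line.split()
            labels = list(line.replace(" ", "")) if len(tokens) == 1 else tokens
            rows.append(labels)
    arr = np.array(rows, dtype="<U1")
    bad = set(arr.ravel().tolist()) - set(SS_CLASSES)
    if bad:
        raise ValueError(f"unknown secondary-structure classes: {sorted(bad)}")
    return arr


def ss_propensity(labels_by_trajectory: Sequence[np.ndarray]
                  ) -> tuple[dict[str, PerResidueProfile], dict[str, tuple[float, float]]]:
    """Secondary-structure propensities from external per-frame labels.

    ``labels_by_trajectory`` holds one (n_frames, n_residues) label matrix
    per trajectory.  Returns per-class per-residue profiles (percent, SEM by
    the trajectory convention) and ensemble-average percentages per class.
    Classes are exhaustive and mutually exclusive, so per-residue
    percentages sum to 100 exactly.
    """
    n_res = {m.shape[1] for m in labels_by_trajectory}
    if len(n_res) != 1:
        raise ValueError("label matrices disagree on residue count")
    profiles: dict[str, PerResidueProfile] = {}
    averages: dict[str, tuple[float, float]] = {}
    for cls in SS_CLASSES:
        per_traj = [
            100.0 * (np.asarray(m) == cls)  # (frames, residues) indicator
            for m in labels_by_trajectory
        ]
        mean, sem = mean_sem(per_traj)
        profiles[cls] = PerResidueProfile(
            statistic_name=f"ss_{cls}", values=mean, sem=sem, units="%")
        overall = [p.mean(axis=1) for p in per_traj]  # per-frame residue avg
        m, s = mean_sem(overall)
        averages[cls] = (float(m), float(s))
    return profiles, averages
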