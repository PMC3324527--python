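"""Optimal rigid-body superposition (Kabsch) and RMSD.

Used by the RMSD time series, the pairwise-RMSD clustering, and the
coarse-grained reconstruction report.  The minimal RMSD over all rigid
rotations/translations is obtained from the SVD of the covariance matrix,
with the determinant sign fixed to exclude reflections.
"""

from __future__ import annotations

import numpy as np

__all__ = ["kabsch_rotation", "kabsch_rmsd", "raw_rmsd"]


def raw_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD without superposition (coordinates compared as given)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix that best maps centered ``b`` onto centered ``a``."""
    a = np.asarray(a, dtype=float) - np.mean(a, axis=0)
    b = np.asarray(b, dtype=float) - np.mean(b, axis=0)
    h = b.T @ a
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, 1.0, d])
    return (u @ corr @ vt).T


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimal RMSD of ``b`` onto ``a`` over rigid-body superpositions."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    rot = kabsch_rotation(a, b)
    diff = bc @ rot.T - ac
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
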