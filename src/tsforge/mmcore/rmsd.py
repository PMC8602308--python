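"""Optimal rigid-body superposition (Kabsch) and RMSD."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["superpose_rmsd", "superpose"]


def superpose(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares superpose ``b`` onto ``a`` (proper rotation + translation).

    Returns the transformed copy of ``b`` and the RMSD in Å.
    """
    a = np.asarray(a, dtype=float).reshape(-1, 3)
    b = np.asarray(b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape or len(a) < 1:
        raise ValueError(f"coordinate sets differ in size: {a.shape} vs {b.shape}")
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    if len(a) == 1:
        return a.copy(), 0.0
    rot, _ = Rotation.align_vectors(a - ca, b - cb)
    moved = rot.apply(b - cb) + ca
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    return moved, rmsd


def superpose_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two equally-sized coordinate sets in Å."""
    return superpose(a, b)[1]
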