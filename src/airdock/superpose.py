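"""Optimal rigid superposition (Kabsch) utilities."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["kabsch", "superposed_rmsd", "rmsd"]


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without fitting."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.einsum("ij,ij->i", d, d))))


def kabsch(mobile: np.ndarray, target: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray]:
    """Best-fit rotation R and translation t mapping mobile onto target.

    Minimizes ``|R @ x + t - y|`` in the least-squares sense; returns a
    proper rotation (no reflection).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - ct, mobile - cm)
    R = rot.as_matrix()
    t = ct - R @ cm
    return R, t


def superposed_rmsd(fit_mobile: np.ndarray, fit_target: np.ndarray,
                    over_mobile: np.ndarray | None = None,
                    over_target: np.ndarray | None = None) -> float:
    """RMSD over one atom set after superposing on another.

    Fits ``fit_mobile`` onto ``fit_target`` and evaluates the RMSD over
    ``over_*`` (defaulting to the fit atoms themselves).
    """
    R, t = kabsch(fit_mobile, fit_target)
    if over_mobile is None:
        over_mobile, over_target = fit_mobile, fit_target
    moved = np.asarray(over_mobile, dtype=float) @ R.T + t
    return rmsd(moved, over_target)
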