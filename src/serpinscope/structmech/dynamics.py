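"""Trajectory statistics: RMSD, RMSF, radius of gyration, essential modes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from serpinscope.structmech.system import Trajectory, StructureError

__all__ = [
    "EssentialModes",
    "TrajectoryStats",
    "kabsch_rotation",
    "superpose",
    "rmsd_series",
    "rmsf_per_residue",
    "radius_of_gyration",
    "essential_modes",
]


@dataclass(frozen=True)
class EssentialModes:
    """Eigen-decomposition of the aligned-coordinate covariance."""

    eigenvalues: np.ndarray  # descending, A^2
    eigenvectors: np.ndarray  # columns, one per mode
    variance_fractions: np.ndarray

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())


@dataclass(frozen=True)
class TrajectoryStats:
    rmsd_series: np.ndarray
    rmsf_per_residue: np.ndarray
    rg_series: np.ndarray
    modes: EssentialModes | None = None


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal least-squares rotation matrix mapping centered mobile -> target."""
    h = mobile.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    return vt.T @ flip @ u.T


def superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rigid superposition of ``mobile`` onto ``target`` (both (n, 3))."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot = kabsch_rotation(mobile - mc, target - tc)
    return (mobile - mc) @ rot.T + tc


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
    superposition: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (A) over ``selection`` after optimal superposition.

    With ``superposition=False`` the raw coordinate deviation is measured,
    which is useful against scripted fixtures with known displacements.
    """
    ref = np.asarray(reference, dtype=float)
    sel = (
        np.arange(traj.n_atoms) if selection is None else np.asarray(selection, dtype=int)
    )
    if sel.size == 0:
        raise StructureError("empty selection")
    if superposition and sel.size < 3:
        raise StructureError("superposition needs >= 3 atoms")
    ref_sel = ref[sel]
    if superposition and np.linalg.matrix_rank(ref_sel - ref_sel.mean(axis=0)) < 2:
        raise StructureError("degenerate (collinear) selection")
    out = np.empty(traj.n_frames)
    for f, frame in enumerate(traj.frames):
        mob = frame[sel]
        if superposition:
            mob = superpose(mob, ref_sel)
        out[f] = np.sqrt(np.mean(np.sum((mob - ref_sel) ** 2, axis=1)))
    return out


def _align_to_mean(coords: np.ndarray, n_iter: int = 2) -> np.ndarray:
    """Align every frame to the (iteratively refined) mean structure."""
    aligned = coords.copy()
    mean = aligned[0]
    for _ in range(n_iter):
        aligned = np.stack([superpose(f, mean) for f in aligned])
        mean = aligned.mean(axis=0)
    return np.stack([superpose(f, mean) for f in aligned])


def rmsf_per_residue(
    traj: Trajectory, selection: np.ndarray, align: bool = True
) -> np.ndarray:
    """Per-atom RMSF (A) of the selection about its mean position.

    Frames are aligned to the average structure (two align/re-average
    passes) before the fluctuation is measured; ``align=False`` skips this
    for fixtures with an externally clamped frame.
    """
    if traj.n_frames < 2:
        raise StructureError("RMSF needs >= 2 frames")
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise StructureError("empty selection")
    coords = traj.frames[:, sel, :]
    if align:
        if sel.size < 3:
            raise StructureError("alignment needs >= 3 atoms")
        coords = _align_to_mean(coords)
    mean = coords.mean(axis=0)
    return np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))


def radius_of_gyration(frame: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted RMS distance (A) from the center of mass."""
    xyz = np.asarray(frame, dtype=float)
    if xyz.ndim != 2 or xyz.shape[0] < 1:
        raise StructureError("need >= 1 atom")
    m = np.ones(xyz.shape[0]) if masses is None else np.asarray(masses, dtype=float)
    total = m.sum()
    if total <= 0:
        raise StructureError("zero total mass")
    com = (m[:, None] * xyz).sum(axis=0) / total
    return float(np.sqrt((m * np.sum((xyz - com) ** 2, axis=1)).sum() / total))


def essential_modes(traj: Trajectory, selection: np.ndarray) -> EssentialModes:
    """Diagonalize the covariance of aligned selection coordinates.

    Eigenvalues come out sorted descending; their sum equals the total
    positional variance (trace identity).
    """
    if traj.n_frames < 3:
        raise StructureError("essential modes need >= 3 frames")
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise StructureError("empty selection")
    coords = traj.frames[:, sel, :]
    if sel.size >= 3:
        coords = _align_to_mean(coords)
    flat = coords.reshape(traj.n_frames, -1)
    flat = flat - flat.mean(axis=0)
    cov = flat.T @ flat / traj.n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    fractions = evals / total if total > 0 else np.zeros_like(evals)
    return EssentialModes(
        eigenvalues=evals, eigenvectors=evecs, variance_fractions=fractions
    )
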