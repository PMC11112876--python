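"""Coordinate geometry primitives.

Centers of mass, Kabsch superposition (via quaternion-based optimal alignment
from scipy, which never returns a reflection), RMSD/RMSF series, total-least-
squares line fitting for helix axes, inter-axis angles and pair-distance
series.

Conventions
-----------
* RMSD and RMSF are computed on the caller's selection with uniform weights
  (conventional for Cα-based profiles).
* A fitted axis direction is the first principal component of the centered
  points, oriented from the first toward the last point of the ordered input
  (N-terminal to C-terminal for a helix).  Inter-axis angles therefore live in
  [0, 180]°: an antiparallel helix pair reads ~180°, not 0°.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import SelectionError
from .structure_io import Trajectory


@dataclass(frozen=True)
class AxisFit:
    """Total-least-squares line through a set of ordered points."""

    centroid: np.ndarray  # (3,), Å
    direction: np.ndarray  # unit vector, oriented first -> last input point
    residual_rms: float  # Å, RMS perpendicular distance to the line


@dataclass(frozen=True)
class SuperpositionResult:
    """Proper rigid motion x -> R @ x + t minimizing weighted RMSD."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,), Å
    rmsd: float  # Å

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class DistanceSeries:
    """Per-frame distances with basic summary statistics."""

    values: np.ndarray  # (n_frames,), Å
    times_ps: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0

    @property
    def median(self) -> float:
        return float(np.median(self.values))


def center_of_mass(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted mean position of a non-empty atom set."""
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if coords.size == 0:
        raise SelectionError("center of mass of an empty atom collection")
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> SuperpositionResult:
    """Optimal proper rotation + translation mapping ``mobile`` onto ``reference``.

    The rotation is always proper (det = +1): for a mirror-image point set the
    best achievable RMSD is strictly positive rather than zero.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"point count mismatch: mobile {mobile.shape} vs reference {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("superposition needs >= 3 points of dimension 3")
    if weights is None:
        w = np.ones(len(mobile))
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
    com_mob = (mobile * w[:, None]).sum(0) / w.sum()
    com_ref = (reference * w[:, None]).sum(0) / w.sum()
    rot, _ = Rotation.align_vectors(reference - com_ref, mobile - com_mob, weights=w)
    R = rot.as_matrix()
    t = com_ref - R @ com_mob
    # recompute the residual from the superposed coordinates: the eigenvalue
    # route loses precision near zero, and exact-copy inputs must read as ~0
    diff = (mobile @ R.T + t) - reference
    rmsd = float(np.sqrt((w * (diff**2).sum(axis=1)).sum() / w.sum()))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def rmsd_series(
    traj: Trajectory,
    selection: Sequence[int],
    reference_frame_index: int = 0,
) -> np.ndarray:
    """Per-frame RMSD after superposing each frame onto a reference frame.

    Both the superposition and the RMSD use the same atom selection; the value
    at the reference frame is 0 by construction.
    """
    idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise SelectionError("rmsd_series: empty selection")
    if not 0 <= reference_frame_index < traj.n_frames:
        raise IndexError(
            f"reference frame {reference_frame_index} out of range [0, {traj.n_frames})"
        )
    ref = traj.coords[reference_frame_index, idx]
    out = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        out[k] = kabsch_superpose(traj.coords[k, idx], ref).rmsd
    return out


def rmsf_per_residue(traj: Trajectory, selection: Sequence[int]) -> np.ndarray:
    """Per-atom RMS fluctuation about the mean structure.

    Two-pass procedure: frames are first aligned to frame 0 on the selection,
    the mean structure is computed, frames are re-aligned to that mean, and
    RMSF_i = sqrt(mean_k |r_i(k) - <r_i>|^2).  With one Cα per residue in the
    selection this is the per-residue fluctuation profile.
    """
    idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise SelectionError("rmsf_per_residue: empty selection")
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    ref = traj.coords[0, idx]
    aligned = np.empty((traj.n_frames, idx.size, 3))
    for k in range(traj.n_frames):
        sup = kabsch_superpose(traj.coords[k, idx], ref)
        aligned[k] = sup.apply(traj.coords[k, idx])
    mean = aligned.mean(axis=0)
    for k in range(traj.n_frames):
        sup = kabsch_superpose(aligned[k], mean)
        aligned[k] = sup.apply(aligned[k])
    mean = aligned.mean(axis=0)
    disp2 = ((aligned - mean) ** 2).sum(axis=2)
    return np.sqrt(disp2.mean(axis=0))


def fit_axis(points: np.ndarray) -> AxisFit:
    """Best straight line through ordered points (total least squares).

    The direction is the first principal component of the centered points,
    sign-fixed so that it points from the first toward the last input point.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("axis fit needs >= 3 points of dimension 3")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if np.allclose(centered, 0.0):
        raise ValueError("axis fit of coincident points is undefined")
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    span = pts[-1] - pts[0]
    if float(direction @ span) < 0:
        direction = -direction
    n = pts.shape[0]
    residual_rms = float(np.sqrt((s[1] ** 2 + s[2] ** 2) / n))
    return AxisFit(centroid=centroid, direction=direction, residual_rms=residual_rms)


def axis_angle(a: AxisFit, b: AxisFit) -> float:
    """Angle between two oriented axes, degrees in [0, 180]."""
    da = np.asarray(a.direction, dtype=float)
    db = np.asarray(b.direction, dtype=float)
    for d in (da, db):
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("axis directions must be unit vectors")
    # atan2 form is accurate near 0 and 180 deg, where arccos loses digits
    ang = 2.0 * np.arctan2(np.linalg.norm(da - db), np.linalg.norm(da + db))
    return float(np.degrees(ang))


def pair_distance_series(
    traj: Trajectory,
    selection_a: Sequence[int],
    selection_b: Sequence[int],
    mode: str = "com",
) -> DistanceSeries:
    """Per-frame Euclidean distance between two atom selections.

    ``mode='com'`` measures between mass-weighted centers of the selections;
    ``mode='single'`` requires one atom on each side.
    """
    ia = np.asarray(selection_a, dtype=int)
    ib = np.asarray(selection_b, dtype=int)
    if ia.size == 0 or ib.size == 0:
        raise SelectionError("pair_distance_series: empty selection")
    if mode == "single":
        if ia.size != 1 or ib.size != 1:
            raise ValueError("mode='single' requires exactly one atom per side")
        pa = traj.coords[:, ia[0], :]
        pb = traj.coords[:, ib[0], :]
    elif mode == "com":
        ma = traj.topology.mass[ia]
        mb = traj.topology.mass[ib]
        pa = (traj.coords[:, ia, :] * ma[None, :, None]).sum(axis=1) / ma.sum()
        pb = (traj.coords[:, ib, :] * mb[None, :, None]).sum(axis=1) / mb.sum()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    values = np.linalg.norm(pa - pb, axis=1)
    return DistanceSeries(values=values, times_ps=traj.times_ps)
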