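"""Per-volume head-motion measures and per-subject summaries.

Two framewise-displacement (FD) variants are provided:

* ``fd_jenkinson`` — RMS deviation of the relative rigid-body transform
  between consecutive volumes, integrated over a ball of radius ``radius``
  (default 80 mm): ``sqrt(radius**2 / 5 * trace(A.T @ A) + b.T @ b)`` where
  ``M = T_t @ inv(T_{t-1}) - I`` splits into rotation/shear block ``A`` and
  translation ``b``.  Used for spike regression and participant exclusion.
* ``fd_power`` — sum of absolute backward differences of the six parameters,
  rotations converted to arc length on a 50 mm sphere.  Used for scrubbing.

DVARS is the RMS across in-mask voxels of the backward temporal difference,
expressed in percent of the mode-1000 intensity scale (i.e. divided by 10).
By convention the first volume of every series scores 0, which keeps all
per-volume vectors aligned with the series length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import BoldSeries, RealignmentParams

__all__ = [
    "fd_jenkinson",
    "fd_power",
    "dvars",
    "mean_fd",
    "MotionSummary",
    "motion_summary",
]


def _rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotation about the volume centre, composed as Rx @ Ry @ Rz.

    The composition order is fixed by convention; for the small angles seen
    in realignment output all orders agree to first order.
    """
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rx @ Ry @ Rz


def rigid_transform(params6: np.ndarray) -> np.ndarray:
    """4x4 homogeneous rigid transform from (tx, ty, tz, rx, ry, rz)."""
    tx, ty, tz, rx, ry, rz = np.asarray(params6, dtype=float)
    T = np.eye(4)
    T[:3, :3] = _rotation_matrix(rx, ry, rz)
    T[:3, 3] = (tx, ty, tz)
    return T


def fd_jenkinson(params: RealignmentParams, radius: float = 80.0) -> np.ndarray:
    """Framewise displacement, Jenkinson RMS-deviation variant (mm).

    Parameters
    ----------
    params
        Canonical realignment parameters.
    radius
        Radius (mm) of the ball over which the mean squared displacement is
        integrated; 80 mm by convention.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    vals = params.values
    n = vals.shape[0]
    fd = np.zeros(n)
    if n == 1:
        return fd
    transforms = [rigid_transform(vals[t]) for t in range(n)]
    r2_over_5 = radius**2 / 5.0
    for t in range(1, n):
        M = transforms[t] @ np.linalg.inv(transforms[t - 1]) - np.eye(4)
        A = M[:3, :3]
        b = M[:3, 3]
        fd[t] = np.sqrt(r2_over_5 * np.trace(A.T @ A) + b @ b)
    return fd


def fd_power(params: RealignmentParams, rot_radius: float = 50.0) -> np.ndarray:
    """Framewise displacement, Power variant (mm).

    Sum of absolute backward differences of the six parameters, with the
    three rotation differences converted to displacement on a sphere of
    ``rot_radius`` mm (default 50).
    """
    if rot_radius <= 0:
        raise ValueError("rot_radius must be positive")
    vals = params.values
    fd = np.zeros(vals.shape[0])
    if vals.shape[0] == 1:
        return fd
    d = np.abs(np.diff(vals, axis=0))
    fd[1:] = d[:, :3].sum(axis=1) + rot_radius * d[:, 3:].sum(axis=1)
    return fd


def dvars(series: BoldSeries, mask: np.ndarray | None = None) -> np.ndarray:
    """DVARS in percent of the mode-1000 scale.

    RMS over in-mask voxels of the volume-to-volume intensity difference,
    divided by 10 so that 1.0 means 1% of a mode-1000-normalized signal.
    For roi-mode series ``mask`` may be omitted (all rows used); for
    voxel-mode series a 3D brain mask is selected down to rows.
    """
    data = series.data
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim == 3:
            if series.space != "voxel":
                raise ValueError("3D mask given for a non-voxel series")
            mask = mask.reshape(-1)
        if mask.size != data.shape[0]:
            raise ValueError("mask length does not match series rows")
        if not mask.any():
            raise ValueError("empty mask")
        data = data[mask]
    elif series.space == "voxel":
        raise ValueError("voxel-mode DVARS requires a brain mask")
    if data.shape[0] == 0:
        raise ValueError("empty series")
    out = np.zeros(data.shape[1])
    if data.shape[1] > 1:
        diffs = np.diff(data, axis=1)
        out[1:] = np.sqrt(np.mean(diffs**2, axis=0)) / 10.0
    return out


def mean_fd(fd: np.ndarray) -> float:
    """Arithmetic mean of a per-volume FD series (mFD, mm)."""
    fd = np.asarray(fd, dtype=float)
    if fd.size == 0:
        raise ValueError("empty FD series")
    return float(fd.mean())


@dataclass(frozen=True)
class MotionSummary:
    """Per-subject motion profile: FD series, DVARS and mFD."""

    fd_jenk: np.ndarray
    fd_power: np.ndarray
    dvars: np.ndarray | None
    mfd: float

    @property
    def n_volumes(self) -> int:
        return self.fd_jenk.size


def motion_summary(
    params: RealignmentParams,
    series: BoldSeries | None = None,
    mask: np.ndarray | None = None,
) -> MotionSummary:
    """Compute FD (both variants), DVARS (if a series is given) and mFD.

    mFD is the mean of the Jenkinson FD over all volumes, the quantity that
    drives the lenient/stringent exclusion criteria and QC-FC.
    """
    fdj = fd_jenkinson(params)
    fdp = fd_power(params)
    dv = None
    if series is not None:
        if series.n_volumes != params.n_volumes:
            raise ValueError("series and parameters disagree on volume count")
        dv = dvars(series, mask)
    return MotionSummary(fd_jenk=fdj, fd_power=fdp, dvars=dv, mfd=mean_fd(fdj))
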