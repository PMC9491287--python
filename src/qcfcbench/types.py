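"""Core in-memory containers shared across the package.

Conventions
-----------
* Time is always the last axis: ``BoldSeries.data`` is (n_series, n_volumes)
  where a "series" is a voxel (voxel mode) or an ROI (roi mode).
* Realignment parameters are canonically ordered (tx, ty, tz, rx, ry, rz):
  translations in mm, rotations in radians, regardless of the dialect of the
  file they came from.
* Per-volume masks and design matrices always span the same volume grid as
  the series they are paired with.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "RealignmentParams",
    "BoldSeries",
    "DesignMatrix",
    "CensorMask",
    "TissueMasks",
    "Subject",
]

#: Canonical realignment-parameter order: translations (mm), rotations (rad).
PARAM_NAMES = ("tx", "ty", "tz", "rx", "ry", "rz")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class RealignmentParams:
    """Per-volume rigid-body motion estimates, one row per volume.

    ``values`` has shape (n_volumes, 6) in canonical order
    (tx, ty, tz, rx, ry, rz) — translations in mm, rotations in radians.
    ``convention`` records the dialect of the source file ("canonical",
    "spm", "fsl") purely as provenance; values are always canonical.
    """

    values: np.ndarray
    convention: str = "canonical"

    def __post_init__(self):
        arr = _as_float_array(self.values, "realignment parameters")
        if arr.ndim != 2 or arr.shape[1] != 6:
            raise ValueError(
                f"realignment parameters must be (n_volumes, 6), got {arr.shape}"
            )
        if arr.shape[0] < 1:
            raise ValueError("realignment parameters need at least one volume")
        object.__setattr__(self, "values", arr)

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    def trim(self, n: int) -> "RealignmentParams":
        """Drop the first ``n`` volumes (paired with BOLD trimming)."""
        if not 0 <= n < self.n_volumes:
            raise ValueError(f"cannot trim {n} of {self.n_volumes} volumes")
        return RealignmentParams(self.values[n:], self.convention)


@dataclass
class BoldSeries:
    """A subject's BOLD data as a (n_series, n_volumes) matrix.

    In voxel mode ``grid_shape`` gives the 3D lattice and rows are voxels in
    C order (``data[i] == volume.reshape(-1)[i]``); masks index the same
    lattice.  In roi mode rows are ROI time series.  ``provenance`` lists the
    processing steps applied, in order.
    """

    data: np.ndarray
    tr: float
    space: str = "roi"  # "roi" | "voxel"
    grid_shape: tuple[int, int, int] | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = _as_float_array(self.data, "BOLD data")
        if self.data.ndim != 2:
            raise ValueError(f"BOLD data must be 2D, got shape {self.data.shape}")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.space not in ("roi", "voxel"):
            raise ValueError(f"space must be 'roi' or 'voxel', got {self.space!r}")
        if self.space == "voxel":
            if self.grid_shape is None:
                raise ValueError("voxel-mode series requires grid_shape")
            self.grid_shape = tuple(int(s) for s in self.grid_shape)
            if int(np.prod(self.grid_shape)) != self.data.shape[0]:
                raise ValueError(
                    f"grid_shape {self.grid_shape} does not match "
                    f"{self.data.shape[0]} rows"
                )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    @property
    def n_series(self) -> int:
        return self.data.shape[0]

    def with_data(self, data: np.ndarray, step: str) -> "BoldSeries":
        """Return a copy holding ``data`` with ``step`` appended to provenance."""
        out = dataclasses.replace(self, data=np.asarray(data, dtype=float))
        out.provenance = [*self.provenance, step]
        return out


@dataclass(frozen=True)
class DesignMatrix:
    """Named nuisance regressors on a common volume grid.

    Column names encode provenance (``hmp.tx``, ``hmp.sq.lag.rx``,
    ``spike.00117``, ``acompcor.wm.3``, ``phys.csf``, ``gsr`` ...).  Columns
    are never all-zero; spike columns carry a single 1.
    """

    columns: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self):
        arr = _as_float_array(self.columns, "design matrix")
        if arr.ndim != 2:
            raise ValueError("design matrix must be 2D (n_volumes, k)")
        names = tuple(self.names)
        if len(names) != arr.shape[1]:
            raise ValueError(
                f"{len(names)} names for {arr.shape[1]} columns"
            )
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate regressor names: {dupes}")
        if arr.shape[1] and np.any(np.all(arr == 0, axis=0)):
            zero = [names[j] for j in np.flatnonzero(np.all(arr == 0, axis=0))]
            raise ValueError(f"all-zero regressor columns: {zero}")
        object.__setattr__(self, "columns", arr)
        object.__setattr__(self, "names", names)

    @property
    def k(self) -> int:
        return self.columns.shape[1]

    @property
    def n_volumes(self) -> int:
        return self.columns.shape[0]

    @classmethod
    def empty(cls, n_volumes: int) -> "DesignMatrix":
        return cls(np.empty((n_volumes, 0)), ())

    def subset_rows(self, keep: np.ndarray) -> "DesignMatrix":
        """Row-subset (e.g. to censored volumes), dropping columns that
        become all-zero (spike columns whose volume was deleted)."""
        cols = self.columns[np.asarray(keep, dtype=bool)]
        if cols.shape[1]:
            nonzero = ~np.all(cols == 0, axis=0)
            cols = cols[:, nonzero]
            names = tuple(n for n, nz in zip(self.names, nonzero) if nz)
        else:
            names = ()
        return DesignMatrix(cols, names)


@dataclass(frozen=True)
class CensorMask:
    """Per-volume keep/remove flags with the rule that removed each volume.

    ``reasons`` maps removed volume index -> tag ("fd_power", "dvars",
    "short_segment").
    """

    keep: np.ndarray
    reasons: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self):
        keep = np.asarray(self.keep, dtype=bool)
        if keep.ndim != 1:
            raise ValueError("censor mask must be 1D")
        reasons = dict(self.reasons)
        removed = set(np.flatnonzero(~keep).tolist())
        if set(reasons) != removed:
            raise ValueError("reasons must tag exactly the removed volumes")
        object.__setattr__(self, "keep", keep)
        object.__setattr__(self, "reasons", reasons)

    @property
    def n_volumes(self) -> int:
        return self.keep.size

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    @property
    def n_removed(self) -> int:
        return self.n_volumes - self.n_kept

    @classmethod
    def keep_all(cls, n_volumes: int) -> "CensorMask":
        return cls(np.ones(n_volumes, dtype=bool), {})


def _as_mask(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.dtype != bool:
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"{name} mask must be binary")
        arr = arr.astype(bool)
    if arr.ndim != 3:
        raise ValueError(f"{name} mask must be 3D")
    return arr


@dataclass
class TissueMasks:
    """Tissue masks / probability maps on the series' voxel grid.

    ``wm``, ``csf``, ``brain`` are binary; ``gm_prob`` is a probability map
    in [0, 1].  ``erosion`` records erosion cycles already applied per tissue.
    """

    gm_prob: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    brain: np.ndarray
    erosion: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.gm_prob = np.asarray(self.gm_prob, dtype=float)
        if self.gm_prob.ndim != 3:
            raise ValueError("gm_prob must be 3D")
        if self.gm_prob.min() < 0 or self.gm_prob.max() > 1:
            raise ValueError("gm_prob must lie in [0, 1]")
        self.wm = _as_mask(self.wm, "wm")
        self.csf = _as_mask(self.csf, "csf")
        self.brain = _as_mask(self.brain, "brain")
        shapes = {self.gm_prob.shape, self.wm.shape, self.csf.shape, self.brain.shape}
        if len(shapes) != 1:
            raise ValueError(f"tissue masks on different grids: {shapes}")
        if np.any(self.wm & self.csf):
            raise ValueError("wm and csf masks overlap")


@dataclass
class Subject:
    """Bundle of one subject's inputs to the benchmark.

    ``bold`` is the ROI x time (or voxel x time) series; ``tissue_series`` is
    the voxel-mode series from which WM/CSF/global nuisance signals are
    extracted when ``bold`` is roi-mode; ``truth`` optionally carries the
    simulator's ground truth.
    """

    subject_id: str
    bold: BoldSeries
    motion: RealignmentParams
    masks: TissueMasks | None = None
    tissue_series: BoldSeries | None = None
    truth: object | None = None
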