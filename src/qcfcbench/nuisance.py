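"""Nuisance-regressor families and their assembly into design matrices.

Implemented families (names in parentheses are the design-matrix column
prefixes):

* 6 head-motion parameters and the Friston 24-parameter expansion
  (``hmp.*``): the parameters, their one-volume lags, and the squares of
  both.
* Spike regressors (``spike.NNNNN``): one indicator column per volume whose
  Jenkinson FD exceeds 0.25 mm.
* Scrubbing masks: volumes with Power FD > 0.2 mm or DVARS > 2% are removed,
  then surviving contiguous runs shorter than 5 volumes are removed too.
* Mean tissue signals (``phys.wm``, ``phys.csf``) from eroded WM/CSF masks
  (5 and 2 one-voxel erosion cycles by convention upstream).
* Anatomical CompCor (``acompcor.<tissue>.<i>``): principal component time
  courses of the variance-normalized in-mask voxel series — either a fixed
  number of components (5) or as many as explain a target fraction of the
  tissue variance (50%).
* Global signal (``gsr``): demeaned mean over the brain mask.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy import ndimage

from .types import BoldSeries, CensorMask, DesignMatrix, PARAM_NAMES, RealignmentParams

__all__ = [
    "hmp6",
    "expand_friston24",
    "spike_regressors",
    "scrub_mask",
    "erode_mask",
    "tissue_mean_signals",
    "compcor",
    "global_signal",
    "assemble_design",
]


def hmp6(params: RealignmentParams) -> DesignMatrix:
    """The six canonical head-motion parameters as regressors (``hmp.*``)."""
    names = tuple(f"hmp.{p}" for p in PARAM_NAMES)
    return DesignMatrix(params.values.copy(), names)


def expand_friston24(params: RealignmentParams, derivatives: bool = False) -> DesignMatrix:
    """Friston 24-parameter motion expansion.

    Columns are, in order: the 6 parameters R, their one-volume lags
    R_{t-1}, R**2 and R_{t-1}**2 (24 columns).  The lagged rows at t=0 are
    zero.  With ``derivatives=True`` the lag blocks are replaced by backward
    differences (an alternative reading of "temporal term"); the default is
    the lag formulation of the original 24-parameter model.

    Raises a degenerate-input error on all-zero motion (the expansion would
    contain all-zero columns).
    """
    R = params.values
    if R.shape[0] < 2:
        raise ValueError("Friston expansion needs at least 2 volumes")
    if derivatives:
        lag = np.zeros_like(R)
        lag[1:] = np.diff(R, axis=0)
        lag_tag = "dt"
    else:
        lag = np.zeros_like(R)
        lag[1:] = R[:-1]
        lag_tag = "lag"
    blocks = [R, lag, R**2, lag**2]
    prefixes = ["hmp", f"hmp.{lag_tag}", "hmp.sq", f"hmp.sq.{lag_tag}"]
    cols = np.hstack(blocks)
    names = tuple(f"{pre}.{p}" for pre in prefixes for p in PARAM_NAMES)
    if np.any(np.all(cols == 0, axis=0)):
        raise ValueError(
            "degenerate motion input: the 24-parameter expansion contains "
            "all-zero columns (is the motion trace constant zero?)"
        )
    return DesignMatrix(cols, names)


def spike_regressors(fd_jenk: np.ndarray, threshold: float = 0.25) -> DesignMatrix:
    """One indicator regressor per motion-contaminated volume.

    A volume is contaminated if its Jenkinson FD strictly exceeds
    ``threshold`` (0.25 mm by default).  Each column holds a 1 at that
    volume and 0 elsewhere; with no contaminated volume the design is empty
    (k = 0).
    """
    fd = np.asarray(fd_jenk, dtype=float)
    if not np.all(np.isfinite(fd)):
        raise ValueError("FD series contains non-finite values")
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    flagged = np.flatnonzero(fd > threshold)
    n = fd.size
    cols = np.zeros((n, flagged.size))
    cols[flagged, np.arange(flagged.size)] = 1.0
    names = tuple(f"spike.{t:05d}" for t in flagged)
    return DesignMatrix(cols, names)


def scrub_mask(
    fd_power: np.ndarray,
    dvars: np.ndarray,
    fd_thr: float = 0.2,
    dvars_thr: float = 2.0,
    min_segment: int = 5,
) -> CensorMask:
    """Volume-censoring mask for scrubbing.

    Removes every volume with Power FD > ``fd_thr`` (mm) or DVARS >
    ``dvars_thr`` (%), then removes each surviving contiguous run shorter
    than ``min_segment`` volumes.  Reasons are tagged per removed volume
    (``fd_power`` takes precedence when both thresholds are violated).
    """
    fd = np.asarray(fd_power, dtype=float)
    dv = np.asarray(dvars, dtype=float)
    if fd.shape != dv.shape:
        raise ValueError(f"length mismatch: FD {fd.shape} vs DVARS {dv.shape}")
    if min_segment < 1:
        raise ValueError("min_segment must be >= 1")
    keep = np.ones(fd.size, dtype=bool)
    reasons: dict[int, str] = {}
    for t in np.flatnonzero((fd > fd_thr) | (dv > dvars_thr)):
        keep[t] = False
        reasons[int(t)] = "fd_power" if fd[t] > fd_thr else "dvars"
    # remove retained runs shorter than min_segment
    t = 0
    n = keep.size
    while t < n:
        if keep[t]:
            end = t
            while end < n and keep[end]:
                end += 1
            if end - t < min_segment:
                for u in range(t, end):
                    keep[u] = False
                    reasons[u] = "short_segment"
            t = end
        else:
            t += 1
    return CensorMask(keep, reasons)


#: 6-neighbour (face-adjacency) structuring element for mask erosion.
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def erode_mask(mask: np.ndarray, cycles: int) -> np.ndarray:
    """Morphologically erode a binary 3D mask ``cycles`` times.

    Uses one-voxel face-adjacency (6-neighbour) erosion per cycle.  If a
    cycle would empty the mask, erosion stops at the last nonempty stage and
    a warning is issued.
    """
    arr = np.asarray(mask)
    if arr.ndim != 3:
        raise ValueError("mask must be 3D")
    if arr.dtype != bool:
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask must be binary")
        arr = arr.astype(bool)
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    out = arr.copy()
    for c in range(cycles):
        nxt = ndimage.binary_erosion(out, structure=_STRUCT6, border_value=0)
        if not nxt.any():
            warnings.warn(
                f"erosion cycle {c + 1} of {cycles} would empty the mask; "
                f"stopping at {int(out.sum())} voxels",
                stacklevel=2,
            )
            break
        out = nxt
    return out


def _mask_rows(series: BoldSeries, mask: np.ndarray, what: str) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 3:
        if series.space != "voxel":
            raise ValueError(f"3D {what} mask given for a non-voxel series")
        mask = mask.reshape(-1)
    if mask.size != series.n_series:
        raise ValueError(f"{what} mask length does not match series rows")
    if not mask.any():
        raise ValueError(f"empty {what} mask")
    return series.data[mask]


def tissue_mean_signals(
    series: BoldSeries, wm_mask: np.ndarray, csf_mask: np.ndarray
) -> DesignMatrix:
    """Mean WM and CSF signals (``phys.wm``, ``phys.csf``), demeaned.

    Masks are expected to be the *eroded* tissue masks; the means are taken
    over in-mask voxels only.
    """
    cols = []
    for name, mask in (("wm", wm_mask), ("csf", csf_mask)):
        try:
            rows = _mask_rows(series, mask, name)
        except ValueError as e:
            raise ValueError(f"tissue {name!r}: {e}") from None
        sig = rows.mean(axis=0)
        cols.append(sig - sig.mean())
    return DesignMatrix(np.column_stack(cols), ("phys.wm", "phys.csf"))


def compcor(
    series: BoldSeries,
    mask: np.ndarray,
    mode: str = "fixed",
    n_components: int = 5,
    variance_target: float = 0.5,
    label: str = "acompcor",
) -> DesignMatrix:
    """Anatomical CompCor component time courses from one tissue mask.

    Each in-mask voxel series is demeaned and variance-normalized, then the
    top right-singular vectors of the voxel x time matrix are returned as
    regressors.  ``mode="fixed"`` returns min(``n_components``, rank)
    components (warning if rank-deficient); ``mode="variance"`` returns the
    smallest number of components whose cumulative squared singular values
    reach ``variance_target``.
    """
    if mode not in ("fixed", "variance"):
        raise ValueError(f"mode must be 'fixed' or 'variance', got {mode!r}")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must be in (0, 1]")
    X = _mask_rows(series, mask, "compcor")
    if X.shape[0] < 2:
        raise ValueError("compcor needs at least 2 in-mask voxels")
    X = X - X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1)
    keep = sd > 1e-12
    if not keep.any():
        raise ValueError("all in-mask voxel series are constant")
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant voxel series before SVD",
            stacklevel=2,
        )
    X = X[keep] / sd[keep, None]
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    var_frac = s**2 / (s**2).sum()
    if mode == "fixed":
        k = min(n_components, rank)
        if k < n_components:
            warnings.warn(
                f"tissue rank {rank} < requested {n_components} components",
                stacklevel=2,
            )
    else:
        k = int(np.searchsorted(np.cumsum(var_frac), variance_target - 1e-12) + 1)
        k = min(k, rank)
    comps = vt[:k]
    # deterministic sign: largest-|value| element of each component positive
    for i in range(k):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    names = tuple(f"{label}.{i}" for i in range(k))
    return DesignMatrix(comps.T.copy(), names)


def global_signal(series: BoldSeries, brain_mask: np.ndarray | None = None) -> DesignMatrix:
    """Demeaned mean signal over the brain (``gsr``).

    In voxel mode the mean is taken over ``brain_mask``; in roi mode over
    all ROI rows (the gray-matter mean) when no mask is given.
    """
    if brain_mask is not None:
        rows = _mask_rows(series, brain_mask, "brain")
    elif series.space == "voxel":
        raise ValueError("voxel-mode global signal requires a brain mask")
    else:
        rows = series.data
    g = rows.mean(axis=0)
    return DesignMatrix((g - g.mean())[:, None], ("gsr",))


def assemble_design(parts: Sequence[DesignMatrix]) -> DesignMatrix:
    """Column-concatenate design blocks, preserving names.

    Rejects blocks on different volume grids and duplicate column names.
    An empty list yields a k=0 design on a zero-volume grid.
    """
    parts = list(parts)
    if not parts:
        return DesignMatrix.empty(0)
    n_rows = {p.n_volumes for p in parts}
    if len(n_rows) != 1:
        raise ValueError(f"design blocks span different volume counts: {sorted(n_rows)}")
    names: list[str] = []
    for p in parts:
        names.extend(p.names)
    cols = np.hstack([p.columns for p in parts])
    return DesignMatrix(cols, tuple(names))
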