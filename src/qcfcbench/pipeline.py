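"""Denoising pipelines: shared preprocessing stages and preset registry.

A pipeline applies, in order: initial-volume trimming, per-series linear
detrending, mode-1000 intensity normalization (voxel mode), optional volume
censoring (scrubbing), nuisance regression against the pipeline's design
matrix, an ideal band-pass filter (0.008-0.08 Hz), and optional spatial
smoothing (voxel mode).  For scrubbed data the band-pass is applied to the
concatenated retained series; no interpolation across the gaps is attempted
and the resulting temporal discontinuity is recorded in provenance.

The preset registry enumerates the 17 benchmark pipelines built from:
6/24 head-motion parameters, mean WM+CSF signals (2phys), anatomical
CompCor (fixed-5 or 50%-variance), global signal regression, spike
regression, scrubbing, and externally supplied ICA-AROMA components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import nuisance
from .motion import dvars as _dvars, fd_jenkinson, fd_power
from .types import (
    BoldSeries,
    CensorMask,
    DesignMatrix,
    RealignmentParams,
    TissueMasks,
)

__all__ = [
    "trim_initial_volumes",
    "linear_detrend",
    "mode1000_normalize",
    "regress_nuisance",
    "apply_censor",
    "bandpass_ideal",
    "gaussian_smooth",
    "PipelineSpec",
    "PipelineResult",
    "run_pipeline",
    "pipeline_registry",
    "STRATEGIES",
]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def trim_initial_volumes(series: BoldSeries, n: int = 4) -> BoldSeries:
    """Drop the first ``n`` volumes (pre-steady-state magnetization).

    Realignment parameters supplied alongside must be trimmed identically by
    the caller (``RealignmentParams.trim``).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n >= series.n_volumes:
        raise ValueError(f"cannot trim {n} of {series.n_volumes} volumes")
    if n == 0:
        return series.with_data(series.data.copy(), "trim:0")
    return series.with_data(series.data[:, n:].copy(), f"trim:{n}")


def linear_detrend(series: BoldSeries) -> BoldSeries:
    """Remove per-series intercept and linear trend by OLS."""
    n = series.n_volumes
    if n < 3:
        raise ValueError("detrending needs at least 3 volumes")
    t = np.arange(n, dtype=float)
    X = np.column_stack([np.ones(n), t])
    beta, *_ = np.linalg.lstsq(X, series.data.T, rcond=None)
    resid = series.data - (X @ beta).T
    return series.with_data(resid, "detrend:linear")


def mode1000_normalize(series: BoldSeries, brain_mask: np.ndarray, bins: int = 100) -> BoldSeries:
    """Scale intensities so the modal in-mask value becomes 1000.

    The mode is the centre of the fullest bin of a fixed ``bins``-bin
    histogram over the in-mask intensity range.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if mask.ndim == 3:
        mask = mask.reshape(-1)
    if mask.size != series.n_series:
        raise ValueError("brain mask length does not match series rows")
    if not mask.any():
        raise ValueError("empty brain mask")
    vals = series.data[mask].ravel()
    if vals.min() <= 0:
        raise ValueError("mode-1000 normalization expects positive in-mask intensities")
    counts, edges = np.histogram(vals, bins=bins)
    j = int(np.argmax(counts))
    mode = 0.5 * (edges[j] + edges[j + 1])
    scale = 1000.0 / mode
    return series.with_data(series.data * scale, f"mode1000:scale={scale:.6g}")


def regress_nuisance(series: BoldSeries, design: DesignMatrix) -> BoldSeries:
    """Residualize every series row against the design (plus an intercept).

    Rank-deficient designs are resolved by the SVD least-norm solution with
    a warning; residuals are orthogonal to every design column either way.
    """
    if design.n_volumes != series.n_volumes:
        raise ValueError(
            f"design spans {design.n_volumes} volumes, series has {series.n_volumes}"
        )
    n = series.n_volumes
    X = np.column_stack([np.ones(n), design.columns]) if design.k else np.ones((n, 1))
    beta, _, rank, _ = np.linalg.lstsq(X, series.data.T, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            f"rank-deficient design ({rank} < {X.shape[1]}): least-norm solution used",
            stacklevel=2,
        )
    resid = series.data - (X @ beta).T
    return series.with_data(resid, f"regress:k={design.k}")


def apply_censor(series: BoldSeries, mask: CensorMask) -> BoldSeries:
    """Delete censored volumes, concatenating the retained ones in order."""
    if mask.n_volumes != series.n_volumes:
        raise ValueError("censor mask length does not match series")
    if mask.n_kept == 0:
        raise ValueError("censoring removed every volume")
    removed = np.flatnonzero(~mask.keep).tolist()
    seconds = mask.n_kept * series.tr
    return series.with_data(
        series.data[:, mask.keep].copy(),
        f"censor:removed={removed};remaining_s={seconds:g}",
    )


def bandpass_ideal(series: BoldSeries, low: float = 0.008, high: float = 0.08) -> BoldSeries:
    """Ideal (rectangular) frequency-domain band-pass filter.

    Fourier coefficients with frequency outside [``low``, ``high``] Hz are
    zeroed (the DC term always is, so the mean is removed) and the series is
    inverse-transformed.  Applying the filter twice equals applying it once.
    """
    nyq = 1.0 / (2.0 * series.tr)
    if not 0 <= low < high:
        raise ValueError("need 0 <= low < high")
    if high > nyq + 1e-12:
        raise ValueError(f"high={high} Hz exceeds Nyquist {nyq:g} Hz")
    n = series.n_volumes
    freqs = np.fft.rfftfreq(n, d=series.tr)
    keep = (freqs >= low) & (freqs <= high)
    keep[0] = False  # remove mean
    spec = np.fft.rfft(series.data, axis=1)
    spec[:, ~keep] = 0.0
    out = np.fft.irfft(spec, n=n, axis=1)
    return series.with_data(out, f"bandpass:{low}-{high}Hz")


FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gaussian_smooth(series: BoldSeries, fwhm: float = 6.0, voxel_size: float = 3.0) -> BoldSeries:
    """Volume-wise separable Gaussian smoothing (voxel mode only).

    ``sigma = fwhm * FWHM_TO_SIGMA / voxel_size`` voxels per axis, with
    reflective boundaries (mass-conserving).
    """
    if series.space != "voxel":
        raise ValueError("spatial smoothing applies to voxel-mode series only")
    if fwhm < 0 or voxel_size <= 0:
        raise ValueError("fwhm must be >= 0 and voxel_size > 0")
    if fwhm == 0:
        return series.with_data(series.data.copy(), "smooth:fwhm=0")
    sigma = fwhm * FWHM_TO_SIGMA / voxel_size
    shape = series.grid_shape
    out = np.empty_like(series.data)
    for t in range(series.n_volumes):
        vol = series.data[:, t].reshape(shape)
        out[:, t] = ndimage.gaussian_filter(vol, sigma=sigma, mode="reflect").reshape(-1)
    return series.with_data(out, f"smooth:fwhm={fwhm}mm")


# ---------------------------------------------------------------------------
# pipeline specification and registry
# ---------------------------------------------------------------------------

STRATEGIES = ("6hmp", "24hmp", "2phys", "acompcor", "acompcor50", "gsr",
              "spike", "scrub", "aroma")

_DEFAULT_OPTIONS = dict(
    spike_fd_thr=0.25,      # mm, Jenkinson FD
    scrub_fd_thr=0.2,       # mm, Power FD
    scrub_dvars_thr=2.0,    # percent
    scrub_min_segment=5,    # volumes
    compcor_n=5,
    compcor_variance=0.5,
    wm_erosion=5,
    csf_erosion=2,
    bandpass=(0.008, 0.08),  # Hz
    smooth_fwhm=6.0,         # mm, voxel mode only
)


@dataclass(frozen=True)
class PipelineSpec:
    """A named denoising pipeline: a set of strategies plus options.

    ``nominal_k`` is the data-independent regressor count (spike columns
    counted at zero); None when the count is data-driven (aCompCor50,
    external AROMA components).
    """

    name: str
    strategies: tuple[str, ...]
    options: dict = field(default_factory=dict)
    nominal_k: int | None = None

    def __post_init__(self):
        strategies = tuple(self.strategies)
        unknown = set(strategies) - set(STRATEGIES)
        if unknown:
            raise ValueError(f"unknown strategies: {sorted(unknown)}")
        if len(set(strategies)) != len(strategies):
            raise ValueError("duplicate strategies")
        if "spike" in strategies and "scrub" in strategies:
            raise ValueError("spike regression and scrubbing are mutually exclusive")
        if "6hmp" in strategies and "24hmp" in strategies:
            raise ValueError("6HMP and 24HMP are mutually exclusive")
        if sum(s in strategies for s in ("2phys", "acompcor", "acompcor50")) > 1:
            raise ValueError("at most one of 2phys / aCompCor / aCompCor50")
        object.__setattr__(self, "strategies", strategies)
        opts = dict(_DEFAULT_OPTIONS)
        opts.update(self.options)
        object.__setattr__(self, "options", opts)

    def needs_tissue_data(self) -> bool:
        return bool({"2phys", "acompcor", "acompcor50"} & set(self.strategies))


def pipeline_registry() -> list[PipelineSpec]:
    """The 17 benchmark pipeline presets.

    Built from the strategy families: 6HMP alone; 24HMP combined with mean
    tissue signals (2phys), aCompCor or aCompCor50, each with and without
    GSR; spike regression added to 6HMP+aCompCor, 24HMP+aCompCor and
    24HMP+2phys (with/without GSR); scrubbing added to 24HMP+2phys
    (with/without GSR); and externally supplied ICA-AROMA components with
    2phys (with/without GSR).
    """
    def spec(*strategies, nominal=None):
        name = "+".join(strategies)
        return PipelineSpec(name=name, strategies=strategies, nominal_k=nominal)

    return [
        spec("6hmp", nominal=6),
        spec("24hmp", "2phys", nominal=26),
        spec("24hmp", "2phys", "gsr", nominal=27),
        spec("24hmp", "acompcor", nominal=34),
        spec("24hmp", "acompcor", "gsr", nominal=35),
        spec("24hmp", "acompcor50"),
        spec("24hmp", "acompcor50", "gsr"),
        spec("6hmp", "acompcor", "spike", nominal=16),
        spec("6hmp", "acompcor", "spike", "gsr", nominal=17),
        spec("24hmp", "acompcor", "spike", nominal=34),
        spec("24hmp", "acompcor", "spike", "gsr", nominal=35),
        spec("24hmp", "2phys", "spike", nominal=26),
        spec("24hmp", "2phys", "spike", "gsr", nominal=27),
        spec("24hmp", "2phys", "scrub", nominal=26),
        spec("24hmp", "2phys", "scrub", "gsr", nominal=27),
        spec("aroma", "2phys"),
        spec("aroma", "2phys", "gsr"),
    ]


@dataclass
class PipelineResult:
    """Output bundle of one pipeline run on one subject."""

    series: BoldSeries
    design: DesignMatrix
    censor: CensorMask
    tdof_used: int  # regressor count + censored volumes


@dataclass
class _SubjectContext:
    """Trimmed, detrended inputs plus cached design building blocks.

    Built once per subject so that the per-preset work is just assembly,
    regression and filtering.
    """

    series: BoldSeries           # trimmed + detrended analysis series
    motion: RealignmentParams    # trimmed
    fd_jenk: np.ndarray
    fd_power: np.ndarray
    dvars: np.ndarray
    parts: dict[str, DesignMatrix]
    scrub: CensorMask


def _erode_tissue_masks(masks: TissueMasks, wm_cycles: int, csf_cycles: int) -> TissueMasks:
    wm = nuisance.erode_mask(masks.wm, wm_cycles)
    csf = nuisance.erode_mask(masks.csf, csf_cycles)
    return replace(masks, wm=wm, csf=csf,
                   erosion={"wm": wm_cycles, "csf": csf_cycles})


def prepare_subject(
    series: BoldSeries,
    motion: RealignmentParams,
    masks: TissueMasks | None = None,
    tissue_series: BoldSeries | None = None,
    aroma_components: DesignMatrix | None = None,
    trim: int = 4,
    options: dict | None = None,
) -> _SubjectContext:
    """Run the shared stages and precompute every design building block.

    ``tissue_series`` is the voxel-mode series from which WM/CSF/brain
    signals are extracted; when the analysis series itself is voxel-mode it
    defaults to that series.  ROI-mode series skip mode-1000 normalization
    (recorded in provenance) and use the ROI mean for the global signal.
    """
    opts = dict(_DEFAULT_OPTIONS)
    if options:
        opts.update(options)

    if motion.n_volumes != series.n_volumes:
        raise ValueError("motion parameters and series disagree on volume count")
    s = trim_initial_volumes(series, trim)
    m = motion.trim(trim) if trim else motion

    if tissue_series is None and series.space == "voxel":
        tissue_series = series
    ts = None
    if tissue_series is not None:
        if tissue_series.n_volumes != series.n_volumes:
            raise ValueError("tissue series and analysis series disagree on volume count")
        ts = trim_initial_volumes(tissue_series, trim)

    if s.space == "voxel":
        if masks is None:
            raise ValueError("voxel-mode pipeline requires tissue masks")
        s = mode1000_normalize(s, masks.brain)
        if ts is not None and ts is not s:
            ts = mode1000_normalize(ts, masks.brain)
    else:
        s.provenance.append("mode1000:skipped (roi mode)")

    fdj = fd_jenkinson(m)
    fdp = fd_power(m)
    dv = _dvars(s, masks.brain if s.space == "voxel" else None)

    s = linear_detrend(s)
    ts_d = linear_detrend(ts) if ts is not None else None

    parts: dict[str, DesignMatrix] = {}
    parts["6hmp"] = nuisance.hmp6(m)
    parts["24hmp"] = nuisance.expand_friston24(m)
    parts["spike"] = nuisance.spike_regressors(fdj, opts["spike_fd_thr"])
    if masks is not None and ts_d is not None:
        eroded = _erode_tissue_masks(masks, opts["wm_erosion"], opts["csf_erosion"])
        parts["2phys"] = nuisance.tissue_mean_signals(ts_d, eroded.wm, eroded.csf)
        for mode, key in (("fixed", "acompcor"), ("variance", "acompcor50")):
            try:
                blocks = [
                    nuisance.compcor(
                        ts_d, tissue_mask, mode=mode,
                        n_components=opts["compcor_n"],
                        variance_target=opts["compcor_variance"],
                        label=f"{key}.{tname}",
                    )
                    for tname, tissue_mask in (("wm", eroded.wm), ("csf", eroded.csf))
                ]
            except ValueError as e:
                # eroded mask too small for a component decomposition:
                # presets needing this family become unavailable
                warnings.warn(f"{key} unavailable: {e}", stacklevel=2)
                continue
            parts[key] = nuisance.assemble_design(blocks)
    if s.space == "voxel":
        parts["gsr"] = nuisance.global_signal(s, masks.brain)
    else:
        parts["gsr"] = nuisance.global_signal(s)
    if aroma_components is not None:
        parts["aroma"] = aroma_components

    scrub = nuisance.scrub_mask(
        fdp, dv,
        fd_thr=opts["scrub_fd_thr"],
        dvars_thr=opts["scrub_dvars_thr"],
        min_segment=opts["scrub_min_segment"],
    )
    return _SubjectContext(series=s, motion=m, fd_jenk=fdj, fd_power=fdp,
                           dvars=dv, parts=parts, scrub=scrub)


def apply_pipeline(ctx: _SubjectContext, spec: PipelineSpec,
                   smooth: bool = False) -> PipelineResult:
    """Assemble the design for ``spec``, censor/regress/filter, and account
    for the temporal degrees of freedom used."""
    missing = [s for s in spec.strategies if s not in ctx.parts and s not in ("scrub",)]
    if missing:
        raise ValueError(
            f"pipeline {spec.name!r} needs unavailable regressors: {missing} "
            "(tissue data or external components not supplied)"
        )
    blocks = [ctx.parts[s] for s in spec.strategies if s != "scrub"]
    blocks = [b for b in blocks if b.k > 0]
    n = ctx.series.n_volumes
    design = nuisance.assemble_design(blocks) if blocks else DesignMatrix.empty(n)

    censor = ctx.scrub if "scrub" in spec.strategies else CensorMask.keep_all(n)
    s = ctx.series
    if censor.n_removed:
        s = apply_censor(s, censor)
        design = design.subset_rows(censor.keep)

    s = regress_nuisance(s, design)
    low, high = spec.options["bandpass"]
    s = bandpass_ideal(s, low, high)
    if smooth and s.space == "voxel":
        s = gaussian_smooth(s, fwhm=spec.options["smooth_fwhm"])
    tdof = design.k + censor.n_removed
    return PipelineResult(series=s, design=design, censor=censor, tdof_used=tdof)


def run_pipeline(
    series: BoldSeries,
    spec: PipelineSpec,
    motion: RealignmentParams,
    masks: TissueMasks | None = None,
    tissue_series: BoldSeries | None = None,
    aroma_components: DesignMatrix | None = None,
    trim: int = 4,
    smooth: bool = False,
) -> PipelineResult:
    """Run one full denoising pipeline on one subject.

    Stage order: trim -> (mode-1000, voxel mode) -> detrend -> censor (if
    scrubbing) -> nuisance regression -> band-pass -> optional smoothing.
    Returns the denoised series together with the design matrix, the censor
    mask, and ``tdof_used`` (regressors + removed volumes).
    """
    ctx = prepare_subject(
        series, motion, masks=masks, tissue_series=tissue_series,
        aroma_components=aroma_components, trim=trim, options=spec.options,
    )
    return apply_pipeline(ctx, spec, smooth=smooth)
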