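"""Synthetic multi-subject BOLD cohorts with known ground truth.

The generator emulates the statistical structure that QC-FC benchmarking
assumes in real resting-state data:

* a cohort of subjects with heterogeneous motion severity; per-subject
  motion traces are AR(1) baselines (translations in mm, rotations in rad)
  plus Poisson-placed transient spikes whose magnitude scales with severity;
* ROI signals = band-limited (0.008-0.08 Hz) Gaussian noise colored by a
  Cholesky factor of a ground-truth correlation matrix, plus additive
  motion artifact, plus WM/CSF physiological couplings and a linear drift,
  on a mode-1000 intensity scale.  The artifact has (i) a motion-locked
  part — six per-parameter saturating |difference| sources, mixed per ROI
  through a spatially smooth signed coupling field whose amplitude decays
  with distance from the head centre, producing the short-distance FC
  inflation motion is known for — and (ii) a small diffuse part of slow
  pseudo-global components with dispersed coupling maps, the residual
  contamination that no regressor set fully removes;
* small 3D voxel lattices per tissue (WM / CSF / GM slabs of one grid)
  built as low-rank expansions of the nuisance signals plus independent
  noise, so mask erosion, CompCor, tissue means and GSR are exercised
  cheaply.

All randomness flows from one integer seed through ``numpy`` SeedSequence
spawning keyed by (label, subject index), so identical specs regenerate
bit-identical cohorts.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .types import BoldSeries, RealignmentParams, Subject, TissueMasks

__all__ = [
    "CohortSpec",
    "SubjectGroundTruth",
    "simulate_motion_trace",
    "simulate_subject",
    "simulate_cohort",
    "default_roi_coords",
    "random_correlation_matrix",
]

# severity -> motion scale mapping (per unit severity)
_AR_PHI = 0.97
_TRANS_SCALE = 0.016   # mm innovation std per unit severity, per axis
_ROT_SCALE = 0.00016   # rad innovation std per unit severity, per axis
_SPIKE_MAG = 0.8       # mm, exponential mean of spike magnitude per unit severity
_NEURAL_SD = 10.0      # BOLD fluctuation std in mode-1000 units (1%)
_F_SHARE = 1.0         # motion-locked share of the injected artifact
_DIFFUSE_SHARE = 0.3   # diffuse (slow pseudo-global) share of the artifact
_N_DIFFUSE = 2         # rank of the diffuse component across ROIs
_DIFFUSE_JITTER = 0.7  # log-normal dispersion of the diffuse coupling maps
_ARTIFACT_SAT = 0.25   # mm-equivalent soft-saturation scale of the artifact
_MIX_SMOOTH_MM = 70.0  # spatial correlation length of the coupling field


_PHYS_COUPLING = 0.1   # ROI-level loading scale of WM/CSF signals
_VOXEL_NOISE_SD = 2.0  # independent voxel noise, mode-1000 units


def _roi_source_weights(spec: "CohortSpec") -> np.ndarray:
    """Cohort-fixed per-ROI coupling weights (unit L2 rows) over the six
    per-parameter artifact sources.

    The weights form a smooth signed random field over the ROI coordinates
    (spatial correlation decaying over ~70 mm): nearby
    regions couple to motion through near-identical mixtures (their
    artifact shares variance, inflating short-distance FC), while distant
    regions couple through near-orthogonal mixtures.  Signed coupling
    reflects that displacement brightens some voxel neighbourhoods
    (inflow/partial volume) and darkens others (dropout).
    """
    rng = _rng(spec.seed, "source-weights")
    H = rng.normal(size=(spec.n_rois, 6))
    if spec.distance_decay > 0:
        diff = spec.roi_coords[:, None, :] - spec.roi_coords[None, :, :]
        d = np.sqrt((diff**2).sum(axis=-1))
        K = np.exp(-d / _MIX_SMOOTH_MM) + 1e-6 * np.eye(spec.n_rois)
        G = np.linalg.cholesky(K) @ H
    else:
        G = H
    return G / np.linalg.norm(G, axis=1, keepdims=True)


def _rng(seed: int, label: str, *index: int) -> np.random.Generator:
    """Counter-based seed splitting: one root seed, keyed streams."""
    key = (zlib.crc32(label.encode()),) + tuple(int(i) for i in index)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))


def default_roi_coords(n_rois: int, seed: int) -> np.ndarray:
    """Deterministic quasi-cortical ROI centroids (mm, stereotaxic-like).

    Points are drawn in a brain-shaped ellipsoid (radii 70 x 85 x 65 mm)
    rejecting the innermost core so centroids sit in a cortical shell.
    """
    rng = _rng(seed, "roi-coords")
    radii = np.array([70.0, 85.0, 65.0])
    pts = []
    while len(pts) < n_rois:
        p = rng.uniform(-1, 1, size=3)
        r = np.linalg.norm(p)
        if 0.35 <= r <= 1.0:
            pts.append(p * radii)
    return np.array(pts)


def random_correlation_matrix(n: int, rng: np.random.Generator, n_factors: int = 4) -> np.ndarray:
    """Random PSD correlation matrix from a low-rank factor model."""
    L = rng.normal(size=(n, n_factors)) * np.sqrt(0.6 / n_factors)
    C = L @ L.T
    d = np.sqrt(np.diag(C) + 0.4)
    C = (C + np.diag(np.full(n, 0.4))) / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return C


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of a synthetic cohort (defaults = study
    conditions: 300-volume sessions at TR 2 s, 60 subjects, 50 ROIs).

    ``spike_rate`` is the expected number of motion spikes per 100 volumes;
    ``artifact_gain`` couples |differentiated motion| into the ROI signals
    (in units of the neural fluctuation amplitude, scaled by severity);
    ``distance_decay`` (mm) sets the spatial structure of that coupling;
    ``n_voxels_per_tissue`` is rounded up to a cube (0 disables voxel
    blocks).
    """

    n_subjects: int = 60
    n_volumes: int = 300
    tr: float = 2.0
    n_rois: int = 50
    roi_coords: np.ndarray | None = None
    n_voxels_per_tissue: int = 512
    motion_severity_range: tuple[float, float] = (0.2, 3.0)
    spike_rate: float = 3.0
    artifact_gain: float = 2.5
    distance_decay: float = 35.0
    drift_amplitude: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.n_volumes < 10:
            raise ValueError("n_volumes must be >= 10")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_rois < 3:
            raise ValueError("n_rois must be >= 3")
        lo, hi = self.motion_severity_range
        if lo < 0 or hi < lo:
            raise ValueError("motion_severity_range must be 0 <= low <= high")
        for name in ("spike_rate", "artifact_gain", "distance_decay", "drift_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_voxels_per_tissue < 0:
            raise ValueError("n_voxels_per_tissue must be >= 0")
        coords = self.roi_coords
        if coords is None:
            coords = default_roi_coords(self.n_rois, self.seed)
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_rois, 3):
            raise ValueError(f"roi_coords must be ({self.n_rois}, 3)")
        object.__setattr__(self, "roi_coords", coords)

    @property
    def tissue_side(self) -> int:
        """Edge length of the cubic per-tissue voxel lattice."""
        if self.n_voxels_per_tissue == 0:
            return 0
        return int(np.ceil(self.n_voxels_per_tissue ** (1 / 3) - 1e-9))


@dataclass
class SubjectGroundTruth:
    """What the generator knows about one subject."""

    true_fc: np.ndarray
    motion_trace: RealignmentParams
    artifact_weights: np.ndarray          # per-ROI coupling, distance-decaying
    diffuse_weights: np.ndarray | None    # dispersed coupling of the diffuse part
    nuisance_signals: dict[str, np.ndarray]  # wm, csf, artifact time courses
    severity: float


def simulate_motion_trace(
    n_volumes: int, severity: float, spike_rate: float, seed: int
) -> RealignmentParams:
    """Simulate a realignment-parameter trace.

    Smooth AR(1) baseline per parameter (translations mm, rotations rad,
    innovation scale proportional to ``severity``) plus Poisson-placed
    transient spikes: an exponential-magnitude step on one random
    translation axis that decays over 2 volumes.  Expected mean FD grows
    monotonically with ``severity``.
    """
    if n_volumes < 2:
        raise ValueError("n_volumes must be >= 2")
    if severity < 0:
        raise ValueError("severity must be nonnegative")
    if spike_rate < 0:
        raise ValueError("spike_rate must be nonnegative")
    rng = _rng(seed, "motion")
    scales = np.array([_TRANS_SCALE] * 3 + [_ROT_SCALE] * 3) * severity
    innov = rng.normal(size=(n_volumes, 6)) * scales
    params = np.zeros((n_volumes, 6))
    for t in range(1, n_volumes):
        params[t] = _AR_PHI * params[t - 1] + innov[t]
    # transient spikes: magnitude m at the spike volume, m/2 the next
    n_spikes = rng.poisson(spike_rate * n_volumes / 100.0)
    if n_spikes and severity > 0:
        times = rng.integers(1, n_volumes, size=n_spikes)
        axes = rng.integers(0, 3, size=n_spikes)
        mags = rng.exponential(_SPIKE_MAG * severity, size=n_spikes)
        signs = rng.choice((-1.0, 1.0), size=n_spikes)
        for t, ax, m, s in zip(times, axes, mags, signs):
            params[t, ax] += s * m
            if t + 1 < n_volumes:
                params[t + 1, ax] += s * m / 2.0
    return RealignmentParams(params)


def _band_limited_noise(
    rng: np.random.Generator, n_rows: int, n_volumes: int, tr: float,
    low: float = 0.008, high: float = 0.08,
) -> np.ndarray:
    """Unit-variance rows of ideal-band-limited Gaussian noise."""
    white = rng.normal(size=(n_rows, n_volumes))
    freqs = np.fft.rfftfreq(n_volumes, d=tr)
    keep = (freqs >= low) & (freqs <= high)
    keep[0] = False
    spec = np.fft.rfft(white, axis=1)
    spec[:, ~keep] = 0.0
    out = np.fft.irfft(spec, n=n_volumes, axis=1)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _ar1_signal(rng: np.random.Generator, n: int, phi: float = 0.9) -> np.ndarray:
    x = np.zeros(n)
    innov = rng.normal(size=n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + innov[t]
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _artifact_sources(motion: RealignmentParams) -> np.ndarray:
    """Per-parameter motion-artifact source series (6 x n_volumes).

    Each source is a standardized, saturating transform of one parameter's
    absolute backward difference (rotations scaled to mm on a 50 mm
    sphere).  The soft saturation (tanh at ~0.25 mm) reflects that BOLD
    disruption cannot grow without bound with displacement: large spikes
    saturate, so sub-threshold motion contributes a non-negligible share of
    artifact variance that volume censoring cannot remove.  The six sources
    are distinct signals (different parameters move at different times),
    making the injected artifact high-rank across regions.
    """
    vals = motion.values
    n = vals.shape[0]
    d = np.zeros((n, 6))
    d[1:] = np.abs(np.diff(vals, axis=0))
    d[:, 3:] *= 50.0
    S = _ARTIFACT_SAT * np.tanh(d.T / _ARTIFACT_SAT)
    # short causal haemodynamic-like smoothing: the BOLD response to a
    # displacement is spread over a few volumes, which caps the
    # volume-to-volume intensity jump (DVARS) the artifact produces
    kernel = np.array([0.55, 0.30, 0.15])
    padded = np.pad(S, ((0, 0), (len(kernel) - 1, 0)), mode="edge")
    S = np.stack([np.convolve(row, kernel, mode="valid") for row in padded])
    S = S - S.mean(axis=1, keepdims=True)
    sd = S.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return S / sd


def _artifact_series(motion: RealignmentParams) -> np.ndarray:
    """Pooled motion-artifact time course (standardized mean of the six
    per-parameter sources) — what mean tissue signals carry."""
    f = _artifact_sources(motion).mean(axis=0)
    sd = f.std()
    if sd > 0:
        f = (f - f.mean()) / sd
    return f


def _voxel_block(
    rng: np.random.Generator,
    signals: np.ndarray,          # (n_signals, n_volumes) time courses to expand
    n_voxels: int,
    drift_amplitude: float,
) -> np.ndarray:
    """Low-rank expansion of nuisance signals plus independent noise, on the
    mode-1000 scale."""
    n_volumes = signals.shape[1]
    loadings = rng.uniform(0.5, 1.0, size=(n_voxels, signals.shape[0]))
    block = 1000.0 + loadings @ signals
    block += rng.normal(scale=_VOXEL_NOISE_SD, size=(n_voxels, n_volumes))
    t = np.linspace(-0.5, 0.5, n_volumes)
    slopes = rng.uniform(-1, 1, size=n_voxels) * drift_amplitude
    block += slopes[:, None] * t
    return block


def _cohort_true_fc(spec: CohortSpec) -> np.ndarray:
    return random_correlation_matrix(spec.n_rois, _rng(spec.seed, "true-fc"))


def simulate_subject(
    spec: CohortSpec,
    severity: float,
    seed: int,
    subject_id: str = "sub-000",
    true_fc: np.ndarray | None = None,
) -> Subject:
    """Simulate one subject: ROI series, motion trace, tissue voxel blocks.

    ``true_fc`` defaults to the cohort-level ground-truth correlation matrix
    derived from ``spec.seed`` (shared network structure across subjects).
    Returns a :class:`Subject` whose ``truth`` is a
    :class:`SubjectGroundTruth`.
    """
    if true_fc is None:
        true_fc = _cohort_true_fc(spec)
    true_fc = np.asarray(true_fc, dtype=float)
    if true_fc.shape != (spec.n_rois, spec.n_rois):
        raise ValueError("true_fc shape does not match n_rois")
    try:
        L = np.linalg.cholesky(true_fc)
    except np.linalg.LinAlgError:
        raise ValueError("requested covariance is not positive semidefinite") from None

    n, tr = spec.n_volumes, spec.tr
    motion = simulate_motion_trace(n, severity, spec.spike_rate, seed)

    neural = L @ _band_limited_noise(_rng(seed, "neural"), spec.n_rois, n, tr)

    # two artifact components, both amplitude-proportional to severity:
    # a motion-locked one (|differentiated parameters|, removable through
    # motion/tissue regressors and censoring) and a diffuse smooth one
    # (slow respiration-coupled pseudo-global signal, which no per-volume
    # motion regressor spans — the residual contamination real pipelines
    # never fully remove)
    artifact = _artifact_series(motion)
    diffuse = _band_limited_noise(_rng(seed, "artifact-diffuse"), _N_DIFFUSE, n, tr)
    if spec.distance_decay > 0:
        dist = np.linalg.norm(spec.roi_coords, axis=1)
        weights = np.exp(-dist / spec.distance_decay)
    else:
        weights = np.ones(spec.n_rois)
    # the diffuse components couple through cohort-fixed, dispersed regional
    # maps (anatomy-driven heterogeneity); the maps are mutually dissimilar,
    # so the diffuse artifact is genuinely rank-2 across ROIs and cannot be
    # spanned by any single global regressor
    rng_w = _rng(spec.seed, "diffuse-weights")
    jitter = rng_w.normal(scale=_DIFFUSE_JITTER, size=(_N_DIFFUSE, spec.n_rois))
    diffuse_weights = weights[None, :] * np.exp(jitter)

    rng_phys = _rng(seed, "phys")
    wm_sig = _ar1_signal(rng_phys, n)
    csf_sig = _ar1_signal(rng_phys, n)
    phys_load = rng_phys.normal(scale=_PHYS_COUPLING, size=(spec.n_rois, 2))

    rng_drift = _rng(seed, "drift")
    slopes = rng_drift.uniform(-1, 1, size=spec.n_rois) * spec.drift_amplitude
    t_axis = np.linspace(-0.5, 0.5, n)

    # regionally varying directional sensitivity: each ROI couples to the
    # six per-parameter artifact sources with its own weights, so the
    # motion-locked artifact is high-rank across ROIs and no single global
    # or tissue-mean regressor spans it — volume deletion removes it,
    # regression only attenuates it
    sources = _artifact_sources(motion)
    mix = _roi_source_weights(spec)
    motion_locked = weights[:, None] * (mix @ sources)

    amp = spec.artifact_gain * severity
    diffuse_scale = _DIFFUSE_SHARE / np.sqrt(_N_DIFFUSE)
    data = 1000.0 + _NEURAL_SD * (
        neural
        + amp * _F_SHARE * motion_locked
        + amp * diffuse_scale * (diffuse_weights.T @ diffuse)
        + phys_load @ np.vstack([wm_sig, csf_sig])
    )
    data += slopes[:, None] * t_axis[None, :]

    bold = BoldSeries(data=data, tr=tr, space="roi", provenance=["simulated"])

    masks = None
    tissue_series = None
    side = spec.tissue_side
    if side:
        nvox = side**3
        # tissue blocks carry physio signal + the motion artifact (motion
        # moves the whole head), which is what makes 2phys/CompCor useful
        art_amp = _NEURAL_SD * spec.artifact_gain * severity * 0.7
        wm_block = _voxel_block(
            _rng(seed, "wm"),
            np.vstack([_NEURAL_SD * wm_sig, art_amp * artifact]),
            nvox, spec.drift_amplitude,
        )
        csf_block = _voxel_block(
            _rng(seed, "csf"),
            np.vstack([_NEURAL_SD * csf_sig, art_amp * artifact]),
            nvox, spec.drift_amplitude,
        )
        gm_block = _voxel_block(
            _rng(seed, "gm"),
            np.vstack([_NEURAL_SD * neural.mean(axis=0),
                       art_amp * artifact]),
            nvox, spec.drift_amplitude,
        )
        grid = (side, side, 3 * side)
        vox = np.vstack([wm_block, csf_block, gm_block])
        tissue_series = BoldSeries(
            data=vox, tr=tr, space="voxel", grid_shape=grid,
            provenance=["simulated"],
        )
        zeros = np.zeros(grid, dtype=bool)
        wm_mask, csf_mask, gm_mask = zeros.copy(), zeros.copy(), zeros.copy()
        wm_mask[:, :, :side] = True
        csf_mask[:, :, side:2 * side] = True
        gm_mask[:, :, 2 * side:] = True
        masks = TissueMasks(
            gm_prob=gm_mask.astype(float),
            wm=wm_mask, csf=csf_mask,
            brain=wm_mask | csf_mask | gm_mask,
        )

    truth = SubjectGroundTruth(
        true_fc=true_fc,
        motion_trace=motion,
        artifact_weights=weights,
        diffuse_weights=diffuse_weights,
        nuisance_signals={
            "wm": wm_sig,
            "csf": csf_sig,
            "artifact": artifact,
            "artifact_sources": sources,
            "artifact_diffuse": diffuse,
        },
        severity=float(severity),
    )
    return Subject(
        subject_id=subject_id,
        bold=bold,
        motion=motion,
        masks=masks,
        tissue_series=tissue_series,
        truth=truth,
    )


def simulate_cohort(spec: CohortSpec) -> list[Subject]:
    """Simulate the full cohort.

    Subject severities are drawn uniformly over ``motion_severity_range``;
    per-subject seeds derive deterministically from ``spec.seed``, so the
    cohort is a pure function of the spec.
    """
    rng = _rng(spec.seed, "severities")
    lo, hi = spec.motion_severity_range
    severities = rng.uniform(lo, hi, size=spec.n_subjects)
    true_fc = _cohort_true_fc(spec)
    seeds = np.random.SeedSequence(
        int(spec.seed), spawn_key=(zlib.crc32(b"subjects"),)
    ).generate_state(spec.n_subjects) % (2**31)
    cohort = []
    for i in range(spec.n_subjects):
        cohort.append(
            simulate_subject(
                spec, float(severities[i]), int(seeds[i]),
                subject_id=f"sub-{i:03d}", true_fc=true_fc,
            )
        )
    return cohort
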