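# Methods

This note documents the models and numerical choices behind `qcfcbench`:
what each stage computes, what the synthetic cohort generator emulates and
deliberately does not, and where the design was genuinely open.

## Preprocessing and pipeline stage order

A pipeline run executes: initial-volume trimming (default 4 volumes) →
mode-1000 intensity normalization (voxel mode; the mode is the fullest bin
of a fixed 100-bin histogram over in-mask intensities) → DVARS → per-series
linear detrending → volume censoring if scrubbing → nuisance regression →
ideal band-pass 0.008–0.08 Hz → optional 6 mm FWHM Gaussian smoothing
(voxel mode). Two ordering decisions deserve note:

- **Mode-1000 before detrending.** Detrending removes the intercept, after
  which an intensity mode is meaningless; normalization therefore runs on
  the trimmed raw intensities, and DVARS is computed on trimmed,
  mode-1000-scaled data before any regression. ROI-mode inputs skip
  normalization and smoothing (recorded in provenance) — ROI averages are
  already on the simulator's mode-1000 scale, and spatial smoothing is
  undefined for them.
- **Scrubbing deletes before regression and filters the concatenated
  retained series.** No interpolation across censored gaps is attempted;
  the discontinuity caveat lives in the provenance log. Nuisance
  regressors are built on the full trimmed grid and row-subset to the
  retained volumes, which is exactly equivalent to delete-then-regress for
  per-volume regressors.

The band-pass is a rectangular frequency-domain mask (DC always removed),
i.e. an orthogonal projection in the Fourier basis: applying it twice
equals applying it once, which the tests assert to 1e−10.

Regression always includes an intercept (harmless after detrending,
numerically safer). Rank-deficient designs fall back to the SVD least-norm
solution with a warning; residuals are orthogonal to the design either
way. Spike columns whose volume is censored away are dropped when a design
is row-subset, so no all-zero columns reach the solver.

## Motion metrics

- FD (Jenkinson): RMS displacement over an 80 mm ball under the relative
  rigid transform between consecutive volumes,
  √(R²/5·tr(AᵀA) + bᵀb). Rotations compose as Rx·Ry·Rz about the volume
  centre; for realignment-scale angles every composition order agrees to
  first order, and a fixed convention keeps results deterministic. The
  implementation is checked against a Monte-Carlo oracle that samples
  2·10⁵ points in the ball and measures RMS displacement directly (1%
  tolerance).
- FD (Power): Σ|Δtranslation| + 50 mm·Σ|Δrotation|, backward differences.
- DVARS: RMS over in-mask voxels of the backward difference, divided by 10
  to express percent of the mode-1000 scale (so the scrubbing threshold
  "2%" equals 20 intensity units).
- First-volume FD and DVARS are 0 by convention so per-volume vectors stay
  aligned with the series.

The 24-parameter motion expansion uses the lag formulation
[R, R_{t−1}, R², R_{t−1}²]; a backward-difference variant is available via
`derivatives=True` for users who read "temporal term" as a derivative.
CompCor variance-normalizes each voxel series before the SVD, returns
right-singular-vector time courses with a deterministic sign convention
(largest-|value| element positive), and in variance mode returns the
smallest k whose cumulative squared singular values reach the target.

## Exclusion regimes

All inequalities are strict; boundary values are retained. The "< 4 min of
non-contaminated data" criterion is evaluated against both censoring
methods (spike regression's flag count and the scrubbing mask), and a
subject failing either is excluded under every regime — this makes the
three criteria sets nest by construction, and `apply_regime` asserts the
nesting on every cohort. The 20%-of-volumes criterion uses the trimmed
series as its denominator, and minutes are counted on the trimmed series.

## QC metrics

FC is Pearson correlation between ROI time series, clipped to
±(1 − 1e−7), Fisher-z transformed. QC-FC correlates each edge's z values
with mFD across subjects (two-sided t-based p, df = n − 2); mFD is
computed on the full trimmed series, not the censored one, so that the
motion summary is comparable across pipelines. Edge significance is
uncorrected p < .05 by design (an FDR variant would be a one-line change
in the caller). Distance-dependence is Spearman ρ with average-rank ties
against Euclidean centroid distances. tDOF-loss is regressors + censored
volumes per subject, summarised as mean ± SD. The regime comparison is a
Kruskal-Wallis test on retained-subject mFD with Bonferroni-corrected
pairwise follow-ups.

In ROI mode the global signal is the mean across ROI series (the
gray-matter mean); in voxel mode it is the mean over the brain mask.

## Pipeline registry

The registry enumerates 17 presets: 6HMP; 24HMP with 2phys, aCompCor or
aCompCor50, each ± GSR; spike regression added to 6HMP+aCompCor,
24HMP+aCompCor and 24HMP+2phys, each ± GSR; scrubbing added to
24HMP+2phys ± GSR; and externally supplied ICA-based components with
2phys ± GSR. A standalone 24HMP preset is deliberately not included; the
registry is an ordinary list of `PipelineSpec` objects and callers can
pass their own. Presets that need externally produced component
regressors are skipped by the benchmark (and listed in the report's
`attrs["skipped"]`) when none are supplied.

## The synthetic cohort generator

The generator's purpose is to emulate, with known ground truth, the
statistical structure that QC-FC benchmarking assumes of real
resting-state data. Defaults: 60 subjects, 300 volumes at TR 2 s, 50 ROIs
with centroids in a cortical shell (ellipsoid radii 70×85×65 mm), 8×8×8
voxel blocks per tissue, severity uniform on (0.2, 3.0), 3 motion spikes
per 100 volumes, artifact gain 2.5, spatial decay 35 mm, drift 20
intensity units.

**Motion.** Each parameter follows an AR(1) baseline (φ = 0.97,
innovation 0.016 mm / 0.00016 rad per unit severity) plus Poisson-placed
transient spikes on a random translation axis (exponential magnitude,
mean 0.8 mm per unit severity, decaying over two volumes). This makes the
FD distribution heavy-tailed and spike-driven: mFD is dominated by
transients, while per-volume FD_Power rarely exceeds the scrubbing
threshold outside spikes. That is what real motion-prone cohorts look
like, and it is what makes the exclusion regimes behave realistically —
the censoring regime (data loss) excludes few subjects (~8%), the
stringent mFD/FD criteria exclude many (~25%).

**Neural signal.** Band-limited (0.008–0.08 Hz) unit-variance noise
colored by the Cholesky factor of a cohort-level random correlation matrix
(low-rank factor structure), scaled to 1% of the 1000 baseline. Sample FC
converges to this ground-truth matrix as the series lengthens.

**Motion artifact.** Two components, both amplitude-proportional to
subject severity:

1. *Motion-locked:* six per-parameter sources — saturating transforms
   (tanh at 0.25 mm-equivalent) of each parameter's |backward difference|,
   causally smoothed over three volumes (a haemodynamic-like response that
   caps the DVARS jump a spike produces). Each ROI couples to the sources
   through a cohort-fixed signed mixing field that is spatially smooth
   (correlation length ~70 mm) with overall amplitude decaying with
   distance from the head centre (35 mm constant). Nearby regions thus
   share artifact variance while distant regions do not — the
   short-distance FC inflation and negative QC-FC distance-dependence that
   motion artifact shows empirically. The saturation matters: large spikes
   saturate, so sub-threshold motion carries a non-negligible artifact
   share that volume censoring cannot remove.
2. *Diffuse:* two slow pseudo-global band-limited components with
   dispersed (log-normal, σ = 0.7) coupling maps — a stand-in for
   respiration-coupled and other slowly varying artifact that no
   parameter-based regressor spans.

This structure was designed so that the generator reproduces the
qualitative phenomena the benchmarks are meant to detect: un-denoised
cohorts show strong QC-FC and negative distance-dependence; no pipeline
reaches the chance floor (the artifact is high-rank across regions, so
regression — including GSR, which removes at most the globally coherent
part — only attenuates it, while censoring removes only its
supra-threshold part); pipelines that combine motion expansion, tissue
regressors and spike censoring do best; six parameters alone do worst;
and excluding high-motion subjects (stringent regime) lowers residual
QC-FC. An earlier, lower-rank artifact model failed in an instructive
way: every multi-regressor pipeline drove QC-FC to the chance floor, at
which point regime comparisons measured only the small-sample inflation of
median |r| (≈ 0.6745/√(n−1)), not denoising quality.

**Tissue blocks.** WM/CSF/GM occupy three slabs of one small voxel grid.
Each block is a low-rank expansion (uniform positive loadings) of its
nuisance signals — the tissue's physiological series plus the pooled
motion-locked artifact — with independent voxel noise (σ = 2 units) and
drift. Erosion (5 WM / 2 CSF cycles, stopping with a warning at the last
nonempty stage on small grids), tissue means, and CompCor therefore all
have real signal to find. ROI series carry small couplings (σ = 0.1) to
the WM/CSF physiological signals.

**Determinism.** All randomness flows from `CohortSpec.seed` through
`numpy` SeedSequence spawning keyed by (stream label, subject index);
identical specs regenerate bit-identical cohorts, and the full benchmark
rerun is byte-identical.

**What the generator does not emulate.** Slice-timing, susceptibility
distortion, scanner/site effects, anatomy (lesions, atrophy), spin-history
physics beyond the additive saturating model, and any task structure.
Passing benchmarks on this cohort shows that the pipeline machinery and QC
metrics behave as the theory predicts under a controlled artifact model —
not that any particular pipeline is best on a given real dataset.

## Problem sizes used by the test and acceptance runs

Unit and oracle tests run on toy inputs (seconds). The statistical
calibration uses 200 artifact-free cohorts of 40 subjects × 50 ROIs
(ROI-only, no voxel blocks — the null QC-FC rate does not involve tissue
regressors). The behavioural benchmark uses 20 replicates of the default
60-subject cohort over the 15 self-contained presets. The determinism
check uses a 12-subject, 20-ROI, 160-volume cohort end to end. The
acceptance script runs 50 null-calibration cohorts plus one full default
benchmark per invocation.

## Known limitations

- The stringent-vs-censoring comparison is a small-sample statement: with
  ~25% exclusions from a 60-subject cohort, the genuine artifact contrast
  exceeds the opposing median-|r| inflation only on average over
  replicates, and the acceptance test is phrased accordingly (paired mean
  within two standard errors).
- ICA-based component estimation is out of scope; the corresponding
  presets run only when component time courses are supplied externally.
- The file-based cohort format stores tissue voxel blocks as plain-text
  matrices with slab geometry in a JSON sidecar; arbitrary NIfTI masks are
  supported in memory and through the NIfTI reader/writer, but the
  benchmark manifest format is the simulator's layout.
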