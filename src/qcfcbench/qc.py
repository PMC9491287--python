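"""Quality-control benchmarking of denoised functional connectivity.

Three QC metrics score each pipeline x exclusion-regime combination:

* **QC-FC** — per connectome edge, the Pearson correlation across subjects
  between Fisher-z functional connectivity and mean framewise displacement
  (mFD).  Summarized as the proportion of edges with p < .05 and the median
  absolute correlation; residual motion contamination inflates both.
* **QC-FC distance-dependence** — Spearman rank correlation between edge
  QC-FC and the Euclidean distance of the ROI centroid pair; motion artifact
  is spatially structured (stronger between nearby regions), so effective
  denoising drives this toward 0.
* **tDOF-loss** — temporal degrees of freedom consumed per subject
  (regressor count + censored volumes), reported as mean ± SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import pipeline as pl
from .exclusion import REGIMES, classify_subject, uncensored_minutes
from .motion import MotionSummary, mean_fd
from .types import BoldSeries, Subject

__all__ = [
    "FCMatrix",
    "QCFCReport",
    "extract_roi_series",
    "fc_matrix",
    "qcfc_correlations",
    "qcfc_distance_dependence",
    "tdof_loss",
    "edge_distances",
    "benchmark_pipelines",
    "compare_regimes",
]

#: correlations are clipped to ±(1 - CLIP_EPS) before the Fisher transform
CLIP_EPS = 1e-7


@dataclass(frozen=True)
class FCMatrix:
    """Fisher-z functional connectivity for one subject under one pipeline."""

    z: np.ndarray  # ROI x ROI, symmetric, zero diagonal
    subject_id: str = ""
    pipeline: str = ""

    def __post_init__(self):
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(z, z.T):
            raise ValueError("FC matrix must be symmetric")
        if not np.all(np.isfinite(z)):
            raise ValueError("FC matrix contains non-finite values")
        object.__setattr__(self, "z", z)

    @property
    def n_rois(self) -> int:
        return self.z.shape[0]

    def edges(self) -> np.ndarray:
        """Upper-triangle edge vector (diagonal excluded)."""
        iu = np.triu_indices(self.n_rois, k=1)
        return self.z[iu]


@dataclass(frozen=True)
class QCFCReport:
    """QC summary for one pipeline x regime cell."""

    pipeline: str
    regime: str
    n_subjects: int
    edge_r: np.ndarray
    edge_p: np.ndarray
    prop_significant: float
    median_abs_qcfc: float
    distance_dependence: float
    tdof_mean: float
    tdof_sd: float

    @property
    def n_edges(self) -> int:
        return self.edge_r.size


def extract_roi_series(
    series: BoldSeries, parcellation: np.ndarray, gm_prob: np.ndarray | None = None
) -> tuple[np.ndarray, list[int]]:
    """GM-probability-weighted ROI mean time series from a voxel series.

    ``parcellation`` is an integer label image (0 = background) on the
    series grid; ``gm_prob`` weights each voxel's contribution (uniform if
    omitted).  Returns (roi x time matrix, roi labels); ROIs with zero total
    weight are dropped with a warning.
    """
    if series.space != "voxel":
        raise ValueError("ROI extraction applies to voxel-mode series")
    labels = np.asarray(parcellation)
    if labels.shape != series.grid_shape:
        raise ValueError("parcellation grid does not match the series grid")
    lab = labels.reshape(-1)
    if gm_prob is None:
        w = np.ones(lab.size)
    else:
        w = np.asarray(gm_prob, dtype=float).reshape(-1)
        if w.size != lab.size:
            raise ValueError("gm_prob grid does not match the series grid")
    roi_ids = [int(v) for v in np.unique(lab) if v != 0]
    if not roi_ids:
        raise ValueError("parcellation contains no ROI labels")
    out, kept = [], []
    dropped = []
    for roi in roi_ids:
        sel = lab == roi
        wsel = w[sel]
        total = wsel.sum()
        if total <= 0:
            dropped.append(roi)
            continue
        out.append((wsel[:, None] * series.data[sel]).sum(axis=0) / total)
        kept.append(roi)
    if dropped:
        import warnings

        warnings.warn(f"ROIs with zero GM weight dropped: {dropped}", stacklevel=2)
    if not kept:
        raise ValueError("no ROI overlaps nonzero GM weight")
    return np.vstack(out), kept


def fc_matrix(roi_series: np.ndarray, subject_id: str = "", pipeline: str = "") -> FCMatrix:
    """Pairwise Pearson correlation of ROI series, Fisher r-to-z transformed.

    Correlations are clipped to ±(1 - 1e-7) so identical series map to a
    finite z (≈ 8.0) rather than infinity.
    """
    X = np.asarray(roi_series, dtype=float)
    if X.ndim != 2:
        raise ValueError("roi_series must be (n_rois, n_volumes)")
    if X.shape[1] < 3:
        raise ValueError("need at least 3 time points")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise ValueError(f"constant ROI series (no variance): rows {bad}")
    r = np.corrcoef(X)
    r = np.clip(r, -1 + CLIP_EPS, 1 - CLIP_EPS)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = 0.5 * (z + z.T)
    return FCMatrix(z=z, subject_id=subject_id, pipeline=pipeline)


def qcfc_correlations(
    fc: list[FCMatrix], mfd: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge QC-FC: Pearson r (and two-sided t-based p) across subjects
    between Fisher-z FC and mFD.

    Requires at least 3 subjects and nonconstant mFD.
    """
    if len(fc) < 3:
        raise ValueError("QC-FC needs at least 3 subjects")
    mfd = np.asarray(mfd, dtype=float)
    if mfd.size != len(fc):
        raise ValueError("one mFD value per subject required")
    if np.ptp(mfd) == 0:
        raise ValueError("mFD has zero variance across subjects; QC-FC undefined")
    n_rois = {f.n_rois for f in fc}
    if len(n_rois) != 1:
        raise ValueError("FC matrices have differing ROI counts")
    E = np.vstack([f.edges() for f in fc])  # subjects x edges
    n = E.shape[0]
    Ec = E - E.mean(axis=0)
    mc = mfd - mfd.mean()
    denom = np.sqrt((Ec**2).sum(axis=0) * (mc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ec * mc[:, None]).sum(axis=0) / denom
    r = np.where(denom == 0, 0.0, r)  # zero-variance edge -> no association
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df)
    return r, p


def edge_distances(coords: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between ROI centroids, as an upper-
    triangle edge vector aligned with ``FCMatrix.edges``."""
    c = np.asarray(coords, dtype=float)
    if c.ndim != 2 or c.shape[1] != 3:
        raise ValueError("coords must be (n_rois, 3) in mm")
    diff = c[:, None, :] - c[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(c.shape[0], k=1)
    return d[iu]


def qcfc_distance_dependence(qcfc_r: np.ndarray, coords: np.ndarray) -> float:
    """Spearman ρ between edge QC-FC and inter-ROI Euclidean distance."""
    qcfc_r = np.asarray(qcfc_r, dtype=float)
    c = np.asarray(coords, dtype=float)
    if c.shape[0] < 3:
        raise ValueError("need at least 3 ROIs")
    d = edge_distances(c)
    if d.size != qcfc_r.size:
        raise ValueError("edge vector and coordinate count disagree")
    if np.ptp(d) == 0:
        raise ValueError("all inter-ROI distances equal; rank correlation undefined")
    rho = stats.spearmanr(d, qcfc_r).statistic
    return float(rho)


def tdof_loss(accounting: list[tuple[int, int]]) -> tuple[float, float]:
    """Cohort mean ± SD of per-subject tDOF-loss (regressors + removed
    volumes)."""
    if not accounting:
        raise ValueError("empty accounting")
    per_subject = np.array([k + removed for k, removed in accounting], dtype=float)
    return float(per_subject.mean()), float(per_subject.std(ddof=0))


# ---------------------------------------------------------------------------
# cohort-level benchmark
# ---------------------------------------------------------------------------

def _subject_machinery(subject: Subject, trim: int, options: dict | None):
    ctx = pl.prepare_subject(
        subject.bold,
        subject.motion,
        masks=subject.masks,
        tissue_series=subject.tissue_series,
        trim=trim,
        options=options,
    )
    summary = MotionSummary(
        fd_jenk=ctx.fd_jenk, fd_power=ctx.fd_power, dvars=ctx.dvars,
        mfd=mean_fd(ctx.fd_jenk),
    )
    tr = subject.bold.tr
    n = ctx.series.n_volumes
    spike_kept = n - ctx.parts["spike"].k
    spike_minutes = spike_kept * tr / 60.0
    scrub_minutes = uncensored_minutes(ctx.scrub, tr)
    return ctx, summary, spike_minutes, scrub_minutes


def benchmark_pipelines(
    cohort: list[Subject],
    coords: np.ndarray,
    registry: list[pl.PipelineSpec] | None = None,
    regimes: tuple[str, ...] = REGIMES,
    trim: int = 4,
    options: dict | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score every pipeline x regime combination on a cohort.

    For each subject the shared stages and design building blocks are
    computed once; each registry preset is then assembled, regressed and
    filtered, and the ROI connectome is Fisher-z transformed.  Per regime,
    QC-FC statistics are computed over the retained subjects.  Presets whose
    regressors are unavailable (externally supplied ICA-AROMA components)
    are skipped and listed in the frame's ``attrs["skipped"]``.

    Returns a tidy DataFrame with one row per pipeline x regime.
    """
    if registry is None:
        registry = pl.pipeline_registry()
    unknown = set(regimes) - set(REGIMES)
    if unknown:
        raise ValueError(f"unknown regimes: {sorted(unknown)}")
    if len(cohort) < 3:
        raise ValueError("benchmark needs at least 3 subjects")

    contexts, mfds, excluded_by_regime = [], [], {r: set() for r in regimes}
    for subj in cohort:
        ctx, summary, spike_min, scrub_min = _subject_machinery(subj, trim, options)
        contexts.append(ctx)
        mfds.append(summary.mfd)
        for regime in regimes:
            d = classify_subject(subj.subject_id, summary, spike_min, scrub_min, regime)
            if d.excluded:
                excluded_by_regime[regime].add(subj.subject_id)
    mfds = np.asarray(mfds)

    runnable, skipped = [], []
    for spec in registry:
        if all(s in contexts[0].parts or s == "scrub" for s in spec.strategies):
            runnable.append(spec)
        else:
            skipped.append(spec.name)

    # exclusion regimes nest, so subjects excluded under every requested
    # regime never enter any QC-FC computation; skip their pipelines
    # entirely (their censored series may retain fewer volumes than the
    # design has columns)
    excluded_everywhere = set.intersection(
        *(excluded_by_regime[r] for r in regimes)
    ) if regimes else set()

    rows = []
    for spec in runnable:
        fcs, tdofs = [], []
        for subj, ctx in zip(cohort, contexts):
            if subj.subject_id in excluded_everywhere:
                fcs.append(None)
                tdofs.append(None)
                continue
            res = pl.apply_pipeline(ctx, spec)
            fcs.append(fc_matrix(res.series.data, subj.subject_id, spec.name))
            tdofs.append((res.design.k, res.censor.n_removed))
        for regime in regimes:
            keep = np.array(
                [s.subject_id not in excluded_by_regime[regime] for s in cohort]
            )
            sub_fc = [f for f, k in zip(fcs, keep) if k]
            sub_tdof = [t for t, k in zip(tdofs, keep) if k]
            if len(sub_fc) < 3:
                raise ValueError(
                    f"regime {regime!r} retains {len(sub_fc)} subjects; "
                    "QC-FC needs at least 3"
                )
            r, p = qcfc_correlations(sub_fc, mfds[keep])
            rho = qcfc_distance_dependence(r, coords)
            tmean, tsd = tdof_loss(sub_tdof)
            rows.append({
                "pipeline": spec.name,
                "regime": regime,
                "n_subjects": len(sub_fc),
                "prop_sig": float(np.mean(p < alpha)),
                "median_abs_qcfc": float(np.median(np.abs(r))),
                "dist_dep_rho": rho,
                "tdof_mean": tmean,
                "tdof_sd": tsd,
            })
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = skipped
    out.attrs["excluded"] = {r: sorted(v) for r, v in excluded_by_regime.items()}
    out.attrs["mfd"] = mfds
    return out


def compare_regimes(mfd_by_regime: dict[str, np.ndarray]) -> dict:
    """Kruskal-Wallis comparison of retained-subject mFD across regimes,
    with Bonferroni-corrected pairwise follow-ups.

    Returns ``{"H": ..., "p": ..., "pairwise": {(a, b): p_adj, ...}}``.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in mfd_by_regime.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, g in groups.items():
        if g.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 members")
    names = list(groups)
    arrays = [groups[n] for n in names]
    if all(np.array_equal(arrays[0], a) for a in arrays[1:]):
        H, p = 0.0, 1.0  # identical groups: no evidence of any difference
    else:
        H, p = stats.kruskal(*arrays)
    pairs = {}
    n_pairs = len(names) * (len(names) - 1) // 2
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = arrays[i], arrays[j]
            if np.array_equal(a, b):
                praw = 1.0
            else:
                praw = stats.kruskal(a, b).pvalue
            pairs[(names[i], names[j])] = min(1.0, praw * n_pairs)
    return {"H": float(H), "p": float(p), "pairwise": pairs}
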