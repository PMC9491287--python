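"""File I/O: BOLD series, realignment dialects, cohort manifests, reports.

Formats
-------
* BOLD: 4D NIfTI (voxel mode, via nibabel) or headered TSV with one row per
  time point and one column per ROI (roi mode).
* Realignment parameters: 6-column whitespace text in the SPM dialect
  (``rp_*.txt``: translations mm then rotations rad — the canonical order)
  or the FSL dialect (``*.par``: rotations rad then translations mm);
  canonical TSV writer with header.
* Cohorts: a manifest TSV naming per-subject files, plus JSON sidecars for
  ground truth and grid geometry.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import BoldSeries, PARAM_NAMES, RealignmentParams, Subject, TissueMasks

__all__ = [
    "read_bold",
    "write_bold_tsv",
    "read_motion",
    "write_motion_tsv",
    "write_cohort",
    "load_cohort",
    "run_full_benchmark",
]


# ---------------------------------------------------------------------------
# BOLD
# ---------------------------------------------------------------------------

def read_bold(path, tr: float | None = None) -> BoldSeries:
    """Read a BOLD series from 4D NIfTI or an ROI x time TSV.

    For NIfTI the repetition time comes from the header unless ``tr``
    overrides it (a conflict warns; the explicit value wins).  TSVs carry no
    timing, so ``tr`` is required.
    """
    path = Path(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
        if data.ndim != 4:
            raise ValueError(f"{path}: expected a 4D image, got {data.ndim}D")
        header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
        if tr is None:
            if header_tr <= 0:
                raise ValueError(f"{path}: no usable TR in header; pass tr explicitly")
            tr = header_tr
        elif header_tr > 0 and abs(header_tr - tr) > 1e-6:
            import warnings

            warnings.warn(
                f"{path}: header TR {header_tr} differs from supplied {tr}; "
                "using the supplied value",
                stacklevel=2,
            )
        grid = data.shape[:3]
        return BoldSeries(
            data=data.reshape(-1, data.shape[3]), tr=tr, space="voxel",
            grid_shape=grid, provenance=[f"read:{path.name}"],
        )
    if path.suffix in (".tsv", ".txt", ".csv"):
        if tr is None:
            raise ValueError("tr is required for TSV BOLD input")
        sep = "," if path.suffix == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep)
        if df.shape[1] < 1 or df.shape[0] < 2:
            raise ValueError(f"{path}: malformed ROI x time table")
        return BoldSeries(
            data=df.to_numpy(dtype=float).T, tr=tr, space="roi",
            provenance=[f"read:{path.name}"],
        )
    raise ValueError(f"unrecognized BOLD format: {path}")


def write_bold_tsv(series: BoldSeries, path, names: list | None = None) -> Path:
    """Write an roi-mode series as a headered time x ROI TSV."""
    if series.space != "roi":
        raise ValueError("TSV writer handles roi-mode series; use NIfTI for voxels")
    path = Path(path)
    cols = names if names is not None else [f"roi{i:03d}" for i in range(series.n_series)]
    pd.DataFrame(series.data.T, columns=cols).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
    return path


def write_bold_nifti(series: BoldSeries, path, voxel_size: float = 3.0) -> Path:
    """Write a voxel-mode series as 4D NIfTI with an isotropic affine."""
    import nibabel as nib

    if series.space != "voxel":
        raise ValueError("NIfTI writer needs a voxel-mode series")
    path = Path(path)
    vol = series.data.reshape(*series.grid_shape, series.n_volumes)
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    img = nib.Nifti1Image(vol.astype(np.float32), affine)
    img.header.set_zooms((voxel_size,) * 3 + (series.tr,))
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# realignment parameters
# ---------------------------------------------------------------------------

def read_motion(path, dialect: str = "auto") -> RealignmentParams:
    """Read realignment parameters, resolving the column-order dialect.

    SPM ``rp_*.txt`` files hold (tx ty tz rx ry rz); FSL ``*.par`` files
    hold (rx ry rz tx ty tz).  ``dialect="auto"`` resolves by filename
    convention and errors when neither convention matches.
    """
    path = Path(path)
    if dialect == "auto":
        if path.name.startswith("rp_") and path.suffix == ".txt":
            dialect = "spm"
        elif path.suffix == ".par":
            dialect = "fsl"
        elif path.suffix == ".tsv":
            dialect = "canonical"
        else:
            raise ValueError(
                f"{path}: cannot infer motion dialect from filename; "
                "pass dialect='spm' or 'fsl'"
            )
    header = 0 if dialect == "canonical" else None
    arr = pd.read_csv(path, sep=r"\s+", header=header).to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 numeric columns, got shape {arr.shape}")
    if dialect == "fsl":
        arr = arr[:, [3, 4, 5, 0, 1, 2]]
    elif dialect not in ("spm", "canonical"):
        raise ValueError(f"unknown dialect {dialect!r}")
    return RealignmentParams(arr, convention=dialect)


def write_motion_tsv(params: RealignmentParams, path) -> Path:
    """Write canonical 6-column TSV with header (tx ty tz rx ry rz)."""
    path = Path(path)
    pd.DataFrame(params.values, columns=list(PARAM_NAMES)).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
    return path


def write_motion_spm(params: RealignmentParams, path) -> Path:
    """Write SPM-style whitespace text (canonical column order, no header)."""
    path = Path(path)
    np.savetxt(path, params.values, fmt="%.10g")
    return path


# ---------------------------------------------------------------------------
# cohorts on disk
# ---------------------------------------------------------------------------

def write_cohort(cohort: list[Subject], coords: np.ndarray, outdir) -> Path:
    """Write a simulated cohort as plain-text fixtures.

    Per subject: ``{id}_bold.tsv`` (time x ROI), ``{id}_motion.txt`` (SPM
    dialect), ``{id}_tissues.tsv`` (time x voxel, flattened grid) and
    ``{id}_truth.json``.  Cohort level: ``manifest.tsv``, ``coords.tsv``
    and ``cohort.json`` (grid geometry, TR).  Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    grid_shape = None
    for subj in cohort:
        sid = subj.subject_id
        bold_p = write_bold_tsv(subj.bold, outdir / f"{sid}_bold.tsv")
        mot_p = write_motion_spm(subj.motion, outdir / f"{sid}_motion.txt")
        row = {
            "subject_id": sid,
            "bold": bold_p.name,
            "motion": mot_p.name,
            "tissues": "",
            "tr": subj.bold.tr,
        }
        if subj.tissue_series is not None:
            grid_shape = subj.tissue_series.grid_shape
            tis_p = outdir / f"{sid}_tissues.tsv"
            pd.DataFrame(
                subj.tissue_series.data.T,
                columns=[f"v{i:05d}" for i in range(subj.tissue_series.n_series)],
            ).to_csv(tis_p, sep="\t", index=False, float_format="%.10g")
            row["tissues"] = tis_p.name
        if subj.truth is not None:
            truth = {
                "severity": subj.truth.severity,
                "true_fc": subj.truth.true_fc.tolist(),
                "artifact_weights": subj.truth.artifact_weights.tolist(),
                "nuisance_signals": {
                    k: v.tolist() for k, v in subj.truth.nuisance_signals.items()
                },
            }
            (outdir / f"{sid}_truth.json").write_text(json.dumps(truth))
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    pd.DataFrame(coords, columns=["x", "y", "z"]).to_csv(
        outdir / "coords.tsv", sep="\t", index=False, float_format="%.10g"
    )
    meta = {"grid_shape": list(grid_shape) if grid_shape else None}
    (outdir / "cohort.json").write_text(json.dumps(meta))
    return outdir / "manifest.tsv"


def _slab_masks(grid_shape: tuple[int, int, int]) -> TissueMasks:
    """Reconstruct the WM/CSF/GM slab masks of the simulator's grid layout."""
    side = grid_shape[2] // 3
    zeros = np.zeros(grid_shape, dtype=bool)
    wm, csf, gm = zeros.copy(), zeros.copy(), zeros.copy()
    wm[:, :, :side] = True
    csf[:, :, side:2 * side] = True
    gm[:, :, 2 * side:] = True
    return TissueMasks(gm_prob=gm.astype(float), wm=wm, csf=csf, brain=wm | csf | gm)


def load_cohort(manifest_path) -> tuple[list[Subject], np.ndarray]:
    """Load a cohort written by :func:`write_cohort`.

    Returns (subjects, ROI centroid coordinates).
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = pd.read_csv(manifest_path, sep="\t")
    required = {"subject_id", "bold", "motion", "tr"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest missing columns: {sorted(required - set(manifest.columns))}")
    if manifest["subject_id"].duplicated().any():
        raise ValueError("duplicate subject ids in manifest")
    meta = {}
    if (root / "cohort.json").exists():
        meta = json.loads((root / "cohort.json").read_text())
    grid_shape = tuple(meta["grid_shape"]) if meta.get("grid_shape") else None

    subjects = []
    for rec in manifest.to_dict("records"):
        sid = str(rec["subject_id"])
        bold_path = root / rec["bold"]
        motion_path = root / rec["motion"]
        for p in (bold_path, motion_path):
            if not p.exists():
                raise FileNotFoundError(f"subject {sid}: missing input file {p}")
        tr = float(rec["tr"])
        bold = read_bold(bold_path, tr=tr)
        motion = read_motion(motion_path, dialect="spm")
        masks = tissue_series = None
        tis = rec.get("tissues", "")
        if isinstance(tis, str) and tis:
            if grid_shape is None:
                raise ValueError("tissue files present but cohort.json lacks grid_shape")
            df = pd.read_csv(root / tis, sep="\t")
            tissue_series = BoldSeries(
                data=df.to_numpy(dtype=float).T, tr=tr, space="voxel",
                grid_shape=grid_shape, provenance=[f"read:{tis}"],
            )
            masks = _slab_masks(grid_shape)
        subjects.append(Subject(
            subject_id=sid, bold=bold, motion=motion,
            masks=masks, tissue_series=tissue_series,
        ))
    coords = pd.read_csv(root / "coords.tsv", sep="\t").to_numpy(dtype=float)
    return subjects, coords


# ---------------------------------------------------------------------------
# full benchmark orchestration
# ---------------------------------------------------------------------------

def run_full_benchmark(manifest_path, outdir, config: dict | None = None) -> dict:
    """Run the end-to-end benchmark on a cohort manifest.

    Loads the cohort, computes motion metrics and confounds, runs every
    configured pipeline, applies the three exclusion regimes, and writes
    ``qc_report.tsv``, ``retention.tsv`` and ``run_log.json`` to ``outdir``.
    Re-running with the same inputs and config byte-reproduces the reports.
    Returns the paths of the written files.
    """
    from . import __version__, pipeline as pl, qc
    from .exclusion import REGIMES

    config = dict(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    subjects, coords = load_cohort(manifest_path)

    registry = pl.pipeline_registry()
    if "pipelines" in config:
        wanted = set(config["pipelines"])
        missing = wanted - {s.name for s in registry}
        if missing:
            raise ValueError(f"unknown pipelines requested: {sorted(missing)}")
        registry = [s for s in registry if s.name in wanted]

    trim = int(config.get("trim", 4))
    report = qc.benchmark_pipelines(
        subjects, coords, registry=registry, trim=trim,
        options=config.get("options"),
    )

    report_path = outdir / "qc_report.tsv"
    report.to_csv(report_path, sep="\t", index=False, float_format="%.10g")

    retention = pd.DataFrame(
        [
            {"regime": r, "n_excluded": len(v),
             "excluded_subjects": ";".join(v)}
            for r, v in report.attrs["excluded"].items()
        ]
    )
    retention_path = outdir / "retention.tsv"
    retention.to_csv(retention_path, sep="\t", index=False)

    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]
    log = {
        "package_version": __version__,
        "config": config,
        "config_hash": config_hash,
        "manifest": str(manifest_path),
        "n_subjects": len(subjects),
        "pipelines_run": sorted({row for row in report["pipeline"].unique()}),
        "pipelines_skipped": report.attrs["skipped"],
        "regimes": list(REGIMES),
    }
    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True))
    return {"report": report_path, "retention": retention_path, "log": log_path}
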