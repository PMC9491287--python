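"""Participant-exclusion regimes based on the motion profile.

Three regimes of increasing strictness decide which subjects are too
motion-contaminated to analyze:

* **censoring** — exclude when less than 4 minutes of non-contaminated data
  remain after volume censoring (evaluated against both censoring methods:
  a subject failing either spike regression's or scrubbing's retention is
  excluded from every pipeline).
* **lenient** — censoring's criterion, plus gross motion mFD > 0.55 mm.
* **stringent** — censoring's criterion, plus any of: mFD > 0.25 mm; more
  than 20% of volumes with Jenkinson FD > 0.2 mm; any volume with FD > 5 mm.

All inequalities are strict; boundary values are retained.  The criteria
nest, so excluded(censoring) ⊆ excluded(lenient) ⊆ excluded(stringent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motion import MotionSummary
from .types import CensorMask

__all__ = [
    "REGIMES",
    "ExclusionDecision",
    "uncensored_minutes",
    "classify_subject",
    "apply_regime",
]

REGIMES = ("censoring", "lenient", "stringent")

MIN_MINUTES = 4.0
LENIENT_MFD = 0.55      # mm
STRINGENT_MFD = 0.25    # mm
STRINGENT_FD = 0.2      # mm, per-volume
STRINGENT_FD_FRACTION = 0.20
STRINGENT_FD_MAX = 5.0  # mm


@dataclass(frozen=True)
class ExclusionDecision:
    """One subject's verdict under one regime, with the triggered criteria."""

    subject_id: str
    regime: str
    excluded: bool
    reasons: tuple[tuple[str, float, float], ...] = field(default_factory=tuple)
    # each reason: (criterion tag, measured value, threshold violated)

    def __post_init__(self):
        if self.excluded != bool(self.reasons):
            raise ValueError("reasons must be nonempty iff excluded")


def uncensored_minutes(mask: CensorMask, tr: float) -> float:
    """Minutes of data retained by a censoring mask."""
    if tr <= 0:
        raise ValueError("tr must be positive")
    return mask.n_kept * tr / 60.0


def classify_subject(
    subject_id: str,
    summary: MotionSummary,
    spike_minutes: float,
    scrub_minutes: float,
    regime: str,
) -> ExclusionDecision:
    """Apply one regime's criteria to one subject's motion summary.

    ``spike_minutes`` / ``scrub_minutes`` are the minutes of non-contaminated
    data each censoring method would retain; a subject below 4 minutes under
    either is excluded in every regime.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; choose from {REGIMES}")
    reasons: list[tuple[str, float, float]] = []

    retained = min(spike_minutes, scrub_minutes)
    if retained < MIN_MINUTES:
        reasons.append(("min_data", retained, MIN_MINUTES))

    if regime == "lenient":
        if summary.mfd > LENIENT_MFD:
            reasons.append(("mfd", summary.mfd, LENIENT_MFD))
    elif regime == "stringent":
        if summary.mfd > STRINGENT_MFD:
            reasons.append(("mfd", summary.mfd, STRINGENT_MFD))
        frac = float(np.mean(summary.fd_jenk > STRINGENT_FD))
        if frac > STRINGENT_FD_FRACTION:
            reasons.append(("fd_fraction", frac, STRINGENT_FD_FRACTION))
        fd_max = float(summary.fd_jenk.max())
        if fd_max > STRINGENT_FD_MAX:
            reasons.append(("fd_max", fd_max, STRINGENT_FD_MAX))

    return ExclusionDecision(
        subject_id=subject_id,
        regime=regime,
        excluded=bool(reasons),
        reasons=tuple(reasons),
    )


def apply_regime(decisions: list[ExclusionDecision]) -> pd.DataFrame:
    """Cohort retention table from per-subject decisions under all regimes.

    Returns one row per regime with excluded/retained counts and
    percentages, and asserts the nesting property
    excluded(censoring) ⊆ excluded(lenient) ⊆ excluded(stringent).
    """
    by_regime: dict[str, dict[str, bool]] = {r: {} for r in REGIMES}
    for d in decisions:
        by_regime[d.regime][d.subject_id] = d.excluded
    sizes = {len(v) for v in by_regime.values()}
    if len(sizes) != 1:
        raise ValueError("all subjects must be classified under all three regimes")

    excl = {r: {s for s, e in v.items() if e} for r, v in by_regime.items()}
    if not (excl["censoring"] <= excl["lenient"] <= excl["stringent"]):
        raise AssertionError(
            "exclusion nesting violated: censoring ⊆ lenient ⊆ stringent failed"
        )

    n = sizes.pop()
    rows = []
    for r in REGIMES:
        k = len(excl[r])
        rows.append({
            "regime": r,
            "n_subjects": n,
            "n_excluded": k,
            "n_retained": n - k,
            "pct_excluded": 100.0 * k / n if n else 0.0,
        })
    return pd.DataFrame(rows)
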