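"""Subject-level quality metrics and exclusion rules.

Four rules exclude a subject: (1) residual motion artifact — a frame with
framewise displacement (FD) above 0.50 mm *coupled with* denoised-series
DVARS above 1 (the conjunction is the rule; high FD alone is not grounds for
exclusion); (2) median TSNR of the denoised series below 50; (3) fewer than
10 retained BOLD components; (4) a coregistration-failure flag accepted as
input.  FD uses the Power convention (rotations converted to arc length on a
50 mm sphere) and DVARS is standardised by its own run median so a typical
frame sits near 1; both conventions, and whether the FD/DVARS conjunction is
evaluated frame-wise or run-wise, are exposed as configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .signal_quality import TSNR_THRESHOLD, compute_tsnr
from .te_denoise import MIN_BOLD_COMPONENTS

#: Radius (mm) converting rotations to displacements in the FD sum.
FD_ROTATION_RADIUS_MM = 50.0


@dataclass
class Thresholds:
    """Exclusion thresholds; defaults follow the four stated rules."""

    fd_mm: float = 0.50
    dvars: float = 1.0
    tsnr: float = TSNR_THRESHOLD
    min_components: int = MIN_BOLD_COMPONENTS
    conjunction: str = "frame"  # "frame": same frame exceeds both; "run": maxima do

    def __post_init__(self) -> None:
        if self.conjunction not in ("frame", "run"):
            raise ValueError("conjunction must be 'frame' or 'run'")


@dataclass
class QCRecord:
    """Per-subject quality metrics plus the exclusion decision."""

    subject_id: str
    fd_series: np.ndarray        # (T-1,) mm
    dvars_series: np.ndarray     # (T-1,) median-standardised
    median_tsnr: float
    n_bold_components: int
    coreg_fail: bool = False
    excluded: Optional[bool] = None
    reasons: set[str] = field(default_factory=set)

    @property
    def max_fd(self) -> float:
        return float(np.max(self.fd_series))


def framewise_displacement(motion: np.ndarray,
                           radius_mm: float = FD_ROTATION_RADIUS_MM) -> np.ndarray:
    """Power-convention FD: sum of absolute backward differences of the six
    motion parameters, rotations (rad) scaled by ``radius_mm``.

    ``motion`` is (T, 6): three translations in mm then three rotations in
    radians.  Returns (T-1,).
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be (T, 6): 3 translations mm, 3 rotations rad")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    d = np.abs(np.diff(motion, axis=0))
    return d[:, :3].sum(axis=1) + radius_mm * d[:, 3:].sum(axis=1)


def dvars(series: np.ndarray) -> np.ndarray:
    """Median-standardised DVARS of a (R, T) series; returns (T-1,).

    Per frame: root-mean-square over regions of the temporal backward
    difference, divided by the run median, so a typical frame is ~1 and the
    measure is invariant to overall signal scale.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[1] < 2:
        raise ValueError("series must be (R, T) with at least 2 frames")
    rms = np.sqrt(np.mean(np.diff(series, axis=1) ** 2, axis=0))
    med = np.median(rms)
    if med == 0:
        raise ValueError("zero-variance run: DVARS standardisation undefined")
    return rms / med


def qc_record(run, denoised: np.ndarray, n_bold_components: int,
              coreg_fail: bool = False) -> QCRecord:
    """Assemble a QCRecord: FD from the run's motion, DVARS and median TSNR
    from the denoised reconstructed series."""
    tsnr = compute_tsnr(denoised, source="multi_echo")
    return QCRecord(
        subject_id=run.subject_id,
        fd_series=framewise_displacement(run.motion),
        dvars_series=dvars(denoised),
        median_tsnr=float(np.nanmedian(tsnr.tsnr)),
        n_bold_components=int(n_bold_components),
        coreg_fail=coreg_fail)


def apply_exclusions(records: Iterable[QCRecord],
                     thresholds: Thresholds = Thresholds()
                     ) -> tuple[list[QCRecord], list[QCRecord]]:
    """Apply the four exclusion rules; returns (kept, excluded).

    Decisions are order-independent and idempotent; each record's
    ``excluded`` flag and ``reasons`` set are filled in place.
    """
    kept, excluded = [], []
    for rec in records:
        for name in ("fd_series", "dvars_series"):
            v = getattr(rec, name)
            if v is None or np.any(~np.isfinite(np.asarray(v, dtype=float))):
                raise ValueError(f"subject {rec.subject_id}: missing/invalid {name}")
        if rec.median_tsnr is None or not np.isfinite(rec.median_tsnr):
            raise ValueError(f"subject {rec.subject_id}: missing median_tsnr")
        if len(rec.fd_series) != len(rec.dvars_series):
            raise ValueError(
                f"subject {rec.subject_id}: FD and DVARS series lengths differ")
        reasons = set()
        fd_high = np.asarray(rec.fd_series) > thresholds.fd_mm
        dv_high = np.asarray(rec.dvars_series) > thresholds.dvars
        if thresholds.conjunction == "frame":
            motion_bad = bool(np.any(fd_high & dv_high))
        else:
            motion_bad = bool(fd_high.any() and dv_high.any())
        if motion_bad:
            reasons.add("fd_dvars")
        if rec.median_tsnr < thresholds.tsnr:
            reasons.add("low_tsnr")
        if rec.n_bold_components < thresholds.min_components:
            reasons.add("few_components")
        if rec.coreg_fail:
            reasons.add("coreg_fail")
        rec.reasons = reasons
        rec.excluded = bool(reasons)
        (excluded if rec.excluded else kept).append(rec)
    return kept, excluded
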