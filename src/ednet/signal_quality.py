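"""Per-region signal quality and TSNR-optimal combination of multi-echo data.

Multi-echo acquisitions read out the BOLD signal at several echo times (TEs)
per volume.  Signal at echo time ``TE`` decays mono-exponentially,
``S(TE) = S0 * exp(-TE / T2*)``, with region-specific baseline intensity
``S0`` and transverse relaxation constant ``T2*`` (ms).  Regions near air
cavities (orbitofrontal cortex, temporal pole) have short T2* and therefore
poor signal at conventional single-echo TEs; combining echoes with
T2*-informed weights recovers much of that signal.

This module provides the temporal signal-to-noise ratio (TSNR; temporal mean
over temporal standard deviation), the log-linear mono-exponential decay fit,
the TSNR-optimal weighted echo combination, and multi- minus single-echo TSNR
difference maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

logger = logging.getLogger("ednet")

#: Echo times (ms) of the emulated acquisition.
DEFAULT_TES = (13.7, 30.0, 47.0)
#: Repetition time (s) of the emulated acquisition.
DEFAULT_TR = 3.0
#: Bounds (ms) applied to log-linear T2* estimates for robustness at long TE.
T2S_BOUNDS = (5.0, 150.0)
#: TSNR display/QC threshold.
TSNR_THRESHOLD = 50.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MultiEchoRun:
    """One subject's multi-echo run at region (parcel) resolution.

    Attributes
    ----------
    tes : (E,) echo times in ms, strictly increasing.
    tr : repetition time in s.
    data : (E, R, T) signal array; all echoes share region/time dimensions.
    motion : (T, 6) motion parameters: 3 translations (mm), 3 rotations (rad).
    subject_id : identifier.
    ground_truth : optional per-subject generator internals (set by the
        synthetic cohort generator; ``None`` for data read from disk).
    """

    tes: np.ndarray
    tr: float
    data: np.ndarray
    motion: np.ndarray
    subject_id: str = "sub-00"
    ground_truth: Optional[object] = None

    def __post_init__(self) -> None:
        self.tes = np.asarray(self.tes, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        self.motion = np.asarray(self.motion, dtype=float)
        if self.tes.ndim != 1 or self.tes.size < 2:
            raise ValueError("need at least two echo times")
        if np.any(self.tes <= 0) or np.any(np.diff(self.tes) <= 0):
            raise ValueError("echo times must be positive and strictly increasing")
        if self.data.ndim != 3 or self.data.shape[0] != self.tes.size:
            raise ValueError("data must be (E, R, T) matching the echo count")
        if self.motion.shape != (self.data.shape[2], 6):
            raise ValueError("motion must be (T, 6)")

    @property
    def n_echoes(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]


@dataclass
class DecayFit:
    """Per-region mono-exponential decay fit.

    ``failed`` marks regions where the log-linear fit was impossible
    (non-positive echo mean) or produced a non-physical decay; their
    S0/T2* entries are NaN and downstream combination falls back to a
    simple echo average.
    """

    s0: np.ndarray
    t2star: np.ndarray
    fit_residual: np.ndarray
    failed: np.ndarray


@dataclass
class TsnrMap:
    """Per-region TSNR with an explicit undefined mask.

    ``source`` is one of ``multi_echo``, ``single_echo_TE2``, ``difference``.
    Zero-variance time series yield ``undefined=True`` rather than infinities.
    """

    tsnr: np.ndarray
    source: str
    undefined: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.tsnr = np.asarray(self.tsnr, dtype=float)
        if self.undefined is None:
            self.undefined = np.zeros(self.tsnr.shape, dtype=bool)
        self.undefined = np.asarray(self.undefined, dtype=bool)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def compute_tsnr(series: np.ndarray, source: str = "multi_echo") -> TsnrMap:
    """TSNR per region: temporal mean divided by temporal standard deviation.

    Parameters
    ----------
    series : (R, T) region x time signal, T >= 2.
    source : provenance tag stored on the map.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[1] < 2:
        raise ValueError("series must be (R, T) with at least 2 time points")
    mean = series.mean(axis=1)
    sd = series.std(axis=1, ddof=1)
    undefined = sd == 0
    tsnr = np.zeros_like(mean)
    np.divide(mean, sd, out=tsnr, where=~undefined)
    tsnr[undefined] = np.nan
    return TsnrMap(tsnr=tsnr, source=source, undefined=undefined)


def fit_monoexponential(mean_per_echo: np.ndarray, tes: np.ndarray) -> tuple[float, float]:
    """Log-linear least-squares fit of ``S(TE) = S0 * exp(-TE / T2*)``.

    Returns ``(S0, T2*)``; exact on noiseless mono-exponential input.  A
    non-positive mean at any echo, or a non-decaying fit, returns
    ``(nan, nan)`` (failure is flagged, never raised, so vectorised callers
    can record a failure mask).
    """
    y = np.asarray(mean_per_echo, dtype=float)
    tes = np.asarray(tes, dtype=float)
    if y.size != tes.size or y.size < 2:
        raise ValueError("need one mean per echo, at least two echoes")
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        return (float("nan"), float("nan"))
    # slope of log S on TE is -1/T2*
    slope, intercept = np.polyfit(tes, np.log(y), 1)
    if slope >= 0:
        return (float("nan"), float("nan"))
    return (float(np.exp(intercept)), float(-1.0 / slope))


def fit_decay(run: MultiEchoRun, t2s_bounds: tuple[float, float] = T2S_BOUNDS) -> DecayFit:
    """Fit S0/T2* per region from the time-averaged echo images.

    T2* estimates are clipped to ``t2s_bounds`` (ms) for robustness to noise
    at long TE; clipping does not mark a region as failed.
    """
    means = run.data.mean(axis=2)  # (E, R)
    n_regions = run.n_regions
    s0 = np.full(n_regions, np.nan)
    t2s = np.full(n_regions, np.nan)
    resid = np.full(n_regions, np.nan)
    failed = np.zeros(n_regions, dtype=bool)
    for r in range(n_regions):
        s0_r, t2s_r = fit_monoexponential(means[:, r], run.tes)
        if not np.isfinite(t2s_r):
            failed[r] = True
            continue
        t2s_r = float(np.clip(t2s_r, *t2s_bounds))
        s0[r] = s0_r
        t2s[r] = t2s_r
        resid[r] = float(np.sum((means[:, r] - s0_r * np.exp(-run.tes / t2s_r)) ** 2))
    if failed.any():
        logger.info("decay fit failed for %d/%d regions; falling back to simple average",
                    int(failed.sum()), n_regions)
    return DecayFit(s0=s0, t2star=t2s, fit_residual=resid, failed=failed)


def combination_weights(tes: np.ndarray, t2star: np.ndarray) -> np.ndarray:
    """Per-region TSNR-optimal echo weights, ``w_e ∝ TE_e * exp(-TE_e/T2*)``.

    Returns an (R, E) array of nonnegative weights summing to 1 per region.
    Regions with NaN T2* get uniform weights (simple average fallback).
    """
    tes = np.asarray(tes, dtype=float)
    t2star = np.atleast_1d(np.asarray(t2star, dtype=float))
    w = tes[None, :] * np.exp(-tes[None, :] / t2star[:, None])
    bad = ~np.isfinite(w).all(axis=1)
    w[bad] = 1.0
    return w / w.sum(axis=1, keepdims=True)


def optimal_combine(run: MultiEchoRun, fit: DecayFit) -> np.ndarray:
    """Weighted sum of echoes maximising TSNR; returns (R, T).

    Weights are fixed per region from the time-averaged decay fit.  Regions
    with failed fits fall back to the simple echo average; if every region
    failed, combination is refused.
    """
    if fit.failed.all():
        raise ValueError("decay fit failed for every region; cannot combine")
    w = combination_weights(run.tes, fit.t2star)  # (R, E)
    return np.einsum("re,ert->rt", w, run.data)


def tsnr_difference_map(multi: TsnrMap, single_te2: TsnrMap) -> TsnrMap:
    """Multi-echo minus single-echo (second-echo proxy) TSNR, elementwise."""
    if multi.tsnr.shape != single_te2.tsnr.shape:
        raise ValueError("TSNR maps cover different region sets")
    undefined = multi.undefined | single_te2.undefined
    diff = multi.tsnr - single_te2.tsnr
    return TsnrMap(tsnr=diff, source="difference", undefined=undefined)
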