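"""Mass-univariate statistics on RSFC maps.

One-sample and paired t maps across subjects, per-parcel, with two display
masks: Bonferroni-corrected significance (``p < alpha / n_comparisons``)
and the absolute top-fraction of connections (default top 10%).  Network
profiles summarise a map as the mean z within each of the 17 cortical
networks and each subcortical structure, with paired contrasts at the
profile level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import CORTICAL_NETWORKS, SUBCORTICAL_STRUCTURES, ToyAtlas

DEFAULT_ALPHA = 0.01
DEFAULT_TOP_FRACTION = 0.10


@dataclass
class StatMap:
    """Per-parcel t/p with Bonferroni and top-fraction masks.

    Parcels with zero variance across subjects are flagged ``undefined``
    (t, p = NaN) and excluded from both masks.
    """

    t: np.ndarray
    p: np.ndarray
    df_t: int
    mask_bonf: np.ndarray
    mask_top: np.ndarray
    undefined: np.ndarray
    contrast: str = ""


@dataclass
class NetworkProfile:
    """Mean z per 17-network label and per subcortical structure."""

    networks: dict[str, float]
    subcortex: dict[str, float]
    subject_id: str = ""

    def as_series(self) -> pd.Series:
        return pd.Series({**self.networks, **self.subcortex})


def _t_and_p(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = values.shape[0]
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    undefined = sd == 0
    t = np.full(mean.shape, np.nan)
    np.divide(mean, sd / np.sqrt(n), out=t, where=~undefined)
    p = np.full(mean.shape, np.nan)
    p[~undefined] = 2.0 * stats.t.sf(np.abs(t[~undefined]), df=n - 1)
    return t, p, undefined


def one_sample_map(rows: np.ndarray, *, alpha: float = DEFAULT_ALPHA,
                   n_comparisons: Optional[int] = None,
                   top_fraction: float = DEFAULT_TOP_FRACTION,
                   contrast: str = "one-sample") -> StatMap:
    """One-sample t test of subject x parcel z values against zero.

    Per parcel: ``t = mean / (sd / sqrt(n))`` with n-1 degrees of freedom,
    two-sided p.  ``n_comparisons`` defaults to the parcel count.
    """
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or rows.shape[0] < 3:
        raise ValueError("rows must be (subjects, parcels) with >= 3 subjects")
    if np.any(~np.isfinite(rows)):
        raise ValueError("NaN/inf in input rows")
    t, p, undefined = _t_and_p(rows)
    n_comp = rows.shape[1] if n_comparisons is None else n_comparisons
    mask_b = bonferroni_mask(p, alpha, n_comp)
    mean = rows.mean(axis=0)
    mask_t = top_fraction_mask(np.where(undefined, np.nan, mean), top_fraction)
    return StatMap(t=t, p=p, df_t=rows.shape[0] - 1, mask_bonf=mask_b,
                   mask_top=mask_t, undefined=undefined, contrast=contrast)


def paired_contrast_map(rows_a: np.ndarray, rows_b: np.ndarray, *,
                        alpha: float = DEFAULT_ALPHA,
                        n_comparisons: Optional[int] = None,
                        top_fraction: float = DEFAULT_TOP_FRACTION,
                        contrast: str = "paired") -> StatMap:
    """Paired t map: one-sample test on per-subject differences a - b."""
    rows_a = np.asarray(rows_a, dtype=float)
    rows_b = np.asarray(rows_b, dtype=float)
    if rows_a.shape != rows_b.shape:
        raise ValueError("paired inputs must share subjects and parcel order")
    return one_sample_map(rows_a - rows_b, alpha=alpha,
                          n_comparisons=n_comparisons,
                          top_fraction=top_fraction, contrast=contrast)


def bonferroni_mask(p: np.ndarray, alpha: float, n_comparisons: int) -> np.ndarray:
    """Mask of parcels with ``p < alpha / n_comparisons`` (NaN -> False)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    p = np.asarray(p, dtype=float)
    with np.errstate(invalid="ignore"):
        return (p < alpha / n_comparisons) & np.isfinite(p)


def top_fraction_mask(values: np.ndarray, fraction: float,
                      parcel_ids: Optional[np.ndarray] = None) -> np.ndarray:
    """Mask of the round(fraction * n) largest-|value| parcels.

    Rounding is half-away-from-zero (1,032 parcels at 10% -> 103).  Ties at
    the cutoff break deterministically by parcel id (lower id wins); NaN
    values are never selected.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n = values.size
    m = int(np.floor(fraction * n + 0.5))
    ids = np.arange(n) if parcel_ids is None else np.asarray(parcel_ids)
    absval = np.abs(values)
    absval = np.where(np.isfinite(absval), absval, -np.inf)
    order = np.lexsort((ids, -absval))  # by descending |value|, then parcel id
    mask = np.zeros(n, dtype=bool)
    chosen = order[:m]
    mask[chosen[np.isfinite(values[chosen])]] = True
    return mask


def network_profile(row: np.ndarray, atlas: ToyAtlas,
                    subject_id: str = "") -> NetworkProfile:
    """Mean z per 17-network label and per subcortical structure.

    Every atlas parcel contributes to exactly one entry; a label without
    parcels is an error (the atlas constructor guarantees coverage).
    """
    row = np.asarray(row, dtype=float)
    if row.size != atlas.n_parcels:
        raise ValueError("row length must match the atlas parcel count")
    nets = atlas.network_labels
    networks, subcortex = {}, {}
    for label in CORTICAL_NETWORKS:
        mask = nets == label
        if not mask.any():
            raise ValueError(f"network {label} has no parcels")
        networks[label] = float(row[mask].mean())
    for label in SUBCORTICAL_STRUCTURES:
        mask = nets == label
        if not mask.any():
            raise ValueError(f"structure {label} has no parcels")
        subcortex[label] = float(row[mask].mean())
    return NetworkProfile(networks=networks, subcortex=subcortex,
                          subject_id=subject_id)


def network_profiles(rows: np.ndarray, atlas: ToyAtlas) -> pd.DataFrame:
    """Subject x label profile table (17 networks + 7 structures)."""
    rows = np.asarray(rows, dtype=float)
    return pd.DataFrame([network_profile(r, atlas).as_series() for r in rows])


def profile_contrast(rows_a: np.ndarray, rows_b: np.ndarray,
                     atlas: ToyAtlas) -> pd.DataFrame:
    """Paired t test per network/structure on profile differences.

    Returns a table indexed by label with columns mean_diff, t, p.
    """
    prof_a = network_profiles(rows_a, atlas)
    prof_b = network_profiles(rows_b, atlas)
    if prof_a.shape != prof_b.shape:
        raise ValueError("profile tables must share subjects")
    diff = prof_a - prof_b
    t, p, undefined = _t_and_p(diff.to_numpy())
    return pd.DataFrame({"mean_diff": diff.mean(axis=0), "t": t, "p": p},
                        index=diff.columns)
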