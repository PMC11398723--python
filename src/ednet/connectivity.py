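"""Coefficient-based resting-state functional connectivity.

RSFC here is the product-moment correlation of the retained-BOLD ICA
coefficients across parcels (parcel x component vectors), not a correlation
of time series.  The Fisher r-to-z transform is scaled by the variance-
stabilising factor for the subject's coefficient count:

    Z = arctanh(R) * sqrt(df - 3)

where df is the number of retained BOLD components, so subjects with more
retained components contribute proportionally more certain edges to the
group matrix.  The diagonal carries no information (a parcel with itself)
and is excluded from all downstream statistics by convention (stored as 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .synthetic import ToyAtlas
from .te_denoise import MEFCData


@dataclass
class RSFCMatrix:
    """Symmetric parcel x parcel matrix of df-adjusted Fisher z values.

    ``df`` is the subject's BOLD component count (None for group means);
    ``parcel_ids`` binds row/column order to an atlas.
    """

    z: np.ndarray
    parcel_ids: np.ndarray
    df: Optional[int] = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.parcel_ids = np.asarray(self.parcel_ids)
        n = self.z.shape[0]
        if self.z.shape != (n, n) or self.parcel_ids.size != n:
            raise ValueError("z must be square and match parcel_ids")
        if np.any(~np.isfinite(self.z)):
            raise ValueError("non-finite values in RSFC matrix")
        if not np.allclose(self.z, self.z.T):
            raise ValueError("RSFC matrix must be symmetric")

    @property
    def n_parcels(self) -> int:
        return self.z.shape[0]

    def row(self, parcel_id) -> np.ndarray:
        """Whole-brain RSFC map of one parcel (its matrix row)."""
        idx = np.nonzero(self.parcel_ids == parcel_id)[0]
        if idx.size != 1:
            raise KeyError(f"parcel {parcel_id} not in matrix")
        return self.z[idx[0]]


def fisher_z(r: np.ndarray, df: int) -> np.ndarray:
    """df-adjusted Fisher transform, ``arctanh(R) * sqrt(df - 3)``.

    |R| is clipped to 1 - 1e-12 so perfectly correlated pairs stay finite.
    Strictly increasing in R for fixed df and in df for fixed R > 0.
    """
    if df <= 3:
        raise ValueError("df must exceed 3 for the variance-stabilised z")
    r = np.clip(np.asarray(r, dtype=float), -1 + 1e-12, 1 - 1e-12)
    return np.arctanh(r) * np.sqrt(df - 3)


def parcellate_coefficients(coeffs: np.ndarray, region_parcels: np.ndarray,
                            atlas: ToyAtlas) -> np.ndarray:
    """Average coefficient rows within each atlas parcel -> (P, K).

    ``region_parcels`` gives the parcel id of each coefficient row; at
    parcel-level resolution this is the identity mapping.  No smoothing.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    region_parcels = np.asarray(region_parcels)
    if coeffs.shape[0] != region_parcels.size:
        raise ValueError("one parcel label per coefficient row required")
    out = np.empty((atlas.n_parcels, coeffs.shape[1]))
    for i, pid in enumerate(atlas.parcel_ids):
        rows = region_parcels == pid
        if not rows.any():
            raise ValueError(f"parcel {pid} has no regions")
        out[i] = coeffs[rows].mean(axis=0)
    return out


def rsfc_from_mefc(coeffs: np.ndarray | MEFCData, df: Optional[int] = None,
                   parcel_ids: Optional[np.ndarray] = None,
                   subject_id: str = "") -> RSFCMatrix:
    """Correlate parcels over the component dimension and Fisher-transform.

    ``coeffs`` is (P, df) — either a plain array with ``df`` given, or an
    MEFCData.  Requires df >= 4 (z needs df - 3 > 0) and >= 2 parcels with
    nonzero variance.
    """
    if isinstance(coeffs, MEFCData):
        df = coeffs.df
        subject_id = subject_id or coeffs.subject_id
        coeffs = coeffs.coeffs
    coeffs = np.asarray(coeffs, dtype=float)
    if df is None or df <= 3:
        raise ValueError("df must be provided and exceed 3")
    if coeffs.shape[0] < 2:
        raise ValueError("need at least 2 parcels")
    sd = coeffs.std(axis=1)
    if np.any(sd == 0):
        bad = np.nonzero(sd == 0)[0]
        raise ValueError(f"zero-variance parcel row(s) at index {bad.tolist()}")
    r = np.corrcoef(coeffs)
    z = fisher_z(r, df)
    np.fill_diagonal(z, 0.0)  # diagonal excluded by convention
    if parcel_ids is None:
        parcel_ids = np.arange(1, coeffs.shape[0] + 1)
    return RSFCMatrix(z=z, parcel_ids=parcel_ids, df=int(df),
                      subject_id=subject_id)


def group_mean_matrix(matrices: Sequence[RSFCMatrix]) -> RSFCMatrix:
    """Elementwise mean of subject z matrices; permutation-invariant."""
    matrices = list(matrices)
    if len(matrices) < 2:
        raise ValueError("group mean needs at least 2 subjects")
    ref = matrices[0].parcel_ids
    for m in matrices[1:]:
        if not np.array_equal(m.parcel_ids, ref):
            raise ValueError("parcel order mismatch across subjects")
    z = np.mean([m.z for m in matrices], axis=0)
    return RSFCMatrix(z=z, parcel_ids=ref, df=None, subject_id="group")


def correlation_matrix(series: np.ndarray) -> np.ndarray:
    """Plain product-moment correlation of (R, T) rows, diagonal zeroed.

    Used for time-series (pre-denoising) connectivity when comparing against
    the coefficient-based route; no df adjustment.
    """
    r = np.corrcoef(np.asarray(series, dtype=float))
    np.fill_diagonal(r, 0.0)
    return r
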