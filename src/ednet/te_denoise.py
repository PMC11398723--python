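"""TE-dependence denoising: ICA decomposition, kappa/rho scoring, BOLD
classification, and the MEFC coefficient outputs.

BOLD fluctuations arise from transverse relaxation changes (ΔR2*): their
percent-signal amplitude grows linearly with echo time.  Scanner and motion
artifacts perturb the baseline intensity (ΔS0): their percent amplitude is
flat across echoes.  Each ICA component is therefore scored by regressing
every echo's percent signal onto the component time course and fitting the
resulting per-echo amplitudes ``beta_e`` with both models:

* ΔR2* model: ``beta_e ∝ TE_e``   -> fit quality summarised by kappa
* ΔS0 model:  ``beta_e = const``  -> fit quality summarised by rho

kappa and rho are coefficient-weighted means over regions of the model F
statistics (weights: squared spatial coefficients).  Components with
kappa > rho are retained as BOLD; the retained coefficient matrix is the
MEFC (multi-echo functional connectivity) data whose column count is the
degrees of freedom carried into the Fisher z transform downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.decomposition import FastICA

from .signal_quality import MultiEchoRun

logger = logging.getLogger("ednet")

#: A subject with fewer retained BOLD components than this fails QC.
MIN_BOLD_COMPONENTS = 10


@dataclass
class ComponentSet:
    """ICA decomposition of the optimally combined series.

    mixing : (T, K) component time courses (unit variance, uncorrelated).
    coeffs : (R, K) spatial coefficients; ``mixing @ coeffs.T + mean``
        reconstructs the input (up to residual when K < rank).
    mean : (R,) temporal mean removed before decomposition.
    kappa, rho : per-component TE-dependence scores (ΔR2* / ΔS0 models).
    variance_explained : per-component fraction of input variance; sums <= 1.
    labels : per-component "BOLD" / "non_BOLD", or None before classification.
    """

    mixing: np.ndarray
    coeffs: np.ndarray
    mean: np.ndarray
    seed: int
    kappa: Optional[np.ndarray] = None
    rho: Optional[np.ndarray] = None
    variance_explained: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    def bold_indices(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("components are not classified yet")
        return np.nonzero(self.labels == "BOLD")[0]


@dataclass
class MEFCData:
    """Retained-BOLD coefficient set; df is the BOLD component count."""

    coeffs: np.ndarray  # (R, df)
    df: int
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.df != self.coeffs.shape[1] or self.df < 1:
            raise ValueError("df must equal the number of coefficient columns (>= 1)")


def default_n_components(combined: np.ndarray) -> int:
    """Data-driven component count: eigenvalues above the noise bulk.

    The sample-covariance eigenvalues of pure noise concentrate below the
    Marchenko-Pastur upper edge ``sigma^2 (1 + sqrt(R/T))^2``; the noise
    level is estimated from the eigenvalue tail by fixed-point iteration and
    K is the count of eigenvalues above the edge.  This tracks the number of
    genuine (network + artifact) sources rather than a fixed explained-
    variance quota, which over-sizes K whenever broadband region-private
    variance is present.
    """
    x = np.asarray(combined, dtype=float).T  # (T, R)
    n_t, n_r = x.shape
    xc = x - x.mean(axis=0)
    ev = np.linalg.svd(xc, compute_uv=False) ** 2 / (n_t - 1)
    edge_factor = (1.0 + np.sqrt(n_r / n_t)) ** 2
    k = 0
    for _ in range(100):
        tail = ev[k:]
        if tail.size == 0:
            break
        edge = tail.mean() * edge_factor
        k_new = int(np.sum(ev > edge))
        if k_new == k:
            break
        k = k_new
    return max(k, 1)


def decompose(combined: np.ndarray, n_components: int, seed: int = 0) -> ComponentSet:
    """ICA of the combined (R, T) series into ``n_components`` sources.

    Deterministic given ``seed``.  Components are ordered by descending
    variance explained; each coefficient column's largest-magnitude entry is
    made positive so the decomposition has a fixed sign convention.
    """
    combined = np.asarray(combined, dtype=float)
    n_regions, n_t = combined.shape
    if not 1 <= n_components < min(n_regions, n_t):
        raise ValueError(
            f"n_components={n_components} must satisfy 1 <= K < "
            f"min(regions={n_regions}, timepoints={n_t})")
    x = combined.T  # samples = time points
    ica = FastICA(n_components=n_components, random_state=seed,
                  whiten="unit-variance", max_iter=1000, tol=1e-5)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*did not converge.*")
        mixing = ica.fit_transform(x)          # (T, K), unit variance
    coeffs = ica.mixing_                       # (R, K)
    mean = ica.mean_

    xc = x - mean
    total_ss = float(np.sum(xc ** 2))
    comp_ss = np.sum(mixing ** 2, axis=0) * np.sum(coeffs ** 2, axis=0)
    var_exp = comp_ss / total_ss
    order = np.argsort(-var_exp, kind="stable")
    mixing, coeffs, var_exp = mixing[:, order], coeffs[:, order], var_exp[order]
    flip = np.sign(coeffs[np.argmax(np.abs(coeffs), axis=0), np.arange(coeffs.shape[1])])
    flip[flip == 0] = 1.0
    return ComponentSet(mixing=mixing * flip, coeffs=coeffs * flip, mean=mean,
                        seed=seed, variance_explained=var_exp)


def te_dependence_metrics(components: ComponentSet, run: MultiEchoRun) -> ComponentSet:
    """Populate kappa/rho by fitting per-echo amplitudes to both TE models.

    For component k and region r, the percent signal of each echo is
    regressed onto the component time course, giving amplitudes
    ``beta_e(r, k)``.  F statistics of the through-origin ΔR2* fit
    (``beta_e = b*TE_e``) and the constant ΔS0 fit are averaged over regions
    with weights ``coeffs**2``.  Both scores are invariant to flipping a
    component's sign.  Zero-variance components get kappa = rho = 0 with a
    warning.
    """
    tes = run.tes
    n_e = tes.size
    s_bar = run.data.mean(axis=2)  # (E, R)
    if np.any(s_bar == 0):
        raise ValueError("zero mean signal; percent signal undefined")
    pct = run.data / s_bar[:, :, None] - 1.0  # (E, R, T)
    pct = pct - pct.mean(axis=2, keepdims=True)

    mix = components.mixing  # (T, K)
    ss = np.sum(mix ** 2, axis=0)  # (K,)
    degenerate = ss <= 1e-12
    if degenerate.any():
        warnings.warn("degenerate (zero-variance) component: kappa=rho=0",
                      RuntimeWarning, stacklevel=2)
    beta = np.einsum("ert,tk->erk", pct, mix)  # (E, R, K)
    beta[:, :, degenerate] = 0.0
    beta = beta / np.where(degenerate, 1.0, ss)[None, None, :]

    sst = np.sum(beta ** 2, axis=0)  # (R, K)
    # ΔR2* model through the origin: beta_e = b * TE_e
    b = np.einsum("erk,e->rk", beta, tes) / np.sum(tes ** 2)
    sse_r2 = np.sum((beta - b[None] * tes[:, None, None]) ** 2, axis=0)
    # ΔS0 model: beta_e = c
    c = beta.mean(axis=0)
    sse_s0 = np.sum((beta - c[None]) ** 2, axis=0)

    eps = 1e-12
    f_r2 = (sst - sse_r2) / (sse_r2 / (n_e - 1) + eps)
    f_s0 = (sst - sse_s0) / (sse_s0 / (n_e - 1) + eps)
    w = components.coeffs ** 2  # (R, K)
    w_sum = w.sum(axis=0)
    w_sum[w_sum == 0] = 1.0
    components.kappa = np.where(degenerate, 0.0, np.sum(w * f_r2, axis=0) / w_sum)
    components.rho = np.where(degenerate, 0.0, np.sum(w * f_s0, axis=0) / w_sum)
    return components


def classify_components(components: ComponentSet,
                        kappa_rho_ratio: float = 1.0) -> ComponentSet:
    """Label components BOLD iff kappa > ratio * rho (ties -> non_BOLD).

    The binary rule depends only on (kappa, rho), never on component index.
    An empty BOLD set is allowed here; downstream QC handles it.
    """
    if components.kappa is None or components.rho is None:
        raise ValueError("run te_dependence_metrics first")
    bold = components.kappa > kappa_rho_ratio * components.rho
    components.labels = np.where(bold, "BOLD", "non_BOLD")
    if not bold.any():
        logger.warning("no BOLD components retained")
    return components


def build_mefc(components: ComponentSet, subject_id: str = "") -> MEFCData:
    """Restrict coefficients to BOLD columns (order preserved); df recorded."""
    idx = components.bold_indices()
    if idx.size == 0:
        raise ValueError(
            "zero BOLD components: subject will fail the few_components QC "
            f"rule (< {MIN_BOLD_COMPONENTS} retained)")
    return MEFCData(coeffs=components.coeffs[:, idx], df=int(idx.size),
                    subject_id=subject_id)


def reconstruct_denoised(components: ComponentSet) -> np.ndarray:
    """Back-project only the BOLD components; returns (R, T).

    The removed temporal mean is added back so the reconstruction lives on
    the original signal scale (TSNR on the denoised series stays meaningful).
    With every component labelled BOLD this equals the decomposition's full
    fit.
    """
    idx = components.bold_indices()
    if idx.size == 0:
        raise ValueError("empty BOLD set: nothing to reconstruct")
    recon = components.mixing[:, idx] @ components.coeffs[:, idx].T  # (T, R)
    return recon.T + components.mean[:, None]


def denoise_run(run: MultiEchoRun, combined: np.ndarray, seed: int = 0,
                n_components: Optional[int] = None,
                kappa_rho_ratio: float = 1.0) -> ComponentSet:
    """Convenience pipeline: decompose, score TE dependence, classify."""
    if n_components is None:
        n_components = default_n_components(combined)
    comps = decompose(combined, n_components, seed=seed)
    comps = te_dependence_metrics(comps, run)
    return classify_components(comps, kappa_rho_ratio=kappa_rho_ratio)
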