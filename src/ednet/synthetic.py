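"""Synthetic multi-echo cohorts with planted network structure.

The generator emulates, at parcel (not voxel) scale, the ingredients the
downstream pipeline needs ground truth for:

* mono-exponential multi-echo decay with region-specific S0 and T2*, with
  short T2* / low S0 in ventral "limbic" parcels to mimic susceptibility
  dropout near the nasal airways;
* BOLD fluctuations entering as ΔR2*-like signal whose percent amplitude
  grows linearly with echo time, and artifact fluctuations entering as
  ΔS0-like signal whose percent amplitude is flat across echoes;
* a planted block-covariance network over parcels carrying 17-network-like
  cortical labels (VIS_A ... TPar, LIM_A, LIM_B) plus subcortical structures,
  with a scenario switch controlling whether limbic parcels load on default
  network (DN) latents ("merged") or on a private limbic latent ("distinct");
* motion time series with optional spikes whose signal transients survive or
  succumb to TE-dependence denoising as configured;
* planted subject-level quality violations (conjunctive FD/DVARS frames, low
  TSNR, too few BOLD components) for exercising exclusion rules.

Latent network time courses are AR(1) (lag-1 coefficient 0.3) driven by
Laplace innovations: heavy tails keep the sources identifiable for the ICA
stage while preserving the intended autocorrelation.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .signal_quality import DEFAULT_TES, DEFAULT_TR, MultiEchoRun

# ---------------------------------------------------------------------------
# label sets
# ---------------------------------------------------------------------------

CORTICAL_NETWORKS = (
    "VIS_A", "VIS_B", "SMN_A", "SMN_B", "DAN_A", "DAN_B", "SAL_A", "SAL_B",
    "FPN_A", "FPN_B", "FPN_C", "DN_A", "DN_B", "DN_C", "TPar", "LIM_A", "LIM_B",
)
SUBCORTICAL_STRUCTURES = ("HIP", "AMY", "NAC", "GP", "PUT", "CAU", "BF")
LIMBIC_NETWORKS = ("LIM_A", "LIM_B")

#: BOLD latents shared by a group of networks; order fixes latent indices.
NETWORK_GROUPS: dict[str, tuple[str, ...]] = {
    "VIS": ("VIS_A", "VIS_B"),
    "SMN": ("SMN_A", "SMN_B"),
    "DAN": ("DAN_A", "DAN_B"),
    "SAL": ("SAL_A", "SAL_B"),
    "FPN": ("FPN_A", "FPN_B", "FPN_C"),
    "DN_A": ("DN_A",),
    "DN_B": ("DN_B", "TPar"),
    "DN_C": ("DN_C",),
}
DN_LATENTS = ("DN_A", "DN_B", "DN_C")

#: Subcortical loadings: structure -> ((latent, weight), ...).  HIP/AMY/NAC/BF
#: attach to the DN latents (with a secondary DN loading so they tie into the
#: DN core rather than a single satellite), basal ganglia to the somatomotor
#: latent.
SUBCORTICAL_LOADINGS = {
    "HIP": (("DN_C", 0.45), ("DN_A", 0.20)),
    "AMY": (("DN_C", 0.40),),
    "NAC": (("DN_A", 0.35), ("DN_C", 0.20)),
    "BF": (("DN_A", 0.40), ("DN_B", 0.20)),
    "GP": (("SMN", 0.50),),
    "PUT": (("SMN", 0.50),),
    "CAU": (("SMN", 0.50),),
}

#: Yeo-7-style warm-start groups (limbic kept separate; subcortex its own).
YEO7_GROUPS = ("VIS", "SMN", "DAN", "SAL", "LIM", "CONT", "DN", "SUB")

NETWORK_LOADING = 0.6        # parcel loading on its group latent
DN_CROSS_LOADING = 0.25      # cross-loading among the three DN latents
LIM_ON_DN_LOADING = 0.6      # merged scenario: limbic loading on a DN latent
LIM_PRIVATE_SD = 0.2         # limbic parcel private residual (both scenarios)
PARCEL_PRIVATE_SD = 0.3      # non-limbic private residual
EXTRA_BOLD_SD = 0.35         # diffuse extra BOLD latent loadings
ARTIFACT_LOADING_SD = 0.3


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------

@dataclass
class ToyAtlas:
    """Toy parcel scheme with 17 cortical network labels + subcortex.

    ``table`` has one row per parcel: parcel_id (1..P, contiguous),
    hemisphere (L/R), network_label, is_limbic, is_ventral_dropout.
    """

    table: pd.DataFrame
    seed: int = 0

    def __post_init__(self) -> None:
        ids = self.table["parcel_id"].to_numpy()
        if not np.array_equal(ids, np.arange(1, len(ids) + 1)):
            raise ValueError("parcel ids must be unique and contiguous from 1")
        lim = self.table["network_label"].isin(LIMBIC_NETWORKS).to_numpy()
        if not np.array_equal(lim, self.table["is_limbic"].to_numpy()):
            raise ValueError("is_limbic must mark exactly the LIM_A/LIM_B parcels")

    @property
    def n_parcels(self) -> int:
        return len(self.table)

    @property
    def parcel_ids(self) -> np.ndarray:
        return self.table["parcel_id"].to_numpy()

    @property
    def network_labels(self) -> np.ndarray:
        return self.table["network_label"].to_numpy()

    @property
    def is_limbic(self) -> np.ndarray:
        return self.table["is_limbic"].to_numpy()

    @property
    def is_ventral_dropout(self) -> np.ndarray:
        return self.table["is_ventral_dropout"].to_numpy()

    @property
    def is_cortical(self) -> np.ndarray:
        return np.isin(self.network_labels, CORTICAL_NETWORKS)

    def limbic_parcels(self) -> np.ndarray:
        """Parcel ids of LIM_A/LIM_B parcels, in atlas order."""
        return self.parcel_ids[self.is_limbic]

    def parcels_of(self, label: str) -> np.ndarray:
        return self.parcel_ids[self.network_labels == label]


def make_atlas(p_cortical: int, p_subcortical: int, seed: int = 0) -> ToyAtlas:
    """Build a toy atlas covering all 17 cortical networks and 7 structures.

    Cortical parcels are distributed as evenly as possible over the 17
    network labels (each needs >= 2 for a bilateral pair) and subcortical
    parcels over the 7 structures (>= 1 each; 14 gives bilateral pairs).
    Hemispheres alternate L/R within each label.
    """
    n_c, n_s = len(CORTICAL_NETWORKS), len(SUBCORTICAL_STRUCTURES)
    c_counts = [p_cortical // n_c + (i < p_cortical % n_c) for i in range(n_c)]
    missing = [lab for lab, c in zip(CORTICAL_NETWORKS, c_counts) if c < 2]
    if missing:
        raise ValueError(
            f"p_cortical={p_cortical} leaves cortical networks without a "
            f"bilateral pair: {', '.join(missing)}")
    s_counts = [p_subcortical // n_s + (i < p_subcortical % n_s) for i in range(n_s)]
    missing = [lab for lab, c in zip(SUBCORTICAL_STRUCTURES, s_counts) if c < 1]
    if missing:
        raise ValueError(
            f"p_subcortical={p_subcortical} leaves structures uncovered: "
            f"{', '.join(missing)}")

    rows = []
    for label, count in zip(CORTICAL_NETWORKS + SUBCORTICAL_STRUCTURES,
                            c_counts + s_counts):
        limbic = label in LIMBIC_NETWORKS
        for j in range(count):
            rows.append({
                "hemisphere": "LR"[j % 2],
                "network_label": label,
                "is_limbic": limbic,
                "is_ventral_dropout": limbic,
            })
    table = pd.DataFrame(rows)
    table.insert(0, "parcel_id", np.arange(1, len(table) + 1))
    return ToyAtlas(table=table, seed=seed)


def yeo7_init(atlas: ToyAtlas) -> np.ndarray:
    """7-network warm-start labels (limbic separate, subcortex its own module).

    Returns integer module labels 1..8 in atlas parcel order, mirroring the
    coarse 7-network scheme used to initialise community detection.
    """
    to_group = {}
    for net in CORTICAL_NETWORKS:
        if net.startswith("VIS"):
            g = "VIS"
        elif net.startswith("SMN"):
            g = "SMN"
        elif net.startswith("DAN"):
            g = "DAN"
        elif net.startswith("SAL"):
            g = "SAL"
        elif net.startswith("LIM"):
            g = "LIM"
        elif net.startswith("FPN"):
            g = "CONT"
        else:  # DN_*, TPar
            g = "DN"
        to_group[net] = g
    for s in SUBCORTICAL_STRUCTURES:
        to_group[s] = "SUB"
    idx = {g: i + 1 for i, g in enumerate(YEO7_GROUPS)}
    return np.array([idx[to_group[n]] for n in atlas.network_labels], dtype=int)


# ---------------------------------------------------------------------------
# ground truth and recipes
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Cohort-level generative truth shared by all subjects."""

    scenario: str
    latent_loadings: np.ndarray          # (P, n_bold) BOLD mixing template
    artifact_loadings: np.ndarray        # (P, n_artifact)
    bold_component_ids: np.ndarray       # indices of BOLD latents
    artifact_component_ids: np.ndarray   # indices of artifact latents (offset)
    planted_partition: np.ndarray        # (P,) module label per parcel
    planted_lim_clusters: dict[int, int] # limbic parcel id -> cluster 1..3
    qc_violations: dict[int, set[str]] = field(default_factory=dict)
    latent_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if set(self.bold_component_ids) & set(self.artifact_component_ids):
            raise ValueError("BOLD and artifact component ids must be disjoint")
        if self.scenario not in ("merged", "distinct"):
            raise ValueError(f"unknown scenario {self.scenario!r}")

    @property
    def n_bold(self) -> int:
        return len(self.bold_component_ids)

    @property
    def n_artifacts(self) -> int:
        return len(self.artifact_component_ids)


@dataclass
class SubjectRecipe:
    """Everything needed to synthesise one subject's multi-echo run."""

    seed: int
    n_timepoints: int = 200
    tr: float = DEFAULT_TR
    tes: tuple[float, ...] = DEFAULT_TES
    noise_sd: float = 2.5                # thermal noise, signal units
    motion_spike_rate: float = 0.0       # per-volume spike probability
    s0_map: Optional[np.ndarray] = None  # (P,) baseline intensity
    t2star_map: Optional[np.ndarray] = None  # (P,) decay constant, ms
    ar_coef: float = 0.3                 # latent lag-1 autocorrelation
    pct_bold: float = 0.02               # fractional BOLD amplitude at mean TE
    pct_artifact: float = 0.02           # fractional artifact amplitude
    bold_scale: float = 1.0              # subject-level fluctuation scaling
    spike_s0_amp: float = 0.02           # ΔS0-like spike transient (fractional)
    spike_r2_amp: float = 0.05           # ΔR2*-like spike transient (fractional)
    forced_spike_frames: tuple[int, ...] = ()
    n_active_bold: Optional[int] = None  # restrict to first k BOLD latents

    def __post_init__(self) -> None:
        tes = np.asarray(self.tes, dtype=float)
        if np.any(tes <= 0) or np.any(np.diff(tes) <= 0):
            raise ValueError("TEs must be positive and strictly increasing")
        if self.t2star_map is not None and np.any(np.asarray(self.t2star_map) <= 0):
            raise ValueError("T2* must be positive everywhere")
        for name in ("s0_map", "t2star_map"):
            m = getattr(self, name)
            if m is not None and np.any(~np.isfinite(np.asarray(m, dtype=float))):
                raise ValueError(f"NaN/inf in {name}")


@dataclass
class SubjectGroundTruth:
    """Per-subject generator internals, attached to the simulated run."""

    z_bold: np.ndarray       # (T, n_bold) latent BOLD time courses
    z_artifact: np.ndarray   # (T, n_artifact)
    loadings: np.ndarray     # (P, n_bold) jittered subject loadings
    frac_bold: np.ndarray    # (P, T) fractional BOLD signal at mean TE
    frac_artifact: np.ndarray  # (P, T) fractional artifact signal
    spike_frames: np.ndarray
    active_bold: np.ndarray  # bool mask over BOLD latents

    def truth_rsfc(self) -> np.ndarray:
        """Correlation of the noiseless BOLD signal across parcels."""
        return np.corrcoef(self.frac_bold)


def make_ground_truth(atlas: ToyAtlas, scenario: str, seed: int = 0,
                      n_extra_bold: int = 0, n_artifacts: int = 6) -> GroundTruth:
    """Plant the block-covariance network structure over the atlas.

    In ``merged`` the limbic parcels load (0.6) on DN latents: the three
    planted limbic sub-clusters attach to DN_A, DN_B and DN_C respectively.
    In ``distinct`` the limbic parcels load (0.6) on a private LIM latent.
    ``n_extra_bold`` appends diffuse BOLD latents loading weakly everywhere
    (used to raise the retained-component count without altering the planted
    community structure).
    """
    rng = np.random.default_rng(seed)
    nets = atlas.network_labels
    p = atlas.n_parcels

    latent_names = list(NETWORK_GROUPS)
    if scenario == "distinct":
        latent_names.append("LIM")
    latent_names += [f"DIFFUSE_{i + 1}" for i in range(n_extra_bold)]
    col = {name: i for i, name in enumerate(latent_names)}
    loadings = np.zeros((p, len(latent_names)))

    for group, members in NETWORK_GROUPS.items():
        mask = np.isin(nets, members)
        loadings[mask, col[group]] = NETWORK_LOADING
    for a in DN_LATENTS:  # DN networks inter-correlate via cross-loadings
        mask = np.isin(nets, NETWORK_GROUPS[a])
        for b in DN_LATENTS:
            if b != a:
                loadings[mask, col[b]] = DN_CROSS_LOADING
    for struct, entries in SUBCORTICAL_LOADINGS.items():
        for latent, w in entries:
            loadings[nets == struct, col[latent]] = w

    lim_ids = atlas.limbic_parcels()
    lim_clusters = {}
    thirds = np.array_split(lim_ids, 3)
    for c, ids in enumerate(thirds, start=1):
        for pid in ids:
            lim_clusters[int(pid)] = c
    lim_rows = np.isin(atlas.parcel_ids, lim_ids)
    loadings[lim_rows, :] = 0.0  # limbic loadings set per scenario below
    if scenario == "merged":
        for pid, c in lim_clusters.items():
            loadings[pid - 1, col[DN_LATENTS[c - 1]]] = LIM_ON_DN_LOADING
    elif scenario == "distinct":
        loadings[lim_rows, col["LIM"]] = LIM_ON_DN_LOADING
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    for j in range(n_extra_bold):
        loadings[:, col[f"DIFFUSE_{j + 1}"]] = rng.normal(0.0, EXTRA_BOLD_SD, p)

    artifact_loadings = rng.normal(0.0, ARTIFACT_LOADING_SD, (p, n_artifacts))

    module = {"VIS": 1, "SMN": 2, "DAN": 3, "SAL": 4, "FPN": 5}
    partition = np.zeros(p, dtype=int)
    for i, net in enumerate(nets):
        if net in ("DN_A", "DN_B", "DN_C", "TPar", "HIP", "AMY", "NAC", "BF"):
            partition[i] = 6
        elif net in ("GP", "PUT", "CAU"):
            partition[i] = 2
        elif net in LIMBIC_NETWORKS:
            partition[i] = 6 if scenario == "merged" else 7
        else:
            for g, m in module.items():
                if net in NETWORK_GROUPS[g]:
                    partition[i] = m
                    break

    n_bold = len(latent_names)
    return GroundTruth(
        scenario=scenario,
        latent_loadings=loadings,
        artifact_loadings=artifact_loadings,
        bold_component_ids=np.arange(n_bold),
        artifact_component_ids=np.arange(n_bold, n_bold + n_artifacts),
        planted_partition=partition,
        planted_lim_clusters=lim_clusters,
        latent_names=tuple(latent_names),
    )


def default_recipe(atlas: ToyAtlas, seed: int, **overrides) -> SubjectRecipe:
    """Recipe with dropout-aware S0/T2* maps drawn deterministically from seed.

    Ventral-dropout parcels get short T2* (20-30 ms) and low S0, strictly
    below the non-dropout median (T2* 45-60 ms, S0 ~1000), emulating
    susceptibility-related signal loss.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA71A5]))
    p = atlas.n_parcels
    drop = atlas.is_ventral_dropout
    s0 = rng.uniform(950.0, 1050.0, p)
    t2s = rng.uniform(45.0, 60.0, p)
    s0[drop] = rng.uniform(600.0, 700.0, int(drop.sum()))
    t2s[drop] = rng.uniform(20.0, 30.0, int(drop.sum()))
    recipe = SubjectRecipe(seed=seed, s0_map=s0, t2star_map=t2s, **overrides)
    _check_dropout_maps(recipe, drop)
    return recipe


def _check_dropout_maps(recipe: SubjectRecipe, dropout: np.ndarray) -> None:
    if dropout.any() and (~dropout).any():
        for name in ("s0_map", "t2star_map"):
            m = np.asarray(getattr(recipe, name), dtype=float)
            if not np.all(m[dropout] < np.median(m[~dropout])):
                raise ValueError(
                    f"{name}: dropout parcels must sit strictly below the "
                    "non-dropout median")


#: Burst-like latent innovations: probability and amplification of bursts.
BURST_PROB = 0.12
BURST_AMP = 4.0


def _ar1(rng: np.random.Generator, n_timepoints: int, n_series: int,
         phi: float) -> np.ndarray:
    """Unit-variance AR(1) series with burst-like innovations, (T, n).

    Innovations are Gaussian amplified by occasional bursts
    (``N(0,1) * (1 + BURST_AMP * Bernoulli(BURST_PROB))``), giving the
    heavy-tailed, event-like temporal structure characteristic of fMRI ICA
    component time courses; heavy tails also keep the sources identifiable
    for the ICA stage.  Each series is standardised to zero mean and unit
    sample variance.
    """
    burn = 50
    e = rng.normal(0.0, 1.0, (burn + n_timepoints, n_series))
    e *= 1.0 + BURST_AMP * (rng.random(e.shape) < BURST_PROB)
    x = np.empty_like(e)
    x[0] = e[0]
    for t in range(1, len(e)):
        x[t] = phi * x[t - 1] + e[t]
    x = x[burn:]
    return (x - x.mean(axis=0)) / x.std(axis=0)


def simulate_subject(atlas: ToyAtlas, truth: GroundTruth,
                     recipe: SubjectRecipe) -> MultiEchoRun:
    """Synthesise one subject's multi-echo run.

    Per-echo signal follows
    ``S_e(r, t) = S0_r exp(-TE_e / T2*_r) * (1 + (TE_e/TE_mean) * b(r,t) + a(r,t)) + noise``
    where ``b`` collects BOLD (ΔR2*-like) fluctuations — latent network time
    courses mixed through the planted loadings plus a parcel-private residual
    — and ``a`` collects artifact (ΔS0-like) fluctuations.  Motion spikes
    displace one translation axis by 1 mm for one frame and inject a signal
    transient with a dominant TE-dependent part (position-dependent
    susceptibility effects) plus a ΔS0 part, so FD and DVARS co-occur.
    """
    p = atlas.n_parcels
    if truth.latent_loadings.shape[0] != p:
        raise ValueError("atlas and ground truth disagree on parcel count")
    if recipe.s0_map is None or recipe.t2star_map is None:
        base = default_recipe(atlas, recipe.seed)
        recipe = replace(
            recipe,
            s0_map=recipe.s0_map if recipe.s0_map is not None else base.s0_map,
            t2star_map=(recipe.t2star_map if recipe.t2star_map is not None
                        else base.t2star_map))
    s0 = np.asarray(recipe.s0_map, dtype=float)
    t2s = np.asarray(recipe.t2star_map, dtype=float)
    if s0.shape != (p,) or t2s.shape != (p,):
        raise ValueError("S0/T2* maps must have one entry per parcel")
    if np.any(~np.isfinite(s0)) or np.any(~np.isfinite(t2s)):
        raise ValueError("NaN in S0/T2* map")
    if np.any(t2s <= 0):
        raise ValueError("negative or zero T2*")

    rng = np.random.default_rng(recipe.seed)
    n_t = recipe.n_timepoints
    tes = np.asarray(recipe.tes, dtype=float)
    te_mean = tes.mean()

    n_bold = truth.n_bold
    z_bold = _ar1(rng, n_t, n_bold, recipe.ar_coef)
    z_art = _ar1(rng, n_t, truth.n_artifacts, recipe.ar_coef)

    loadings = truth.latent_loadings.copy()
    jitter = rng.normal(0.0, 0.05, loadings.shape)
    loadings = loadings + jitter * (truth.latent_loadings != 0)
    active = np.ones(n_bold, dtype=bool)
    if recipe.n_active_bold is not None:
        if not 1 <= recipe.n_active_bold <= n_bold:
            raise ValueError("n_active_bold out of range")
        active[recipe.n_active_bold:] = False
        loadings[:, ~active] = 0.0

    private_sd = np.where(atlas.is_limbic, LIM_PRIVATE_SD, PARCEL_PRIVATE_SD)
    private = rng.normal(0.0, 1.0, (p, n_t)) * private_sd[:, None]
    frac_bold = recipe.pct_bold * recipe.bold_scale * (loadings @ z_bold.T + private)
    frac_art = recipe.pct_artifact * (truth.artifact_loadings @ z_art.T)

    # motion: smooth random walk, optional 1 mm single-frame spikes
    steps = np.concatenate([rng.normal(0.0, 0.02, (n_t, 3)),
                            rng.normal(0.0, 0.0004, (n_t, 3))], axis=1)
    motion = np.cumsum(steps, axis=0)
    spikes = set(int(f) for f in recipe.forced_spike_frames)
    if recipe.motion_spike_rate > 0:
        hits = np.nonzero(rng.random(n_t) < recipe.motion_spike_rate)[0]
        spikes.update(int(t) for t in hits if t > 0)
    spike_frames = np.array(sorted(spikes), dtype=int)
    if spike_frames.size:
        pat_s0 = rng.normal(0.0, 1.0, p)
        pat_r2 = rng.normal(0.0, 1.0, p)
        for t in spike_frames:
            if not 0 < t < n_t:
                raise ValueError(f"spike frame {t} outside run")
            motion[t, rng.integers(0, 3)] += 1.0
            frac_art[:, t] += recipe.spike_s0_amp * pat_s0
            frac_bold[:, t] += recipe.spike_r2_amp * pat_r2

    decay = s0[:, None] * np.exp(-tes[None, :] / t2s[:, None])  # (P, E)
    data = np.empty((tes.size, p, n_t))
    for e in range(tes.size):
        clean = decay[:, e][:, None] * (
            1.0 + (tes[e] / te_mean) * frac_bold + frac_art)
        data[e] = clean + rng.normal(0.0, recipe.noise_sd, (p, n_t))

    return MultiEchoRun(
        tes=tes, tr=recipe.tr, data=data, motion=motion,
        subject_id=f"sub-{recipe.seed}",
        ground_truth=SubjectGroundTruth(
            z_bold=z_bold, z_artifact=z_art, loadings=loadings,
            frac_bold=frac_bold, frac_artifact=frac_art,
            spike_frames=spike_frames, active_bold=active))


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    atlas: ToyAtlas
    truth: GroundTruth
    runs: list[MultiEchoRun]
    recipes: list[SubjectRecipe] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.runs)


def simulate_cohort(n_subjects: int, scenario: str = "merged",
                    master_seed: int = 0, *,
                    p_cortical: int = 102, p_subcortical: int = 14,
                    n_extra_bold: int = 0, n_artifacts: int = 6,
                    qc_violations: Optional[dict[int, set[str]]] = None,
                    **recipe_overrides) -> Cohort:
    """Simulate a cohort sharing one planted partition; subject seeds and
    loading jitter derive deterministically from ``master_seed``.

    ``qc_violations`` maps subject index -> subset of
    {"fd_dvars", "low_tsnr", "few_components"}; the named subjects are
    generated so that the corresponding exclusion rule genuinely fires:

    * ``fd_dvars`` — two forced motion spikes with signal transients;
    * ``low_tsnr`` — fluctuation amplitude x4 (median TSNR well below 50);
    * ``few_components`` — only the first 7 BOLD latents active, so the
      retained-component count stays below 10 even when the decomposition
      picks up an extra component or two of region-private fluctuation
      (requires a cohort configured with >= 10 BOLD latents).
    """
    if n_subjects < 2:
        raise ValueError("group statistics need at least 2 subjects")
    qc_violations = {int(k): set(v) for k, v in (qc_violations or {}).items()}
    atlas = make_atlas(p_cortical, p_subcortical, seed=master_seed)
    truth = make_ground_truth(atlas, scenario, seed=master_seed,
                              n_extra_bold=n_extra_bold, n_artifacts=n_artifacts)
    truth.qc_violations = qc_violations
    if any("few_components" in v for v in qc_violations.values()) and truth.n_bold < 10:
        raise ValueError(
            "few_components violation needs a cohort with >= 10 BOLD latents "
            "(raise n_extra_bold)")

    rng = np.random.default_rng(master_seed)
    seeds = rng.integers(0, 2 ** 31 - 1, n_subjects)
    runs, recipes = [], []
    for i in range(n_subjects):
        over = dict(recipe_overrides)
        v = qc_violations.get(i, set())
        if "fd_dvars" in v:
            n_t = over.get("n_timepoints", 200)
            over["forced_spike_frames"] = (n_t // 3, (2 * n_t) // 3)
        if "low_tsnr" in v:
            over["bold_scale"] = 4.0
        if "few_components" in v:
            over["n_active_bold"] = 7
        recipe = default_recipe(atlas, int(seeds[i]), **over)
        run = simulate_subject(atlas, truth, recipe)
        run.subject_id = f"sub-{i:02d}"
        runs.append(run)
        recipes.append(recipe)
    return Cohort(atlas=atlas, truth=truth, runs=runs, recipes=recipes)


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def write_fixture(cohort: Cohort, directory: str, mode: str = "tsv") -> dict:
    """Write a cohort to ``directory``; returns (and writes) the manifest.

    One file per echo per subject (TSV parcel x time, or a tiny 4-D NIfTI
    with 2x2 voxels per parcel when ``mode='nifti'``), a 6-column motion TSV
    per subject, the atlas table, and the ground-truth JSON.  The manifest
    (file name -> sha256) is written last, so a partial write leaves no
    manifest.
    """
    if mode not in ("tsv", "nifti"):
        raise ValueError("mode must be 'tsv' or 'nifti'")
    os.makedirs(directory, exist_ok=True)
    if not os.access(directory, os.W_OK):
        raise PermissionError(f"directory not writable: {directory}")
    written: list[str] = []

    atlas_path = os.path.join(directory, "atlas.tsv")
    cohort.atlas.table.to_csv(atlas_path, sep="\t", index=False)
    written.append("atlas.tsv")

    if mode == "nifti":
        import nibabel as nib
        labels = np.repeat(cohort.atlas.parcel_ids, 4).reshape(-1, 2, 2)
        labels = np.transpose(labels, (1, 2, 0)).astype(np.int32)
        nib.save(nib.Nifti1Image(labels, np.eye(4)),
                 os.path.join(directory, "atlas_labels.nii"))
        written.append("atlas_labels.nii")

    for i, run in enumerate(cohort.runs):
        for e in range(run.n_echoes):
            name = f"sub-{i:02d}_echo-{e + 1}." + ("tsv" if mode == "tsv" else "nii")
            path = os.path.join(directory, name)
            if mode == "tsv":
                df = pd.DataFrame(run.data[e], index=cohort.atlas.parcel_ids)
                df.index.name = "parcel_id"
                df.to_csv(path, sep="\t", float_format="%.10g")
            else:
                import nibabel as nib
                vol = np.repeat(run.data[e], 4, axis=0)  # (4P, T)
                vol = vol.reshape(-1, 2, 2, run.n_timepoints)
                vol = np.transpose(vol, (1, 2, 0, 3))
                nib.save(nib.Nifti1Image(vol.astype(np.float32), np.eye(4)), path)
            written.append(name)
        mname = f"sub-{i:02d}_motion.tsv"
        pd.DataFrame(run.motion, columns=["trans_x", "trans_y", "trans_z",
                                          "rot_x", "rot_y", "rot_z"]).to_csv(
            os.path.join(directory, mname), sep="\t", index=False,
            float_format="%.10g")
        written.append(mname)

    truth = cohort.truth
    truth_doc = {
        "scenario": truth.scenario,
        "latent_names": list(truth.latent_names),
        "latent_loadings": truth.latent_loadings.tolist(),
        "artifact_loadings": truth.artifact_loadings.tolist(),
        "bold_component_ids": truth.bold_component_ids.tolist(),
        "artifact_component_ids": truth.artifact_component_ids.tolist(),
        "planted_partition": truth.planted_partition.tolist(),
        "planted_lim_clusters": {str(k): v for k, v in truth.planted_lim_clusters.items()},
        "qc_violations": {str(k): sorted(v) for k, v in truth.qc_violations.items()},
        "tes": list(cohort.runs[0].tes),
        "tr": cohort.runs[0].tr,
    }
    with open(os.path.join(directory, "truth.json"), "w") as fh:
        json.dump(truth_doc, fh, indent=1)
    written.append("truth.json")

    manifest = {
        "mode": mode,
        "n_subjects": cohort.n_subjects,
        "n_echoes": cohort.runs[0].n_echoes,
        "files": {name: _sha256(os.path.join(directory, name)) for name in written},
    }
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def read_fixture(directory: str) -> Cohort:
    """Read a fixture back into a parcel-level cohort.

    NIfTI-mode fixtures are parcellated back to parcel x time by averaging the
    (identical) voxels of each parcel.  Generator internals are not persisted,
    so ``ground_truth`` on the runs is None; the cohort-level truth is
    restored from truth.json.
    """
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    table = pd.read_csv(os.path.join(directory, "atlas.tsv"), sep="\t")
    atlas = ToyAtlas(table=table)
    with open(os.path.join(directory, "truth.json")) as fh:
        doc = json.load(fh)
    truth = GroundTruth(
        scenario=doc["scenario"],
        latent_loadings=np.asarray(doc["latent_loadings"]),
        artifact_loadings=np.asarray(doc["artifact_loadings"]),
        bold_component_ids=np.asarray(doc["bold_component_ids"]),
        artifact_component_ids=np.asarray(doc["artifact_component_ids"]),
        planted_partition=np.asarray(doc["planted_partition"]),
        planted_lim_clusters={int(k): v for k, v in doc["planted_lim_clusters"].items()},
        qc_violations={int(k): set(v) for k, v in doc["qc_violations"].items()},
        latent_names=tuple(doc["latent_names"]),
    )
    tes, tr = np.asarray(doc["tes"]), float(doc["tr"])
    runs = []
    for i in range(manifest["n_subjects"]):
        echoes = []
        for e in range(manifest["n_echoes"]):
            if manifest["mode"] == "tsv":
                df = pd.read_csv(os.path.join(directory, f"sub-{i:02d}_echo-{e + 1}.tsv"),
                                 sep="\t", index_col="parcel_id")
                echoes.append(df.to_numpy())
            else:
                import nibabel as nib
                vol = np.asanyarray(nib.load(
                    os.path.join(directory, f"sub-{i:02d}_echo-{e + 1}.nii")).dataobj,
                    dtype=float)
                echoes.append(vol.mean(axis=(0, 1)))
        motion = pd.read_csv(os.path.join(directory, f"sub-{i:02d}_motion.tsv"),
                             sep="\t").to_numpy()
        runs.append(MultiEchoRun(tes=tes, tr=tr, data=np.stack(echoes),
                                 motion=motion, subject_id=f"sub-{i:02d}"))
    return Cohort(atlas=atlas, truth=truth, runs=runs)
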