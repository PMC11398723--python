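# Methods

## The generative model

Every downstream stage is validated against a synthetic multi-echo cohort
whose network structure is planted. One subject's per-echo signal at parcel
r, frame t is

    S_e(r, t) = S0_r · exp(−TE_e / T2*_r) · (1 + (TE_e / T̄E) · b(r, t) + a(r, t)) + ε

with ε white Gaussian thermal noise. The two fractional fluctuation
channels implement the physics that TE-dependence denoising exploits:

* **b(r, t)** — BOLD-like (ΔR2*) signal whose percent amplitude grows
  linearly with echo time. It is a mixture of latent network time courses
  through a parcel × latent loading matrix, plus a parcel-private residual.
* **a(r, t)** — artifact-like (ΔS0) signal whose percent amplitude is flat
  across echoes: six artifact latents with dense Gaussian loadings
  (sd 0.3).

**Latent time courses.** All latents are AR(1) with lag-1 coefficient 0.3,
driven by burst-like innovations: standard normal draws amplified fivefold
with probability 0.12, standardised to unit variance. The bursts give the
event-like, heavy-tailed temporal structure characteristic of fMRI ICA
component time courses; they are also what makes the sources identifiable —
with Gaussian (or even Laplace) innovations at 200 frames, ICA returns
near-arbitrary rotations of the source subspace and the per-component
TE-dependence scores become meaningless.

**Network structure.** The toy atlas carries the 17 cortical network labels
(VIS_A … TPar, LIM_A, LIM_B) and 7 subcortical structures, as bilateral
pairs; the default is 102 cortical + 14 subcortical = 116 parcels. Eight
BOLD latents correspond to network groups (VIS, SMN, DAN, SAL, FPN, DN_A,
DN_B + TPar, DN_C); parcels load 0.6 on their group latent. The three DN
latents cross-load at 0.25 onto each other's parcels, so the DN behaves as
one community with three subnetworks. Subcortical structures attach to the
system they ride with physiologically: basal ganglia to the somatomotor
latent (0.5); hippocampus, amygdala, accumbens and basal forebrain to DN
latents (0.35–0.45), each with a secondary DN loading (0.2) so they tie
into the DN core rather than forming a satellite of a single subnetwork.

**The scenario switch.** In `merged` cohorts, limbic parcels are split into
three planted sub-clusters loading 0.6 on DN_A, DN_B and DN_C respectively
(private residual sd 0.2); in `distinct` cohorts they load 0.6 on a private
limbic latent instead. This is the hypothesis under test expressed as a
generative truth: community detection and clustering are asked to recover
whichever structure was planted.

**Susceptibility dropout.** Ventral limbic parcels get short T2*
(20–30 ms vs 45–60 ms) and low S0 (600–700 vs ~1000), strictly below the
non-dropout median, emulating signal loss near the nasal airways. This is
what makes the multi- minus single-echo TSNR difference map positive in
exactly those parcels.

**Motion and QC violations.** Motion parameters are smooth random walks
(typical FD ≈ 0.1 mm). A spike displaces one translation axis by 1 mm for
one frame and injects a signal transient with a dominant TE-dependent part
(fractional amplitude 0.05) plus a ΔS0 part (0.02). The TE-dependent part
models position-dependent susceptibility effects; it matters because the
exclusion rule evaluates DVARS on the *denoised* series — a purely
ΔS0-like transient would be removed by the κ/ρ classifier and the rule
could never fire. Planted violations: `fd_dvars` forces two spikes;
`low_tsnr` scales fluctuation amplitude ×4 (median TSNR ≈ 15–20, far below
the 50 threshold); `few_components` activates only 7 of ≥ 12 BOLD latents,
so the retained count lands at 7–9 — reliably below the 10-component floor
even when the decomposition picks up an extra component or two of
region-private fluctuation.

## Key parameters

| parameter | default | unit | why |
|---|---|---|---|
| TEs | 13.7 / 30 / 47 | ms | the emulated three-echo acquisition |
| TR | 3.0 | s | idem |
| frames | 200 | volumes | one 10-minute run at TR 3 s |
| thermal noise sd | 2.5 | signal units | combined-series TSNR ≈ 50–70, realistic for 3 T |
| BOLD fractional amplitude | 0.02 | — per unit latent | ~1.3 % signal change at the mean TE |
| artifact fractional amplitude | 0.02 | — | artifact variance comparable to BOLD, so denoising is consequential |
| AR(1) coefficient | 0.3 | — | mild autocorrelation at TR 3 s |
| network loading / limbic-on-DN loading | 0.6 | — | strong enough for recovery, weak enough to be nontrivial |
| parcel-private residual sd | 0.3 (0.2 limbic) | — | keeps within-network correlations < 1 and planted limbic-latent correlations > 0.9 |
| subject loading jitter sd | 0.05 | — | between-subject variability |

## Pipeline numerics

* **Decay fit** — log-linear least squares on time-averaged echo images;
  T2* clipped to [5, 150] ms; non-positive echo means flag the region as
  failed (simple-average fallback in combination).
* **Component count K** — eigenvalues of the combined-series covariance
  above a Marchenko–Pastur noise edge `σ²(1 + √(R/T))²`, with σ² estimated
  by fixed-point iteration on the eigenvalue tail. A fixed
  explained-variance quota (e.g. 95 %) was rejected: broadband
  region-private variance forces K far past the source count and the split
  sources classify at chance.
* **κ/ρ** — per-echo percent-signal amplitudes regressed on the component
  time course; F statistics of the through-origin ΔR2* fit and the
  constant ΔS0 fit, averaged over regions with squared-coefficient weights.
  Ties (κ = ρ) classify non-BOLD; the κ/ρ ratio threshold is exposed.
  Zero-variance components score κ = ρ = 0 with a warning.
* **Fisher z** — `Z = arctanh(R)·√(df−3)` with |R| clipped to 1 − 1e−12;
  the diagonal carries no information and is stored as 0, excluded from all
  statistics. df is the subject's retained-component count.
* **Community detection** — negative edges are thresholded to 0 for both
  algorithms (random-walk semantics require nonnegative weights; a shared
  graph keeps the two partitions comparable). Louvain: strict-gain local
  moves, lowest module id wins ties, seeded sweep orders, 10 restarts, Q
  computed with γ multiplying the degree-product null term. Map equation:
  two-level codelength on stationary visit rates; disconnected graphs
  evaluate with zero exit terms and a warning; the one-module and
  all-singleton partitions are always scored as candidates.
* **Ward** — scipy linkage on the similarity-matrix rows; reported merge
  heights are the error-sum-of-squares increments (scipy's distances
  squared, halved). The cut level k is explicit; the height-gap table
  supports choosing it, and no automatic k selection is applied.
* **Eta squared** — pairwise-mean / grand-mean form; bounded in [0, 1]
  because the pairwise mean minimises each squared deviation term.
  Self-similarity columns of the profile rows are retained.
* **Masks** — Bonferroni is a literal `p < α/n` comprehension; the top-10 %
  rule keeps `round(fraction·n)` parcels (half-away-from-zero; 1,032 → 103)
  by |value| with ties broken by parcel id. Zero-variance parcels are
  flagged undefined and never masked.
* **DVARS** — RMS frame difference standardised by its run median, so
  "DVARS > 1" means "above a typical frame"; the FD/DVARS conjunction is
  evaluated frame-wise by default (run-wise is exposed as configuration).

## Problem sizes

Tests and the acceptance script run 20-subject cohorts (116 parcels,
200 frames, 3 echoes) for the merged/distinct mechanism, denoising and
clustering checks; a 16-subject cohort with three planted violators for QC;
exhaustive partition enumeration on ≤ 8-node graphs (Bell(8) = 4,140
partitions); and 200 null replicates of 20 × 500 for the family-wise error
calibration. The full suite completes in well under a minute on one CPU.

## What passing does and does not show

The generator produces parcel-level data with block covariance, exact
mono-exponential decay, and exactly TE-linear BOLD scaling. It does not
model hemodynamic response shapes, spatial autocorrelation within parcels,
physiological (cardiac/respiratory) waveforms, field inhomogeneity beyond
the static dropout maps, multi-band reconstruction artifacts, or
between-site variability. Recovery of the planted structure therefore
demonstrates that the pipeline's inferential chain is correct — not that it
would reach the same decisions on arbitrary real data, where component
counts are larger, TE dependence is approximate, and communities are less
block-like. Voxel-level processing exists only as a thin NIfTI round-trip
(2 × 2 voxels per parcel) to exercise I/O.

Two deliberate departures from the obvious defaults, both argued above:
burst-like rather than Gaussian latent innovations (ICA identifiability),
and noise-floor rather than variance-quota component selection. The
remaining free choices — bilateral subcortical pairs, frame-wise
conjunction, median-standardised DVARS, retained self-columns in eta
squared — are configuration-exposed and documented where they are defined.
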