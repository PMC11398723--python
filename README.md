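# ednet

Multi-echo fMRI network analysis at desk scale: is the "limbic network" a
distinct system, or part of an extended default network?

Resting-state parcellations classically assign the temporal poles, ventral
anterior temporal lobes, and orbitofrontal cortex to a standalone "limbic
network" (LIM_A/LIM_B). These regions sit next to air-filled cavities, have
short T2*, and therefore carry some of the worst signal in single-echo fMRI —
so their segregation into a private network may reflect shared signal dropout
rather than shared function. Multi-echo acquisition plus TE-dependence
denoising restores signal in exactly these regions and makes the question
testable: do data-driven community assignments place limbic parcels with the
default network (DN)?

`ednet` implements that full analysis chain as a tested Python library, and
pairs it with a synthetic multi-echo cohort generator in which the answer is
*planted* — so every stage can be validated against ground truth:

1. **signal quality** (`ednet.signal_quality`) — TSNR, mono-exponential decay
   fits `S(TE) = S0 · exp(−TE/T2*)`, TSNR-optimal echo combination with
   weights `w_e ∝ TE_e · exp(−TE_e/T2*)`, multi- vs single-echo difference
   maps.
2. **TE-dependence denoising** (`ednet.te_denoise`) — ICA of the combined
   series; per-component per-echo amplitudes β_e fitted against the ΔR2*
   model (β_e ∝ TE_e, BOLD-like, summarised by κ) and the ΔS0 model
   (β_e constant, artifact-like, summarised by ρ); components with κ > ρ are
   retained. The retained coefficient matrix is the MEFC (multi-echo
   functional connectivity) data.
3. **QC** (`ednet.qc`) — framewise displacement (Power convention, 50 mm
   sphere), median-standardised DVARS, and four exclusion rules, including
   the conjunctive "FD > 0.50 mm *and* DVARS > 1 on the same frame".
4. **connectivity** (`ednet.connectivity`) — RSFC as the product-moment
   correlation of MEFC coefficients across parcels, Fisher-transformed with
   the subject's component count as degrees of freedom:
   `Z = arctanh(R) · sqrt(df − 3)`.
5. **community detection** (`ednet.community`) — Louvain maximisation of
   `Q = (1/l) Σ_ij [w_ij − γ k_i k_j / l] δ(m_i, m_j)` with resolution γ and
   warm starts from 7-network labels, plus a two-level map-equation
   (Infomap-style) partitioner; both on the group-mean matrix.
6. **subnetwork clustering** (`ednet.clustering`) — eta-squared similarity of
   limbic parcels' whole-brain connectivity profiles, Ward agglomeration
   (merge heights = error-sum-of-squares increases), explicit dendrogram cuts
   with height-gap diagnostics.
7. **statistical maps** (`ednet.stat_maps`) — mass-univariate one-sample and
   paired t maps, Bonferroni masks (`p < α/n`), absolute top-10% masks, and
   17-network + subcortical profiles.

The generator (`ednet.synthetic`) plants a block-covariance network over a
toy atlas (17 cortical network labels + 7 subcortical structures), with a
scenario switch: in **merged** cohorts, limbic parcels load on DN latents; in
**distinct** cohorts they load on a private limbic latent. It also plants
ΔR2*- vs ΔS0-like components, susceptibility dropout (short T2* ventrally),
motion spikes, and per-subject QC violations.

## Worked example

```python
import numpy as np
import ednet

cohort = ednet.simulate_cohort(20, scenario="merged", master_seed=7)
results = [ednet.process_subject(run, seed=100 + i,
                                 parcel_ids=cohort.atlas.parcel_ids)
           for i, run in enumerate(cohort.runs)]

dfs = [r.mefc.df for r in results]
print(f"retained BOLD components (df): min {min(dfs)}, max {max(dfs)}")

# the toy cohort plants 8 BOLD sources (real data yields dozens), so the
# component-count floor is scaled to the toy source count
thresholds = ednet.Thresholds(min_components=6)
kept, excluded = ednet.apply_exclusions([r.qc_record for r in results],
                                        thresholds)
print(f"QC: kept {len(kept)} / {len(results)} subjects")

group = ednet.group_mean_matrix([r.rsfc for r in results])
part = ednet.louvain(group.z, gamma=1.0,
                     init_labels=ednet.yeo7_init(cohort.atlas), seed=5)
lim = np.nonzero(cohort.atlas.is_limbic)[0]
dn = np.isin(cohort.atlas.network_labels, ("DN_A", "DN_B", "DN_C"))
dn_modules = set(part.assignment[dn])
frac = np.mean([part.assignment[i] in dn_modules for i in lim])
print(f"Louvain (gamma=1): Q = {part.q:.3f}, {part.n_modules} modules, "
      f"{100 * frac:.0f}% of limbic parcels in the default-network module")

lim_ids = cohort.atlas.limbic_parcels()
sim = ednet.group_similarity([r.rsfc for r in results], lim_ids)
solution = ednet.ward_cluster(sim)
labels = ednet.cut_dendrogram(solution, 3)
gaps = ednet.height_gaps(solution)
print(f"Ward clustering: largest merge-height gap at "
      f"k = {max(gaps, key=gaps.get)}, "
      f"cluster sizes {np.bincount(labels)[1:].tolist()}")
```

Output:

```
retained BOLD components (df): min 8, max 10
QC: kept 20 / 20 subjects
Louvain (gamma=1): Q = 0.744, 6 modules, 100% of limbic parcels in the default-network module
Ward clustering: largest merge-height gap at k = 3, cluster sizes [4, 4, 4]
```

Reading the output: every subject retained 8–10 BOLD-like components (the
cohort plants 8 BOLD and 6 artifact sources); nobody tripped a QC rule; on
the group matrix, Louvain found six modules and placed every limbic parcel in
the module containing the DN parcels — the planted "merged" truth; and the
limbic similarity dendrogram supports exactly the three planted sub-clusters,
each attached to one DN subnetwork. Running the same script on a
`scenario="distinct"` cohort instead leaves the limbic parcels in a module of
their own.

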