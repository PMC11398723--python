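"""End-to-end glue: run one subject (or a cohort) through combination,
TE-dependence denoising, QC metrics, and coefficient-based connectivity."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import connectivity, qc, signal_quality, te_denoise
from .signal_quality import MultiEchoRun
from .synthetic import Cohort


@dataclass
class SubjectResult:
    run: MultiEchoRun
    combined: np.ndarray
    components: te_denoise.ComponentSet
    mefc: Optional[te_denoise.MEFCData]
    denoised: Optional[np.ndarray]
    rsfc: Optional[connectivity.RSFCMatrix]
    qc_record: Optional[qc.QCRecord]


def process_subject(run: MultiEchoRun, seed: int = 0,
                    n_components: Optional[int] = None,
                    parcel_ids: Optional[np.ndarray] = None) -> SubjectResult:
    """Combine echoes, denoise, and build the subject RSFC matrix.

    Stages that need retained BOLD components (MEFC, reconstruction, RSFC,
    QC record) are None when classification retains nothing, or when the
    retained count is too small for the Fisher z transform (df <= 3).
    """
    fit = signal_quality.fit_decay(run)
    combined = signal_quality.optimal_combine(run, fit)
    comps = te_denoise.denoise_run(run, combined, seed=seed,
                                   n_components=n_components)
    n_bold = int((comps.labels == "BOLD").sum())
    mefc = denoised = rsfc = record = None
    if n_bold >= 1:
        mefc = te_denoise.build_mefc(comps, subject_id=run.subject_id)
        denoised = te_denoise.reconstruct_denoised(comps)
        record = qc.qc_record(run, denoised, n_bold)
        if mefc.df > 3:
            rsfc = connectivity.rsfc_from_mefc(mefc, parcel_ids=parcel_ids,
                                               subject_id=run.subject_id)
    return SubjectResult(run=run, combined=combined, components=comps,
                         mefc=mefc, denoised=denoised, rsfc=rsfc,
                         qc_record=record)


def process_cohort(cohort: Cohort, seed: int = 0,
                   n_components: Optional[int] = None) -> list[SubjectResult]:
    """Process every subject; per-subject seeds derive from ``seed``."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, cohort.n_subjects)
    return [process_subject(run, seed=int(s), n_components=n_components,
                            parcel_ids=cohort.atlas.parcel_ids)
            for run, s in zip(cohort.runs, seeds)]
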