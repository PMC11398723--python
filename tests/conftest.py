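"""Shared cohorts and graph fixtures.

The expensive pieces — three fully processed 20/16-subject cohorts — are
session-scoped so every test (including the acceptance suite) reuses the
same simulated data.
"""

import itertools

import numpy as np
import pytest

import ednet


MERGED_SEED = 7
DISTINCT_SEED = 7
QC_SEED = 11


@pytest.fixture(scope="session")
def merged_cohort():
    return ednet.simulate_cohort(20, "merged", MERGED_SEED)


@pytest.fixture(scope="session")
def merged_results(merged_cohort):
    return [ednet.process_subject(run, seed=100 + i,
                                  parcel_ids=merged_cohort.atlas.parcel_ids)
            for i, run in enumerate(merged_cohort.runs)]


@pytest.fixture(scope="session")
def merged_group_z(merged_cohort, merged_results):
    return ednet.group_mean_matrix([r.rsfc for r in merged_results])


@pytest.fixture(scope="session")
def distinct_cohort():
    return ednet.simulate_cohort(20, "distinct", DISTINCT_SEED)


@pytest.fixture(scope="session")
def distinct_results(distinct_cohort):
    return [ednet.process_subject(run, seed=300 + i,
                                  parcel_ids=distinct_cohort.atlas.parcel_ids)
            for i, run in enumerate(distinct_cohort.runs)]


@pytest.fixture(scope="session")
def qc_cohort():
    violations = {3: {"fd_dvars"}, 9: {"low_tsnr"}, 14: {"few_components"}}
    return ednet.simulate_cohort(16, "merged", QC_SEED, n_extra_bold=4,
                                 qc_violations=violations)


@pytest.fixture(scope="session")
def qc_records(qc_cohort):
    return [ednet.process_subject(run, seed=200 + i,
                                  parcel_ids=qc_cohort.atlas.parcel_ids).qc_record
            for i, run in enumerate(qc_cohort.runs)]


def small_graph_suite() -> dict[str, np.ndarray]:
    """Weighted graphs with <= 8 nodes for exhaustive-enumeration checks."""
    graphs = {}
    w = np.zeros((6, 6))
    for a, b in itertools.combinations(range(3), 2):
        w[a, b] = w[b, a] = 1.0
    for a, b in itertools.combinations(range(3, 6), 2):
        w[a, b] = w[b, a] = 1.0
    graphs["two_cliques"] = w.copy()
    w = w.copy()
    w[2, 3] = w[3, 2] = 0.1
    graphs["two_cliques_bridge"] = w

    ring = np.zeros((8, 8))
    for i in range(8):
        ring[i, (i + 1) % 8] = ring[(i + 1) % 8, i] = 1.0
    graphs["ring8"] = ring

    blocks = np.zeros((8, 8))
    for a, b in itertools.combinations(range(4), 2):
        blocks[a, b] = blocks[b, a] = 2.0
    for a, b in itertools.combinations(range(4, 8), 2):
        blocks[a, b] = blocks[b, a] = 1.5
    blocks[0, 4] = blocks[4, 0] = 0.3
    blocks[1, 5] = blocks[5, 1] = 0.2
    graphs["weighted_blocks"] = blocks

    star = np.zeros((7, 7))
    star[0, 1:] = star[1:, 0] = 1.0
    graphs["star7"] = star

    for s in range(2):
        rng = np.random.default_rng(10 + s)
        a = rng.random((7, 7))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        graphs[f"random{s}"] = np.where(a > 0.55, a, 0.0)
    return graphs


@pytest.fixture(scope="session")
def small_graphs():
    return small_graph_suite()


def three_clique_graph() -> tuple[np.ndarray, np.ndarray]:
    """12-node graph of 3 planted cliques with weak bridges, plus truth."""
    w = np.zeros((12, 12))
    for c in range(3):
        for a, b in itertools.combinations(range(4 * c, 4 * c + 4), 2):
            w[a, b] = w[b, a] = 1.0
    for a, b in ((3, 4), (7, 8), (11, 0)):
        w[a, b] = w[b, a] = 0.2
    truth = np.repeat([1, 2, 3], 4)
    return w, truth


@pytest.fixture(scope="session")
def planted_cliques():
    return three_clique_graph()
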