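"""Graph community detection on connectivity matrices.

Two complementary data-driven parcel-to-network assignments:

* Louvain modularity maximisation.  The quality of a partition is

      Q = (1/l) * sum_ij [ w_ij - gamma * k_i * k_j / l ] * delta(m_i, m_j)

  with ``l`` the total weight, ``k_i`` the weighted degree, and the
  resolution parameter ``gamma`` multiplying the degree-product null term
  (gamma > 1 favours more, smaller modules).  The search is the standard
  greedy two-phase scheme (local node moves, then aggregation), warm-started
  from prior labels when given, with seeded sweep orders and several
  restarts.

* The two-level map equation.  A partition is scored by the expected
  per-step description length of a random walk under a two-level codebook,

      L = q * H(exit) + sum_m p_m * H(within_m)

  using stationary visit rates of the weighted walk; the Infomap-style
  search greedily minimises L.

Negative connectivity edges are thresholded to zero before either search:
random-walk semantics require nonnegative weights, and using the same graph
for both algorithms keeps their partitions comparable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.metrics import adjusted_rand_score

logger = logging.getLogger("ednet")

_EPS = 1e-12


@dataclass
class Partition:
    """Parcel -> module assignment with the objective that produced it.

    Module ids are contiguous from 1 in order of first appearance.  ``q``
    (Louvain) and ``codelength`` (map equation) are recomputable from the
    assignment and the matrix.
    """

    assignment: np.ndarray
    method: str
    seed: int
    gamma: Optional[float] = None
    q: Optional[float] = None
    codelength: Optional[float] = None
    init_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.assignment = _relabel(np.asarray(self.assignment))

    @property
    def n_modules(self) -> int:
        return int(self.assignment.max())

    def members(self, module: int) -> np.ndarray:
        return np.nonzero(self.assignment == module)[0]


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Contiguous module ids from 1, ordered by first occurrence."""
    out = np.empty(labels.size, dtype=int)
    seen: dict = {}
    for i, lab in enumerate(labels):
        if lab not in seen:
            seen[lab] = len(seen) + 1
        out[i] = seen[lab]
    return out


def _check_square_symmetric(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if np.any(~np.isfinite(w)):
        raise ValueError("weight matrix must be finite")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    return w


def threshold_negative(w: np.ndarray) -> np.ndarray:
    """Zero out negative edges (logged); community searches require it."""
    w = _check_square_symmetric(w)
    n_neg = int((w < 0).sum())
    if n_neg:
        logger.info("thresholding %d negative edges to 0", n_neg)
    return np.where(w > 0, w, 0.0)


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------

def modularity_q(w: np.ndarray, assignment: np.ndarray, gamma: float = 1.0) -> float:
    """Generalized modularity of a partition; exact arithmetic on the inputs.

    Self-loop weight (diagonal) counts once toward both the within-module
    weight and the degree, which keeps Q invariant under Louvain-style graph
    aggregation.
    """
    w = _check_square_symmetric(w)
    assignment = np.asarray(assignment)
    if assignment.size != w.shape[0]:
        raise ValueError("one module label per node required")
    l_tot = w.sum()
    if l_tot <= 0:
        raise ValueError("total weight must be positive")
    k = w.sum(axis=1)
    q = 0.0
    for m in np.unique(assignment):
        idx = assignment == m
        q += w[np.ix_(idx, idx)].sum() - gamma * k[idx].sum() ** 2 / l_tot
    return float(q / l_tot)


def _local_move_q(w: np.ndarray, labels: np.ndarray, gamma: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """One phase of greedy node moves; returns (labels, number of moves).

    A node moves only on a strictly positive modularity gain; ties among
    best targets go to the lowest module id.
    """
    n = w.shape[0]
    l_tot = w.sum()
    k = w.sum(axis=1)
    labels = labels.copy()
    n_comm = labels.max() + 1
    sigma = np.bincount(labels, weights=k, minlength=n_comm)
    total_moves = 0
    while True:
        moved = 0
        for i in rng.permutation(n):
            a = labels[i]
            w_ic = np.bincount(labels, weights=w[i], minlength=n_comm)
            w_ic[a] -= w[i, i]  # self-loop is not a link to the community
            sigma_a = sigma[a] - k[i]
            # gain of moving i into community c, relative to staying in a
            gain = 2.0 * (w_ic - w_ic[a]) - 2.0 * gamma * k[i] * (sigma - k[i] * (np.arange(n_comm) == a) - sigma_a) / l_tot
            gain[a] = 0.0
            b = int(np.argmax(gain))  # argmax takes the lowest index on ties
            if gain[b] > _EPS and b != a:
                labels[i] = b
                sigma[a] -= k[i]
                sigma[b] += k[i]
                moved += 1
        total_moves += moved
        if moved == 0:
            break
    return labels, total_moves


def _aggregate(w: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, idx = np.unique(labels, return_inverse=True)
    m = uniq.size
    agg = np.zeros((m, m))
    np.add.at(agg, (idx[:, None].repeat(w.shape[0], 1), idx[None, :].repeat(w.shape[0], 0)), w)
    return agg, idx


def _louvain_once(w: np.ndarray, gamma: float, init: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    mapping = np.arange(w.shape[0])
    wc = w
    labels_c = _relabel(init) - 1
    for _ in range(64):  # level cap; toy graphs converge in a few levels
        labels_c, n_moves = _local_move_q(wc, labels_c, gamma, rng)
        wc_new, idx = _aggregate(wc, labels_c)
        reduced = wc_new.shape[0] < wc.shape[0]
        mapping = idx[mapping]
        if n_moves == 0 and not reduced:
            break
        wc = wc_new
        labels_c = np.arange(wc.shape[0])
    return mapping


def louvain(w: np.ndarray, gamma: float = 1.0,
            init_labels: Optional[np.ndarray] = None, seed: int = 0,
            n_restarts: int = 10) -> Partition:
    """Greedy two-phase Louvain from the given initial assignment.

    Deterministic given ``seed`` (node sweep orders are seeded); the best of
    ``n_restarts`` sweep orders is returned, so the output Q is never below
    the Q of the initial assignment.
    """
    w = threshold_negative(w)
    n = w.shape[0]
    if init_labels is None:
        init = np.arange(n)
    else:
        init = np.asarray(init_labels)
        if init.size != n:
            raise ValueError("init_labels length must match the node count")
    best_labels, best_q = None, -np.inf
    for child in np.random.SeedSequence(seed).spawn(n_restarts):
        labels = _louvain_once(w, gamma, init, np.random.default_rng(child))
        q = modularity_q(w, labels, gamma)
        if q > best_q + _EPS:
            best_labels, best_q = labels, q
    return Partition(assignment=best_labels, method="louvain", seed=seed,
                     gamma=gamma, q=best_q,
                     init_labels=None if init_labels is None else np.asarray(init_labels))


# ---------------------------------------------------------------------------
# map equation
# ---------------------------------------------------------------------------

def _plogp(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log2(x[pos])
    return out


def map_equation_codelength(w: np.ndarray, assignment: np.ndarray) -> float:
    """Two-level map equation L (bits/step) for a partition.

    ``L = q * H(exit) + sum_m p_m * H(within_m)`` with stationary visit rates
    ``p_i = k_i / l`` of the weighted random walk and module exit rates
    proportional to inter-module weight.  Nonnegative weights required;
    disconnected graphs evaluate fine (zero exit terms) but emit a warning.
    Invariant to rescaling all weights.
    """
    w = _check_square_symmetric(w)
    if np.any(w < 0):
        raise ValueError("map equation requires nonnegative weights")
    l_tot = w.sum()
    if l_tot <= 0:
        raise ValueError("total weight must be positive")
    n_comp = connected_components((w > 0).astype(int), directed=False)[0]
    if n_comp > 1:
        warnings.warn(f"graph has {n_comp} connected components; codelength "
                      "computed on the union", RuntimeWarning, stacklevel=2)
    assignment = np.asarray(assignment)
    p = w.sum(axis=1) / l_tot
    total = 0.0
    q_exit = []
    for m in np.unique(assignment):
        idx = assignment == m
        within = w[np.ix_(idx, idx)].sum() / l_tot
        p_m = p[idx].sum()
        q_m = p_m - within  # exit probability mass of module m
        q_exit.append(q_m)
        denom = q_m + p_m
        if denom > 0:
            h = -(_plogp(np.append(p[idx], q_m) / denom)).sum()
            total += denom * h
    q_exit = np.asarray(q_exit)
    q_tot = q_exit.sum()
    if q_tot > 0:
        total += q_tot * float(-(_plogp(q_exit / q_tot)).sum())
    return float(total)


def _codelength_from_aggregates(q_arr: np.ndarray, p_arr: np.ndarray,
                                node_plogp: float) -> float:
    """Expanded-form L from per-module exit mass and visit mass.

    ``L = plogp(sum q) - 2*sum plogp(q_m) - sum_i plogp(p_i)
         + sum_m plogp(q_m + p_m)``; ``node_plogp`` caches the constant
    node term.
    """
    q_tot = q_arr.sum()
    return float(_plogp(np.array([q_tot]))[0] - 2.0 * _plogp(q_arr).sum()
                 - node_plogp + _plogp(q_arr + p_arr).sum())


def _infomap_once(w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = w.shape[0]
    l_tot = w.sum()
    p = w.sum(axis=1) / l_tot
    node_plogp = float(_plogp(p).sum())
    labels = np.arange(n)
    # per-module aggregates
    p_m = p.copy()
    within = np.diag(w).copy() / l_tot
    k_m = p.copy()

    def q_arr():
        return k_m - within

    def move_delta(i, a, b, w_ia, w_ib):
        qa, qb = k_m[a] - within[a], k_m[b] - within[b]
        pa, pb = p_m[a], p_m[b]
        qa2 = (k_m[a] - p[i]) - (within[a] - (2 * w_ia + w[i, i] / l_tot))
        qb2 = (k_m[b] + p[i]) - (within[b] + (2 * w_ib + w[i, i] / l_tot))
        pa2, pb2 = pa - p[i], pb + p[i]
        q_tot = (k_m - within).sum()
        q_tot2 = q_tot - qa - qb + qa2 + qb2
        d = (_plogp(np.array([q_tot2]))[0] - _plogp(np.array([q_tot]))[0]
             - 2 * (_plogp(np.array([qa2, qb2])).sum() - _plogp(np.array([qa, qb])).sum())
             + _plogp(np.array([qa2 + pa2, qb2 + pb2])).sum()
             - _plogp(np.array([qa + pa, qb + pb])).sum())
        return d

    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            a = labels[i]
            w_ic = np.bincount(labels, weights=w[i], minlength=p_m.size) / l_tot
            w_ic[a] -= w[i, i] / l_tot
            candidates = np.unique(labels[w[i] > 0])
            best_b, best_d = a, -_EPS
            for b in sorted(int(c) for c in candidates):
                if b == a:
                    continue
                d = move_delta(i, a, b, w_ic[a], w_ic[b])
                if d < best_d - _EPS:
                    best_d, best_b = d, b
            if best_b != a and best_d < -_EPS:
                b = best_b
                # apply aggregate updates
                w_ia, w_ib = w_ic[a], w_ic[b]
                k_m[a] -= p[i]
                k_m[b] += p[i]
                within[a] -= 2 * w_ia + w[i, i] / l_tot
                within[b] += 2 * w_ib + w[i, i] / l_tot
                p_m[a] -= p[i]
                p_m[b] += p[i]
                labels[i] = b
                improved = True
    return labels


def infomap_partition(w: np.ndarray, seed: int = 0,
                      n_restarts: int = 5) -> Partition:
    """Louvain-style greedy search minimising the two-level map equation.

    Deterministic given ``seed``.  The one-module and all-singleton
    partitions are always evaluated as candidates, so the returned
    codelength never exceeds either.
    """
    w = threshold_negative(w)
    n = w.shape[0]
    candidates = [np.zeros(n, dtype=int), np.arange(n)]
    for child in np.random.SeedSequence(seed).spawn(n_restarts):
        candidates.append(_infomap_once(w, np.random.default_rng(child)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        scored = [(map_equation_codelength(w, c), i) for i, c in enumerate(candidates)]
    best_l, best_i = min(scored)
    n_comp = connected_components((w > 0).astype(int), directed=False)[0]
    if n_comp > 1:
        logger.warning("graph has %d components; map equation computed on the union",
                       n_comp)
    return Partition(assignment=candidates[best_i], method="infomap", seed=seed,
                     codelength=best_l)


def compare_partitions(a: np.ndarray | Partition, b: np.ndarray | Partition) -> float:
    """Adjusted Rand index between two assignments of the same parcel set."""
    la = a.assignment if isinstance(a, Partition) else np.asarray(a)
    lb = b.assignment if isinstance(b, Partition) else np.asarray(b)
    if la.size != lb.size:
        raise ValueError("partitions cover different parcel sets")
    return float(adjusted_rand_score(la, lb))
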