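"""Cluster-pruned range retrieval over a slice database.

The database is grouped into exemplar-centred clusters by affinity
propagation on the pairwise similarity matrix (similarity = -distance).
Each cluster stores its radius, the largest centre-to-member distance.
A range query with sphere (query, r) then proceeds in two phases:

1. keep only the *affected clusters*, those whose ball can intersect the
   retrieval sphere: d(centre, query) <= R_j + r;
2. scan only their members, admitting those with d(member, query) <= r.

For a metric distance the triangle inequality makes this exact: a member
of a discarded cluster satisfies d(member, query) >= d(centre, query) -
R_j > r. A learned distance need not be metric, so pruned-vs-sequential
recall is a measurement, not a guarantee; ``retrieve_sequential`` is the
oracle either way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, List, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

Distance = Callable[[int, int], float]


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class APConfig:
    preference: float | str = "median"
    damping: float = 0.5
    max_iter: int = 200
    convergence_window: int = 15
    seed: int = 0

    def validate(self) -> None:
        if not (0.5 <= self.damping < 1.0):
            raise ValidationError("damping must be in [0.5, 1)")
        if not (self.max_iter >= self.convergence_window >= 1):
            raise ValidationError("need max_iter >= convergence_window >= 1")


@dataclass
class APResult:
    exemplars: np.ndarray       # exemplar index per point
    exemplar_set: np.ndarray    # sorted unique exemplar indices
    n_iter: int
    converged: bool


def ap_cluster(similarity: np.ndarray, config: APConfig = APConfig()) -> APResult:
    """Affinity propagation on a square similarity matrix.

    Iterates the responsibility and availability message updates with
    damping; availabilities start at zero so responsibilities can be
    computed in the first sweep. Diagonal entries are overwritten with
    the preference (self-similarity), which controls how many exemplars
    emerge. Stops when the exemplar set is stable for
    ``convergence_window`` iterations; on non-convergence the last
    assignment is returned with ``converged=False``.
    """
    config.validate()
    s = np.array(similarity, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValidationError(f"similarity must be square, got {s.shape}")
    n = s.shape[0]
    if n == 1:
        return APResult(np.zeros(1, int), np.zeros(1, int), 0, True)

    pref = float(np.median(s[~np.eye(n, dtype=bool)])) \
        if config.preference == "median" else float(config.preference)
    np.fill_diagonal(s, pref)
    # tiny seeded jitter breaks exact ties between identical points
    rng = np.random.default_rng(config.seed)
    s = s + 1e-12 * rng.standard_normal((n, n)) * (np.abs(s).max() + 1e-300)

    lam = config.damping
    r = np.zeros((n, n))
    a = np.zeros((n, n))
    idx = np.arange(n)
    last = None
    stable = 0
    it = 0
    for it in range(1, config.max_iter + 1):
        # responsibilities: r(i,k) <- s(i,k) - max_{k' != k} [a(i,k') + s(i,k')]
        as_ = a + s
        first = as_.argmax(axis=1)
        max1 = as_[idx, first]
        as_[idx, first] = -np.inf
        max2 = as_.max(axis=1)
        as_[idx, first] = max1
        rnew = s - max1[:, None]
        rnew[idx, first] = s[idx, first] - max2
        r = lam * r + (1 - lam) * rnew

        # availabilities: a(i,k) <- min(0, r(k,k) + sum_{i' not in {i,k}} max(0, r(i',k)))
        rp = np.maximum(r, 0.0)
        np.fill_diagonal(rp, r.diagonal())
        col = rp.sum(axis=0)
        anew = np.minimum(0.0, col[None, :] - rp)
        anew[idx, idx] = col - r.diagonal()
        a = lam * a + (1 - lam) * anew

        exemplars = ((a + r).diagonal() > 0).nonzero()[0]
        key = exemplars.tobytes()
        if last is not None and key == last and len(exemplars):
            stable += 1
            if stable >= config.convergence_window:
                break
        else:
            stable = 0
        last = key

    converged = stable >= config.convergence_window
    if not converged:
        logger.warning("affinity propagation did not converge in %d iterations",
                       config.max_iter)
    exemplars = ((a + r).diagonal() > 0).nonzero()[0]
    if len(exemplars) == 0:           # degenerate: pick the best single exemplar
        exemplars = np.array([int((a + r).diagonal().argmax())])
    assign = exemplars[s[:, exemplars].argmax(axis=1)]
    assign[exemplars] = exemplars     # every exemplar assigns to itself
    return APResult(assign, np.sort(exemplars), it, converged)


@dataclass
class Cluster:
    center_id: int
    member_ids: np.ndarray
    radius: float


@dataclass
class ClusterIndex:
    clusters: List[Cluster]
    n_items: int
    config: APConfig

    @property
    def centers(self) -> np.ndarray:
        return np.array([c.center_id for c in self.clusters])


@dataclass(frozen=True)
class RetrievalSphere:
    """A range query: everything within distance r_R of the query."""

    query: object
    r_R: float

    def __post_init__(self) -> None:
        if self.r_R < 0:
            raise ValidationError("r_R must be >= 0")


def build_index(n_items: int, distance: Distance,
                config: APConfig = APConfig(),
                center_mode: str = "exemplar",
                distance_matrix: np.ndarray | None = None) -> ClusterIndex:
    """Cluster item ids 0..n-1 with AP on similarity = -distance and store
    per-cluster radii.

    ``center_mode='exemplar'`` keeps the AP exemplar as the centre;
    ``'random'`` draws a random member instead (seeded), which inflates
    radii and weakens pruning but is available for fidelity.
    """
    if n_items < 1:
        raise ValidationError("empty database")
    if center_mode not in ("exemplar", "random"):
        raise ValidationError(f"unknown center_mode {center_mode!r}")
    if distance_matrix is None:
        distance_matrix = np.zeros((n_items, n_items))
        for i in range(n_items):
            for j in range(i + 1, n_items):
                distance_matrix[i, j] = distance_matrix[j, i] = distance(i, j)
    res = ap_cluster(-distance_matrix, config)
    rng = np.random.default_rng(config.seed)
    clusters = []
    for ex in res.exemplar_set:
        members = np.flatnonzero(res.exemplars == ex)
        center = int(ex) if center_mode == "exemplar" else int(rng.choice(members))
        radius = float(distance_matrix[center, members].max()) if len(members) else 0.0
        clusters.append(Cluster(center, members, radius))
    return ClusterIndex(clusters, n_items, config)


def retrieve_pruned(sphere: RetrievalSphere, index: ClusterIndex,
                    distance_to_query: Callable[[int], float]
                    ) -> Tuple[np.ndarray, int]:
    """Two-phase pruned range query.

    Returns the admitted ids and the number of distance evaluations
    (centre checks + member scans). Boundary convention: a cluster is
    pruned iff d(centre, query) > R_j + r_R; a member is admitted iff
    d(member, query) <= r_R.
    """
    evals = 0
    center_d = {}
    for cl in index.clusters:
        center_d[cl.center_id] = distance_to_query(cl.center_id)
        evals += 1
    result = []
    for cl in index.clusters:
        if center_d[cl.center_id] > cl.radius + sphere.r_R:
            continue                    # cluster ball cannot meet the sphere
        for i in cl.member_ids:
            i = int(i)
            if i == cl.center_id:
                d = center_d[i]
            else:
                d = distance_to_query(i)
                evals += 1
            if d <= sphere.r_R:
                result.append(i)
    return np.array(sorted(result), dtype=int), evals


def retrieve_sequential(sphere: RetrievalSphere, n_items: int,
                        distance_to_query: Callable[[int], float]) -> np.ndarray:
    """Brute-force range query — the correctness oracle."""
    return np.array([i for i in range(n_items)
                     if distance_to_query(i) <= sphere.r_R], dtype=int)


def top_k(k: int, n_items: int, distance_to_query: Callable[[int], float]
          ) -> List[Tuple[int, float]]:
    """The k nearest ids with their distances; ties broken by id order."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > n_items:
        logger.warning("k=%d exceeds database size %d; returning everything",
                       k, n_items)
        k = n_items
    d = np.array([distance_to_query(i) for i in range(n_items)])
    order = np.lexsort((np.arange(n_items), d))[:k]
    return [(int(i), float(d[i])) for i in order]
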