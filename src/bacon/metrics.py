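"""Graph-theoretical measures and their posterior propagation.

Every measure operates on a binary, symmetric, zero-diagonal adjacency
matrix.  A posterior over a measure is obtained by evaluating it on each
MCMC graph sample and summarizing the resulting values with mean,
median, standard deviation and a 95% highest-posterior-density (HPD)
interval.  Small-worldness normalizes clustering and path length by
means over density-matched uniform random graphs (100 by default); the
null statistics are cached per (K, e1) and shared across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import networkx as nx
import numpy as np

from .model import n_pairs, validate_adjacency

__all__ = [
    "MetricPosterior",
    "PathLengthResult",
    "density",
    "clustering_coefficient",
    "characteristic_path_length",
    "random_density_matched_graph",
    "NullModelCache",
    "small_worldness",
    "louvain_modularity",
    "betweenness_centrality",
    "hpd_interval",
    "posterior_metric",
    "METRIC_NAMES",
]

METRIC_NAMES = (
    "density",
    "clustering",
    "path_length",
    "small_worldness",
    "modularity",
    "betweenness",
)


def _graph(A: np.ndarray) -> nx.Graph:
    return nx.from_numpy_array(np.asarray(A))


def density(graph: np.ndarray) -> float:
    """Fraction of the K(K-1)/2 possible edges that are present."""
    A = validate_adjacency(graph)
    K = A.shape[0]
    return float(np.triu(A, 1).sum() / n_pairs(K))


def clustering_coefficient(graph: np.ndarray) -> float:
    """Average nodal clustering; nodes of degree < 2 contribute 0."""
    A = validate_adjacency(graph)
    return float(nx.average_clustering(_graph(A)))


class PathLengthResult(NamedTuple):
    value: float
    disconnected: bool

    def __float__(self) -> float:
        return self.value


def characteristic_path_length(graph: np.ndarray) -> PathLengthResult:
    """Mean shortest-path length over ordered reachable pairs.

    Unreachable pairs are excluded from the mean; the ``disconnected``
    flag reports whether any existed, so disconnection is surfaced
    rather than silently absorbed.
    """
    A = validate_adjacency(graph)
    K = A.shape[0]
    if K < 2:
        raise ValueError("path length needs at least 2 nodes")
    G = _graph(A)
    total = 0
    reachable = 0
    for _, dists in nx.all_pairs_shortest_path_length(G):
        total += sum(dists.values())  # self-distance 0 adds nothing
        reachable += len(dists) - 1
    if reachable == 0:
        raise ValueError("no reachable pairs: graph has no edges")
    disconnected = reachable < K * (K - 1)
    return PathLengthResult(total / reachable, disconnected)


def random_density_matched_graph(
    K: int, e1: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform draw from simple graphs with K nodes and exactly e1 edges."""
    M = n_pairs(K)
    if not 0 <= e1 <= M:
        raise ValueError(f"e1 must be in [0, {M}], got {e1}")
    iu = np.triu_indices(K, 1)
    chosen = rng.choice(M, size=e1, replace=False)
    A = np.zeros((K, K), dtype=np.int8)
    A[iu[0][chosen], iu[1][chosen]] = 1
    return A + A.T


class NullModelCache:
    """Mean clustering and path length of density-matched random graphs.

    Keyed by (K, e1, n_null); shared across posterior samples and the
    thresholded baseline so their normalizations are comparable.
    """

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self._cache: dict[tuple[int, int, int], tuple[float, float]] = {}

    def stats(self, K: int, e1: int, n_null: int) -> tuple[float, float]:
        key = (K, e1, n_null)
        if key not in self._cache:
            cs, ls = [], []
            for _ in range(n_null):
                R = random_density_matched_graph(K, e1, self.rng)
                cs.append(clustering_coefficient(R))
                if R.sum() > 0:
                    ls.append(characteristic_path_length(R).value)
            self._cache[key] = (float(np.mean(cs)), float(np.mean(ls)) if ls else np.nan)
        return self._cache[key]


def small_worldness(
    graph: np.ndarray,
    n_null: int = 100,
    rng: Optional[np.random.Generator] = None,
    cache: Optional[NullModelCache] = None,
) -> float:
    """Small-world coefficient sigma = (C/<C_rand>) / (L/<L_rand>).

    ``<C_rand>`` and ``<L_rand>`` are means over ``n_null`` uniform
    random graphs with the same node and edge counts.  sigma > 1 marks
    small-world topology (lattice-like clustering with random-like path
    length).  Null graphs are not forced to be connected; their path
    length, like the graph's own, averages over reachable pairs.
    """
    A = validate_adjacency(graph)
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    if cache is None:
        cache = NullModelCache(rng if rng is not None else np.random.default_rng())
    K = A.shape[0]
    e1 = int(np.triu(A, 1).sum())
    c_rand, l_rand = cache.stats(K, e1, n_null)
    if not c_rand > 0:
        raise ValueError(
            f"null clustering is zero at K={K}, e1={e1}: small-worldness undefined"
        )
    C = clustering_coefficient(A)
    L = characteristic_path_length(A).value
    return float((C / c_rand) / (L / l_rand))


def louvain_modularity(
    graph: np.ndarray,
    n_runs: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, list[set[int]]]:
    """Best Newman-Girvan modularity over repeated Louvain runs.

    Louvain is greedy and order-dependent, so it is restarted ``n_runs``
    times with different random node orders and the highest-scoring
    partition is kept.
    """
    A = validate_adjacency(graph)
    if np.sum(A) == 0:
        raise ValueError("modularity is undefined for an empty graph")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    G = _graph(A)
    best_q, best_part = -np.inf, None
    for _ in range(n_runs):
        part = nx.community.louvain_communities(
            G, seed=int(rng.integers(2**31))
        )
        q = nx.community.modularity(G, part)
        if q > best_q:
            best_q, best_part = q, part
    return float(best_q), [set(c) for c in best_part]


def betweenness_centrality(graph: np.ndarray) -> np.ndarray:
    """Normalized betweenness: fraction of shortest paths through each node.

    Brandes accumulation, normalized by (K-1)(K-2) ordered source-target
    pairs so values lie in [0, 1]; unreachable pairs contribute 0.
    """
    A = validate_adjacency(graph)
    bc = nx.betweenness_centrality(_graph(A), normalized=True)
    return np.array([bc[i] for i in range(A.shape[0])])


def hpd_interval(values: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous window of order statistics holding ``mass``.

    Sorts the draws and returns the narrowest window containing
    ``ceil(mass * n)`` of them; ties go to the smallest lower bound.
    """
    x = np.sort(np.asarray(values, dtype=np.float64).ravel())
    if x.size == 0:
        raise ValueError("hpd_interval needs at least one value")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    n = x.size
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))  # first minimum = smallest lower bound
    return float(x[i]), float(x[i + k - 1])


@dataclass
class MetricPosterior:
    """Posterior distribution of one graph measure.

    ``values`` holds the measure evaluated on every posterior sample;
    the summaries include a 95% HPD credible interval.  For path-based
    measures ``disconnected_fraction`` reports how many samples were
    disconnected (their values average over reachable pairs only).
    """

    name: str
    values: np.ndarray
    mean: float
    median: float
    std: float
    hpd_low: float
    hpd_high: float
    hpd_mass: float = 0.95
    disconnected_fraction: float = 0.0
    node: Optional[int] = None

    @classmethod
    def from_values(
        cls,
        name: str,
        values,
        hpd_mass: float = 0.95,
        disconnected_fraction: float = 0.0,
        node: Optional[int] = None,
    ) -> "MetricPosterior":
        v = np.asarray(values, dtype=np.float64)
        lo, hi = hpd_interval(v, hpd_mass)
        return cls(
            name=name,
            values=v,
            mean=float(v.mean()),
            median=float(np.median(v)),
            std=float(v.std(ddof=0)),
            hpd_low=lo,
            hpd_high=hi,
            hpd_mass=hpd_mass,
            disconnected_fraction=disconnected_fraction,
            node=node,
        )


def posterior_metric(
    samples,
    metric: str,
    n_null: int = 100,
    n_louvain_runs: int = 100,
    hpd_mass: float = 0.95,
    rng: Optional[np.random.Generator] = None,
):
    """Evaluate one measure on every posterior sample.

    Parameters
    ----------
    samples : GraphSampleSet
    metric : one of ``METRIC_NAMES``
    rng : random source for null graphs (small-worldness) and Louvain
        restarts; required for those measures to be reproducible.

    Returns a :class:`MetricPosterior`, or a list of one per node for
    ``betweenness``.
    """
    if metric not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r}; valid names: {METRIC_NAMES}")
    if len(samples) == 0:
        raise ValueError("sample set is empty")
    if rng is None:
        rng = np.random.default_rng()
    cache = NullModelCache(rng)

    if metric == "betweenness":
        per_node = np.stack([betweenness_centrality(A) for A in samples])
        return [
            MetricPosterior.from_values(
                "betweenness", per_node[:, i], hpd_mass, node=i
            )
            for i in range(per_node.shape[1])
        ]

    values = np.empty(len(samples))
    n_disconnected = 0
    for s, A in enumerate(samples):
        if metric == "density":
            values[s] = density(A)
        elif metric == "clustering":
            values[s] = clustering_coefficient(A)
        elif metric == "path_length":
            res = characteristic_path_length(A)
            values[s] = res.value
            n_disconnected += res.disconnected
        elif metric == "small_worldness":
            disconnected = characteristic_path_length(A).disconnected
            n_disconnected += disconnected
            values[s] = small_worldness(A, n_null=n_null, cache=cache)
        elif metric == "modularity":
            values[s], _ = louvain_modularity(A, n_runs=n_louvain_runs, rng=rng)
    return MetricPosterior.from_values(
        metric, values, hpd_mass, disconnected_fraction=n_disconnected / len(samples)
    )
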