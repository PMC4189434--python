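"""Metropolis sampler over adjacency matrices.

Proposals toggle one symmetric edge pair (a_ij, a_ji); the acceptance
ratio is the sum of the closed-form log likelihood ratio and log prior
ratio, so a step costs O(1) given cached per-row quantities.  One
posterior sample is stored per *sweep*: a pass proposing a toggle for
every unordered pair in a fresh uniformly random order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import lgamma, log
from typing import Iterator, Optional

import numpy as np

from .model import (
    Hyperparameters,
    StreamlineCounts,
    as_count_array,
    edge_count,
    log_likelihood,
    log_prior,
    n_pairs,
)
from .baseline import symmetrize_counts, threshold_to_edge_count

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerState",
    "GraphSampleSet",
    "initialize_state",
    "metropolis_step",
    "sweep",
    "run_chains",
    "edge_probability_matrix",
    "enumerate_graphs",
    "exact_posterior",
    "split_rhat",
]


@dataclass
class SamplerState:
    """Mutable chain state with incrementally maintained caches.

    ``conc_sums[i]`` is the row concentration total
    ``deg_i * d1 + (K-1-deg_i) * d0``; ``log_likelihood_cached`` is the
    full log likelihood of ``graph`` (refreshed periodically to bound
    floating-point drift).
    """

    graph: np.ndarray
    degrees: np.ndarray
    conc_sums: np.ndarray
    e1: int
    log_likelihood_cached: float
    sweep_index: int = 0
    chain_id: int = 0
    n_accepted: int = 0
    n_proposed: int = 0

    @property
    def n_regions(self) -> int:
        return self.graph.shape[0]

    def refresh(self, counts, hyper: Hyperparameters) -> None:
        """Recompute all cached quantities from the graph."""
        K = self.n_regions
        self.degrees = self.graph.sum(axis=1).astype(np.int64)
        self.conc_sums = self.degrees * hyper.d1 + (K - 1 - self.degrees) * hyper.d0
        self.e1 = edge_count(self.graph)
        self.log_likelihood_cached = log_likelihood(counts, self.graph, hyper)

    def check_consistency(self, counts, hyper: Hyperparameters, atol: float = 1e-6):
        """Assert caches match a fresh recomputation (debug aid)."""
        K = self.n_regions
        deg = self.graph.sum(axis=1)
        assert np.array_equal(deg, self.degrees), "degree cache drifted"
        conc = deg * hyper.d1 + (K - 1 - deg) * hyper.d0
        assert np.allclose(conc, self.conc_sums), "concentration cache drifted"
        assert self.e1 == edge_count(self.graph), "edge count cache drifted"
        ll = log_likelihood(counts, self.graph, hyper)
        assert abs(ll - self.log_likelihood_cached) < atol, (
            f"likelihood cache drift {ll - self.log_likelihood_cached:.3g}"
        )


def _state_from_graph(
    A: np.ndarray, counts, hyper: Hyperparameters, chain_id: int = 0
) -> SamplerState:
    K = A.shape[0]
    degrees = A.sum(axis=1).astype(np.int64)
    conc_sums = degrees * hyper.d1 + (K - 1 - degrees) * hyper.d0
    return SamplerState(
        graph=A.astype(np.int8),
        degrees=degrees,
        conc_sums=conc_sums.astype(np.float64),
        e1=edge_count(A),
        log_likelihood_cached=log_likelihood(counts, A, hyper),
        chain_id=chain_id,
    )


def initialize_state(
    counts, hyper: Hyperparameters, rng: np.random.Generator, chain_id: int = 0
) -> SamplerState:
    """Initial state: thresholded symmetrized counts at the prior-mode density.

    The symmetrized count matrix (sum of both directions) is thresholded
    to ``m0 = round(M * mode)`` edges, where ``mode`` is the mode of the
    Beta prior on density (falling back to the prior mean when the mode
    is undefined, i.e. alpha <= 1 or beta <= 1).  Ties at the cutoff are
    resolved uniformly at random.  Starting near the prior-mode density
    with the data's strongest edges minimises burn-in.
    """
    N = as_count_array(counts)
    K = N.shape[0]
    mode = hyper.prior_density_mode()
    if not (hyper.alpha > 1 and hyper.beta > 1):
        logger.info(
            "Beta prior mode undefined (alpha=%g, beta=%g); initializing at the "
            "prior mean density %.4f", hyper.alpha, hyper.beta, mode,
        )
    m0 = int(round(n_pairs(K) * mode))
    W = symmetrize_counts(N)
    A = threshold_to_edge_count(W, m0, rng)
    return _state_from_graph(A, N, hyper, chain_id=chain_id)


def _toggle_delta(
    N: np.ndarray,
    row_totals: np.ndarray,
    state: SamplerState,
    i: int,
    j: int,
    hyper: Hyperparameters,
    M: int,
) -> tuple[float, float, float]:
    """(log likelihood ratio, log prior ratio, concentration shift) for a toggle."""
    d0, d1 = hyper.d0, hyper.d1
    present = state.graph[i, j]
    if present:
        a_old, a_new, dA = d1, d0, d0 - d1
    else:
        a_old, a_new, dA = d0, d1, d1 - d0
    d_lik = 0.0
    for r, c in ((i, j), (j, i)):
        A0 = state.conc_sums[r]
        S = row_totals[r]
        n = N[r, c]
        d_lik += (
            lgamma(A0 + dA)
            - lgamma(A0)
            - lgamma(S + A0 + dA)
            + lgamma(S + A0)
            + lgamma(n + a_new)
            - lgamma(a_new)
            - lgamma(n + a_old)
            + lgamma(a_old)
        )
    e1, e0 = state.e1, M - state.e1
    if present:
        d_prior = log(e0 + hyper.beta) - log(e1 + hyper.alpha - 1.0)
    else:
        d_prior = log(e1 + hyper.alpha) - log(e0 + hyper.beta - 1.0)
    return d_lik, d_prior, dA


def _apply_toggle(state: SamplerState, i: int, j: int, d_lik: float, dA: float):
    new = 1 - state.graph[i, j]
    state.graph[i, j] = state.graph[j, i] = new
    step = 1 if new else -1
    state.degrees[i] += step
    state.degrees[j] += step
    state.conc_sums[i] += dA
    state.conc_sums[j] += dA
    state.e1 += step
    state.log_likelihood_cached += d_lik


def metropolis_step(
    state: SamplerState,
    pair: tuple[int, int],
    counts,
    hyper: Hyperparameters,
    rng: np.random.Generator,
) -> SamplerState:
    """One Metropolis proposal: toggle the symmetric edge pair ``pair``.

    Accepts with probability min(1, exp(Delta)) where Delta is the sum
    of the likelihood and prior log ratios; comparison is done in log
    space.  The state is updated in place and returned.
    """
    i, j = pair
    if i == j:
        raise ValueError("pair must join two distinct regions")
    N = as_count_array(counts)
    row_totals = N.sum(axis=1)
    M = n_pairs(state.n_regions)
    d_lik, d_prior, dA = _toggle_delta(N, row_totals, state, i, j, hyper, M)
    state.n_proposed += 1
    if log(rng.random()) < d_lik + d_prior:
        _apply_toggle(state, i, j, d_lik, dA)
        state.n_accepted += 1
    return state


def sweep(
    state: SamplerState,
    counts,
    hyper: Hyperparameters,
    rng: np.random.Generator,
) -> SamplerState:
    """One full sweep: propose every unordered pair once in random order."""
    N = as_count_array(counts)
    _sweep_fast(state, N, N.sum(axis=1), hyper, rng)
    return state


def _sweep_fast(
    state: SamplerState,
    N: np.ndarray,
    row_totals: np.ndarray,
    hyper: Hyperparameters,
    rng: np.random.Generator,
) -> None:
    K = state.n_regions
    M = n_pairs(K)
    iu, ju = np.triu_indices(K, 1)
    order = rng.permutation(M)
    # one uniform per proposal keeps the RNG stream length fixed
    logu = np.log(rng.random(M))
    for k, u in zip(order, logu):
        i = int(iu[k])
        j = int(ju[k])
        d_lik, d_prior, dA = _toggle_delta(N, row_totals, state, i, j, hyper, M)
        state.n_proposed += 1
        if u < d_lik + d_prior:
            _apply_toggle(state, i, j, d_lik, dA)
            state.n_accepted += 1
    state.sweep_index += 1


# ---------------------------------------------------------------------------
# Sample storage
# ---------------------------------------------------------------------------

@dataclass
class GraphSampleSet:
    """Ordered MCMC graph samples, bit-packed by upper triangle.

    ``packed[s]`` holds the M upper-triangle bits of sample ``s``
    (row-major pair order, ``np.triu_indices(K, 1)``), packed into
    bytes.  For K = 90 and 10^4 samples this is about 5 MB.
    """

    packed: np.ndarray
    n_regions: int
    chain_ids: np.ndarray
    sweep_indices: np.ndarray
    hyper: Hyperparameters
    seed: Optional[int] = None
    acceptance_rates: Optional[dict] = None

    def __len__(self) -> int:
        return self.packed.shape[0]

    def __iter__(self) -> Iterator[np.ndarray]:
        for s in range(len(self)):
            yield self.graph(s)

    def graph(self, idx: int) -> np.ndarray:
        """Unpack sample ``idx`` into a full K x K adjacency matrix."""
        K = self.n_regions
        bits = np.unpackbits(self.packed[idx], count=n_pairs(K))
        A = np.zeros((K, K), dtype=np.int8)
        A[np.triu_indices(K, 1)] = bits
        return A + A.T

    def edge_counts(self) -> np.ndarray:
        """Per-sample number of edges e1."""
        M = n_pairs(self.n_regions)
        return np.unpackbits(self.packed, axis=1, count=M).sum(axis=1)

    def edge_probability_matrix(self) -> np.ndarray:
        return edge_probability_matrix(self)

    @classmethod
    def from_graphs(
        cls,
        graphs,
        hyper: Hyperparameters,
        chain_ids=None,
        sweep_indices=None,
        seed=None,
        acceptance_rates=None,
    ) -> "GraphSampleSet":
        graphs = list(graphs)
        if not graphs:
            raise ValueError("at least one sample is required")
        K = graphs[0].shape[0]
        iu = np.triu_indices(K, 1)
        packed = np.stack(
            [np.packbits(np.asarray(g)[iu].astype(np.uint8)) for g in graphs]
        )
        n = len(graphs)
        return cls(
            packed=packed,
            n_regions=K,
            chain_ids=np.asarray(
                chain_ids if chain_ids is not None else np.zeros(n, dtype=np.int32)
            ),
            sweep_indices=np.asarray(
                sweep_indices if sweep_indices is not None else np.arange(n)
            ),
            hyper=hyper,
            seed=seed,
            acceptance_rates=acceptance_rates,
        )


def edge_probability_matrix(samples: GraphSampleSet) -> np.ndarray:
    """Marginal posterior edge probabilities.

    Entry (i, j) is the fraction of samples containing edge (i, j);
    symmetric with zero diagonal.
    """
    if len(samples) == 0:
        raise ValueError("sample set is empty")
    K = samples.n_regions
    M = n_pairs(K)
    bits = np.unpackbits(samples.packed, axis=1, count=M)
    marg = bits.mean(axis=0)
    P = np.zeros((K, K))
    P[np.triu_indices(K, 1)] = marg
    return P + P.T


# ---------------------------------------------------------------------------
# Chain runner
# ---------------------------------------------------------------------------

def run_chains(
    counts,
    hyper: Hyperparameters = Hyperparameters(),
    n_samples_per_chain: int = 5000,
    n_chains: int = 2,
    burn_in: int = 0,
    seed: Optional[int] = None,
    refresh_every: int = 100,
    progress_every: int = 1000,
) -> GraphSampleSet:
    """Run independent Metropolis chains and collect posterior samples.

    Each chain stores one bit-packed sample per sweep after discarding
    ``burn_in`` sweeps.  The defaults (5000 samples in 2 chains, 10000
    samples total, burn-in 0 with prior-mode initialization) follow the
    reference estimation protocol.  Chain RNG streams are spawned from
    the master seed by chain index, so adding chains never perturbs
    earlier chains' streams, and the full run is reproducible.
    """
    if n_samples_per_chain < 1 or n_chains < 1 or burn_in < 0:
        raise ValueError("need n_samples_per_chain >= 1, n_chains >= 1, burn_in >= 0")
    N = as_count_array(counts)
    row_totals = N.sum(axis=1)
    K = N.shape[0]
    M = n_pairs(K)

    packed_all, chain_ids, sweep_ids = [], [], []
    acceptance = {}
    iu = np.triu_indices(K, 1)
    root = np.random.SeedSequence(seed)
    for c in range(n_chains):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=root.entropy, spawn_key=(c,))
        )
        state = initialize_state(N, hyper, rng, chain_id=c)
        total_sweeps = burn_in + n_samples_per_chain
        for t in range(total_sweeps):
            _sweep_fast(state, N, row_totals, hyper, rng)
            if refresh_every and state.sweep_index % refresh_every == 0:
                state.refresh(N, hyper)
            if progress_every and state.sweep_index % progress_every == 0:
                rate = state.n_accepted / max(state.n_proposed, 1)
                logger.info(
                    "chain %d sweep %d: %d edges, acceptance %.3f",
                    c, state.sweep_index, state.e1, rate,
                )
            if t >= burn_in:
                packed_all.append(
                    np.packbits(state.graph[iu].astype(np.uint8))
                )
                chain_ids.append(c)
                sweep_ids.append(state.sweep_index)
        acceptance[c] = state.n_accepted / max(state.n_proposed, 1)

    return GraphSampleSet(
        packed=np.stack(packed_all),
        n_regions=K,
        chain_ids=np.asarray(chain_ids, dtype=np.int32),
        sweep_indices=np.asarray(sweep_ids, dtype=np.int32),
        hyper=hyper,
        seed=seed,
        acceptance_rates=acceptance,
    )


def split_rhat(traces: np.ndarray) -> float:
    """Split potential-scale-reduction diagnostic on scalar chain traces.

    ``traces`` has shape (n_chains, n_sweeps).  Each chain is split in
    half and the classical between/within variance ratio is returned.
    Values near 1 indicate the chains have mixed.  This diagnostic (and
    the between-chain marginal agreement) are this implementation's own
    convergence reporting.
    """
    traces = np.asarray(traces, dtype=np.float64)
    n_chains, n = traces.shape
    half = n // 2
    if half < 2:
        return float("nan")
    halves = np.concatenate([traces[:, :half], traces[:, half : 2 * half]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else float("inf")
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


# ---------------------------------------------------------------------------
# Exact posterior by enumeration (tractable for K <= 5)
# ---------------------------------------------------------------------------

def enumerate_graphs(K: int) -> Iterator[np.ndarray]:
    """Yield all 2^(K(K-1)/2) simple graphs on K labelled nodes."""
    M = n_pairs(K)
    iu = np.triu_indices(K, 1)
    for code in range(2 ** M):
        bits = (code >> np.arange(M)) & 1
        A = np.zeros((K, K), dtype=np.int8)
        A[iu] = bits
        yield A + A.T


def exact_posterior(counts, hyper: Hyperparameters) -> tuple[list[np.ndarray], np.ndarray]:
    """Brute-force posterior over all graphs (small K only).

    Weights every graph by exp(log prior + log likelihood) and
    normalizes.  Used as the ground truth against which the Metropolis
    sampler is validated on enumerable problems.
    """
    N = as_count_array(counts)
    K = N.shape[0]
    if n_pairs(K) > 20:
        raise ValueError(f"enumeration over 2^{n_pairs(K)} graphs is intractable")
    graphs = list(enumerate_graphs(K))
    logw = np.array(
        [log_prior(A, hyper) + log_likelihood(N, A, hyper) for A in graphs]
    )
    logw -= logw.max()
    w = np.exp(logw)
    return graphs, w / w.sum()
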