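"""Generative model of structural connectivity from streamline counts.

The latent object is a symmetric, zero-diagonal binary adjacency matrix
``A`` over ``K`` brain regions.  The model has two parts:

Prior (Beta-Binomial on graphs)
    A global edge probability ``p ~ Beta(alpha, beta)`` is shared by all
    unordered region pairs, each edge being Bernoulli(p).  Integrating
    ``p`` out couples the edges through the graph density and yields

        P(A | alpha, beta) = B(e1 + alpha, e0 + beta) / B(alpha, beta)

    where ``e1`` is the number of edges, ``e0`` the number of non-edges
    among the ``M = K(K-1)/2`` pairs, and ``B`` is the Beta function.

Likelihood (Dirichlet-multinomial on count rows)
    Probabilistic tractography launches ``S_i`` streamlines from region
    ``i``; the count vector over the other ``K-1`` regions is
    Multinomial(S_i, x_i) with ``x_i ~ Dirichlet(conc_i)`` where the
    concentration for target ``j`` is ``d1`` if the edge (i, j) exists
    and ``d0`` otherwise.  The Dirichlet is conjugate and is integrated
    out analytically, giving a Dirichlet-multinomial per row.

All probability computations are done in log space through log-gamma
functions; streamline budgets in real data reach 10^5--10^7 and direct
factorials or Beta functions would overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import betaln, gammaln

__all__ = [
    "Hyperparameters",
    "StreamlineCounts",
    "validate_adjacency",
    "validate_counts",
    "edge_count",
    "n_pairs",
    "log_prior",
    "log_prior_ratio",
    "sample_graph_from_prior",
    "dirichlet_concentrations",
    "log_likelihood_row",
    "log_likelihood",
    "log_likelihood_ratio",
    "expected_nonedge_mass",
    "simulate_nonedge_mass",
    "forward_simulate",
]


@dataclass(frozen=True)
class Hyperparameters:
    """Hyperparameters of the generative model.

    Parameters
    ----------
    alpha, beta : float
        Shape parameters of the Beta prior on the global edge
        probability.  The defaults (14, 53) place the prior mode of the
        graph density at (alpha-1)/(alpha+beta-2) = 0.2, a vague prior
        favouring sparse networks.
    d0 : float
        Dirichlet concentration assigned to absent edges.  Controls how
        much streamline mass may leak onto non-edges (the expected
        false-positive rate); default 0.01.
    d1 : float
        Dirichlet concentration assigned to present edges; default 1
        (uniform over probability vectors restricted to the edges, i.e.
        agnostic about how streamlines distribute over connections).

    The model specification demands ``d0 < d1``; equality is tolerated
    numerically (it makes the likelihood independent of the graph) but
    ``d0 > d1`` is rejected.
    """

    alpha: float = 14.0
    beta: float = 53.0
    d0: float = 0.01
    d1: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "d0", "d1"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite real, got {v!r}")
        if self.d0 > self.d1:
            raise ValueError(
                f"model requires d0 <= d1 (got d0={self.d0}, d1={self.d1})"
            )

    def prior_density_mode(self) -> float:
        """Mode of the Beta prior on graph density.

        Defined for ``alpha, beta > 1``; otherwise falls back to the
        prior mean ``alpha / (alpha + beta)``.
        """
        a, b = self.alpha, self.beta
        if a > 1 and b > 1:
            return (a - 1.0) / (a + b - 2.0)
        return a / (a + b)


@dataclass
class StreamlineCounts:
    """A K x K streamline count matrix with optional region labels.

    Rows are seed regions, columns target regions; the matrix is
    asymmetric in general because seeding is directional.  Diagonal
    entries are outside the model and must be zero.
    """

    counts: np.ndarray
    labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        validate_counts(self.counts)
        self.counts = self.counts.astype(np.int64)
        if self.labels is not None:
            self.labels = [str(x) for x in self.labels]
            if len(self.labels) != self.counts.shape[0]:
                raise ValueError(
                    f"{len(self.labels)} labels for {self.counts.shape[0]} regions"
                )

    @property
    def n_regions(self) -> int:
        return self.counts.shape[0]

    @property
    def row_totals(self) -> np.ndarray:
        """Per-region streamline budgets S_i (off-diagonal row sums)."""
        return self.counts.sum(axis=1)


def as_count_array(counts) -> np.ndarray:
    """Coerce a ``StreamlineCounts`` or array-like to a validated array."""
    if isinstance(counts, StreamlineCounts):
        return counts.counts
    arr = np.asarray(counts)
    validate_counts(arr)
    return arr.astype(np.int64)


def n_pairs(K: int) -> int:
    """Number of unordered region pairs M = K(K-1)/2."""
    return K * (K - 1) // 2


def validate_adjacency(A: np.ndarray) -> np.ndarray:
    """Check that ``A`` is a square, binary, symmetric, hollow matrix."""
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency matrix must be square, got shape {A.shape}")
    if not np.isin(A, (0, 1)).all():
        raise ValueError("adjacency matrix entries must be 0 or 1")
    if np.any(A != A.T):
        raise ValueError("adjacency matrix must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency matrix must have a zero diagonal (no self-loops)")
    return A


def validate_counts(N: np.ndarray) -> np.ndarray:
    """Check that ``N`` is a square, non-negative integer, hollow matrix."""
    N = np.asarray(N)
    if N.ndim != 2 or N.shape[0] != N.shape[1]:
        raise ValueError(f"count matrix must be square, got shape {N.shape}")
    if not np.issubdtype(N.dtype, np.number) or np.any(N != np.round(N)):
        raise ValueError("count matrix entries must be integers")
    if np.any(N < 0):
        i, j = np.argwhere(N < 0)[0]
        raise ValueError(f"negative streamline count at row {i}, column {j}")
    if np.any(np.diag(N) != 0):
        (i,) = np.argwhere(np.diag(N) != 0)[0]
        raise ValueError(
            f"nonzero diagonal entry at region {i}: self-counts are outside the "
            "model; zero the diagonal upstream"
        )
    return N


def edge_count(A: np.ndarray) -> int:
    """Number of edges e1 (unordered pairs with an edge)."""
    return int(np.triu(A, 1).sum())


# ---------------------------------------------------------------------------
# Prior
# ---------------------------------------------------------------------------

def log_prior(graph: np.ndarray, hyper: Hyperparameters) -> float:
    """Log prior probability of one labelled graph under the Beta-Binomial.

    Returns ``log B(e1+alpha, e0+beta) - log B(alpha, beta)``: the
    probability of exactly this graph, not of its density class.
    """
    A = validate_adjacency(graph)
    K = A.shape[0]
    e1 = edge_count(A)
    e0 = n_pairs(K) - e1
    return float(
        betaln(e1 + hyper.alpha, e0 + hyper.beta) - betaln(hyper.alpha, hyper.beta)
    )


def log_prior_ratio(
    graph: np.ndarray, pair: tuple[int, int], hyper: Hyperparameters
) -> float:
    """Change in log prior when the edge at ``pair`` is toggled.

    Closed form from ratios of Beta functions: adding an edge to a graph
    with ``e1`` edges and ``e0`` non-edges gives
    ``log[(e1+alpha)/(e0+beta-1)]``; removing gives
    ``log[(e0+beta)/(e1+alpha-1)]``.
    """
    A = np.asarray(graph)
    i, j = pair
    if i == j:
        raise ValueError("pair must join two distinct regions")
    K = A.shape[0]
    e1 = edge_count(A)
    e0 = n_pairs(K) - e1
    if A[i, j]:  # removing
        return float(np.log(e0 + hyper.beta) - np.log(e1 + hyper.alpha - 1.0))
    return float(np.log(e1 + hyper.alpha) - np.log(e0 + hyper.beta - 1.0))


def sample_graph_from_prior(
    K: int, hyper: Hyperparameters, rng: np.random.Generator
) -> np.ndarray:
    """Draw a graph from the Beta-Binomial prior.

    One global ``p ~ Beta(alpha, beta)`` is drawn, then every unordered
    pair is an independent Bernoulli(p) edge.
    """
    if K < 2:
        raise ValueError(f"need at least 2 regions, got K={K}")
    p = rng.beta(hyper.alpha, hyper.beta)
    iu = np.triu_indices(K, 1)
    bits = rng.random(len(iu[0])) < p
    A = np.zeros((K, K), dtype=np.int8)
    A[iu] = bits
    A += A.T
    return A


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def dirichlet_concentrations(row: np.ndarray, hyper: Hyperparameters) -> np.ndarray:
    """Concentration vector for one adjacency row: d1 on edges, d0 off."""
    row = np.asarray(row)
    return np.where(row == 1, hyper.d1, hyper.d0)


def log_likelihood_row(
    counts_row: np.ndarray, adjacency_row: np.ndarray, hyper: Hyperparameters
) -> float:
    """Log Dirichlet-multinomial probability of one region's count row.

    ``counts_row`` and ``adjacency_row`` have length K-1 (the region's
    own diagonal entry is excluded).  An all-zero row (budget S_i = 0)
    has probability one and contributes 0.
    """
    n = np.asarray(counts_row, dtype=np.float64)
    if np.any(n < 0):
        raise ValueError("streamline counts must be non-negative")
    conc = dirichlet_concentrations(adjacency_row, hyper)
    if conc.shape != n.shape:
        raise ValueError("counts and adjacency rows must have equal length")
    S = n.sum()
    A0 = conc.sum()
    coeff = gammaln(S + 1.0) - gammaln(n + 1.0).sum()
    return float(
        coeff
        + gammaln(A0)
        - gammaln(S + A0)
        + (gammaln(n + conc) - gammaln(conc)).sum()
    )


def _offdiag(mat: np.ndarray) -> np.ndarray:
    """Rows of ``mat`` with the diagonal entry removed: shape (K, K-1)."""
    K = mat.shape[0]
    mask = ~np.eye(K, dtype=bool)
    return mat[mask].reshape(K, K - 1)


def log_likelihood(counts, graph: np.ndarray, hyper: Hyperparameters) -> float:
    """Total log likelihood: sum of Dirichlet-multinomial rows."""
    N = as_count_array(counts)
    A = validate_adjacency(graph)
    if N.shape != A.shape:
        raise ValueError(
            f"count matrix shape {N.shape} does not match graph shape {A.shape}"
        )
    n = _offdiag(N).astype(np.float64)
    conc = _offdiag(np.where(A == 1, hyper.d1, hyper.d0))
    S = n.sum(axis=1)
    A0 = conc.sum(axis=1)
    coeff = gammaln(S + 1.0) - gammaln(n + 1.0).sum(axis=1)
    per_row = (
        coeff
        + gammaln(A0)
        - gammaln(S + A0)
        + (gammaln(n + conc) - gammaln(conc)).sum(axis=1)
    )
    return float(per_row.sum())


def log_likelihood_ratio(
    counts, graph: np.ndarray, pair: tuple[int, int], hyper: Hyperparameters
) -> float:
    """Change in total log likelihood when the edge at ``pair`` is toggled.

    Only rows i and j are affected, and within each row only the row-sum
    gamma terms and the toggled entry's gamma terms change; multinomial
    coefficients cancel.
    """
    N = as_count_array(counts)
    A = np.asarray(graph)
    i, j = pair
    if i == j:
        raise ValueError("pair must join two distinct regions")
    K = A.shape[0]
    d0, d1 = hyper.d0, hyper.d1
    present = bool(A[i, j])
    a_old, a_new = (d1, d0) if present else (d0, d1)
    dA = (d1 - d0) * (-1.0 if present else 1.0)

    delta = 0.0
    for r, c in ((i, j), (j, i)):
        deg = int(A[r].sum())
        A0 = deg * d1 + (K - 1 - deg) * d0
        S = float(N[r].sum())
        nrc = float(N[r, c])
        delta += (
            gammaln(A0 + dA)
            - gammaln(A0)
            - gammaln(S + A0 + dA)
            + gammaln(S + A0)
            + gammaln(nrc + a_new)
            - gammaln(a_new)
            - gammaln(nrc + a_old)
            + gammaln(a_old)
        )
    return float(delta)


# ---------------------------------------------------------------------------
# d0 calibration primitives
# ---------------------------------------------------------------------------

def expected_nonedge_mass(
    degree: int, n_targets: int, hyper: Hyperparameters
) -> float:
    """Expected streamline probability mass landing on non-edge targets.

    For a region with ``degree`` edges among ``n_targets`` possible
    targets, the Dirichlet mean mass on the ``m = n_targets - degree``
    non-edges is ``m*d0 / (m*d0 + degree*d1)``.  This is the expected
    false-positive rate in the streamline counts and is the quantity
    used to calibrate ``d0``.
    """
    if not 0 <= degree <= n_targets:
        raise ValueError(f"degree must be in [0, {n_targets}], got {degree}")
    m = n_targets - degree
    if m == 0:
        return 0.0
    num = m * hyper.d0
    return float(num / (num + degree * hyper.d1))


def simulate_nonedge_mass(
    degree: int,
    n_targets: int,
    hyper: Hyperparameters,
    n_draws: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the non-edge streamline mass.

    Draws ``n_draws`` probability vectors from the row Dirichlet and
    averages the total mass on non-edge targets.  Returns the mean and
    its standard error.  Companion to :func:`expected_nonedge_mass`
    (whose value it should match within Monte-Carlo error); the
    simulation route mirrors how the calibration curves were obtained.
    """
    if not 0 <= degree <= n_targets:
        raise ValueError(f"degree must be in [0, {n_targets}], got {degree}")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    conc = np.r_[np.full(degree, hyper.d1), np.full(n_targets - degree, hyper.d0)]
    masses = np.empty(n_draws)
    # draw in batches to bound memory at large n_draws
    batch = 20000
    for start in range(0, n_draws, batch):
        stop = min(start + batch, n_draws)
        draws = rng.dirichlet(conc, size=stop - start)
        masses[start:stop] = draws[:, degree:].sum(axis=1)
    mean = float(masses.mean())
    se = float(masses.std(ddof=1) / np.sqrt(n_draws)) if n_draws > 1 else 0.0
    return mean, se


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

def forward_simulate(
    K: int,
    hyper: Hyperparameters,
    streamline_budget,
    rng: np.random.Generator,
    graph: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, StreamlineCounts]:
    """Simulate (A, X, N) from the generative model.

    If ``graph`` is omitted a graph is drawn from the Beta-Binomial
    prior.  Each region's streamline probability vector ``x_i`` is drawn
    from its row Dirichlet and ``S_i`` streamlines are distributed
    multinomially.  This is the synthetic stand-in for aggregated
    probabilistic-tractography output.

    Returns
    -------
    A : (K, K) int array — the ground-truth adjacency matrix
    X : (K, K-1) float array — row streamline probability vectors
    N : StreamlineCounts — the simulated count matrix
    """
    budgets = np.broadcast_to(np.asarray(streamline_budget, dtype=np.int64), (K,))
    if np.any(budgets < 0):
        raise ValueError("streamline budgets must be non-negative")
    if graph is None:
        A = sample_graph_from_prior(K, hyper, rng)
    else:
        A = validate_adjacency(graph).astype(np.int8)
        if A.shape[0] != K:
            raise ValueError(f"graph has {A.shape[0]} regions, expected {K}")
    X = np.empty((K, K - 1))
    N = np.zeros((K, K), dtype=np.int64)
    for i in range(K):
        targets = np.r_[0:i, i + 1 : K]
        conc = dirichlet_concentrations(A[i, targets], hyper)
        x = rng.dirichlet(conc)
        X[i] = x
        if budgets[i] > 0:
            N[i, targets] = rng.multinomial(budgets[i], x)
    return A, X, StreamlineCounts(N)
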