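"""Scikit-learn style estimators over the sampler and baseline.

``BayesianConnectome`` plays the role of a network-structure estimator
(compare ``sklearn.covariance.GraphicalLasso``): ``fit`` takes one
square streamline-count matrix and exposes the posterior over binary
graphs through fitted attributes.  ``CountThresholder`` is the
conventional point-estimate baseline in the same clothing.  Both
compose with sklearn's ``clone``/``get_params`` machinery.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .baseline import symmetrize_counts, threshold_at_count, threshold_to_edge_count
from .metrics import posterior_metric
from .model import Hyperparameters, as_count_array
from .sampler import run_chains, split_rhat

__all__ = ["BayesianConnectome", "CountThresholder"]


class BayesianConnectome(BaseEstimator):
    """Posterior over binary structural networks from streamline counts.

    Parameters
    ----------
    alpha, beta : float, default (14, 53)
        Beta prior on the global edge probability; the defaults put the
        prior density mode at 0.2 (a vague sparse-network prior).
    d0, d1 : float, default (0.01, 1.0)
        Dirichlet concentrations off and on edges; d0 = 0.01 calibrates
        the expected false-positive streamline mass at density 0.2 to a
        few percent.
    n_samples : int, default 5000
        Stored samples per chain (one per sweep).
    n_chains : int, default 2
    burn_in : int, default 0
        Discarded sweeps per chain; initialization at the prior-mode
        density keeps the default burn-in small.
    random_state : int or None
        Master seed for all chains.

    Attributes
    ----------
    sample_set_ : GraphSampleSet
        The posterior graph samples.
    edge_probability_ : ndarray of shape (K, K)
        Marginal posterior probability of each edge.
    mean_edge_count_ : float
    mean_density_ : float
    acceptance_rate_ : float
        Proposal acceptance rate pooled over chains.
    rhat_edge_count_ : float
        Split-R-hat of the per-sweep edge-count trace (own diagnostic).
    n_regions_ : int

    Examples
    --------
    >>> from bacon import generate_fixture, BayesianConnectome
    >>> truth, counts, _ = generate_fixture("tiny", seed=0)
    >>> model = BayesianConnectome(n_samples=200, random_state=0).fit(counts)
    >>> model.edge_probability_.shape
    (4, 4)
    """

    def __init__(
        self,
        alpha: float = 14.0,
        beta: float = 53.0,
        d0: float = 0.01,
        d1: float = 1.0,
        n_samples: int = 5000,
        n_chains: int = 2,
        burn_in: int = 0,
        random_state: Optional[int] = None,
    ):
        self.alpha = alpha
        self.beta = beta
        self.d0 = d0
        self.d1 = d1
        self.n_samples = n_samples
        self.n_chains = n_chains
        self.burn_in = burn_in
        self.random_state = random_state

    def _hyper(self) -> Hyperparameters:
        return Hyperparameters(self.alpha, self.beta, self.d0, self.d1)

    def fit(self, X, y=None):
        """Run the Metropolis chains on a K x K streamline count matrix."""
        N = as_count_array(X)
        self.sample_set_ = run_chains(
            N,
            self._hyper(),
            n_samples_per_chain=self.n_samples,
            n_chains=self.n_chains,
            burn_in=self.burn_in,
            seed=self.random_state,
        )
        self.n_regions_ = N.shape[0]
        self.n_features_in_ = N.shape[1]
        self.edge_probability_ = self.sample_set_.edge_probability_matrix()
        counts = self.sample_set_.edge_counts()
        self.mean_edge_count_ = float(counts.mean())
        K = self.n_regions_
        self.mean_density_ = self.mean_edge_count_ / (K * (K - 1) / 2)
        rates = self.sample_set_.acceptance_rates or {}
        self.acceptance_rate_ = float(np.mean(list(rates.values()))) if rates else np.nan
        per_chain = counts.reshape(self.n_chains, -1)
        self.rhat_edge_count_ = split_rhat(per_chain)
        return self

    def posterior(self, metric: str, rng=None, **options):
        """Posterior distribution of a graph measure over the samples."""
        check_is_fitted(self, "sample_set_")
        if rng is None and self.random_state is not None:
            rng = np.random.default_rng(self.random_state)
        return posterior_metric(self.sample_set_, metric, rng=rng, **options)


class CountThresholder(BaseEstimator):
    """Point-estimate baseline: symmetrize counts and threshold.

    Exactly one of ``n_edges`` (keep the top-n_edges pairs, ties broken
    uniformly at random) or ``min_count`` (keep pairs with symmetrized
    count >= min_count) must be set.
    """

    def __init__(
        self,
        n_edges: Optional[int] = None,
        min_count: Optional[int] = None,
        random_state: Optional[int] = None,
    ):
        self.n_edges = n_edges
        self.min_count = min_count
        self.random_state = random_state

    def fit(self, X, y=None):
        self.adjacency_ = self.transform(X)
        self.n_features_in_ = self.adjacency_.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Binary adjacency matrix for a count matrix ``X``."""
        if (self.n_edges is None) == (self.min_count is None):
            raise ValueError("set exactly one of n_edges or min_count")
        W = symmetrize_counts(as_count_array(X))
        if self.n_edges is not None:
            rng = np.random.default_rng(self.random_state)
            return threshold_to_edge_count(W, self.n_edges, rng)
        return threshold_at_count(W, self.min_count)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).adjacency_
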