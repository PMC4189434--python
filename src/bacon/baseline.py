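"""Thresholding baseline and point-vs-posterior comparison statistics.

The conventional way to turn streamline counts into a binary network is
to symmetrize the count matrix and keep pairs above a cutoff.  These
routines implement that baseline (with a posterior-matched edge budget),
the per-region centrality distance z_i between point and posterior
betweenness estimates, group-level edge-probability difference Z-maps,
and the Dirichlet simulation used to calibrate d0 against an expected
false-positive rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    Hyperparameters,
    as_count_array,
    expected_nonedge_mass,
    n_pairs,
    simulate_nonedge_mass,
)

__all__ = [
    "symmetrize_counts",
    "threshold_to_edge_count",
    "threshold_at_count",
    "CentralityDistance",
    "centrality_distance",
    "median_centrality_distance",
    "group_edge_difference",
    "d0_calibration",
]


def symmetrize_counts(counts) -> np.ndarray:
    """Sum streamline counts from either direction: W = N + N.T."""
    N = as_count_array(counts)
    return N + N.T


def threshold_to_edge_count(
    weights: np.ndarray, m_target: int, rng: np.random.Generator
) -> np.ndarray:
    """Binary graph with exactly ``m_target`` edges from a weight matrix.

    All pairs strictly above the cutoff weight are included; among pairs
    tied at the cutoff, the remainder are chosen uniformly at random.
    """
    W = np.asarray(weights)
    K = W.shape[0]
    M = n_pairs(K)
    if not 0 <= m_target <= M:
        raise ValueError(f"m_target must be in [0, {M}], got {m_target}")
    iu = np.triu_indices(K, 1)
    w = W[iu]
    A = np.zeros((K, K), dtype=np.int8)
    if m_target > 0:
        cutoff = np.sort(w)[::-1][m_target - 1]
        above = w > cutoff
        ties = np.flatnonzero(w == cutoff)
        need = m_target - int(above.sum())
        chosen = np.zeros(M, dtype=bool)
        chosen[above] = True
        chosen[rng.choice(ties, size=need, replace=False)] = True
        A[iu] = chosen
        A += A.T
    return A


def threshold_at_count(weights: np.ndarray, t: int) -> np.ndarray:
    """Binary graph keeping pairs with weight >= t (t=1 is maximally dense)."""
    if t < 0:
        raise ValueError("threshold must be non-negative")
    W = np.asarray(weights)
    K = W.shape[0]
    upper = np.triu(np.ones((K, K), dtype=bool), 1)
    A = ((W >= t) & upper).astype(np.int8)
    return A + A.T


@dataclass
class CentralityDistance:
    """Per-region distance between point and posterior betweenness.

    ``z[i] = (point[i] - posterior_median[i]) / posterior_std[i]``;
    entries with zero posterior standard deviation are NaN and flagged
    in ``undefined`` rather than silently zeroed.
    """

    z: np.ndarray
    point_estimate: np.ndarray
    posterior_median: np.ndarray
    posterior_std: np.ndarray
    undefined: np.ndarray


def centrality_distance(
    point_betweenness: np.ndarray, betweenness_posteriors: Sequence
) -> CentralityDistance:
    """Standardized distance z_i of a point estimate from the posterior.

    ``betweenness_posteriors`` is the per-node list of MetricPosterior
    objects from ``posterior_metric(..., "betweenness")``.
    """
    point = np.asarray(point_betweenness, dtype=np.float64)
    med = np.array([mp.median for mp in betweenness_posteriors])
    std = np.array([mp.std for mp in betweenness_posteriors])
    if point.shape != med.shape:
        raise ValueError("point estimate and posterior have different lengths")
    undefined = std == 0
    z = np.full(point.shape, np.nan)
    ok = ~undefined
    z[ok] = (point[ok] - med[ok]) / std[ok]
    return CentralityDistance(z, point, med, std, undefined)


def median_centrality_distance(distances: Sequence[CentralityDistance]) -> np.ndarray:
    """Per-region median of z_i across subjects (NaN-aware)."""
    zs = np.stack([d.z for d in distances])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        return np.nanmedian(zs, axis=0)


def group_edge_difference(
    thresholded_graphs: Sequence[np.ndarray],
    posterior_probs: Sequence[np.ndarray],
    z_cut: float = 2.3,
) -> tuple[np.ndarray, list[tuple[int, int, float]]]:
    """Group-level Z-map of thresholded minus posterior edge probabilities.

    Averages the thresholded adjacency matrices and the posterior
    edge-probability matrices over subjects; for every pair non-zero in
    either group mean, the difference (threshold mean - posterior mean)
    is standardized by the mean and standard deviation of the included
    differences.  Returns the symmetric Z matrix (zero outside the
    included pairs) and the pairs with |Z| > z_cut.
    """
    if len(thresholded_graphs) == 0 or len(thresholded_graphs) != len(posterior_probs):
        raise ValueError("need equal-length, non-empty subject lists")
    thr = np.mean([np.asarray(g, dtype=float) for g in thresholded_graphs], axis=0)
    post = np.mean([np.asarray(p, dtype=float) for p in posterior_probs], axis=0)
    if thr.shape != post.shape or thr.shape[0] != thr.shape[1]:
        raise ValueError("subject matrices must share one square shape")
    K = thr.shape[0]
    iu = np.triu_indices(K, 1)
    include = (thr[iu] != 0) | (post[iu] != 0)
    diffs = thr[iu][include] - post[iu][include]
    Z = np.zeros((K, K))
    extreme: list[tuple[int, int, float]] = []
    if diffs.size:
        sd = diffs.std(ddof=1) if diffs.size > 1 else 0.0
        if sd == 0:
            warnings.warn(
                "degenerate Z-transform: included differences have zero spread",
                RuntimeWarning,
            )
            z = np.zeros_like(diffs)
        else:
            z = (diffs - diffs.mean()) / sd
        zu = np.zeros(len(iu[0]))
        zu[include] = z
        Z[iu] = zu
        Z += Z.T
        for i, j, zij in zip(iu[0][include], iu[1][include], z):
            if abs(zij) > z_cut:
                extreme.append((int(i), int(j), float(zij)))
    return Z, extreme


def d0_calibration(
    d0_grid: Sequence[float],
    density_grid: Sequence[float],
    K: int = 90,
    d1: float = 1.0,
    n_draws: int = 100000,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Simulated and analytic false-positive mass over a (d0, density) grid.

    For each cell, a region of degree ``round(density * (K-1))`` is
    simulated by Dirichlet draws (d1 on edges, d0 off) and the mean
    probability mass on non-edges is tabulated next to the closed-form
    expectation.  This is the experiment behind the choice d0 = 0.01:
    at density 0.2 the expected false-positive rate is about 5%.
    """
    if len(d0_grid) == 0 or len(density_grid) == 0:
        raise ValueError("grids must be non-empty")
    if rng is None:
        rng = np.random.default_rng()
    n_targets = K - 1
    rows = []
    for d0 in d0_grid:
        hyper = Hyperparameters(d0=d0, d1=d1)
        for dens in density_grid:
            degree = int(round(dens * n_targets))
            sim, se = simulate_nonedge_mass(degree, n_targets, hyper, n_draws, rng)
            rows.append(
                {
                    "d0": d0,
                    "density": dens,
                    "degree": degree,
                    "simulated_mass": sim,
                    "simulated_se": se,
                    "analytic_mass": expected_nonedge_mass(degree, n_targets, hyper),
                }
            )
    return pd.DataFrame(rows)
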