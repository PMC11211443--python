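"""Distance-based comparison of diet composition between groups.

Bray-Curtis dissimilarity, the multi-response permutation procedure
(MRPP) with the chance-corrected within-group agreement statistic A, and
indicator species analysis (IndVal) with Monte Carlo significance.
Permutation p-values use the add-one rule, p = (1 + #{perm as extreme}) /
(n_perm + 1), and never return zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "MRPPResult",
    "IndicatorResult",
    "bray_curtis",
    "mrpp",
    "indicator_species",
]


def bray_curtis(matrix: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y)."""
    X = np.asarray(matrix, float)
    if np.any(X < 0):
        raise ValueError("Bray-Curtis requires non-negative data")
    sums = X.sum(axis=1)
    if np.count_nonzero(sums == 0) >= 2:
        raise ValueError("distance undefined between two all-zero rows")
    return squareform(pdist(X, metric="braycurtis"))


@dataclass
class MRPPResult:
    A: float
    observed_delta: float
    expected_delta: float
    p_value: float
    n_permutations: int


def _weighted_delta(dist: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    """Group-size-weighted mean within-group distance."""
    n = len(labels)
    delta = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = dist[np.ix_(idx, idx)]
        m = len(idx)
        delta += (m / n) * sub[np.triu_indices(m, k=1)].mean()
    return delta


def mrpp(
    dist: np.ndarray,
    labels,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> MRPPResult:
    """Multi-response permutation procedure on a precomputed distance matrix.

    Observed delta is the group-size-weighted mean within-group distance;
    A = 1 - observed/expected where expected is the permutation mean;
    p is the lower-tail add-one permutation probability.  ``exhaustive``
    enumerates every distinct label permutation instead of sampling.
    """
    dist = np.asarray(dist, float)
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("MRPP needs at least two groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least two members")

    observed = _weighted_delta(dist, labels, groups)

    if exhaustive:
        perms = np.array(list(set(itertools.permutations(labels))))
        deltas = np.array([_weighted_delta(dist, p, groups) for p in perms])
        expected = float(deltas.mean())
        # exact test over the permutation distribution
        p = float((deltas <= observed + 1e-12).mean())
        return MRPPResult(1.0 - observed / expected, observed, expected, p, len(perms))

    rng = np.random.default_rng(seed)
    deltas = np.empty(n_perm)
    lab = labels.copy()
    for i in range(n_perm):
        rng.shuffle(lab)
        deltas[i] = _weighted_delta(dist, lab, groups)
    expected = float(deltas.mean())
    p = (1 + int((deltas <= observed + 1e-12).sum())) / (n_perm + 1)
    return MRPPResult(1.0 - observed / expected, observed, expected, p, n_perm)


@dataclass
class IndicatorResult:
    indval: pd.DataFrame  # taxa x groups, 0..100
    max_indval: pd.Series  # per taxon
    best_group: pd.Series
    p_values: pd.Series
    n_permutations: int


def _indval_matrix(X: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """IndVal_{i,g} = 100 * specificity * fidelity for every taxon/group."""
    n_taxa = X.shape[1]
    means = np.empty((len(groups), n_taxa))
    fidel = np.empty((len(groups), n_taxa))
    for k, g in enumerate(groups):
        sub = X[labels == g]
        means[k] = sub.mean(axis=0)
        fidel[k] = (sub > 0).mean(axis=0)
    denom = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        spec = np.where(denom > 0, means / denom, 0.0)
    return 100.0 * spec * fidel


def indicator_species(
    matrix: pd.DataFrame | np.ndarray,
    labels,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> IndicatorResult:
    """Dufrene-Legendre indicator value analysis with permutation tests.

    Per taxon the statistic is the maximum IndVal over groups; p is the
    add-one upper-tail permutation probability of that maximum.
    """
    if isinstance(matrix, pd.DataFrame):
        taxa = list(matrix.columns)
        X = matrix.to_numpy(float)
    else:
        X = np.asarray(matrix, float)
        taxa = [f"taxon_{i}" for i in range(X.shape[1])]
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("indicator analysis needs at least two groups")

    obs = _indval_matrix(X, labels, groups)
    max_obs = obs.max(axis=0)
    best = groups[obs.argmax(axis=0)]

    if exhaustive:
        perms = list(set(itertools.permutations(labels)))
        maxima = np.array([_indval_matrix(X, np.array(p), groups).max(axis=0) for p in perms])
        p_vals = (maxima >= max_obs - 1e-12).mean(axis=0)
        n_done = len(perms)
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(X.shape[1])
        lab = labels.copy()
        for _ in range(n_perm):
            rng.shuffle(lab)
            exceed += _indval_matrix(X, lab, groups).max(axis=0) >= max_obs - 1e-12
        p_vals = (1 + exceed) / (n_perm + 1)
        n_done = n_perm
    absent = X.sum(axis=0) == 0
    p_vals = np.where(absent, 1.0, p_vals)
    return IndicatorResult(
        indval=pd.DataFrame(obs.T, index=taxa, columns=groups),
        max_indval=pd.Series(max_obs, index=taxa),
        best_group=pd.Series(best, index=taxa),
        p_values=pd.Series(p_vals, index=taxa),
        n_permutations=n_done,
    )
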