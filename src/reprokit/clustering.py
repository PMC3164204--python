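"""Fuzzy c-means clustering of regulated expression profiles.

Soft partitioning of per-probe contrast profiles (z-scored) with the
standard FCM alternation; the fuzzifier m controls how soft memberships
are (m -> 1 approaches k-means hard assignment).  The alpha-core of a
cluster keeps only members whose maximal membership clears a threshold,
discarding poorly clustered profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_FUZZIFIER = 1.7
DEFAULT_ALPHA = 0.5


@dataclass
class FuzzyClusterResult:
    centroids: np.ndarray          # c x p
    membership: pd.DataFrame       # n x c, rows sum to 1
    n_iter: int
    converged: bool
    objective: list[float]

    def __post_init__(self) -> None:
        if self.centroids.shape[0] < 2:
            raise ValueError("need at least 2 clusters")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("non-finite centroids")
        rowsum = self.membership.to_numpy().sum(axis=1)
        if np.any(np.abs(rowsum - 1.0) > 1e-9):
            raise ValueError("membership rows must sum to 1")


def standardize_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row across conditions; constant rows map to zeros."""
    arr = profiles.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((arr - mean) / sd, index=profiles.index,
                        columns=profiles.columns)


def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update u_ij ∝ (1/d_ij^2)^(1/(m-1)), rows normalized.
    Points coinciding with a centroid get membership 1 there (limit)."""
    exp = 1.0 / (m - 1.0)
    zero = d2 <= 1e-300
    # normalize by the row minimum before exponentiation so small
    # fuzzifiers (large exponents) cannot overflow
    d2s = np.maximum(d2, 1e-300)
    ratio = d2s / d2s.min(axis=1, keepdims=True)
    with np.errstate(under="ignore"):
        w = ratio ** (-exp)
    u = w / w.sum(axis=1, keepdims=True)
    hit = zero.any(axis=1)
    if hit.any():
        u[hit] = 0.0
        first = zero[hit].argmax(axis=1)
        u[np.flatnonzero(hit), first] = 1.0
    return u


def fuzzy_cmeans(profiles: pd.DataFrame, c: int, m: float = DEFAULT_FUZZIFIER,
                 tol: float = 1e-6, max_iter: int = 300,
                 rng_seed: int = 0, standardize: bool = True) -> FuzzyClusterResult:
    """Fuzzy c-means with Euclidean distance on (optionally) z-scored rows.

    Initial centroids are ``c`` distinct profiles sampled by the seeded
    RNG; the alternation stops when the maximal centroid shift drops
    below ``tol`` or after ``max_iter`` sweeps.  The objective
    sum(u^m d^2) is recorded per iteration and is non-increasing.
    """
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    n = profiles.shape[0]
    if not n > c >= 2:
        raise ValueError("need n > c >= 2")
    X = (standardize_profiles(profiles) if standardize else profiles).to_numpy(dtype=float)
    rng = np.random.default_rng(rng_seed)
    centroids = X[rng.choice(n, size=c, replace=False)].copy()

    objective: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        u = _memberships(d2, m)
        objective.append(float((u ** m * d2).sum()))
        um = u ** m
        new_centroids = (um.T @ X) / um.sum(axis=0)[:, None]
        shift = np.abs(new_centroids - centroids).max()
        centroids = new_centroids
        if shift < tol:
            converged = True
            break
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    u = _memberships(d2, m)
    membership = pd.DataFrame(u, index=profiles.index,
                              columns=[f"C{j + 1}" for j in range(c)])
    return FuzzyClusterResult(centroids, membership, it, converged, objective)


def alpha_core(result: FuzzyClusterResult, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Assign each profile to its argmax cluster iff that membership
    reaches ``alpha``; below-threshold profiles stay unassigned.

    Returns a DataFrame (index = profile id) with columns ``cluster``
    (label or None), ``membership`` and ``in_alpha_core``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    u = result.membership
    best = u.idxmax(axis=1)
    best_val = u.max(axis=1)
    in_core = best_val >= alpha
    return pd.DataFrame({
        "cluster": best.where(in_core, None),
        "membership": best_val,
        "in_alpha_core": in_core,
    })


def core_members(assignment: pd.DataFrame) -> dict[str, list[str]]:
    """Per-cluster lists of alpha-core member ids."""
    out: dict[str, list[str]] = {}
    core = assignment[assignment["in_alpha_core"]]
    for cluster, sub in core.groupby("cluster", sort=True):
        out[str(cluster)] = list(sub.index)
    return out
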