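"""Statistical evaluation of ID-fingerprint analyses.

* scaled PCA on ID allele frequencies (each allele contributes equal
  variance after scaling),
* Mantel permutation test between distance matrices (e.g. geographic vs
  genetic),
* an exact / permutation test for replicate-specific clades, and
* the conjugate Beta-binomial posterior for the per-split recovery
  probability used to compare reconstructed trees against a random-tree
  null.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fingerprint import FL_LABEL, FrequencyMatrix

__all__ = [
    "PCAResult",
    "scaled_pca",
    "mantel_test",
    "clade_permutation_test",
    "SplitPosterior",
    "split_share_posterior",
    "spearman_with_coordinate",
    "haversine_distance_matrix",
]


# ---------------------------------------------------------------------------
# scaled PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # alleles x components
    variance_fraction: np.ndarray
    contributions: pd.DataFrame   # alleles x components, columns sum to 1

    def contribution_to(self, component: int = 1) -> pd.Series:
        return self.contributions[f"PC{component}"].sort_values(ascending=False)


def scaled_pca(
    matrix: FrequencyMatrix,
    exclude: Optional[Sequence[str]] = None,
) -> PCAResult:
    """PCA of the ID allele frequencies with unit-variance scaling.

    The FL column is excluded (it is the complement of the IDs); constant
    columns are dropped with a warning; ``exclude`` removes named alleles
    (e.g. the KP deletion) before the decomposition.  Columns are centered
    and scaled so every retained allele contributes equal variance; scores
    come from the SVD of the standardized matrix.  Components are oriented
    so that the largest-magnitude loading is positive.
    """
    cols = [c for c in matrix.id_alleles if not exclude or c not in set(exclude)]
    x = matrix.table[cols].to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least three samples")
    sd = x.std(axis=0, ddof=1)
    const = sd <= 1e-12
    if const.any():
        warnings.warn(f"dropping {int(const.sum())} constant allele columns")
        cols = [c for c, bad in zip(cols, const) if not bad]
        x = x[:, ~const]
        sd = sd[~const]
    if x.shape[1] < 2:
        raise ValueError("need at least two non-constant ID alleles")
    z = (x - x.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    # orient each component so its largest-|loading| entry is positive
    for k in range(len(s)):
        imax = int(np.argmax(np.abs(vt[k])))
        if vt[k, imax] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    scores = u * s
    var = s**2
    var_frac = var / var.sum() if var.sum() > 0 else var
    pcs = [f"PC{k + 1}" for k in range(len(s))]
    loadings = pd.DataFrame(vt.T, index=cols, columns=pcs)
    contrib = loadings**2
    contrib = contrib / contrib.sum(axis=0)
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.samples, columns=pcs),
        loadings=loadings,
        variance_fraction=var_frac,
        contributions=contrib,
    )


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


def _upper(arr: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(arr.shape[0], k=1)
    return arr[iu]


def mantel_test(
    D1,
    D2,
    n_perm: int = 100_000,
    rng: Optional[np.random.Generator] = None,
) -> tuple:
    """One-sided Mantel permutation test for positive association.

    Pearson correlation of the off-diagonal upper triangles; the null is
    generated by simultaneous row/column permutation of ``D2``;
    ``p = (1 + #{r_perm >= r_obs}) / (1 + n_perm)``.

    ``D1``/``D2`` are square arrays or ``skbio.DistanceMatrix`` with
    matching label order.  Returns ``(r, p)``.
    """
    rng = rng if rng is not None else np.random.default_rng()

    def coerce(D):
        if hasattr(D, "data") and hasattr(D, "ids"):
            return list(D.ids), np.asarray(D.data, dtype=float)
        return None, np.asarray(D, dtype=float)

    ids1, a1 = coerce(D1)
    ids2, a2 = coerce(D2)
    if a1.shape != a2.shape or a1.ndim != 2 or a1.shape[0] != a1.shape[1]:
        raise ValueError("distance matrices must be square and equally sized")
    if ids1 is not None and ids2 is not None and ids1 != ids2:
        raise ValueError("distance matrices must carry the same labels in order")
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    x = _upper(a1)
    r_obs = float(np.corrcoef(x, _upper(a2))[0, 1])
    n = a1.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r = np.corrcoef(x, _upper(a2[np.ix_(perm, perm)]))[0, 1]
        if r >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return r_obs, p


# ---------------------------------------------------------------------------
# replicate-clade permutation test
# ---------------------------------------------------------------------------


def _canonical_partition(groups) -> frozenset:
    return frozenset(frozenset(g) for g in groups)


def clade_permutation_test(
    partition: Sequence[Sequence],
    n_perm: int = 100_000,
    rng: Optional[np.random.Generator] = None,
    exact: bool = False,
) -> float:
    """Probability that a random equal-partition of the samples matches the
    observed grouping up to relabeling of the groups.

    Used for the question "do samples from the same invasion replicate fall
    into replicate-specific clades?": with g groups of sizes s_i over n
    samples the exact probability of the matched partition is
    ``g! * prod(s_i!) / n!``.  The permutation estimate shuffles the sample
    labels, cuts them into consecutive groups of the observed sizes, and
    applies +1 smoothing.
    """
    groups = [list(g) for g in partition]
    sizes = [len(g) for g in groups]
    if len(set(sizes)) != 1:
        raise ValueError("groups must be of equal size")
    items = [x for g in groups for x in g]
    n = len(items)
    if len(set(map(str, items))) != n:
        raise ValueError("samples must be unique across groups")
    if exact:
        g = len(groups)
        num = math.factorial(g) * math.prod(math.factorial(s) for s in sizes)
        return num / math.factorial(n)
    rng = rng if rng is not None else np.random.default_rng()
    target = _canonical_partition(groups)
    arr = np.array([str(x) for x in items])
    bounds = np.cumsum([0] + sizes)
    # vectorized batches: each permutation is one row of shuffled labels
    hits = 0
    batch = 100_000
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        order = np.argsort(rng.random((b, n)), axis=1)
        shuffled = arr[order]
        for row in shuffled:
            parts = _canonical_partition(
                row[bounds[k]:bounds[k + 1]] for k in range(len(sizes))
            )
            if parts == target:
                hits += 1
        done += b
    return (1 + hits) / (1 + n_perm)


# ---------------------------------------------------------------------------
# Beta-binomial posterior for shared-split recovery
# ---------------------------------------------------------------------------


@dataclass
class SplitPosterior:
    """Posterior for the per-split recovery probability p under
    k_t ~ Binomial(n_max, p) per tree with a flat Beta(1, 1) prior."""

    alpha: float
    beta: float

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    def credible_interval(self, level: float = 0.95) -> tuple:
        lo = (1 - level) / 2
        dist = sps.beta(self.alpha, self.beta)
        return float(dist.ppf(lo)), float(dist.ppf(1 - lo))

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return rng.beta(self.alpha, self.beta, size=size)


def split_share_posterior(shared_counts: Sequence[int], n_max: int = 8) -> SplitPosterior:
    """Conjugate update: T trees with shared-split counts k_t in
    [0, n_max] give posterior Beta(1 + sum k, 1 + T * n_max - sum k)."""
    counts = np.asarray(shared_counts, dtype=int)
    if counts.size and (counts.min() < 0 or counts.max() > n_max):
        raise ValueError(f"shared counts must lie in [0, {n_max}]")
    total = int(counts.sum())
    trials = int(counts.size) * n_max
    return SplitPosterior(alpha=1.0 + total, beta=1.0 + trials - total)


# ---------------------------------------------------------------------------
# geography utilities
# ---------------------------------------------------------------------------

_EARTH_RADIUS_KM = 6371.0088


def haversine_distance_matrix(coords: pd.DataFrame) -> np.ndarray:
    """Great-circle distances (km) from a table with columns ``lat`` and
    ``lon`` in decimal degrees; rows are samples."""
    lat = np.radians(coords["lat"].to_numpy(dtype=float))
    lon = np.radians(coords["lon"].to_numpy(dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def spearman_with_coordinate(scores: pd.Series, coordinate: pd.Series) -> tuple:
    """Tie-corrected Spearman rank correlation of a PC score with a
    geographic coordinate; returns (rho, p) with the t approximation."""
    joined = pd.concat([scores, coordinate], axis=1, join="inner").dropna()
    rho, p = sps.spearmanr(joined.iloc[:, 0], joined.iloc[:, 1])
    return float(rho), float(p)
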