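"""Derived feature vector for a duplicate triplet: p = 4m + 84 features.

The layout, fixed and versioned, is:

==================  ============================================================
index (1-based)     feature
==================  ============================================================
1                   t_pc (scaled duplication time)
2 .. 3m+1           raw triplet (eP1, eC1, eA1, ..., ePm, eCm, eAm)
3m+2 .. 4m+1        per-tissue combined expression eP + eC
4m+2 .. 4m+5        dist(P,C), dist(P,A), dist(C,A), dist(PC,A)  (Euclidean)
4m+6 .. 4m+8        branch(P), branch(C), branch(A)  (three-point formulas)
4m+9 .. 4m+12       ranks of the four distances among dist(G)
4m+13 .. 4m+44      kth raw moments of [dist - dist(G)] / max{dist(G)}, k=1..8
4m+45 .. 4m+48      cor(P,C), cor(P,A), cor(C,A), cor(PC,A)  (Pearson)
4m+49 .. 4m+52      ranks of the four correlations among cor(G)
4m+53 .. 4m+84      kth raw moments of [cor - cor(G)], k=1..8
==================  ============================================================

Rank/moment features compare the triplet's divergence to the genome-wide
single-copy background, so the network learns "how unusual is this
divergence" rather than absolute distances.  Moments are raw (non-central)
moments of the difference distribution; ranks are 1-based counts of pool
elements strictly below the value.
"""

from __future__ import annotations

from math import comb

import numpy as np

from .background import BackgroundDistributions, pearson_rows

__all__ = [
    "FEATURE_VERSION",
    "K_MOMENTS",
    "n_features",
    "feature_names",
    "pairwise_distances",
    "branch_lengths",
    "pairwise_correlations",
    "rank_among",
    "normalized_moments",
    "assemble_feature_vector",
    "assemble_feature_matrix",
]

FEATURE_VERSION = "oudup-features-v1"
K_MOMENTS = 8

_PAIRS = ("PC", "PA", "CA", "PCtoA")


def n_features(m: int) -> int:
    """p = 4m + 84."""
    return 4 * m + 84


def feature_names(m: int) -> list[str]:
    """Versioned column names, f001.. in the fixed layout order."""
    names: list[str] = ["tpc"]
    for j in range(1, m + 1):
        names += [f"eP{j}", f"eC{j}", f"eA{j}"]
    names += [f"ePC{j}" for j in range(1, m + 1)]
    names += [f"dist_{p}" for p in _PAIRS]
    names += ["branch_P", "branch_C", "branch_A"]
    names += [f"rank_dist_{p}" for p in _PAIRS]
    names += [f"mom_dist_{p}_k{k}" for p in _PAIRS for k in range(1, K_MOMENTS + 1)]
    names += [f"cor_{p}" for p in _PAIRS]
    names += [f"rank_cor_{p}" for p in _PAIRS]
    names += [f"mom_cor_{p}_k{k}" for p in _PAIRS for k in range(1, K_MOMENTS + 1)]
    assert len(names) == n_features(m)
    return [f"f{i + 1:03d}_{n}" for i, n in enumerate(names)]


def _split_triplet(triplets: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = np.atleast_2d(np.asarray(triplets, dtype=float))
    if t.shape[1] % 3 != 0:
        raise ValueError("triplet length must be a multiple of 3")
    return t[:, 0::3], t[:, 1::3], t[:, 2::3]


def pairwise_distances(triplets: np.ndarray) -> tuple[np.ndarray, ...]:
    """Euclidean distances over tissues: dist(P,C), dist(P,A), dist(C,A) and
    dist(PC,A), the latter comparing per-tissue eP + eC against eA.

    Accepts a single 3m-vector or an (n, 3m) matrix; returns scalars or
    (n,) arrays accordingly.
    """
    squeeze = np.asarray(triplets).ndim == 1
    ep, ec, ea = _split_triplet(triplets)

    def d(a, b):
        out = np.sqrt(((a - b) ** 2).sum(axis=1))
        return float(out[0]) if squeeze else out

    return d(ep, ec), d(ep, ea), d(ec, ea), d(ep + ec, ea)


def branch_lengths(dpc, dpa, dca):
    """Three-point branch lengths from the pairwise distances.

    branch(P) = (dPC + dPA - dCA)/2 and cyclic analogues.  Negative values
    (three-point condition failures) are passed through: these are features,
    not tree estimates.
    """
    bp = (dpc + dpa - dca) / 2.0
    bc = (dpc + dca - dpa) / 2.0
    ba = (dpa + dca - dpc) / 2.0
    return bp, bc, ba


def pairwise_correlations(triplets: np.ndarray) -> tuple[np.ndarray, ...]:
    """Pearson correlations across tissues: cor(P,C), cor(P,A), cor(C,A),
    cor(PC,A).  Constant vectors yield 0 with a warning."""
    squeeze = np.asarray(triplets).ndim == 1
    ep, ec, ea = _split_triplet(triplets)
    if ep.shape[1] < 2:
        raise ValueError("need m >= 2 tissues for correlations")

    def c(a, b):
        out = pearson_rows(a, b)
        return float(out[0]) if squeeze else out

    return c(ep, ec), c(ep, ea), c(ec, ea), c(ep + ec, ea)


def rank_among(values, pool: np.ndarray):
    """1-based rank: 1 + number of pool elements strictly less than the value
    (ties take the lower rank).  Vectorized over ``values``."""
    pool_sorted = np.sort(np.asarray(pool, dtype=float))
    ranks = 1 + np.searchsorted(pool_sorted, np.asarray(values, dtype=float), side="left")
    if np.isscalar(values) or np.asarray(values).ndim == 0:
        return int(ranks)
    return ranks.astype(float)


def _pool_power_means(pool: np.ndarray, k_max: int) -> np.ndarray:
    """Mean of pool**j for j = 0..k_max (the precomputation behind the
    binomial-expansion moment evaluation)."""
    pool = np.asarray(pool, dtype=float)
    return np.array([np.mean(pool**j) for j in range(k_max + 1)])


def normalized_moments(
    values,
    pool: np.ndarray,
    normalizer: float = 1.0,
    k_max: int = K_MOMENTS,
    _power_means: np.ndarray | None = None,
):
    """kth raw moments of (value - pool)/normalizer for k = 1..k_max.

    Expanding ((v - g)/c)^k binomially reduces the pool sum to precomputed
    power means, making each query O(k_max^2) instead of O(|pool| * k_max).
    Vectorized over ``values``; returns shape (..., k_max).
    """
    if normalizer <= 0:
        raise ValueError("normalizer must be positive")
    pm = _power_means if _power_means is not None else _pool_power_means(pool, k_max)
    v = np.asarray(values, dtype=float)
    squeeze = v.ndim == 0
    v = np.atleast_1d(v)
    out = np.empty((v.size, k_max))
    vp = np.vander(v, k_max + 1, increasing=True)  # v**0 .. v**k_max
    for k in range(1, k_max + 1):
        acc = np.zeros_like(v)
        for j in range(k + 1):
            acc += comb(k, j) * ((-1.0) ** j) * pm[j] * vp[:, k - j]
        out[:, k - 1] = acc / normalizer**k
    return out[0] if squeeze else out


def assemble_feature_matrix(
    triplets: np.ndarray, t_pc: np.ndarray, background: BackgroundDistributions
) -> np.ndarray:
    """Build the (n, 4m+84) feature matrix for ``n`` triplets at once."""
    triplets = np.atleast_2d(np.asarray(triplets, dtype=float))
    n, threem = triplets.shape
    if threem % 3 != 0:
        raise ValueError("triplet width must be a multiple of 3")
    m = threem // 3
    t_pc = np.broadcast_to(np.asarray(t_pc, dtype=float), (n,))

    ep, ec, ea = _split_triplet(triplets)
    dists = pairwise_distances(triplets)
    branches = branch_lengths(*dists[:3])
    cors = pairwise_correlations(triplets)

    dist_pm = _pool_power_means(background.dist_g, K_MOMENTS)
    cor_pm = _pool_power_means(background.cor_g, K_MOMENTS)

    blocks = [t_pc[:, None], triplets, ep + ec]
    blocks += [np.column_stack(dists), np.column_stack(branches)]
    blocks += [np.column_stack([rank_among(d, background.dist_sorted) for d in dists])]
    blocks += [
        normalized_moments(d, background.dist_g, background.max_dist, _power_means=dist_pm)
        for d in dists
    ]
    blocks += [np.column_stack(cors)]
    blocks += [np.column_stack([rank_among(c, background.cor_sorted) for c in cors])]
    blocks += [
        normalized_moments(c, background.cor_g, 1.0, _power_means=cor_pm) for c in cors
    ]
    x = np.hstack(blocks)
    assert x.shape == (n, n_features(m))
    return x


def assemble_feature_vector(
    triplet: np.ndarray, t_pc: float, background: BackgroundDistributions
) -> np.ndarray:
    """Feature vector for a single triplet; see the module docstring for the
    exact layout."""
    triplet = np.asarray(triplet, dtype=float)
    if triplet.ndim != 1:
        raise ValueError("expected a single 3m-vector; use assemble_feature_matrix")
    return assemble_feature_matrix(triplet[None, :], np.array([t_pc]), background)[0]
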