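"""Ornstein-Uhlenbeck model of expression evolution on a three-gene tree.

After a duplication at scaled time ``t_pc`` on a two-species tree of root
height 1, the expression level of the parent copy (P), child copy (C) and the
single-copy ancestral ortholog (A) in the sister species is, per tissue,
multivariate normal with a mean pulled from the ancestral optimum ``theta_a``
toward the copy-specific optima ``theta_p`` / ``theta_c`` at rate ``alpha``,
and a covariance set by the drift rate ``sigma2`` and the shared branch
lengths.  Five retention mechanisms (conservation, neofunctionalization of
either copy, subfunctionalization, specialization) are encoded as equality /
additivity constraints on the per-tissue optima; scenarios drawn under those
constraints are the supervised training signal for the downstream classifier.

Tissues are treated as independent: an ``m``-tissue observation is ``m``
independent 3-dimensional MVN draws, flattened in (P, C, A) tissue-major
order.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RetentionClass",
    "CLASS_LABELS",
    "GeneTreeTimes",
    "TissueOUParams",
    "ParameterRanges",
    "DuplicateScenario",
    "ou_mean",
    "ou_covariance",
    "sample_expression_triplet",
    "draw_scenario_parameters",
    "draw_parameter_batch",
    "sample_triplet_batch",
]

#: tolerance below which two optima are considered equal when enforcing the
#: strict-inequality class constraints (reject-and-resample)
NEQ_TOL = 1e-6


class RetentionClass(enum.IntEnum):
    """The five duplicate-gene retention mechanisms (fixed integer encoding)."""

    CONSERVED = 0
    NEOFUNCTIONALIZED_PARENT = 1
    NEOFUNCTIONALIZED_CHILD = 2
    SUBFUNCTIONALIZED = 3
    SPECIALIZED = 4


CLASS_LABELS = (
    "Conserved",
    "NeofunctionalizedParent",
    "NeofunctionalizedChild",
    "Subfunctionalized",
    "Specialized",
)


class InvalidParameterError(ValueError):
    """Raised when OU parameters violate their domain (alpha, sigma2 > 0...)."""


@dataclass(frozen=True)
class GeneTreeTimes:
    """Scaled node times of the ((P,C),A) gene tree.

    ``t_pc`` is the duplication time divided by the root height; ``t_pca`` is
    the root time after scaling (1 by construction).
    """

    t_pc: float
    t_pca: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.t_pc < self.t_pca):
            raise InvalidParameterError(
                f"need 0 < t_pc < t_pca, got t_pc={self.t_pc}, t_pca={self.t_pca}"
            )


@dataclass(frozen=True)
class TissueOUParams:
    """Per-tissue OU parameters: optima (log10 expression units), selection
    strength ``alpha`` and drift variance rate ``sigma2`` (per unit scaled
    time)."""

    theta_p: float
    theta_c: float
    theta_a: float
    alpha: float
    sigma2: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise InvalidParameterError(f"alpha must be > 0, got {self.alpha}")
        if not self.sigma2 > 0:
            raise InvalidParameterError(f"sigma2 must be > 0, got {self.sigma2}")
        for name in ("theta_p", "theta_c", "theta_a"):
            if not np.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")


@dataclass(frozen=True)
class ParameterRanges:
    """Training-simulation parameter ranges (log10 scale for alpha, sigma2)."""

    theta: tuple[float, float] = (-4.0, 4.0)
    log10_alpha: tuple[float, float] = (0.0, 3.0)
    log10_sigma2: tuple[float, float] = (-2.0, 3.0)


@dataclass
class DuplicateScenario:
    """A retention scenario: tree times, per-tissue OU parameters, class label.

    ``cls`` is a single label for uniform scenarios or a per-tissue list for
    mixed-mechanism scenarios.
    """

    tree: GeneTreeTimes
    per_tissue: list[TissueOUParams]
    cls: RetentionClass | list[RetentionClass]

    @property
    def m(self) -> int:
        return len(self.per_tissue)


def ou_mean(params: TissueOUParams, tree: GeneTreeTimes) -> np.ndarray:
    """Expected (P, C, A) expression under the OU model.

    The parent/child means are convex combinations of the copy optimum and the
    ancestral optimum with weight ``exp(-alpha * t_pc)`` on the ancestor; the
    ancestral gene sits at its own optimum.
    """
    w = np.exp(-params.alpha * tree.t_pc)
    return np.array(
        [
            (1.0 - w) * params.theta_p + w * params.theta_a,
            (1.0 - w) * params.theta_c + w * params.theta_a,
            params.theta_a,
        ]
    )


def ou_covariance(params: TissueOUParams, tree: GeneTreeTimes) -> np.ndarray:
    """3x3 stationary-scaled OU covariance of (P, C, A) expression.

    Variances are ``sigma2 / (2 alpha)``; the P-C covariance decays with the
    time since duplication, and both covariances with A decay with the time
    since speciation.
    """
    s = params.sigma2 / (2.0 * params.alpha)
    a = np.exp(-2.0 * params.alpha * tree.t_pc)
    b = np.exp(-2.0 * params.alpha * tree.t_pca)
    return s * np.array([[1.0, a, b], [a, 1.0, b], [b, b, 1.0]])


def _split(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def sample_expression_triplet(
    scenario: DuplicateScenario, n: int, rng_seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` expression triplets; returns an (n, 3m) array ordered
    (eP1, eC1, eA1, ..., ePm, eCm, eAm)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _split(rng_seed)
    m = scenario.m
    out = np.empty((n, 3 * m))
    for j, params in enumerate(scenario.per_tissue):
        mu = ou_mean(params, scenario.tree)
        sigma = ou_covariance(params, scenario.tree)
        out[:, 3 * j : 3 * j + 3] = rng.multivariate_normal(
            mu, sigma, size=n, method="cholesky"
        )
    return out


def _draw_thetas(
    cls: RetentionClass, n: int, m: int, ranges: ParameterRanges, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (n, m) draws of (theta_p, theta_c, theta_a) under the class
    constraints, with reject-and-resample of near-equalities at NEQ_TOL."""
    lo, hi = ranges.theta

    def u() -> np.ndarray:
        return rng.uniform(lo, hi, size=(n, m))

    if cls == RetentionClass.CONSERVED:
        th = u()
        return th, th.copy(), th.copy()

    if cls == RetentionClass.NEOFUNCTIONALIZED_PARENT:
        th = u()
        tp = u()
        bad = np.abs(tp - th) < NEQ_TOL
        while bad.any():
            tp[bad] = rng.uniform(lo, hi, size=int(bad.sum()))
            bad = np.abs(tp - th) < NEQ_TOL
        return tp, th.copy(), th

    if cls == RetentionClass.NEOFUNCTIONALIZED_CHILD:
        th = u()
        tc = u()
        bad = np.abs(tc - th) < NEQ_TOL
        while bad.any():
            tc[bad] = rng.uniform(lo, hi, size=int(bad.sum()))
            bad = np.abs(tc - th) < NEQ_TOL
        return th.copy(), tc, th

    if cls == RetentionClass.SUBFUNCTIONALIZED:
        ta = u()
        tp = u()
        # theta_c is forced by the additivity constraint; reject draws where
        # either copy would coincide with the ancestral optimum
        bad = (np.abs(tp - ta) < NEQ_TOL) | (np.abs(ta - tp - ta) < NEQ_TOL)
        while bad.any():
            tp[bad] = rng.uniform(lo, hi, size=int(bad.sum()))
            bad = (np.abs(tp - ta) < NEQ_TOL) | (np.abs((ta - tp) - ta) < NEQ_TOL)
        return tp, ta - tp, ta

    if cls == RetentionClass.SPECIALIZED:
        ta = u()
        tp = u()
        tc = u()

        def bad_mask(tp_, tc_, ta_):
            return (
                (np.abs(tp_ - ta_) < NEQ_TOL)
                | (np.abs(tc_ - ta_) < NEQ_TOL)
                | (np.abs(tp_ + tc_ - ta_) < NEQ_TOL)
            )

        bad = bad_mask(tp, tc, ta)
        while bad.any():
            k = int(bad.sum())
            tp[bad] = rng.uniform(lo, hi, size=k)
            tc[bad] = rng.uniform(lo, hi, size=k)
            bad = bad_mask(tp, tc, ta)
        return tp, tc, ta

    raise ValueError(f"unknown retention class: {cls!r}")


def draw_parameter_batch(
    cls: RetentionClass,
    n: int,
    m: int,
    t_pc: np.ndarray,
    ranges: ParameterRanges | None = None,
    rng: int | np.random.Generator = 0,
) -> dict[str, np.ndarray]:
    """Draw ``n`` scenarios' worth of per-tissue parameters as flat arrays.

    Returns a dict with keys ``theta_p``, ``theta_c``, ``theta_a``, ``alpha``,
    ``sigma2`` of shape (n, m) plus ``t_pc`` of shape (n,).  This is the
    vectorized workhorse behind :func:`draw_scenario_parameters` and the
    experiment-scale dataset generators.
    """
    ranges = ranges or ParameterRanges()
    rng = _split(rng)
    t_pc = np.asarray(t_pc, dtype=float)
    if t_pc.shape != (n,):
        raise ValueError("t_pc must have shape (n,)")
    tp, tc, ta = _draw_thetas(cls, n, m, ranges, rng)
    alpha = 10.0 ** rng.uniform(*ranges.log10_alpha, size=(n, m))
    sigma2 = 10.0 ** rng.uniform(*ranges.log10_sigma2, size=(n, m))
    return {
        "t_pc": t_pc,
        "theta_p": tp,
        "theta_c": tc,
        "theta_a": ta,
        "alpha": alpha,
        "sigma2": sigma2,
    }


def draw_scenario_parameters(
    cls: RetentionClass,
    tree_times: GeneTreeTimes,
    m: int,
    ranges: ParameterRanges | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> DuplicateScenario:
    """Draw one retention scenario: per-tissue OU parameters under the class's
    optimum constraints, alpha and sigma2 log-uniform within ``ranges``."""
    batch = draw_parameter_batch(
        cls, 1, m, np.array([tree_times.t_pc]), ranges, rng_seed
    )
    per_tissue = [
        TissueOUParams(
            theta_p=batch["theta_p"][0, j],
            theta_c=batch["theta_c"][0, j],
            theta_a=batch["theta_a"][0, j],
            alpha=batch["alpha"][0, j],
            sigma2=batch["sigma2"][0, j],
        )
        for j in range(m)
    ]
    return DuplicateScenario(tree=tree_times, per_tissue=per_tissue, cls=cls)


def sample_triplet_batch(
    params: dict[str, np.ndarray],
    rng: int | np.random.Generator,
    t_pca: float = 1.0,
) -> np.ndarray:
    """One MVN expression triplet per scenario row, vectorized over scenarios.

    ``params`` is the dict produced by :func:`draw_parameter_batch`.  The 3x3
    per-tissue Cholesky factor has closed form, so the whole batch reduces to
    elementwise arithmetic on standard-normal draws.  Returns (n, 3m).
    """
    rng = _split(rng)
    tp, tc, ta = params["theta_p"], params["theta_c"], params["theta_a"]
    alpha, sigma2 = params["alpha"], params["sigma2"]
    t_pc = params["t_pc"][:, None]
    n, m = tp.shape

    w = np.exp(-alpha * t_pc)
    mu_p = (1.0 - w) * tp + w * ta
    mu_c = (1.0 - w) * tc + w * ta
    mu_a = ta

    s = sigma2 / (2.0 * alpha)
    a = np.exp(-2.0 * alpha * t_pc)
    b = np.exp(-2.0 * alpha * t_pca)
    # Cholesky of [[1,a,b],[a,1,b],[b,b,1]] (rows P, C, A)
    l21 = a
    l22 = np.sqrt(np.maximum(1.0 - a * a, 0.0))
    l31 = b
    with np.errstate(invalid="ignore", divide="ignore"):
        l32 = np.where(l22 > 0.0, b * (1.0 - a) / l22, 0.0)
    l33 = np.sqrt(np.maximum(1.0 - l31 * l31 - l32 * l32, 0.0))

    z = rng.standard_normal((n, m, 3))
    sd = np.sqrt(s)
    e_p = mu_p + sd * z[:, :, 0]
    e_c = mu_c + sd * (l21 * z[:, :, 0] + l22 * z[:, :, 1])
    e_a = mu_a + sd * (l31 * z[:, :, 0] + l32 * z[:, :, 1] + l33 * z[:, :, 2])

    out = np.empty((n, 3 * m))
    out[:, 0::3] = e_p
    out[:, 1::3] = e_c
    out[:, 2::3] = e_a
    return out
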