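"""Multinomial processing tree (MPT) model of Tower of London planning performance.

The planning task uses a 2x2 within-subject design crossing *Goal Ambiguity*
(GA: low/high) and *Search Depth* (SD: low/high).  Each subject attempts ``T``
problems per cell (the study used T=2) and the dependent variable is the number
of problems solved in the minimum number of moves.

The MPT model has three probability parameters per latent class:

``b``
    baseline probability of solving a problem with low demands on both factors;
``g``
    multiplicative demand factor applied when Goal Ambiguity is high (the
    planning literature sometimes labels this parameter *f*);
``s``
    multiplicative demand factor applied when Search Depth is high.

The success probability in a cell is ``b * g**[GA high] * s**[SD high]``,
so the four processing trees share parameters across cells.  Within a class
the four cell counts are independent Binomial(T, p_cell) draws; population
heterogeneity is captured by a finite mixture of K such parameter triples.

Canonical cell order, used for every 4-vector and matrix in this package, is

    ``(LL, GA, SD, HH)`` = (low/low, GA-high only, SD-high only, high/high).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "CELL_NAMES",
    "CELLS",
    "CellDemand",
    "MPTParams",
    "ClassMixture",
    "SubjectCounts",
    "Dataset",
    "cell_success_probability",
    "subject_log_likelihood",
    "mixture_log_likelihood",
    "expected_cell_means",
    "model_covariance",
    "enumerate_support",
]

#: Canonical cell order of the 2x2 design.
CELL_NAMES: tuple[str, ...] = ("LL", "GA", "SD", "HH")

# Indicator vectors for the canonical cell order.
GA_HIGH = np.array([0.0, 1.0, 0.0, 1.0])
SD_HIGH = np.array([0.0, 0.0, 1.0, 1.0])

#: Guard for exact enumeration of the outcome support.
MAX_SUPPORT = 1_000_000


@dataclass(frozen=True)
class CellDemand:
    """One cell of the 2x2 demand design."""

    ga_high: bool
    sd_high: bool


#: The four design cells in canonical order (LL, GA, SD, HH).
CELLS: tuple[CellDemand, ...] = (
    CellDemand(False, False),
    CellDemand(True, False),
    CellDemand(False, True),
    CellDemand(True, True),
)


def _check_prob(name: str, value: float) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0) or not np.isfinite(value):
        raise ValueError(f"parameter {name} must lie in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class MPTParams:
    """Parameter triple (b, g, s) of one latent class.

    ``g = s = 1`` reduces every cell's success probability to the baseline ``b``.
    """

    b: float
    g: float
    s: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "b", _check_prob("b", self.b))
        object.__setattr__(self, "g", _check_prob("g", self.g))
        object.__setattr__(self, "s", _check_prob("s", self.s))

    def cell_probabilities(self) -> np.ndarray:
        """Success probability per cell, canonical order (LL, GA, SD, HH)."""
        return self.b * self.g ** GA_HIGH * self.s ** SD_HIGH

    def as_array(self) -> np.ndarray:
        return np.array([self.b, self.g, self.s])


@dataclass(frozen=True)
class ClassMixture:
    """A K-class finite mixture of MPT parameter triples.

    Free-parameter count is ``3K + (K - 1)``: three probabilities per class
    plus K-1 mixing weights.
    """

    weights: tuple[float, ...]
    params: tuple[MPTParams, ...]
    T: int = 2

    def __post_init__(self) -> None:
        weights = tuple(float(w) for w in self.weights)
        params = tuple(self.params)
        if len(weights) != len(params) or len(weights) < 1:
            raise ValueError("weights and params must have equal, positive length")
        if any(w < 0 for w in weights):
            raise ValueError("mixing weights must be nonnegative")
        total = sum(weights)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixing weights must sum to 1, got {total!r}")
        # renormalise away rounding noise so downstream sums are exact
        weights = tuple(w / total for w in weights)
        if not (isinstance(self.T, (int, np.integer)) and self.T >= 1):
            raise ValueError("T (trials per cell) must be a positive integer")
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "params", params)
        object.__setattr__(self, "T", int(self.T))

    @property
    def K(self) -> int:
        return len(self.weights)

    @property
    def n_free_params(self) -> int:
        return 3 * self.K + (self.K - 1)

    def weight_array(self) -> np.ndarray:
        return np.asarray(self.weights)

    def probability_matrix(self) -> np.ndarray:
        """(K, 4) matrix of cell success probabilities, canonical cell order."""
        return np.vstack([p.cell_probabilities() for p in self.params])


@dataclass(frozen=True)
class SubjectCounts:
    """Correct-solution counts of a single subject, canonical cell order."""

    x: tuple[int, ...]
    T: int = 2

    def __post_init__(self) -> None:
        x = tuple(int(v) for v in self.x)
        if len(x) != 4:
            raise ValueError("exactly four cell counts are required")
        if any(v < 0 or v > self.T for v in x):
            raise ValueError(f"counts must lie in 0..T={self.T}, got {x}")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "T", int(self.T))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.x, dtype=np.int64)


@dataclass
class Dataset:
    """A cohort of subjects sharing the same design.

    Attributes
    ----------
    counts : (N, 4) integer array, canonical cell order.
    T : trials per cell, shared by all subjects.
    group : optional length-N array of manifest labels (e.g. "PD"/"control").
    covariates : optional mapping of name -> length-N numeric array.
    subject_ids : optional length-N identifiers.
    """

    counts: np.ndarray
    T: int = 2
    group: np.ndarray | None = None
    covariates: dict[str, np.ndarray] = field(default_factory=dict)
    subject_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[1] != 4 or counts.shape[0] < 1:
            raise ValueError("counts must be an (N, 4) array with N >= 1")
        if counts.min() < 0 or counts.max() > self.T:
            raise ValueError(f"counts must lie in 0..T={self.T}")
        self.counts = counts
        self.T = int(self.T)
        if self.group is not None:
            self.group = np.asarray(self.group)
            if len(self.group) != len(counts):
                raise ValueError("group labels must match the number of subjects")
        for name, values in self.covariates.items():
            values = np.asarray(values, dtype=float)
            if len(values) != len(counts):
                raise ValueError(f"covariate {name!r} must match the number of subjects")
            self.covariates[name] = values
        if self.subject_ids is not None:
            self.subject_ids = np.asarray(self.subject_ids)
            if len(self.subject_ids) != len(counts):
                raise ValueError("subject_ids must match the number of subjects")

    @property
    def N(self) -> int:
        return self.counts.shape[0]

    @classmethod
    def from_subjects(
        cls,
        subjects: list[SubjectCounts],
        group=None,
        covariates=None,
        subject_ids=None,
    ) -> "Dataset":
        if not subjects:
            raise ValueError("at least one subject is required")
        T = subjects[0].T
        if any(s.T != T for s in subjects):
            raise ValueError("all subjects must share the same T")
        counts = np.vstack([s.as_array() for s in subjects])
        return cls(counts, T=T, group=group, covariates=covariates or {}, subject_ids=subject_ids)


def cell_success_probability(params: MPTParams, cell: CellDemand) -> float:
    """Probability of solving a problem in ``cell`` under ``params``.

    Equals ``b`` in the baseline cell; each high demand multiplies in the
    corresponding factor (``g`` for goal ambiguity, ``s`` for search depth).
    """
    return float(
        params.b * params.g ** (1 if cell.ga_high else 0) * params.s ** (1 if cell.sd_high else 0)
    )


def _binom_logpmf(x: np.ndarray, T: int, p: np.ndarray) -> np.ndarray:
    """Elementwise log Binomial(x; T, p) with exact handling of p in {0, 1}.

    Impossible observations (p = 0 with x > 0, or p = 1 with x < T) map to
    -inf rather than raising, so mixture likelihoods stay computable when a
    single class is degenerate.
    """
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    x, p = np.broadcast_arrays(x, p)
    out = np.full(x.shape, -np.inf)
    logc = gammaln(T + 1) - gammaln(x + 1) - gammaln(T - x + 1)
    interior = (p > 0.0) & (p < 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out[interior] = (
            logc[interior]
            + x[interior] * np.log(p[interior])
            + (T - x[interior]) * np.log1p(-p[interior])
        )
    out[(p == 0.0) & (x == 0)] = 0.0
    out[(p == 1.0) & (x == T)] = 0.0
    return out


def subject_log_likelihood(counts: SubjectCounts | np.ndarray, params: MPTParams, T: int | None = None) -> float:
    """Log-likelihood of one subject's count 4-vector under a single class.

    The four cells are independent binomials, so the value is the sum of the
    four binomial log-pmfs.  Returns ``-inf`` when any count is impossible
    under a degenerate cell probability.
    """
    if isinstance(counts, SubjectCounts):
        x, T = counts.as_array(), counts.T
    else:
        x = np.asarray(counts)
        if T is None:
            raise ValueError("T must be given when counts is a bare array")
        if x.shape != (4,):
            raise ValueError("counts must be a 4-vector")
        if x.min() < 0 or x.max() > T:
            raise ValueError(f"counts must lie in 0..T={T}")
    return float(_binom_logpmf(x, T, params.cell_probabilities()).sum())


def log_likelihood_matrix(counts: np.ndarray, model: ClassMixture) -> np.ndarray:
    """(N, K) matrix of per-subject, per-class log-likelihoods."""
    counts = np.asarray(counts, dtype=np.int64)
    P = model.probability_matrix()  # (K, 4)
    N, K = counts.shape[0], model.K
    out = np.empty((N, K))
    for k in range(K):
        out[:, k] = _binom_logpmf(counts, model.T, P[k][None, :]).sum(axis=1)
    return out


def mixture_log_likelihood(data: Dataset, model: ClassMixture) -> float:
    """Observed-data log-likelihood of the K-class mixture, stable in log space."""
    if data.N < 1:
        raise ValueError("dataset is empty")
    if data.T != model.T:
        raise ValueError(f"dataset T={data.T} does not match model T={model.T}")
    ll = log_likelihood_matrix(data.counts, model)
    with np.errstate(divide="ignore"):
        logw = np.log(model.weight_array())
    return float(logsumexp(ll + logw[None, :], axis=1).sum())


def expected_cell_means(model: ClassMixture) -> np.ndarray:
    """Model-implied expected correct count per cell: mu_c = T * sum_k w_k p_kc."""
    return model.T * model.weight_array() @ model.probability_matrix()


def model_covariance(model: ClassMixture) -> np.ndarray:
    """Model-implied 4x4 covariance of a subject's count vector.

    Within a class the cells are independent binomials, so the within-class
    covariance is diagonal; mixing adds the between-class spread of the cell
    means.  For K = 1 the matrix is therefore diagonal.
    """
    w = model.weight_array()
    P = model.probability_matrix()
    T = model.T
    mu = expected_cell_means(model)
    # E[X Xᵀ] = sum_k w_k [diag(T p (1-p)) + T² p pᵀ]
    second = np.zeros((4, 4))
    for k in range(model.K):
        p = P[k]
        second += w[k] * (np.diag(T * p * (1.0 - p)) + T * T * np.outer(p, p))
    cov = second - np.outer(mu, mu)
    return (cov + cov.T) / 2.0


def enumerate_support(model: ClassMixture) -> tuple[np.ndarray, np.ndarray]:
    """Exact joint pmf of the count 4-vector over its full finite support.

    Returns ``(outcomes, pmf)`` where ``outcomes`` is an ((T+1)^4, 4) integer
    array (81 outcomes for T=2) and ``pmf`` sums to one.  This enumeration is
    the exact-moment oracle behind the covariance-structure fit statistic.
    """
    T = model.T
    n_outcomes = (T + 1) ** 4
    if n_outcomes > MAX_SUPPORT:
        raise ValueError(f"support of {n_outcomes} outcomes exceeds the enumeration guard")
    outcomes = np.array(list(itertools.product(range(T + 1), repeat=4)), dtype=np.int64)
    ll = log_likelihood_matrix(outcomes, model)
    with np.errstate(divide="ignore"):
        logw = np.log(model.weight_array())
    pmf = np.exp(logsumexp(ll + logw[None, :], axis=1))
    return outcomes, pmf
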