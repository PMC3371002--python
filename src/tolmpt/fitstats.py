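"""Moment-based goodness-of-fit statistics and chi-square power analysis.

Two asymptotically chi-square statistics check a fitted latent-class MPT
mixture against the data's first and second moments:

* the mean-structure statistic ``M3`` — a Pearson chi-square comparing the
  pooled correct/incorrect counts per design cell with their model-implied
  expectations (df = 4 - P, where P is the number of free parameters);
* the covariance-structure statistic ``S1`` — a residual-based quadratic
  form on the difference between the sample covariance matrix of the
  per-subject count 4-vectors and the model-implied covariance.  The weight
  matrix is the pseudo-inverse of the asymptotic covariance of the sample
  (co)variances — computed exactly from the fitted model's fourth moments
  over the finite outcome support — projected onto the orthocomplement of
  the model's tangent space, so that the statistic is asymptotically
  chi-square with df = 10 - P for any root-N-consistent parameter estimate
  (10 being the distinct entries of a symmetric 4x4 matrix; df is further
  reduced by any rank deficiency of the weight matrix).

A one-class fit of the 2x2 design (P = 3) thus leaves df = 1 for the mean
structure and df = 7 for the covariance structure; a two-class fit (P = 7)
exhausts the mean structure and leaves df = 3 for the covariance structure.

The module also provides central chi-square critical values and the
alpha = beta power computation: the noncentrality lambda at which a
noncentral chi-square test first attains power 1 - beta, converted to
Cohen's effect size w = sqrt(lambda / n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .model import ClassMixture, Dataset, enumerate_support, expected_cell_means, model_covariance

__all__ = [
    "FitStatistic",
    "PowerSpec",
    "m3_statistic",
    "s1_statistic",
    "chi2_critical",
    "detectable_effect",
]

#: Relative singular-value cutoff for the pseudo-inverse of the weight matrix.
_PINV_RTOL = 1e-10

#: Cohen's conventional anchors for the chi-square effect size w.
COHEN_ANCHORS = {"small": 0.1, "medium": 0.3, "large": 0.5}

# vech index pairs (i >= j) of a 4x4 symmetric matrix, row-major lower triangle
_VECH_ROWS, _VECH_COLS = np.tril_indices(4)


@dataclass
class FitStatistic:
    """One goodness-of-fit statistic with its degrees of freedom and p-value.

    ``df`` and ``p_value`` are ``None`` when the fitted model leaves no
    testable degrees of freedom.
    """

    name: str
    value: float
    df: int | None
    p_value: float | None
    warnings: list[str] = field(default_factory=list)


@dataclass
class PowerSpec:
    """Specification and result of an alpha/beta chi-square power analysis."""

    alpha: float
    beta: float
    df: int
    n_observations: int
    noncentrality: float | None = None
    w: float | None = None
    classification: str | None = None


def _resolve(fit) -> tuple[ClassMixture, int]:
    """Accept a FitResult or a bare ClassMixture; return (model, free params)."""
    if isinstance(fit, ClassMixture):
        return fit, fit.n_free_params
    return fit.model, fit.n_free_params


def m3_statistic(data: Dataset, fit) -> FitStatistic:
    """Mean-structure Pearson chi-square on pooled per-cell counts.

    For each design cell the observed pooled correct count O_c (out of N*T
    trials) is compared with its expectation E_c under the fitted mixture:

        M3 = sum_c [(O_c - E_c)^2 / E_c + (O'_c - E'_c)^2 / E'_c]

    with O'_c = NT - O_c the incorrect counts.  A cell whose expectation sits
    at 0 or NT while the observation disagrees yields an infinite statistic.
    """
    model, P = _resolve(fit)
    if data.T != model.T:
        raise ValueError("data and fitted model must share T")
    N, T = data.N, data.T
    observed = data.counts.sum(axis=0).astype(float)
    expected = N * expected_cell_means(model)
    total = float(N * T)
    warnings: list[str] = []

    value = 0.0
    for O, E in zip(observed, expected):
        for o, e in ((O, E), (total - O, total - E)):
            if e <= 0.0:
                if o > 0.0:
                    value = np.inf
                continue
            value += (o - e) ** 2 / e
    df = 4 - P
    if df <= 0:
        return FitStatistic("M3", float(value), None, None, warnings)
    p = float(stats.chi2.sf(value, df)) if np.isfinite(value) else 0.0
    return FitStatistic("M3", float(value), df, p, warnings)


def vech(matrix: np.ndarray) -> np.ndarray:
    """Half-vectorisation: the 10 distinct entries of a symmetric 4x4 matrix."""
    return np.asarray(matrix)[_VECH_ROWS, _VECH_COLS]


def _vech_asymptotic_cov(model: ClassMixture, N: int) -> np.ndarray:
    """Asymptotic covariance of vech(S) under the model, S = divisor-N sample cov.

    Entry ((c,d),(e,f)) is (mu_cdef - sigma_cd sigma_ef) / N, where mu_cdef is
    the central fourth moment E[(X_c-mu_c)(X_d-mu_d)(X_e-mu_e)(X_f-mu_f)],
    computed exactly by enumerating the outcome support.
    """
    outcomes, pmf = enumerate_support(model)
    mu = expected_cell_means(model)
    dev = outcomes - mu[None, :]
    mu4 = np.einsum("m,mc,md,me,mf->cdef", pmf, dev, dev, dev, dev)
    sigma = model_covariance(model)
    omega = (
        mu4[_VECH_ROWS[:, None], _VECH_COLS[:, None], _VECH_ROWS[None, :], _VECH_COLS[None, :]]
        - np.outer(vech(sigma), vech(sigma))
    ) / N
    return (omega + omega.T) / 2.0


def _free_param_vector(model: ClassMixture) -> np.ndarray:
    """(b_k, g_k, s_k) for every class followed by the first K-1 weights."""
    parts = [p.as_array() for p in model.params]
    if model.K > 1:
        parts.append(np.asarray(model.weights[:-1]))
    return np.concatenate(parts)


def _mixture_from_vector(theta: np.ndarray, K: int, T: int) -> ClassMixture:
    from .model import MPTParams

    params = tuple(MPTParams(*theta[3 * k : 3 * k + 3]) for k in range(K))
    if K == 1:
        weights: tuple[float, ...] = (1.0,)
    else:
        wfree = theta[3 * K :]
        weights = tuple(wfree) + (1.0 - float(wfree.sum()),)
    return ClassMixture(weights, params, T)


def _cov_structure_jacobian(model: ClassMixture, h: float = 1e-6) -> np.ndarray:
    """d vech(Sigma) / d theta by central differences, one-sided at the box edge."""
    theta = _free_param_vector(model)
    K, T = model.K, model.T

    def f(vec: np.ndarray) -> np.ndarray:
        return vech(model_covariance(_mixture_from_vector(vec, K, T)))

    D = np.empty((10, len(theta)))
    for j, tj in enumerate(theta):
        lo, hi = tj - h, tj + h
        if lo < 0.0:
            lo = tj
        if hi > 1.0:
            hi = tj
        for side in ("hi", "lo"):
            try:
                vec_hi = theta.copy(); vec_hi[j] = hi
                vec_lo = theta.copy(); vec_lo[j] = lo
                D[:, j] = (f(vec_hi) - f(vec_lo)) / (hi - lo)
                break
            except ValueError:
                # perturbed weight vector left the simplex; shrink to one side
                if side == "hi":
                    hi = tj
                    lo = tj - h
    return D


def s1_statistic(data: Dataset, fit) -> FitStatistic:
    """Covariance-structure statistic: residual quadratic form on vech(S - Sigma_hat).

    S is the sample covariance of the per-subject count 4-vectors (divisor N,
    matching the asymptotic scaling), Sigma_hat the model-implied covariance
    of the fitted mixture.  The residual d = vech(S - Sigma_hat) is weighted
    by ``W - W D (D' W D)^+ D' W`` where W is the pseudo-inverse of the exact
    asymptotic covariance of vech(S) under the fitted model and D the
    Jacobian of vech(Sigma) in the free parameters; projecting out the model
    tangent space makes the statistic insensitive to how the parameters were
    estimated.  df = 10 - P, reduced further if the weight matrix is rank
    deficient.
    """
    model, P = _resolve(fit)
    if data.T != model.T:
        raise ValueError("data and fitted model must share T")
    if data.N < 10:
        raise ValueError("the covariance-structure statistic needs N >= 10 (asymptotic)")
    S = np.cov(data.counts.T.astype(float), bias=True)
    d = vech(S - model_covariance(model))
    omega = _vech_asymptotic_cov(model, data.N)

    U, sv, Vt = np.linalg.svd(omega, hermitian=True)
    keep = sv > _PINV_RTOL * sv.max() if sv.max() > 0 else np.zeros_like(sv, dtype=bool)
    rank = int(keep.sum())
    W = (Vt[keep].T / sv[keep]) @ U[:, keep].T if rank else np.zeros_like(omega)
    D = _cov_structure_jacobian(model)
    WD = W @ D
    middle = np.linalg.pinv(D.T @ WD, rcond=1e-12, hermitian=True)
    weight = W - WD @ middle @ WD.T
    value = float(d @ weight @ d)
    value = max(value, 0.0)

    warnings: list[str] = []
    deficiency = 10 - rank
    if deficiency > 0:
        warnings.append(f"weight matrix rank deficient by {deficiency}; df reduced accordingly")
    df = 10 - P - deficiency
    if df <= 0:
        return FitStatistic("S1", value, None, None, warnings)
    p = float(stats.chi2.sf(value, df)) if np.isfinite(value) else 0.0
    return FitStatistic("S1", value, df, p, warnings)


def chi2_critical(df: int, alpha: float) -> float:
    """Upper-alpha critical value of the central chi-square with ``df`` degrees.

    Full precision is returned; reports conventionally display two decimals
    (e.g. 6.63 for df = 1 at alpha = .01).
    """
    if not (isinstance(df, (int, np.integer)) and df >= 1):
        raise ValueError("df must be a positive integer")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie strictly between 0 and 1")
    return float(stats.chi2.isf(alpha, df))


def _classify_w(w: float) -> str:
    if w < COHEN_ANCHORS["small"]:
        return "below small"
    if w < COHEN_ANCHORS["medium"]:
        return "small-to-medium"
    if w < COHEN_ANCHORS["large"]:
        return "medium-to-large"
    return "large or larger"


def detectable_effect(spec: PowerSpec) -> PowerSpec:
    """Smallest effect a chi-square test detects at the given alpha and beta.

    Solves for the noncentrality lambda at which the noncentral chi-square
    with ``spec.df`` degrees of freedom exceeds the central critical value
    with probability 1 - beta, then converts to Cohen's w = sqrt(lambda / n)
    and classifies it against the conventional anchors
    (small .1, medium .3, large .5).
    """
    if not (0.0 < spec.alpha < 1.0 and 0.0 < spec.beta < 1.0):
        raise ValueError("alpha and beta must lie strictly between 0 and 1")
    if spec.n_observations < 1:
        raise ValueError("n_observations must be >= 1")
    crit = chi2_critical(spec.df, spec.alpha)
    target = 1.0 - spec.beta

    def gap(lam: float) -> float:
        return float(stats.ncx2.sf(crit, spec.df, lam)) - target

    lo, hi = 1e-12, 1.0
    while gap(hi) < 0.0:
        hi *= 2.0
        if hi > 1e8:
            raise ValueError("no noncentrality solves the power equation in bracket")
    lam = float(optimize.brentq(gap, lo, hi, xtol=1e-8))
    w = float(np.sqrt(lam / spec.n_observations))
    return PowerSpec(
        alpha=spec.alpha,
        beta=spec.beta,
        df=spec.df,
        n_observations=spec.n_observations,
        noncentrality=lam,
        w=w,
        classification=_classify_w(w),
    )
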