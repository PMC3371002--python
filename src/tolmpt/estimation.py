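"""Maximum-likelihood estimation of latent-class MPT mixtures by EM.

The E-step computes posterior class-membership probabilities by Bayes' rule;
the M-step maximises the posterior-weighted binomial log-likelihood of each
class over the box [eps, 1-eps]^3 (jointly across classes when a parameter is
restricted to be equal), and mixing weights update to the posterior column
means.  Identical count 4-vectors are aggregated into unique response
patterns first — an exact reformulation that makes large-N fits cheap, since
at most (T+1)^4 patterns exist.

Label switching is resolved by a canonical class order: descending search-depth
parameter ``s``, ties broken by descending mixing weight.  Class 0 is thus the
class that copes best with high search depth (the "SD+" class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp

from .model import GA_HIGH, SD_HIGH, ClassMixture, Dataset, MPTParams, SubjectCounts

__all__ = [
    "Restriction",
    "FitResult",
    "LRTestResult",
    "em_fit",
    "lr_test",
    "posterior_class_probabilities",
    "assign_classes",
]

_EPS = 1e-8
#: Estimates closer than this to 0 or 1 are reported as exactly 0 or 1.
_BOUNDARY_SNAP = 1e-3

_PARAM_INDEX = {"b": 0, "g": 1, "s": 2}


@dataclass(frozen=True)
class Restriction:
    """Equality restriction of one parameter across all latent classes."""

    parameter: str

    def __post_init__(self) -> None:
        if self.parameter not in _PARAM_INDEX:
            raise ValueError("restriction parameter must be one of 'b', 'g', 's'")


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood mixture fit."""

    model: ClassMixture
    loglik: float
    posteriors: np.ndarray
    n_free_params: int
    converged: bool
    n_iterations: int
    n_starts_used: int
    seed: int
    restriction: Restriction | None = None
    loglik_trace: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.model.K


@dataclass(frozen=True)
class LRTestResult:
    """Likelihood-ratio test of a nested (restricted) model against the full one."""

    delta_l: float
    df: int
    p_value: float


def _aggregate_patterns(counts: np.ndarray):
    patterns, inverse, npat = np.unique(counts, axis=0, return_inverse=True, return_counts=True)
    return patterns, inverse, npat.astype(float)


def _pattern_loglik(patterns: np.ndarray, logc: np.ndarray, P: np.ndarray, T: int) -> np.ndarray:
    """(n_patterns, K) log binomial likelihood; P interior in (0, 1)."""
    logp = np.log(P)        # (K, 4)
    log1mp = np.log1p(-P)
    X = patterns.astype(float)
    return logc[:, None] + X @ logp.T + (T - X) @ log1mp.T


def _theta_index(K: int, restriction: Restriction | None) -> tuple[np.ndarray, int]:
    """Map from a free-parameter vector theta to the full (K, 3) parameter grid."""
    idx = np.arange(3 * K).reshape(K, 3)
    if restriction is not None:
        j = _PARAM_INDEX[restriction.parameter]
        idx[:, j] = idx[0, j]
        # compact the index set
        _, idx = np.unique(idx, return_inverse=True)
        idx = idx.reshape(K, 3)
    n_theta = int(idx.max()) + 1
    return idx, n_theta


def _mstep(theta0, idx, A, B):
    """Maximise sum_kc A_kc log p_kc + B_kc log(1 - p_kc) over the box.

    A (B) are posterior-weighted counts of correct (incorrect) solutions per
    class and cell.  Returns (theta, objective); never worse than theta0.
    """

    def negloglik_and_grad(theta):
        full = theta[idx]  # (K, 3)
        b, g, s = full[:, 0], full[:, 1], full[:, 2]
        p = b[:, None] * g[:, None] ** GA_HIGH[None, :] * s[:, None] ** SD_HIGH[None, :]
        f = float(np.sum(A * np.log(p) + B * np.log1p(-p)))
        common = A - B * p / (1.0 - p)  # (K, 4)
        gfull = np.empty_like(full)
        gfull[:, 0] = common.sum(axis=1) / b
        gfull[:, 1] = (common * GA_HIGH[None, :]).sum(axis=1) / g
        gfull[:, 2] = (common * SD_HIGH[None, :]).sum(axis=1) / s
        gtheta = np.zeros(theta.shape)
        np.add.at(gtheta, idx.ravel(), gfull.ravel())
        return -f, -gtheta

    res = optimize.minimize(
        negloglik_and_grad,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(_EPS, 1.0 - _EPS)] * len(theta0),
        options={"maxiter": 25},
    )
    f0 = negloglik_and_grad(theta0)[0]
    if res.fun <= f0:
        return res.x, -res.fun
    return theta0, -f0  # optimizer failed to improve; keep warm start


#: Burn-in iterations each random start receives before only the best
#: continues to full convergence (short-run multi-start).
_SHORT_RUN_ITER = 40


def _run_em(patterns, npat, logc, T, K, theta0, w0, idx, tol, max_iter):
    """One EM run from a given initialisation; returns (ll, theta, w, trace, converged, iters)."""
    theta = np.asarray(theta0, dtype=float)
    w = np.asarray(w0, dtype=float)
    trace = []
    ll_prev = -np.inf
    converged = False
    n_total = npat.sum()
    it = 0
    for it in range(1, max_iter + 1):
        full = theta[idx]
        P = full[:, 0][:, None] * full[:, 1][:, None] ** GA_HIGH[None, :] * full[:, 2][:, None] ** SD_HIGH[None, :]
        L = _pattern_loglik(patterns, logc, P, T)
        with np.errstate(divide="ignore"):
            logw = np.log(np.maximum(w, 1e-300))
        joint = L + logw[None, :]
        lse = logsumexp(joint, axis=1)
        ll = float(npat @ lse)
        trace.append(ll)
        if ll - ll_prev < tol and it > 1:
            converged = True
            break
        ll_prev = ll
        post = np.exp(joint - lse[:, None])  # (n_patterns, K)
        wn = npat[:, None] * post
        w = wn.sum(axis=0) / n_total
        A = wn.T @ patterns.astype(float)          # (K, 4) weighted correct
        B = wn.T @ (T - patterns.astype(float))    # (K, 4) weighted incorrect
        theta, _ = _mstep(theta, idx, A, B)
    return ll, theta, w, np.asarray(trace), converged, it


def _snap_boundary(value: float) -> float:
    if value <= _BOUNDARY_SNAP:
        return 0.0
    if value >= 1.0 - _BOUNDARY_SNAP:
        return 1.0
    return float(value)


def em_fit(
    data: Dataset,
    K: int,
    n_starts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 2000,
    seed: int = 0,
    restriction: Restriction | None = None,
) -> FitResult:
    """Fit a K-class MPT mixture by maximum likelihood (EM, multi-start).

    Parameters
    ----------
    data
        The cohort to fit; all subjects share ``T`` trials per cell.
    K
        Number of latent classes (1 <= K <= N).
    n_starts
        Random initialisations; parameters ~ Uniform(.1, .9), weights ~
        symmetric Dirichlet(1).  The best final log-likelihood wins.
    tol, max_iter
        EM stops when the log-likelihood gain drops below ``tol`` or after
        ``max_iter`` iterations.
    seed
        Drives all starts through a spawned seed sequence; identical seeds
        give bit-identical results.
    restriction
        Optional equality restriction of one parameter across classes.

    Notes
    -----
    Estimates within 1e-3 of the box boundary are reported as exactly 0 or 1
    (matching how floor-level search-depth performance is conventionally
    printed); the log-likelihood refers to the unsnapped maximiser.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > data.N:
        raise ValueError(f"cannot fit K={K} classes to N={data.N} subjects")
    patterns, inverse, npat = _aggregate_patterns(data.counts)
    T = data.T
    X = patterns.astype(float)
    logc = (gammaln(T + 1) - gammaln(X + 1) - gammaln(T - X + 1)).sum(axis=1)
    idx, n_theta = _theta_index(K, restriction)

    n_starts = max(1, n_starts)
    children = np.random.SeedSequence(seed).spawn(n_starts)
    short = min(_SHORT_RUN_ITER, max_iter) if n_starts > 1 else max_iter
    best = None
    for child in children:
        rng = np.random.default_rng(child)
        full0 = rng.uniform(0.1, 0.9, size=(K, 3))
        if restriction is not None:
            j = _PARAM_INDEX[restriction.parameter]
            full0[:, j] = full0[0, j]
        theta0 = np.zeros(n_theta)
        theta0[idx.ravel()] = full0.ravel()
        w0 = rng.dirichlet(np.ones(K))
        result = _run_em(patterns, npat, logc, T, K, theta0, w0, idx, tol, short)
        if best is None or result[0] > best[0]:
            best = result

    ll, theta, w, trace, converged, iters = best
    if not converged and iters < max_iter:
        # continue only the best short run to full convergence
        ll, theta, w, trace2, converged, iters2 = _run_em(
            patterns, npat, logc, T, K, theta, w, idx, tol, max_iter - iters
        )
        trace = np.concatenate([trace, trace2])
        iters += iters2
    full = theta[idx]

    # canonical order: descending s, then descending weight
    order = np.lexsort((-w, -full[:, 2]))
    full = full[order]
    w = w[order]

    params = tuple(
        MPTParams(_snap_boundary(full[k, 0]), _snap_boundary(full[k, 1]), _snap_boundary(full[k, 2]))
        for k in range(K)
    )
    model = ClassMixture(weights=tuple(w / w.sum()), params=params, T=T)

    # final posteriors from the unsnapped maximiser (the actual MLE)
    P = full[:, 0][:, None] * full[:, 1][:, None] ** GA_HIGH[None, :] * full[:, 2][:, None] ** SD_HIGH[None, :]
    L = _pattern_loglik(patterns, logc, P, T)
    with np.errstate(divide="ignore"):
        logw = np.log(np.maximum(w, 1e-300))
    joint = L + logw[None, :]
    post_patterns = np.exp(joint - logsumexp(joint, axis=1)[:, None])
    posteriors = post_patterns[inverse]

    n_restricted = (K - 1) if restriction is not None else 0
    warnings = [] if converged else ["EM did not converge within max_iter in the best start"]
    return FitResult(
        model=model,
        loglik=ll,
        posteriors=posteriors,
        n_free_params=3 * K + (K - 1) - n_restricted,
        converged=converged,
        n_iterations=iters,
        n_starts_used=max(1, n_starts),
        seed=seed,
        restriction=restriction,
        loglik_trace=trace,
        warnings=warnings,
    )


def lr_test(full: FitResult, restricted: FitResult) -> LRTestResult:
    """Likelihood-ratio test Delta-l = 2 (l_full - l_restricted) against chi-square.

    The restricted model must be nested in the full one (same data, same K,
    fewer free parameters); df is the number of active restrictions.
    """
    if restricted.K != full.K:
        raise ValueError("full and restricted fits must have the same number of classes")
    if restricted.posteriors.shape[0] != full.posteriors.shape[0]:
        raise ValueError("full and restricted fits must be computed on the same data")
    df = full.n_free_params - restricted.n_free_params
    if df < 1:
        raise ValueError("restricted model has no fewer free parameters than the full model")
    delta = 2.0 * (full.loglik - restricted.loglik)
    if delta < -0.1:
        # far beyond optimizer noise: the "full" fit cannot be the maximum
        raise ValueError(
            f"restricted log-likelihood exceeds the full one by {-delta / 2:.3g}; "
            "the full fit is not at its maximum"
        )
    delta = max(delta, 0.0)  # numerical floor: nesting guarantees delta >= 0
    return LRTestResult(delta_l=delta, df=df, p_value=float(stats.chi2.sf(delta, df)))


def posterior_class_probabilities(model: ClassMixture, counts: SubjectCounts | np.ndarray) -> np.ndarray:
    """Bayes-rule posterior membership probabilities of one subject.

    Entry k is proportional to ``w_k * L(x | params_k)``, computed in log
    space.  Raises if the observation is impossible under every class.
    """
    from .model import subject_log_likelihood

    if isinstance(counts, SubjectCounts):
        sc = counts
    else:
        sc = SubjectCounts(tuple(np.asarray(counts).tolist()), T=model.T)
    if sc.T != model.T:
        raise ValueError("subject T does not match model T")
    ll = np.array([subject_log_likelihood(sc, p) for p in model.params])
    with np.errstate(divide="ignore"):
        logw = np.log(np.maximum(model.weight_array(), 1e-300))
    joint = ll + logw
    if np.all(np.isinf(joint)):
        raise ValueError("observation has zero likelihood under every latent class")
    return np.exp(joint - logsumexp(joint))


def assign_classes(fit: FitResult) -> np.ndarray:
    """Hard class labels: argmax of each posterior row.

    Ties break to the lower class index, i.e. the class with the higher
    search-depth parameter under the canonical order.
    """
    return np.argmax(fit.posteriors, axis=1)
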