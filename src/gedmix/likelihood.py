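"""Right-censored mixture likelihood, score equations and ML fitting.

The labelled likelihood assumes component membership is known for the
observed failures while the censored items are pooled: with ``r_j``
failures from component ``j`` and ``n - r`` censored items anchored at
``t``,

    L = pi1^r1 (1-pi1)^r2 * prod_j prod_i f_j(x_ji) * S(t)^(n-r),

where ``S(t) = 1 - pi1 F1(t) - (1-pi1) F2(t)`` is the mixture survival.
The unlabelled likelihood (used for real datasets, where membership is
latent) replaces the labelled product with the mixture density and uses
each record's own censoring time.

Parameter vectors are ordered ``(lambda1, lambda2, theta1, theta2, pi1)``
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .censoring import CensoredSample
from .distributions import GEDParams, MixtureParams, mixture_cdf, mixture_pdf

__all__ = [
    "MLEResult",
    "log_likelihood",
    "score",
    "fit_mle",
    "unlabeled_log_likelihood",
    "fit_mle_unlabeled",
    "hessian",
    "third_derivatives",
]

_EPS = np.finfo(float).eps


@dataclass
class MLEResult:
    """Outcome of likelihood maximisation.

    ``sigma`` is the inverse of the observed information (negative Hessian
    of the log-likelihood) at the optimum — the curvature matrix that
    drives Lindley's approximation.
    """

    params_hat: MixtureParams
    loglik: float
    score_norm: float
    sigma: np.ndarray
    converged: bool
    n_iter: int


def _split(sample: CensoredSample):
    if sample.labels is None:
        raise ValueError("labelled likelihood requires component labels")
    x1, x2 = sample.observed_by_component()
    n, r = sample.n, sample.r
    t = sample.t_anchor
    if n > r and t is None:
        raise ValueError("censored sample requires a t_anchor")
    return x1, x2, n, r, t


def _survival_factor(omega: MixtureParams, t: float) -> float:
    return 1.0 - mixture_cdf(t, omega)


def log_likelihood(sample: CensoredSample, omega: MixtureParams) -> float:
    """Labelled right-censored mixture log-likelihood.

    Returns ``-inf`` (rather than raising) when the survival factor at the
    anchor is numerically non-positive for the supplied parameters.
    """
    x1, x2, n, r, t = _split(sample)
    l1, l2 = omega.comp1.lambda_shape, omega.comp2.lambda_shape
    th1, th2 = omega.comp1.theta_rate, omega.comp2.theta_rate
    p1 = omega.pi1
    r1, r2 = len(x1), len(x2)

    def comp_term(x, lam, th):
        if len(x) == 0:
            return 0.0
        log1m = np.log(-np.expm1(-th * x))
        return (
            len(x) * (np.log(lam) + np.log(th))
            - th * x.sum()
            + (lam - 1.0) * log1m.sum()
        )

    ll = r1 * np.log(p1) + r2 * np.log1p(-p1)
    ll += comp_term(x1, l1, th1) + comp_term(x2, l2, th2)
    if n > r:
        s = _survival_factor(omega, t)
        if s <= 0.0:
            return -np.inf
        ll += (n - r) * np.log(s)
    return float(ll)


def score(sample: CensoredSample, omega: MixtureParams) -> np.ndarray:
    """Gradient of the labelled log-likelihood in the order
    (lambda1, lambda2, theta1, theta2, pi1)."""
    x1, x2, n, r, t = _split(sample)
    l1, l2 = omega.comp1.lambda_shape, omega.comp2.lambda_shape
    th1, th2 = omega.comp1.theta_rate, omega.comp2.theta_rate
    p1 = omega.pi1
    r1, r2 = len(x1), len(x2)
    m = n - r

    def comp_grads(x, lam, th):
        rj = len(x)
        if rj == 0:
            return 0.0, 0.0
        one_m = -np.expm1(-th * x)
        log1m = np.log(one_m)
        d_lam = rj / lam + log1m.sum()
        d_th = rj / th - x.sum() + (lam - 1.0) * (x * np.exp(-th * x) / one_m).sum()
        return d_lam, d_th

    dl1, dt1 = comp_grads(x1, l1, th1)
    dl2, dt2 = comp_grads(x2, l2, th2)
    dp = r1 / p1 - r2 / (1.0 - p1)

    if m > 0:
        c1, c2 = -np.expm1(-th1 * t), -np.expm1(-th2 * t)
        F1, F2 = c1**l1, c2**l2
        s = 1.0 - p1 * F1 - (1.0 - p1) * F2
        if s <= 0.0:
            return np.full(5, np.nan)
        dl1 -= m * p1 * F1 * np.log(c1) / s
        dl2 -= m * (1.0 - p1) * F2 * np.log(c2) / s
        dt1 -= m * p1 * l1 * t * np.exp(-th1 * t) * c1 ** (l1 - 1.0) / s
        dt2 -= m * (1.0 - p1) * l2 * t * np.exp(-th2 * t) * c2 ** (l2 - 1.0) / s
        dp += m * (F2 - F1) / s
    return np.array([dl1, dl2, dt1, dt2, dp])


# ---------------------------------------------------------------------------
# numerical derivatives of the log-likelihood (built on the analytic score)

def _fd_steps(omega_vec: np.ndarray, order: int) -> np.ndarray:
    # optimal step scaling for first (order=1) / second (order=2) central
    # differences of an analytically computed gradient
    base = _EPS ** (1.0 / 3.0) if order == 1 else _EPS**0.25
    scale = np.maximum(np.abs(omega_vec), 0.1)
    h = base * scale
    # keep pi1 +- 2h inside (0, 1)
    h[4] = min(h[4], 0.25 * omega_vec[4], 0.25 * (1.0 - omega_vec[4]))
    return h


def hessian(sample: CensoredSample, omega: MixtureParams) -> np.ndarray:
    """Second-derivative matrix L_ij by central differences of the score."""
    v = omega.to_vector()
    h = _fd_steps(v, order=1)
    H = np.zeros((5, 5))
    for i in range(5):
        vp, vm = v.copy(), v.copy()
        vp[i] += h[i]
        vm[i] -= h[i]
        sp = score(sample, MixtureParams.from_vector(vp))
        sm = score(sample, MixtureParams.from_vector(vm))
        H[i] = (sp - sm) / (2.0 * h[i])
    return 0.5 * (H + H.T)


def third_derivatives(sample: CensoredSample, omega: MixtureParams) -> np.ndarray:
    """Third-derivative tensor L_ijk by second central differences of the
    score: ``T[i, j, k] = d^2 s_k / dOmega_i dOmega_j``.

    Symmetric in (i, j) by construction; returned after symmetrising over
    all index permutations to suppress finite-difference asymmetry.
    """
    v = omega.to_vector()
    h = _fd_steps(v, order=2)
    s0 = score(sample, omega)
    T = np.zeros((5, 5, 5))

    def s_at(delta):
        return score(sample, MixtureParams.from_vector(v + delta))

    for i in range(5):
        ei = np.zeros(5)
        ei[i] = h[i]
        T[i, i] = (s_at(ei) - 2.0 * s0 + s_at(-ei)) / h[i] ** 2
        for j in range(i + 1, 5):
            ej = np.zeros(5)
            ej[j] = h[j]
            mixed = (
                s_at(ei + ej) - s_at(ei - ej) - s_at(-ei + ej) + s_at(-ei - ej)
            ) / (4.0 * h[i] * h[j])
            T[i, j] = mixed
            T[j, i] = mixed
    # average over the 3! orderings
    T = (
        T
        + T.transpose(0, 2, 1)
        + T.transpose(1, 0, 2)
        + T.transpose(1, 2, 0)
        + T.transpose(2, 0, 1)
        + T.transpose(2, 1, 0)
    ) / 6.0
    return T


# ---------------------------------------------------------------------------
# fitting

def _to_unconstrained(v: np.ndarray) -> np.ndarray:
    z = np.log(v.copy())
    z[4] = special.logit(v[4])
    return z


def _from_unconstrained(z: np.ndarray) -> np.ndarray:
    v = np.exp(z.copy())
    v[4] = special.expit(z[4])
    return v


def _mom_ged(x: np.ndarray) -> GEDParams:
    """Method-of-moments starting values for one GED component."""
    mean = x.mean()
    if len(x) < 2 or x.var(ddof=1) == 0.0:
        return GEDParams(1.0, 1.0 / mean)
    cv2 = x.var(ddof=1) / mean**2

    def gap(log_lam):
        lam = np.exp(log_lam)
        mu = special.digamma(lam + 1.0) - special.digamma(1.0)
        var = special.polygamma(1, 1.0) - special.polygamma(1, lam + 1.0)
        return var / mu**2 - cv2

    try:
        log_lam = optimize.brentq(gap, np.log(1e-3), np.log(1e3))
        lam = float(np.exp(log_lam))
    except ValueError:
        lam = 1.0
    theta = float((special.digamma(lam + 1.0) - special.digamma(1.0)) / mean)
    return GEDParams(lam, theta)


def fit_mle(
    sample: CensoredSample,
    init: MixtureParams | str = "auto",
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 5,
    seed: int = 0,
) -> MLEResult:
    """Maximise the labelled log-likelihood by quasi-Newton iteration on
    transformed coordinates (log for shapes and rates, logit for pi1).

    ``init="auto"`` seeds the shapes and rates by per-component method of
    moments on the labelled failures and ``pi1`` by ``r1 / r``.  On
    convergence failure up to ``n_restarts`` perturbed restarts are tried.
    """
    x1, x2, n, r, t = _split(sample)
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("need at least 2 observed failures per component")

    if init == "auto":
        p1_0 = len(x1) / r
        init = MixtureParams(_mom_ged(x1), _mom_ged(x2), min(max(p1_0, 0.02), 0.98))

    def negloglik_and_grad(z):
        v = _from_unconstrained(z)
        omega = MixtureParams.from_vector(v)
        ll = log_likelihood(sample, omega)
        if not np.isfinite(ll):
            return 1e12, np.zeros(5)
        g = score(sample, omega)
        jac = v.copy()
        jac[4] = v[4] * (1.0 - v[4])
        return -ll, -g * jac

    rng = np.random.default_rng(seed)
    z0 = _to_unconstrained(init.to_vector())
    best = None
    for attempt in range(n_restarts + 1):
        z_start = z0 if attempt == 0 else z0 + rng.normal(scale=0.5, size=5)
        res = optimize.minimize(
            negloglik_and_grad,
            z_start,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-14},
        )
        omega_hat = MixtureParams.from_vector(_from_unconstrained(res.x))
        sc = score(sample, omega_hat)
        score_norm = float(np.max(np.abs(sc))) if np.all(np.isfinite(sc)) else np.inf
        cand = (res.fun, omega_hat, score_norm, res.nit)
        if best is None or res.fun < best[0]:
            best = cand
        # accept when the untransformed score is small relative to curvature
        if score_norm < 1e-4 * max(1.0, abs(res.fun)):
            best = cand
            break

    fun, omega_hat, score_norm, nit = best
    H = hessian(sample, omega_hat)
    converged = score_norm < 1e-3 * max(1.0, abs(fun))
    try:
        sigma = np.linalg.inv(-H)
        if converged and np.any(np.diag(sigma) <= 0):
            converged = False
    except np.linalg.LinAlgError:
        sigma = np.full((5, 5), np.nan)
        converged = False
    return MLEResult(
        params_hat=omega_hat,
        loglik=float(-fun),
        score_norm=score_norm,
        sigma=sigma,
        converged=bool(converged),
        n_iter=int(nit),
    )


# ---------------------------------------------------------------------------
# unlabelled likelihood (real datasets)

def unlabeled_log_likelihood(sample: CensoredSample, omega: MixtureParams) -> float:
    """Standard right-censored mixture log-likelihood without labels:
    observed records contribute ``log f(x)``, censored records
    ``log S(x)`` at their own censoring times."""
    obs = sample.status == 1
    x_o, x_c = sample.times[obs], sample.times[~obs]
    with np.errstate(divide="ignore"):
        ll = np.sum(np.log(mixture_pdf(x_o, omega))) if len(x_o) else 0.0
        if len(x_c):
            surv = 1.0 - mixture_cdf(x_c, omega)
            if np.any(surv <= 0.0):
                return -np.inf
            ll += np.sum(np.log(surv))
    return float(ll)


def fit_mle_unlabeled(
    sample: CensoredSample,
    model: str = "2CMGED",
    n_starts: int = 20,
    seed: int = 0,
) -> MLEResult:
    """Fit the unlabelled censored mixture by multi-start quasi-Newton.

    ``model="2CMED"`` constrains both shape parameters to 1 (exponential
    mixture).  Components are reported with ``theta1 <= theta2`` to
    resolve label switching.
    """
    model = model.upper()
    if model not in ("2CMGED", "2CMED"):
        raise ValueError(f"unknown model {model!r}")
    free_shape = model == "2CMGED"
    x = sample.times
    scale = float(np.mean(x[sample.status == 1]))
    rng = np.random.default_rng(seed)

    def unpack(z):
        # shapes confined to [1e-3, 1e3]: the complete-data mixture
        # likelihood is unbounded along spike directions (lambda, theta ->
        # inf with vanishing weight), so the search region must exclude
        # degenerate point-mass components
        p1 = float(np.clip(special.expit(z[-1]), 1e-12, 1.0 - 1e-12))
        if free_shape:
            l1, l2 = np.exp(np.clip(z[:2], -7.0, 7.0))
            th1, th2 = np.exp(np.clip(z[2:4], -30.0, 30.0))
        else:
            l1 = l2 = 1.0
            th1, th2 = np.exp(np.clip(z[:2], -30.0, 30.0))
        return MixtureParams(GEDParams(l1, th1), GEDParams(l2, th2), p1)

    def neg(z):
        ll = unlabeled_log_likelihood(sample, unpack(z))
        return -ll if np.isfinite(ll) else 1e12

    best = None
    for s in range(n_starts):
        th0 = 1.0 / scale * np.exp(rng.normal(scale=1.0, size=2))
        p0 = rng.uniform(0.15, 0.85)
        if free_shape:
            lam0 = np.exp(rng.normal(scale=0.7, size=2))
            z0 = np.array([np.log(lam0[0]), np.log(lam0[1]), np.log(th0[0]), np.log(th0[1]), special.logit(p0)])
        else:
            z0 = np.array([np.log(th0[0]), np.log(th0[1]), special.logit(p0)])
        res = optimize.minimize(neg, z0, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-10})
        res2 = optimize.minimize(neg, res.x, method="Nelder-Mead",
                                 options={"maxiter": 4000, "xatol": 1e-12, "fatol": 1e-12})
        if best is None or res2.fun < best.fun:
            best = res2
    omega = unpack(best.x)
    # canonical component order theta1 <= theta2
    if omega.comp1.theta_rate > omega.comp2.theta_rate:
        omega = MixtureParams(omega.comp2, omega.comp1, 1.0 - omega.pi1)
    return MLEResult(
        params_hat=omega,
        loglik=float(-best.fun),
        score_norm=np.nan,
        sigma=np.full((5, 5), np.nan),
        converged=bool(best.success or best.fun < 1e11),
        n_iter=int(best.nit),
    )
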