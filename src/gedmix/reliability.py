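"""Reliability characteristics of the mixture: survival, hazard and
reversed hazard, with their Bayes estimation.

At a time ``t`` the three characteristics are

    R(t)   = 1 - F(t)         (survival)
    HR(t)  = f(t) / R(t)      (hazard rate)
    RHR(t) = f(t) / F(t)      (reversed hazard rate)

so the identities ``HR * R = f`` and ``RHR * F = f`` hold by construction.
Bayes estimates treat each characteristic as a scalar functional of the
parameter set and push it through either the Lindley expansion (with
numerical derivatives of the functional) or the importance-sampling draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .censoring import CensoredSample
from .distributions import MixtureParams, mixture_cdf, mixture_pdf
from .importance import ISDraws, draw_proposals, _weighted_moments
from .lindley import (
    EstimationResult,
    LOSSES,
    LindleyWorkspace,
    PriorSpec,
    curvature_risk,
    estimates_from_moments,
    lindley_expectation,
)

__all__ = ["ReliabilityChars", "reliability_chars", "bayes_estimate_rcs"]

RC_NAMES = ("R", "HR", "RHR")


@dataclass(frozen=True)
class ReliabilityChars:
    t: float
    R: float
    HR: float
    RHR: float


def reliability_chars(omega: MixtureParams, t: float) -> ReliabilityChars:
    """Survival, hazard and reversed hazard of the mixture at time t."""
    if t <= 0:
        raise ValueError("t must be positive")
    F = mixture_cdf(t, omega)
    f = mixture_pdf(t, omega)
    R = 1.0 - F
    if R <= 0.0:
        raise ZeroDivisionError("survival is zero at t; hazard undefined")
    if F <= 0.0:
        raise ZeroDivisionError("CDF is zero at t; reversed hazard undefined")
    return ReliabilityChars(t=t, R=R, HR=f / R, RHR=f / F)


def _rc_value(v: np.ndarray, which: str, t: float) -> float:
    omega = MixtureParams.from_vector(v)
    rc = reliability_chars(omega, t)
    return getattr(rc, which)


def _numeric_grad_hess(fun, v: np.ndarray):
    """Richardson-free central differences; adequate for the smooth RC
    functionals on the interior of the parameter space."""
    h = (np.finfo(float).eps ** 0.25) * np.maximum(np.abs(v), 0.1)
    h[4] = min(h[4], 0.25 * v[4], 0.25 * (1.0 - v[4]))
    f0 = fun(v)
    g = np.zeros(5)
    H = np.zeros((5, 5))
    fp, fm = np.zeros(5), np.zeros(5)
    for i in range(5):
        vp, vm = v.copy(), v.copy()
        vp[i] += h[i]
        vm[i] -= h[i]
        fp[i], fm[i] = fun(vp), fun(vm)
        g[i] = (fp[i] - fm[i]) / (2 * h[i])
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(5):
        for j in range(i + 1, 5):
            vpp, vpm, vmp, vmm = v.copy(), v.copy(), v.copy(), v.copy()
            vpp[[i, j]] += h[[i, j]]
            vmm[[i, j]] -= h[[i, j]]
            vpm[i] += h[i]
            vpm[j] -= h[j]
            vmp[i] -= h[i]
            vmp[j] += h[j]
            H[i, j] = H[j, i] = (fun(vpp) - fun(vpm) - fun(vmp) + fun(vmm)) / (
                4 * h[i] * h[j]
            )
    return f0, g, H


def bayes_estimate_rcs(
    sample: CensoredSample,
    prior: PriorSpec,
    loss: str,
    method: str,
    t: float,
    m: int = 10000,
    seed: int = 0,
    workspace: LindleyWorkspace | None = None,
    draws: ISDraws | None = None,
) -> EstimationResult:
    """Bayes estimates (and posterior risks) of R, HR and RHR at time t.

    ``method`` is "LA" (Lindley expansion with numerically differentiated
    functionals) or "IS" (weighted averages over the posterior draws).
    """
    if loss not in LOSSES:
        raise ValueError(f"loss must be one of {LOSSES}")
    if method not in ("LA", "IS"):
        raise ValueError("method must be LA or IS")
    est, risks = {}, {}
    if method == "LA":
        ws = workspace if workspace is not None else LindleyWorkspace.build(sample, prior)
        v = ws.mle.params_hat.to_vector()
        for which in RC_NAMES:
            base = lambda vv: _rc_value(vv, which, t)
            mom = {}
            for key, tf in (
                ("mean", lambda y: y),
                ("mean_sq", lambda y: y * y),
                ("mean_inv", lambda y: 1.0 / y),
                ("mean_log", np.log),
                ("mean_exp_neg", lambda y: np.exp(-y)),
            ):
                f0, g, H = _numeric_grad_hess(lambda vv: tf(base(vv)), v)
                mom[key] = lindley_expectation(ws, f0, g, H)
                if key == "mean":
                    # delta-method variance of the plain functional,
                    # reused for the consistent-order risk
                    var_phi = float(g @ ws.sigma @ g)
                    phi_hat = f0
            try:
                est[which], _ = estimates_from_moments(mom, loss)
            except FloatingPointError:
                est[which] = np.nan
            risks[which] = curvature_risk(var_phi, phi_hat, loss)
        return EstimationResult("LA", prior.kind, loss, est, risks, {"t": t})

    d = draws if draws is not None else draw_proposals(sample, prior, m, seed)
    w = d.normalized_weights
    keep = w > 0
    vals = {which: np.empty(d.m) for which in RC_NAMES}
    F = (
        d.draws[:, 4] * (-np.expm1(-d.draws[:, 2] * t)) ** d.draws[:, 0]
        + (1 - d.draws[:, 4]) * (-np.expm1(-d.draws[:, 3] * t)) ** d.draws[:, 1]
    )
    dens = (
        d.draws[:, 4]
        * d.draws[:, 0] * d.draws[:, 2]
        * (-np.expm1(-d.draws[:, 2] * t)) ** (d.draws[:, 0] - 1)
        * np.exp(-d.draws[:, 2] * t)
        + (1 - d.draws[:, 4])
        * d.draws[:, 1] * d.draws[:, 3]
        * (-np.expm1(-d.draws[:, 3] * t)) ** (d.draws[:, 1] - 1)
        * np.exp(-d.draws[:, 3] * t)
    )
    vals["R"] = 1.0 - F
    with np.errstate(divide="ignore", invalid="ignore"):
        vals["HR"] = np.where(keep, dens / np.maximum(1.0 - F, 1e-300), 1.0)
        vals["RHR"] = np.where(keep, dens / np.maximum(F, 1e-300), 1.0)
        vals["R"] = np.where(keep, np.maximum(vals["R"], 1e-300), 1.0)
    for which in RC_NAMES:
        mom = _weighted_moments(vals[which], w)
        est[which], risks[which] = estimates_from_moments(mom, loss)
    return EstimationResult(
        "IS", prior.kind, loss, est, risks,
        {"t": t, "ess": d.effective_sample_size, "n_dropped": d.n_dropped},
    )
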