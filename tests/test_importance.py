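import numpy as np
import pytest
from scipy import stats

from gedmix import (
    CensoredSample,
    GEDParams,
    MixtureParams,
    PriorSpec,
    bayes_estimate_is,
    draw_proposals,
    h14_log_weight,
)
from gedmix.importance import _chi, log_posterior_unnormalized

from conftest import make_complete_sample


def toy_sample():
    """3-point complete labelled sample: 2 failures in component 1, one in
    component 2."""
    return CensoredSample(
        np.array([0.5, 1.2, 0.8]),
        np.ones(3, dtype=int),
        np.array([1, 1, 2]),
        t_anchor=1.2,
    )


def censored_toy_sample():
    return CensoredSample(
        np.array([0.5, 1.2, 0.8, 1.2]),
        np.array([1, 1, 1, 0]),
        np.array([1, 1, 2, 2]),
        t_anchor=1.2,
    )


NIP = PriorSpec.noninformative()


class TestProposals:
    def test_deterministic_given_seed(self):
        s = toy_sample()
        a = draw_proposals(s, NIP, 50, seed=4)
        b = draw_proposals(s, NIP, 50, seed=4)
        np.testing.assert_array_equal(a.draws, b.draws)
        np.testing.assert_array_equal(a.log_weights, b.log_weights)

    def test_mixing_weight_marginal_is_beta(self):
        s = toy_sample()
        d = draw_proposals(s, NIP, 20000, seed=8)
        # r1 = 2, r2 = 1 -> pi1 ~ Beta(3, 2)
        res = stats.kstest(d.draws[:, 4], "beta", args=(3, 2))
        assert res.pvalue > 0.01

    def test_conditional_shape_draw_mean(self):
        # lambda_j | theta_j ~ Gamma(r_j + 1, chi_j): check the conditional
        # mean by regressing the draws on (r_j + 1) / chi_j(theta_j)
        s = toy_sample()
        d = draw_proposals(s, NIP, 40000, seed=2)
        x1 = s.observed_by_component()[0]
        cond_mean = 3.0 / _chi(d.draws[:, 2], x1)
        resid = d.draws[:, 0] - cond_mean
        assert abs(resid.mean()) < 3 * resid.std() / np.sqrt(len(resid))

    def test_empty_component_rejected(self):
        s = CensoredSample(np.array([1.0, 2.0]), np.ones(2, int),
                           np.array([1, 1]), t_anchor=2.0)
        with pytest.raises(ValueError):
            draw_proposals(s, NIP, 100, seed=0)

    def test_normalized_weights_sum_to_one(self):
        d = draw_proposals(censored_toy_sample(), NIP, 500, seed=3)
        assert d.normalized_weights.sum() == pytest.approx(1.0, rel=1e-12)
        assert 1.0 <= d.effective_sample_size <= d.m


class TestResidualWeight:
    def test_complete_sample_has_no_survival_contribution(self):
        # with n = r the survival factor contributes nothing: the weight
        # must coincide for two anchors
        s1 = toy_sample()
        s2 = CensoredSample(s1.times, s1.status, s1.labels, t_anchor=50.0)
        draw = np.array([0.6, 0.9, 1.1, 1.4, 0.5])
        assert h14_log_weight(draw, s1) == pytest.approx(
            h14_log_weight(draw, s2), rel=1e-12
        )

    def test_invariant_to_sample_order(self):
        s = censored_toy_sample()
        perm = np.array([3, 1, 0, 2])
        sp = CensoredSample(s.times[perm], s.status[perm], s.labels[perm],
                            t_anchor=s.t_anchor)
        draw = np.array([0.6, 0.9, 1.1, 1.4, 0.5])
        assert h14_log_weight(draw, s) == pytest.approx(
            h14_log_weight(draw, sp), rel=1e-12
        )

    def test_nonpositive_survival_gives_minus_inf(self):
        s = censored_toy_sample()
        # enormous rates push F(t) to 1 so the survival factor vanishes
        draw = np.array([5.0, 5.0, 80.0, 80.0, 0.5])
        assert h14_log_weight(draw, s) == -np.inf

    @pytest.mark.parametrize("prior", [NIP, PriorSpec(
        kind="IP", a1=2, b1=2, a11=2, b11=3.1, a12=1.4, b12=2.2,
        a21=2.5, b21=1.3, a22=2, b22=0.9)])
    def test_pointwise_posterior_identity(self, prior):
        # exp(log h14) x proposal densities must be proportional to the
        # unnormalised posterior: the log-ratio is constant across draws
        s = censored_toy_sample()
        x1, x2 = s.observed_by_component()
        r1, r2 = len(x1), len(x2)
        K1, K2 = x1.sum(), x2.sum()
        if prior.kind == "IP":
            g = prior.gamma_hyper()
            ab_beta = (r1 + prior.a1, r2 + prior.b1)
        else:
            g = {k: (1.0, 0.0) for k in ("lambda1", "lambda2", "theta1", "theta2")}
            ab_beta = (r1 + 1, r2 + 1)
        d = draw_proposals(s, prior, 200, seed=10)
        keep = np.isfinite(d.log_weights)
        consts = []
        for k in np.nonzero(keep)[0][:20]:
            l1, l2, t1, t2, p1 = d.draws[k]
            chi1 = float(_chi(t1, x1))
            chi2 = float(_chi(t2, x2))
            logq = (
                stats.beta.logpdf(p1, *ab_beta)
                + stats.gamma.logpdf(t1, r1 + g["theta1"][0],
                                     scale=1 / (K1 + g["theta1"][1]))
                + stats.gamma.logpdf(t2, r2 + g["theta2"][0],
                                     scale=1 / (K2 + g["theta2"][1]))
                + stats.gamma.logpdf(l1, r1 + g["lambda1"][0],
                                     scale=1 / (chi1 + g["lambda1"][1]))
                + stats.gamma.logpdf(l2, r2 + g["lambda2"][0],
                                     scale=1 / (chi2 + g["lambda2"][1]))
            )
            lp = log_posterior_unnormalized(
                MixtureParams.from_vector(d.draws[k]), s, prior
            )
            consts.append(d.log_weights[k] + logq - lp)
        consts = np.array(consts)
        assert consts.max() - consts.min() < 1e-8


TOY_IP = PriorSpec(kind="IP", a1=2.0, b1=2.0, a11=2.0, b11=2.0, a12=2.0,
                   b12=2.0, a21=2.0, b21=1.0, a22=2.0, b22=1.0)


def quadrature_posterior_means(sample, prior):
    """Independent oracle for the posterior means on complete labelled
    data: the posterior factorises over components, the shape integrates
    out analytically given the rate, and a dense 1-d quadrature over each
    rate does the rest.  The mixing weight's posterior is exactly Beta.
    """
    if prior.kind == "IP":
        g = prior.gamma_hyper()
        beta_ab = (prior.a1, prior.b1)
    else:
        g = {k: (1.0, 0.0) for k in ("lambda1", "lambda2", "theta1", "theta2")}
        beta_ab = (1.0, 1.0)
    out = {}
    for j, (lam_name, th_name) in ((1, ("lambda1", "theta1")),
                                   (2, ("lambda2", "theta2"))):
        x = sample.observed_by_component()[j - 1]
        r, K = len(x), x.sum()
        a_l, b_l = g[lam_name]
        a_t, b_t = g[th_name]
        th = np.linspace(1e-4, 60.0, 120001)
        chi = -np.sum(np.log(-np.expm1(-np.outer(th, x))), axis=1)
        # rate-marginal after integrating the shape analytically:
        # theta^{r+a_t-1} e^{-theta (K+b_t)} e^{chi} (chi+b_l)^{-(r+a_l)}
        lp = ((r + a_t - 1) * np.log(th) - th * (K + b_t) + chi
              - (r + a_l) * np.log(chi + b_l))
        w = np.exp(lp - lp.max())
        w /= w.sum()
        out[th_name] = float(np.sum(w * th))
        out[lam_name] = float(np.sum(w * (r + a_l) / (chi + b_l)))
    x1, x2 = sample.observed_by_component()
    r1, r2 = len(x1), len(x2)
    out["pi1"] = (r1 + beta_ab[0]) / (r1 + r2 + sum(beta_ab))
    return out


class TestEstimates:
    def test_matches_nested_quadrature_on_toy_sample(self):
        # under the flat prior the tiny sample leaves a pathologically
        # heavy rate tail (shape and rate can grow together), which no
        # finite proposal sample can integrate; the informative prior
        # tempers the posterior, making the quadrature oracle sharp
        s = toy_sample()
        oracle = quadrature_posterior_means(s, TOY_IP)
        res = bayes_estimate_is(s, TOY_IP, "SELF", m=200000, seed=6)
        for name, target in oracle.items():
            assert res.estimates[name] == pytest.approx(target, rel=0.01), name

    def test_jensen_orderings_hold_exactly(self, omega0):
        s = make_complete_sample(omega0, 80, seed=44)
        d = draw_proposals(s, NIP, 4000, seed=9)
        results = {
            loss: bayes_estimate_is(s, NIP, loss, draws=d)
            for loss in ("SELF", "PLF", "ELF", "LLF")
        }
        for p in ("lambda1", "lambda2", "theta1", "theta2", "pi1"):
            self_, plf = results["SELF"].estimates[p], results["PLF"].estimates[p]
            elf, llf = results["ELF"].estimates[p], results["LLF"].estimates[p]
            assert plf >= self_ >= llf
            assert self_ >= elf

    def test_risks_nonnegative(self, omega0):
        s = make_complete_sample(omega0, 80, seed=44)
        d = draw_proposals(s, NIP, 4000, seed=9)
        for loss in ("SELF", "PLF", "ELF", "LLF"):
            res = bayes_estimate_is(s, NIP, loss, draws=d)
            assert all(r >= -1e-12 for r in res.posterior_risks.values())

    def test_ess_diagnostics_reported(self, omega0):
        s = make_complete_sample(omega0, 80, seed=44)
        res = bayes_estimate_is(s, NIP, "SELF", m=2000, seed=1)
        assert "ess" in res.diagnostics and "n_dropped" in res.diagnostics
        assert res.diagnostics["m"] == 2000

    def test_monte_carlo_error_shrinks_with_m(self):
        s = toy_sample()
        sds = []
        for m in (500, 8000):
            vals = [
                bayes_estimate_is(s, TOY_IP, "SELF", m=m, seed=sd).estimates["theta1"]
                for sd in range(12)
            ]
            sds.append(np.std(vals))
        # 16x the draws should shrink the spread by roughly 4; allow slack
        assert sds[1] < 0.6 * sds[0]
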