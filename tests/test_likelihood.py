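import numpy as np
import pytest

from gedmix import (
    CensoredSample,
    GEDParams,
    MixtureParams,
    fit_mle,
    log_likelihood,
    sample_mixture,
    score,
    unlabeled_log_likelihood,
)
from gedmix.distributions import ged_pdf, mixture_cdf, mixture_pdf
from gedmix.likelihood import hessian, third_derivatives

from conftest import make_complete_sample


def toy_censored_sample():
    times = np.array([0.4, 0.9, 1.3, 1.3, 1.3])
    status = np.array([1, 1, 1, 0, 0])
    labels = np.array([1, 2, 1, 1, 2])
    return CensoredSample(times, status, labels, t_anchor=1.3)


def product_form_loglik(sample, omega):
    """Independent oracle: the likelihood assembled factor by factor."""
    x1, x2 = sample.observed_by_component()
    val = 1.0
    for x in x1:
        val *= omega.pi1 * ged_pdf(x, omega.comp1)
    for x in x2:
        val *= (1 - omega.pi1) * ged_pdf(x, omega.comp2)
    val *= (1 - mixture_cdf(sample.t_anchor, omega)) ** (sample.n - sample.r)
    return np.log(val)


class TestLogLikelihood:
    def test_single_observation_hand_value(self):
        s = CensoredSample(np.array([1.0]), np.array([1]), np.array([1]),
                           t_anchor=1.0)
        om = MixtureParams(GEDParams(1, 2), GEDParams(1, 2), 0.5)
        expected = np.log(0.5) + np.log(2.0) - 2.0
        assert log_likelihood(s, om) == pytest.approx(expected, rel=1e-12)

    def test_matches_product_form_oracle(self, omega0):
        s = toy_censored_sample()
        assert log_likelihood(s, omega0) == pytest.approx(
            product_form_loglik(s, omega0), abs=1e-10
        )

    def test_complete_sample_has_no_survival_term(self, omega0):
        times = np.array([0.4, 0.9, 1.3])
        labels = np.array([1, 2, 1])
        s_complete = CensoredSample(times, np.ones(3, int), labels, t_anchor=1.3)
        direct = sum(
            np.log(omega0.pi1 * ged_pdf(x, omega0.comp1)) if l == 1
            else np.log((1 - omega0.pi1) * ged_pdf(x, omega0.comp2))
            for x, l in zip(times, labels)
        )
        assert log_likelihood(s_complete, omega0) == pytest.approx(direct, rel=1e-12)

    def test_permutation_invariance(self, omega0):
        s = toy_censored_sample()
        perm = np.array([4, 2, 0, 3, 1])
        sp = CensoredSample(s.times[perm], s.status[perm], s.labels[perm],
                            t_anchor=s.t_anchor)
        assert log_likelihood(sp, omega0) == log_likelihood(s, omega0)

    def test_degenerate_survival_returns_neg_inf(self):
        # with both shapes tiny, F(t) ~ 1 and the survival factor underflows
        s = toy_censored_sample()
        om = MixtureParams(GEDParams(1e-8, 50.0), GEDParams(1e-8, 50.0), 0.5)
        assert log_likelihood(s, om) == -np.inf

    def test_missing_labels_rejected(self, omega0):
        s = CensoredSample(np.array([1.0, 2.0]), np.array([1, 1]))
        with pytest.raises(ValueError):
            log_likelihood(s, omega0)


class TestScore:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        om = MixtureParams(
            GEDParams(rng.uniform(0.3, 2), rng.uniform(0.5, 2)),
            GEDParams(rng.uniform(0.3, 2), rng.uniform(0.5, 2)),
            rng.uniform(0.2, 0.8),
        )
        times = rng.gamma(1.5, 1.0, size=10)
        labels = rng.integers(1, 3, size=10)
        status = np.ones(10, int)
        status[times.argsort()[-3:]] = 0
        s = CensoredSample(times, status, labels,
                           t_anchor=float(times[status == 1].max()))
        v = om.to_vector()
        g = score(s, om)
        for i in range(5):
            h = 1e-6 * (1 + abs(v[i]))
            vp, vm = v.copy(), v.copy()
            vp[i] += h
            vm[i] -= h
            fd = (
                log_likelihood(s, MixtureParams.from_vector(vp))
                - log_likelihood(s, MixtureParams.from_vector(vm))
            ) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-5)

    def test_mixing_weight_component_closed_form(self, labeled_sample, omega0):
        # complete data: d/dpi1 = r1/pi1 - r2/(1-pi1), zero at r1/r
        g = score(labeled_sample, omega0)
        r1, r2 = labeled_sample.r1, labeled_sample.r2
        assert g[4] == pytest.approx(r1 / 0.45 - r2 / 0.55, rel=1e-12)
        p_hat = r1 / (r1 + r2)
        om_at = MixtureParams(omega0.comp1, omega0.comp2, p_hat)
        assert score(labeled_sample, om_at)[4] == pytest.approx(0.0, abs=1e-9)

    def test_stationary_at_optimum(self, labeled_sample):
        res = fit_mle(labeled_sample)
        assert res.converged
        assert np.max(np.abs(score(labeled_sample, res.params_hat))) < 1e-3


class TestDerivativeTensors:
    def test_hessian_matches_richardson_oracle(self, omega0):
        s = toy_censored_sample()
        H = hessian(s, omega0)
        v = omega0.to_vector()
        # Richardson-extrapolated second differences of the log-likelihood
        for i in range(5):
            h = 1e-3 * (1 + abs(v[i]))

            def d2(hh):
                vp, vm = v.copy(), v.copy()
                vp[i] += hh
                vm[i] -= hh
                f = lambda vv: log_likelihood(s, MixtureParams.from_vector(vv))
                return (f(vp) - 2 * f(v) + f(vm)) / hh**2

            rich = (4 * d2(h / 2) - d2(h)) / 3
            assert H[i, i] == pytest.approx(rich, rel=1e-5)
        assert np.allclose(H, H.T)

    def test_third_tensor_symmetric(self, omega0):
        s = toy_censored_sample()
        T = third_derivatives(s, omega0)
        for perm in ((0, 2, 1), (1, 0, 2), (2, 1, 0)):
            np.testing.assert_allclose(T, np.transpose(T, perm), rtol=1e-7,
                                       atol=1e-7)


class TestFitMLE:
    def test_parameter_recovery_large_sample(self, omega0):
        s = make_complete_sample(omega0, 2000, seed=31)
        res = fit_mle(s)
        assert res.converged
        se = np.sqrt(np.diag(res.sigma))
        err = np.abs(res.params_hat.to_vector() - omega0.to_vector())
        assert np.all(err < 3 * se + 1e-6)

    def test_complete_sample_mixing_weight_closed_form(self, labeled_sample):
        res = fit_mle(labeled_sample)
        expected = labeled_sample.r1 / labeled_sample.r
        assert res.params_hat.pi1 == pytest.approx(expected, abs=1e-6)

    def test_optimum_dominates_truth(self, omega0):
        s = make_complete_sample(omega0, 300, seed=5)
        res = fit_mle(s)
        assert res.loglik >= log_likelihood(s, omega0)

    def test_requires_two_failures_per_component(self, omega0):
        s = CensoredSample(np.array([1.0, 2.0, 3.0]), np.ones(3, int),
                           np.array([1, 1, 2]), t_anchor=3.0)
        with pytest.raises(ValueError):
            fit_mle(s)


class TestUnlabeledLikelihood:
    def test_toy_hand_evaluation(self, omega0):
        times = np.array([0.3, 0.7, 1.1, 1.6, 2.2])
        status = np.array([1, 1, 0, 1, 0])
        s = CensoredSample(times, status)
        expected = sum(
            np.log(mixture_pdf(x, omega0)) for x in times[status == 1]
        ) + sum(np.log(1 - mixture_cdf(x, omega0)) for x in times[status == 0])
        assert unlabeled_log_likelihood(s, omega0) == pytest.approx(
            expected, abs=1e-10
        )

    def test_label_swap_symmetry(self, omega0):
        s = CensoredSample(np.array([0.3, 0.7, 1.1]), np.array([1, 1, 0]))
        swapped = MixtureParams(omega0.comp2, omega0.comp1, 1 - omega0.pi1)
        assert unlabeled_log_likelihood(s, omega0) == pytest.approx(
            unlabeled_log_likelihood(s, swapped), rel=1e-12
        )

    def test_single_component_limit(self):
        s = CensoredSample(np.array([0.5, 1.5]), np.array([1, 0]))
        p = GEDParams(0.8, 1.1)
        om = MixtureParams(p, GEDParams(3.0, 3.0), 1 - 1e-12)
        single = np.log(ged_pdf(0.5, p)) + np.log(1 - mixture_cdf(1.5, MixtureParams(p, p, 0.5)))
        assert unlabeled_log_likelihood(s, om) == pytest.approx(single, rel=1e-6)

    def test_exponential_mixture_reduction(self):
        om = MixtureParams(GEDParams(1.0, 0.9), GEDParams(1.0, 2.0), 0.35)
        times = np.array([0.2, 0.8, 1.4])
        s = CensoredSample(times, np.ones(3, int))
        expected = np.sum(
            np.log(0.35 * 0.9 * np.exp(-0.9 * times) + 0.65 * 2.0 * np.exp(-2.0 * times))
        )
        assert unlabeled_log_likelihood(s, om) == pytest.approx(expected, rel=1e-12)


class TestConsistencyTrend:
    def test_error_decreases_with_sample_size(self, omega0):
        sizes = (50, 200, 1000)
        mae = []
        for n in sizes:
            errs = []
            for seed in range(8):
                s = make_complete_sample(omega0, n, seed=100 + seed)
                res = fit_mle(s)
                if res.converged:
                    errs.append(
                        np.abs(res.params_hat.to_vector() - omega0.to_vector())
                    )
            mae.append(np.mean(errs, axis=0))
        mae = np.array(mae)
        # each parameter's mean absolute error shrinks from n=50 to n=1000
        assert np.all(mae[2] < mae[0])
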