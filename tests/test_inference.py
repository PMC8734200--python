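import numpy as np
import pytest
from scipy import stats

from handgp import (
    DoseResponseData,
    GeneratorSpec,
    HmcSettings,
    Hyperparameters,
    build_priors,
    fit_map,
    generate,
    hpd_interval,
    log_marginal_likelihood,
    run_hmc,
)
from handgp.inference import PriorSpec, _chain_inputs, _start_phi, split_rhat
from handgp._hmc import lp_and_grad_grid
from handgp.kernels import JITTER


class TestBuildPriors:
    def test_length_scale_moment_matching(self, greco_like):
        data, _ = greco_like
        priors = build_priors(data, c=1.0)
        # Dmax = 50, mean 50, variance 2.5 -> Gamma(1000, 20)
        assert priors.alpha[2] == pytest.approx(1000.0)
        assert priors.beta[2] == pytest.approx(20.0)
        # Dmax = 5 on axis 2: mean 5, variance 0.25 -> Gamma(100, 20)
        assert priors.alpha[3] == pytest.approx(100.0)
        assert priors.beta[3] == pytest.approx(20.0)

    def test_amplitude_prior_scales_with_observed_effect(self):
        d = DoseResponseData(
            [0, 0, 1, 1], [0, 1, 0, 1], [100.0, 50.0, 25.0, 0.0]
        )
        priors = build_priors(d)
        # Emax_obs = 100: mean 50, variance 5 -> Gamma(500, 10)
        assert priors.alpha[1] == pytest.approx(500.0)
        assert priors.beta[1] == pytest.approx(10.0)

    def test_noise_prior_by_scale(self, greco_like):
        data, _ = greco_like
        assert tuple(build_priors(data).alpha[:1]) == (2.0,)
        frac = DoseResponseData(data.dose1, data.dose2, data.response / 100.0,
                                response_scale="fraction")
        p = build_priors(frac)
        assert p.alpha[0] == pytest.approx(0.14)
        assert p.beta[0] == pytest.approx(1.14)

    def test_auto_c_uses_monotherapy_effect_ratio(self, greco_like):
        data, _ = greco_like
        p = build_priors(data, c="auto")
        mono = np.concatenate([data.monotherapy(1)[1], data.monotherapy(2)[1]])
        expected = np.abs(mono).min() / np.abs(mono).max()
        assert p.c == pytest.approx(expected)
        assert 0 < p.c < 1  # strongly responding data shrink the length scales

    def test_invalid_c(self, greco_like):
        with pytest.raises(ValueError):
            build_priors(greco_like[0], c=-1.0)


class TestHpd:
    def test_degenerate(self):
        assert hpd_interval(np.full(200, 3.3)) == (3.3, 3.3)

    def test_standard_normal(self):
        rng = np.random.default_rng(0)
        lo, hi = hpd_interval(rng.standard_normal(1_000_000))
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)

    def test_shorter_than_equal_tail_for_skewed(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(2.0, 1.0, size=200_000)
        lo, hi = hpd_interval(x)
        eq = np.quantile(x, [0.025, 0.975])
        assert hi - lo < eq[1] - eq[0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hpd_interval([])


def test_split_rhat_flags_trending_chain():
    rng = np.random.default_rng(2)
    good = rng.standard_normal(4000)
    bad = np.linspace(0, 5, 4000) + rng.standard_normal(4000) * 0.1
    assert split_rhat(good) < 1.01
    assert split_rhat(bad) > 1.5


def test_log_space_density_matches_positive_space(greco_like):
    """The sampled log-space target equals marginal likelihood + Gamma prior
    + Jacobian evaluated in the positive parameterization."""
    data, _ = greco_like
    priors = build_priors(data)
    ux1, ux2, id1, id2, y, Y, gm, pa, pb = _chain_inputs(data, priors)
    phi = _start_phi(priors) + 0.25
    lp, _ = lp_and_grad_grid(phi, ux1, ux2, Y, pa, pb, JITTER)
    s2, sf, l1, l2 = np.exp(phi)
    theta = Hyperparameters(s2, sf**2, l1, l2)
    lml = log_marginal_likelihood(data, theta)
    direct = lml
    for val, a, b in zip((s2, sf, l1, l2), priors.alpha, priors.beta):
        direct += stats.gamma.logpdf(val, a, scale=1 / b) + np.log(val)  # Jacobian
    # lp omits the Gamma normalizing constants; compare differences instead
    phi2 = phi - 0.1
    lp2, _ = lp_and_grad_grid(phi2, ux1, ux2, Y, pa, pb, JITTER)
    s2b, sfb, l1b, l2b = np.exp(phi2)
    thetab = Hyperparameters(s2b, sfb**2, l1b, l2b)
    direct2 = log_marginal_likelihood(data, thetab)
    for val, a, b in zip((s2b, sfb, l1b, l2b), priors.alpha, priors.beta):
        direct2 += stats.gamma.logpdf(val, a, scale=1 / b) + np.log(val)
    assert lp - lp2 == pytest.approx(direct - direct2, rel=1e-9)


class TestHmc:
    SETTINGS = HmcSettings(burn_in=500, n_samples=5000, seed=0)

    def test_sample_count_and_acceptance(self, greco_like):
        data, _ = greco_like
        post = run_hmc(data, build_priors(data), self.SETTINGS)
        assert post.samples.shape == (5000, 4)
        assert post.acceptance_rate >= 0.6
        assert post.divergence_rate <= 0.05

    def test_reproducible_given_seed(self, greco_like):
        data, _ = greco_like
        p1 = run_hmc(data, build_priors(data), self.SETTINGS)
        p2 = run_hmc(data, build_priors(data), self.SETTINGS)
        np.testing.assert_array_equal(p1.samples, p2.samples)
        assert p1.step_size_used == p2.step_size_used

    def test_chains_mixed(self, greco_like):
        data, _ = greco_like
        post = run_hmc(data, build_priors(data), self.SETTINGS)
        assert (post.rhat < 1.05).all()

    def test_posterior_concentrates_with_design_size(self):
        theta = Hyperparameters(sigma2=4.0, sigma_f2=900.0, l1=50.0, l2=5.0)
        import handgp

        small = handgp.gp_sample(theta, np.linspace(0, 50, 6), np.linspace(0, 5, 6),
                                 seed=7, mean=50.0)
        big = handgp.gp_sample(theta, np.linspace(0, 50, 11), np.linspace(0, 5, 11),
                               seed=7, mean=50.0)
        settings = HmcSettings(burn_in=300, n_samples=2000, seed=0)
        widths = []
        for d in (small, big):
            pri = PriorSpec(
                alpha=np.array([2.0, 500.0, 1000.0, 100.0]),
                beta=np.array([1.0, 10.0, 20.0, 20.0]),
            )
            post = run_hmc(d, pri, settings)
            h = post.hpd95
            widths.append(h[0, 1] - h[0, 0])  # noise-variance HPD width
        assert widths[1] < widths[0]

    def test_dense_path_used_for_replicates(self, greco_like):
        data, _ = greco_like
        rep = DoseResponseData(
            np.append(data.dose1, 0.0), np.append(data.dose2, 0.0),
            np.append(data.response, 99.0),
        )
        assert _chain_inputs(rep, build_priors(rep))[6] is False
        post = run_hmc(rep, build_priors(rep),
                       HmcSettings(burn_in=200, n_samples=500, seed=0))
        assert np.isfinite(post.samples).all()


class TestMap:
    def test_deterministic(self, greco_like):
        data, _ = greco_like
        priors = build_priors(data)
        t1 = fit_map(data, priors)
        t2 = fit_map(data, priors)
        np.testing.assert_array_equal(t1.to_array(), t2.to_array())

    def test_objective_at_map_beats_prior_mean(self, greco_like):
        data, _ = greco_like
        priors = build_priors(data)
        theta_map = fit_map(data, priors)

        def lp(theta_arr):
            ux1, ux2, id1, id2, y, Y, gm, pa, pb = _chain_inputs(data, priors)
            phi = np.array([
                np.log(theta_arr[0]), 0.5 * np.log(theta_arr[1]),
                np.log(theta_arr[2]), np.log(theta_arr[3]),
            ])
            return lp_and_grad_grid(phi, ux1, ux2, Y, pa, pb, JITTER)[0]

        prior_mean_theta = np.array([
            priors.mean[0], priors.mean[1] ** 2, priors.mean[2], priors.mean[3]
        ])
        assert lp(theta_map.to_array()) >= lp(prior_mean_theta)

    def test_recovers_noise_variance_on_simulated_data(self):
        data, _ = generate(GeneratorSpec(seed=5, noise_sd=5.0))
        theta = fit_map(data, build_priors(data))
        assert theta.sigma2 == pytest.approx(25.0, rel=0.6)
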