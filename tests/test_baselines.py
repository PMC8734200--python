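import numpy as np
import pytest

from handgp import (
    DoseResponseData,
    HillCurveModel,
    HillParams,
    MuSyCParams,
    MuSyCRegressor,
    fit_hill,
    fit_musyc,
    hill_curve,
    musyc_effect_surface,
    musyc_response,
)
from handgp.baselines import bootstrap_ci
from handgp.data import PredictionGrid

HILL = HillParams(E0=100.0, Emax=0.0, h=1.0, C=10.0)


class TestHillCurve:
    def test_boundary_values(self):
        assert hill_curve(HILL, 0.0) == pytest.approx(100.0)
        assert hill_curve(HILL, HILL.C) == pytest.approx(50.0)

    def test_printed_example(self):
        # E0=100, Emax=0, h=1, C=10 at d=30: 100 / (1 + 3) = 25
        assert hill_curve(HILL, 30.0) == pytest.approx(25.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            HillParams(100.0, 0.0, -1.0, 10.0)


class TestFitHill:
    DOSES = np.array([0.0, 1.0, 3.0, 10.0, 30.0, 100.0])

    def test_noiseless_recovery(self):
        p_true = HillParams(95.0, 5.0, 1.4, 8.0)
        y = hill_curve(p_true, self.DOSES)
        p = fit_hill(self.DOSES, y)
        for got, want in zip(p.to_array(), p_true.to_array()):
            assert got == pytest.approx(want, rel=1e-4)

    def test_constant_data_degenerate_contract(self):
        y = np.full(6, 80.0)
        p = fit_hill(self.DOSES, y)
        # flat data: fitted curve must be (near) constant at E0
        np.testing.assert_allclose(hill_curve(p, self.DOSES), 80.0, atol=1e-3)

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError):
            fit_hill([0.0, 1.0, 2.0], [100, 90, 80])


class TestBootstrap:
    def _fit_fns(self):
        return (
            lambda d, y: fit_hill(d, y),
            lambda p, d: hill_curve(p, d),
        )

    def test_noiseless_data_degenerate_intervals(self):
        d = TestFitHill.DOSES
        y = hill_curve(HILL, d)
        p = fit_hill(d, y)
        fit_fn, pred_fn = self._fit_fns()
        ci, fail = bootstrap_ci(fit_fn, pred_fn, p, d, y, B=20, seed=0)
        np.testing.assert_allclose(ci[:, 0], ci[:, 1], atol=1e-4)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(0)
        d = TestFitHill.DOSES
        y = hill_curve(HILL, d) + rng.normal(0, 3, size=6)
        p = fit_hill(d, y)
        fit_fn, pred_fn = self._fit_fns()
        ci1, _ = bootstrap_ci(fit_fn, pred_fn, p, d, y, B=30, seed=42)
        ci2, _ = bootstrap_ci(fit_fn, pred_fn, p, d, y, B=30, seed=42)
        np.testing.assert_array_equal(ci1, ci2)

    def test_more_noise_gives_wider_intervals(self):
        d = np.r_[TestFitHill.DOSES, TestFitHill.DOSES]
        fit_fn, pred_fn = self._fit_fns()
        widths = []
        for sd in (1.0, 8.0):
            rng = np.random.default_rng(7)
            y = hill_curve(HILL, d) + rng.normal(0, sd, size=d.size)
            p = fit_hill(d, y)
            ci, _ = bootstrap_ci(fit_fn, pred_fn, p, d, y, B=60, seed=1)
            widths.append(ci[3, 1] - ci[3, 0])  # C interval
        assert widths[1] > widths[0]


class TestMuSyCResponse:
    FULL = MuSyCParams(E0=100.0, E1=10.0, E2=30.0, E3=5.0, h1=1.3, h2=0.8,
                       C1=5.0, C2=2.0, alpha12=2.0, alpha21=0.5,
                       gamma12=1.5, gamma21=0.9)

    def test_zero_dose_gives_e0(self):
        assert musyc_response(self.FULL, 0.0, 0.0) == pytest.approx(100.0)

    def test_monotherapy_edges_reduce_to_hill(self):
        d = np.linspace(0, 50, 40)
        got = musyc_response(self.FULL, d, 0.0)
        want = hill_curve(HillParams(100.0, 10.0, 1.3, 5.0), d)
        np.testing.assert_allclose(got, want, atol=1e-10)
        got2 = musyc_response(self.FULL, 0.0, d)
        want2 = hill_curve(HillParams(100.0, 30.0, 0.8, 2.0), d)
        np.testing.assert_allclose(got2, want2, atol=1e-10)

    def test_high_dose_limits(self):
        assert musyc_response(self.FULL, 1e8, 0.0) == pytest.approx(10.0, rel=1e-4)
        assert musyc_response(self.FULL, 0.0, 1e8) == pytest.approx(30.0, rel=1e-4)
        assert musyc_response(self.FULL, 1e8, 1e8) == pytest.approx(5.0, rel=1e-3)

    def test_beta_derived_from_state_effects(self):
        # beta = (min(E1,E2) - E3) / (E0 - min(E1,E2))
        assert self.FULL.beta == pytest.approx((10.0 - 5.0) / (100.0 - 10.0))

    def test_constrained_null_diagonal_bracketed_by_monotherapies(self):
        null = MuSyCParams(E0=100.0, E1=10.0, E2=10.0, E3=10.0, h1=1.3, h2=1.3,
                           C1=5.0, C2=5.0)
        d = np.linspace(0.01, 20, 30)
        diag = musyc_response(null, d, d)
        mono = musyc_response(null, d, 0.0)
        assert (diag <= mono + 1e-9).all()  # combination at least as effective
        assert (diag >= 10.0 - 1e-9).all()


class TestFitMuSyC:
    def _simulate(self, params, n=8, noise=0.5, seed=0):
        d1 = np.r_[0.0, np.geomspace(0.5, 50, n - 1)]
        d2 = np.r_[0.0, np.geomspace(0.2, 20, n - 1)]
        g1, g2 = np.meshgrid(d1, d2, indexing="ij")
        y = musyc_response(params, g1, g2).ravel()
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0, noise, size=y.size)
        return DoseResponseData(g1.ravel(), g2.ravel(), y)

    def test_parameter_recovery_low_noise(self):
        true = MuSyCParams(E0=100.0, E1=5.0, E2=20.0, E3=2.0, h1=1.2, h2=0.9,
                           C1=5.0, C2=2.0, alpha12=1.0, alpha21=1.0,
                           gamma12=1.0, gamma21=1.0)
        data = self._simulate(true, noise=0.5, seed=1)
        fit = fit_musyc(data)
        for name in ("E0", "E1", "E2", "E3"):
            assert getattr(fit, name) == pytest.approx(getattr(true, name), abs=0.1 * 100)
        for name in ("C1", "C2"):
            assert getattr(fit, name) == pytest.approx(getattr(true, name), rel=0.10)

    def test_constrained_fit_of_sham_like_data(self):
        true = MuSyCParams(E0=100.0, E1=8.0, E2=8.0, E3=8.0, h1=1.0, h2=1.0,
                           C1=5.0, C2=5.0)
        data = self._simulate(true, noise=1.0, seed=2)
        fit = fit_musyc(data, constrained=True)
        assert fit.alpha12 == 1.0 and fit.gamma21 == 1.0
        assert fit.beta == pytest.approx(0.0, abs=1e-12)
        resid = musyc_response(fit, data.dose1, data.dose2) - data.y
        assert np.sqrt(np.mean(resid**2)) < 3.0  # comparable to noise sd

    def test_effect_surface_zero_when_null_equals_full(self):
        p = MuSyCParams(E0=100.0, E1=10.0, E2=10.0, E3=10.0, h1=1.0, h2=1.0,
                        C1=5.0, C2=5.0)
        grid = PredictionGrid(np.linspace(0, 50, 11), np.linspace(0, 20, 11))
        eff, vd = musyc_effect_surface(p, p, grid)
        assert np.allclose(eff, 0.0)
        assert vd == pytest.approx(0.0, abs=1e-9)


def test_estimators_follow_sklearn_protocol():
    from sklearn.base import clone

    est = MuSyCRegressor(constrained=True)
    est2 = clone(est)
    assert est2.get_params()["constrained"] is True
    hill = HillCurveModel()
    d = np.array([0.0, 1.0, 3.0, 10.0, 30.0, 100.0])
    y = np.asarray(hill_curve(HILL, d))
    hill.fit(d, y)
    np.testing.assert_allclose(hill.predict(d), y, atol=1e-3)
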