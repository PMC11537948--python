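"""Penalized P-spline fitting of age-varying LMS curves."""

import numpy as np
import pytest
from sklearn.base import clone

from lmsref import bccg
from lmsref.fitting import (ConvergenceError, FitConfig, LMSRegressor,
                            fit_lms, select_smoothing_gcv)


def _draw(n, truth, seed, age_range=(4.0, 20.9)):
    rng = np.random.default_rng(seed)
    age = rng.uniform(*age_range, n)
    L, M, S = truth(age)
    y = bccg.sample((L, M, S), rng=rng)
    return age, y


def constant_truth(age, L=1.0, M=10.0, S=0.1):
    one = np.ones_like(age)
    return L * one, M * one, S * one


class TestFitBasics:
    def test_constant_truth_heavy_penalty_gives_constant_curves(self):
        age, y = _draw(1500, constant_truth, seed=2)
        # a first-order difference penalty shrinks to a constant in the
        # penalty-dominated limit (order 2 would only shrink to a line)
        est = fit_lms(age, y, FitConfig(penalty_order=1, lambda_l=1e9,
                                        lambda_m=1e9, lambda_s=1e9))
        grid = np.linspace(5, 20, 40)
        L, M, S = est.predict_params(grid)
        assert np.ptp(L) < 1e-3 * max(1.0, abs(L.mean()))
        assert np.ptp(M) < 1e-3 * M.mean()
        assert np.ptp(S) < 1e-3 * S.mean()
        assert abs(M.mean() - 10.0) < 0.1
        assert abs(S.mean() - 0.1) < 0.01

    def test_lognormal_closed_form(self):
        """L frozen at 0 with constant M, S reproduces lognormal ML."""
        rng = np.random.default_rng(5)
        age = rng.uniform(4, 20, 800)
        y = rng.lognormal(mean=1.5, sigma=0.2, size=800)
        est = fit_lms(age, y, FitConfig(fix_l=0.0, constant=("m", "s")))
        _, M, S = est.predict_params(np.array([10.0]))
        logy = np.log(y)
        assert M[0] == pytest.approx(np.exp(logy.mean()), rel=1e-3)
        assert S[0] == pytest.approx(logy.std(), rel=1e-3)

    def test_penalized_deviance_nonincreasing(self):
        age, y = _draw(600, constant_truth, seed=3)
        est = fit_lms(age, y, FitConfig(lambda_l=10, lambda_m=10, lambda_s=10))
        assert np.all(np.diff(est.deviance_trace_) <= 1e-8)

    def test_median_within_data_envelope(self):
        age, y = _draw(800, constant_truth, seed=4)
        est = fit_lms(age, y, FitConfig(lambda_l=100, lambda_m=100,
                                        lambda_s=100))
        M = est.predict(age)
        assert np.all(M > y.min()) and np.all(M < y.max())

    def test_input_validation(self):
        age = np.linspace(5, 18, 40)
        with pytest.raises(ValueError, match="at least 50"):
            fit_lms(age, np.ones(40))
        age = np.linspace(5, 18, 60)
        y = np.ones(60)
        y[0] = -1.0
        with pytest.raises(ValueError, match="> 0"):
            fit_lms(age, y)

    def test_nonconvergence_carries_last_iterate(self):
        age, y = _draw(400, constant_truth, seed=6)
        with pytest.raises(ConvergenceError) as exc:
            fit_lms(age, y, FitConfig(lambda_l=1.0, lambda_m=1.0,
                                      lambda_s=1.0, tol=1e-14, max_iter=2))
        assert isinstance(exc.value.estimator, LMSRegressor)
        assert hasattr(exc.value.estimator, "coef_m_")


class TestSmoothingSelection:
    def test_edf_nonincreasing_in_penalty(self):
        age, y = _draw(900, constant_truth, seed=7)
        edfs = []
        for lam in (1.0, 100.0, 1e4, 1e6):
            est = fit_lms(age, y, FitConfig(lambda_l=1e4, lambda_m=lam,
                                            lambda_s=1e4))
            edfs.append(est.edf_["m"])
        assert all(b <= a + 1e-6 for a, b in zip(edfs, edfs[1:]))

    def test_constant_truth_selects_heavy_penalty(self):
        age, y = _draw(1200, constant_truth, seed=8)
        est = fit_lms(age, y, FitConfig(lambda_l=1e5, lambda_s=1e5))
        assert est.edf_["m"] < 4.0      # near the penalty null space

    def test_curvature_in_m_selects_more_edf(self):
        def bumpy(age):
            one = np.ones_like(age)
            return one, 10.0 + 3.0 * np.sin(age / 2.0), 0.1 * one

        age_c, y_c = _draw(1500, constant_truth, seed=9)
        age_b, y_b = _draw(1500, bumpy, seed=9)
        cfg = FitConfig(lambda_l=1e5, lambda_s=1e5)
        lam_c, _ = select_smoothing_gcv(age_c, y_c, cfg)
        lam_b, prof = select_smoothing_gcv(age_b, y_b, cfg)
        est_c = fit_lms(age_c, y_c, cfg)
        est_b = fit_lms(age_b, y_b, cfg)
        assert est_b.edf_["m"] > est_c.edf_["m"]
        assert lam_b["m"] < lam_c["m"]
        assert "m" in prof and len(prof["m"][0]) == len(prof["m"][1])


@pytest.fixture(scope="module")
def fitted():
    age, y = _draw(900, constant_truth, seed=10)
    return fit_lms(age, y, FitConfig(lambda_l=100, lambda_m=100,
                                     lambda_s=100))


class TestEvaluation:

    def test_refuses_extrapolation(self, fitted):
        lo, hi = fitted.age_range_
        with pytest.raises(ValueError, match="extrapolation"):
            fitted.predict_params(np.array([lo - 0.5]))
        with pytest.raises(ValueError, match="extrapolation"):
            fitted.predict_params(np.array([hi + 0.5]))

    def test_continuity_at_knots(self, fitted):
        knot = fitted.knots_[len(fitted.knots_) // 2]
        eps = 1e-7
        left = np.array(fitted.predict_params(np.array([knot - eps])))
        right = np.array(fitted.predict_params(np.array([knot + eps])))
        assert np.allclose(left, right, atol=1e-5)

    def test_zscore_roundtrip(self, fitted):
        ages = np.array([6.0, 12.0, 18.0])
        L, M, S = fitted.predict_params(ages)
        y = bccg.value_from_z(np.array([1.5, -0.5, 0.0]), (L, M, S))
        z = fitted.zscore(ages, y)
        assert np.allclose(z, [1.5, -0.5, 0.0], atol=1e-9)

    def test_centiles_monotone_across_levels(self, fitted):
        grid = np.linspace(5, 20, 16)
        table = fitted.centiles(grid)
        assert np.all(np.diff(table, axis=1) > 0)

    def test_serialization_roundtrip(self, fitted, tmp_path):
        path = tmp_path / "curve.json"
        fitted.save(path, sex="female", variable="FMI", method="DXA")
        back = LMSRegressor.load(path)
        ages = np.linspace(5, 20, 25)
        np.testing.assert_allclose(np.array(back.predict_params(ages)),
                                   np.array(fitted.predict_params(ages)),
                                   rtol=0, atol=1e-12)

    def test_sklearn_protocol(self):
        est = LMSRegressor(lambda_m=5.0)
        params = est.get_params()
        assert params["lambda_m"] == 5.0
        cloned = clone(est)
        assert cloned.get_params()["lambda_m"] == 5.0
        est.set_params(lambda_m=7.0)
        assert est.lambda_m == 7.0


def test_recovery_smoke_against_known_truth():
    """Sanity envelope: one synthetic fit tracks its generating curves."""
    from lmsref.tables import load_reference_table
    from lmsref.simulate import TruthCurves
    truth = TruthCurves(load_reference_table("fmi_dxa_female"))
    age, y = _draw(2000, truth.params, seed=12)
    est = fit_lms(age, y, FitConfig())
    grid = np.arange(6.0, 17.01, 0.5)
    Lf, Mf, Sf = est.predict_params(grid)
    Lt, Mt, St = truth.params(grid)
    assert np.max(np.abs(Mf - Mt) / Mt) < 0.08
    assert np.max(np.abs(Sf - St) / St) < 0.25
    assert np.max(np.abs(Lf - Lt)) < 0.6
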