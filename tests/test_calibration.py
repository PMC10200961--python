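"""Evaluation metrics, SCE-UA behaviour and the calibration machinery."""

import numpy as np
import pandas as pd
import pytest

from twoleaf import calibration as cal
from twoleaf.sceua import SceUaSettings, sceua_minimize


class TestAgreementIndex:
    def test_perfect_prediction(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert cal.agreement_index(x, x) == 1.0

    def test_antisymmetric_two_point_example(self):
        # numerator 8, denominator (1+1)^2 + (1+1)^2 = 8 -> d = 0
        assert cal.agreement_index([2.0, 0.0], [0.0, 2.0]) == pytest.approx(0.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        o = rng.normal(5, 2, 50)
        p = o + rng.normal(0, 1, 50)
        assert cal.agreement_index(p + 13.7, o + 13.7) == pytest.approx(
            cal.agreement_index(p, o), rel=1e-12)

    def test_degenerate_observed_rejected(self):
        with pytest.raises(ValueError):
            cal.agreement_index(np.ones(5), np.ones(5))


class TestMetrics:
    def test_perfect_prediction_floors_sse(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        m = cal.metrics(x, x, k_params=2)
        assert m.rmse == pytest.approx(np.sqrt(1e-12 / 4))
        assert m.r == 1.0 and m.d == 1.0
        assert np.isfinite(m.aic)

    def test_constant_offset(self):
        o = np.array([1.0, 2.0, 3.0, 4.0])
        m = cal.metrics(o + 0.5, o, k_params=2)
        assert m.rmse == pytest.approx(0.5)
        assert m.r == pytest.approx(1.0)

    def test_hand_sized_vectors_against_brute_force(self):
        p = np.array([1.0, 2.5, 3.0, 5.0])
        o = np.array([1.2, 2.0, 3.5, 4.4])
        m = cal.metrics(p, o, k_params=2)
        sse = float(((p - o) ** 2).sum())
        assert m.rmse == pytest.approx(np.sqrt(sse / 4))
        assert m.aic == pytest.approx(4 * np.log(sse / 4) + 4)
        assert m.r == pytest.approx(np.corrcoef(p, o)[0, 1])
        obar = o.mean()
        d = 1 - sse / np.sum((np.abs(p - obar) + np.abs(o - obar)) ** 2)
        assert m.d == pytest.approx(d)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            cal.metrics([1.0, 2.0], [1.0, 2.0], k_params=2)

    def test_shift_invariance_of_rmse_and_r(self):
        rng = np.random.default_rng(1)
        o = rng.normal(0, 1, 30)
        p = o + rng.normal(0, 0.5, 30)
        m0 = cal.metrics(p, o, 2)
        m1 = cal.metrics(p + 4.2, o + 4.2, 2)
        assert m1.rmse == pytest.approx(m0.rmse, rel=1e-12)
        assert m1.r == pytest.approx(m0.r, rel=1e-9)


class TestSceUa:
    def test_convex_quadratic_recovery(self):
        target = np.array([0.3, -1.2])
        res = sceua_minimize(lambda x: ((x - target) ** 2).sum(),
                             [(-2, 2), (-2, 2)], seed=0)
        assert np.abs(res.x - target).max() < 1e-4

    def test_optimum_on_boundary(self):
        # unconstrained optimum outside the box -> solution on the bound
        target = np.array([3.0, 0.5])
        res = sceua_minimize(lambda x: ((x - target) ** 2).sum(),
                             [(-2, 2), (-2, 2)], seed=1)
        assert res.x[0] == pytest.approx(2.0, abs=1e-4)
        assert res.x[1] == pytest.approx(0.5, abs=1e-4)

    def test_deterministic_given_seed(self):
        f = lambda x: np.sin(3 * x[0]) * np.cos(2 * x[1]) + 0.1 * (x ** 2).sum()
        r1 = sceua_minimize(f, [(-3, 3), (-3, 3)], seed=7)
        r2 = sceua_minimize(f, [(-3, 3), (-3, 3)], seed=7)
        np.testing.assert_array_equal(r1.x, r2.x)
        assert r1.n_evaluations == r2.n_evaluations

    def test_multimodal_global_minimum(self):
        # Six-hump camel: global minima at (+-0.0898, -+0.7126), f = -1.0316
        def camel(x):
            a, b = x
            return (4 - 2.1 * a ** 2 + a ** 4 / 3) * a ** 2 + a * b + (-4 + 4 * b ** 2) * b ** 2
        res = sceua_minimize(camel, [(-2, 2), (-1, 1)],
                             SceUaSettings(max_evaluations=6000, tol=1e-8), seed=3)
        assert res.fun == pytest.approx(-1.0316, abs=1e-3)

    def test_rejects_broken_objective(self):
        with pytest.raises(ValueError):
            sceua_minimize(lambda x: np.nan, [(0, 1), (0, 1)], seed=0)

    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            sceua_minimize(lambda x: 0.0, [(0, 0), (0, 1)], seed=0)


class TestCalibrationSchemes:
    def test_sea_recovers_constant_truth_and_matches_egs(self, clean_data):
        # truth constant across seasons -> both schemes recover it and the
        # three SEA estimates coincide
        import twoleaf.synthetic_flux as sf
        from twoleaf.params import ParameterSet

        const = {s: ParameterSet(0.65, 3.2, 10.0, 12.0, s)
                 for s in ("spring", "summer", "autumn")}
        spec = sf.SyntheticSiteSpec(years=2, noise=(0, 0), seed=11, true_params=const)
        daily, _, windows = sf.forward_simulate(spec)
        data = cal.CalibrationData(daily, windows)
        cfg = cal.CalibrationConfig(n_experiments=1, seed=2,
                                    sceua=SceUaSettings(max_evaluations=4000, tol=1e-7))
        sea = cal.calibrate_scheme(data, "SEA", cfg)
        egs = cal.calibrate_scheme(data, "EGS", cfg)
        for name in ("eps_msu", "eps_msh", "g_su", "g_sh"):
            truth = getattr(const["spring"], name)
            for s in ("spring", "summer", "autumn"):
                assert getattr(sea[s], name) == pytest.approx(truth, rel=0.01)
            assert getattr(egs["all"], name) == pytest.approx(truth, rel=0.01)

    def test_sea_recovers_seasonal_truth(self, clean_data):
        spec, data, _ = clean_data
        cfg = cal.CalibrationConfig(n_experiments=1, seed=3,
                                    sceua=SceUaSettings(max_evaluations=4000, tol=1e-7))
        sea = cal.calibrate_scheme(data, "SEA", cfg)
        for s, p in sea.items():
            truth = spec.true_params[s]
            for name in ("eps_msu", "eps_msh", "g_su", "g_sh"):
                assert getattr(p, name) == pytest.approx(getattr(truth, name), rel=0.01)

    def test_egs_lue_between_seasonal_extremes(self, clean_data):
        spec, data, _ = clean_data
        cfg = cal.CalibrationConfig(n_experiments=1, seed=4)
        egs = cal.calibrate_scheme(data, "EGS", cfg)["all"]
        lo = min(p.eps_msu for p in spec.true_params.values())
        hi = max(p.eps_msu for p in spec.true_params.values())
        assert lo < egs.eps_msu < hi

    def test_bound_clipped_truth_estimated_at_bound(self):
        import twoleaf.synthetic_flux as sf
        from twoleaf.params import PARAM_BOUNDS, ParameterSet

        at_bound = {s: ParameterSet(PARAM_BOUNDS["eps_msu"][0], 3.0, 10.0, 12.0, s)
                    for s in ("spring", "summer", "autumn")}
        spec = sf.SyntheticSiteSpec(years=1, noise=(0, 0), seed=13, true_params=at_bound)
        daily, _, windows = sf.forward_simulate(spec)
        data = cal.CalibrationData(daily, windows)
        cfg = cal.CalibrationConfig(n_experiments=1, seed=5)
        egs = cal.calibrate_scheme(data, "EGS", cfg)["all"]
        assert egs.eps_msu == pytest.approx(PARAM_BOUNDS["eps_msu"][0], abs=1e-3)

    def test_sparse_season_raises(self, clean_data):
        _, data, _ = clean_data
        cfg = cal.CalibrationConfig(n_experiments=1, min_season_days=10)
        idx = np.where(data.season == "spring")[0][:5]
        with pytest.raises(ValueError, match="summer|spring|autumn"):
            cal.calibrate_scheme(data, "SEA", cfg, idx=idx)


@pytest.fixture(scope="module")
def small_run(noisy_site):
    _, daily, _, windows = noisy_site
    data = cal.CalibrationData(daily, windows)
    cfg = cal.CalibrationConfig(n_experiments=4, seed=5)
    return data, cfg, cal.run_randomized_experiments(data, cfg)


class TestRandomizedExperiments:
    def test_reproducible(self, noisy_site, small_run):
        _, daily, _, windows = noisy_site
        data, cfg, res = small_run
        again = cal.run_randomized_experiments(data, cfg)
        pd.testing.assert_frame_equal(res["SEA"].metrics, again["SEA"].metrics)

    def test_split_proportions_per_season(self, small_run):
        data, cfg, res = small_run
        rng = np.random.default_rng(0)
        train, test = cal._stratified_split(data, rng, 0.7)
        for s in cal.SEASONS:
            n_season = int((data.season == s).sum())
            n_train = int((data.season[train] == s).sum())
            assert n_train == round(0.7 * n_season)
            assert n_train + int((data.season[test] == s).sum()) == n_season

    def test_validation_and_calibration_partition(self, small_run):
        data, cfg, res = small_run
        m = res["EGS"].metrics
        npair = m[m["variable"] == "GPP"].groupby("experiment")["n"].sum()
        assert (npair == data.n).all()

    def test_noise_free_validation_equals_calibration(self, clean_data):
        _, data, _ = clean_data
        cfg = cal.CalibrationConfig(n_experiments=1, seed=6,
                                    sceua=SceUaSettings(max_evaluations=4000, tol=1e-7))
        res = cal.run_randomized_experiments(data, cfg, schemes=("SEA",))
        m = res["SEA"].metrics.set_index(["group", "variable"])
        for var in ("GPP", "Tc"):
            c = m.loc[("calibration", var)]
            v = m.loc[("validation", var)]
            # perfect recovery: errors are numerically zero in both groups
            assert c["rmse"].max() < 1e-4 and v["rmse"].max() < 1e-4
            assert c["d"].min() > 1 - 1e-6 and v["d"].min() > 1 - 1e-6


class TestCompareSchemes:
    def _result(self, rmse_values):
        rows = [{"experiment": i, "group": "validation", "variable": "GPP",
                 "aic": 0.0, "rmse": v, "r": 0.9, "d": 0.9, "n": 100}
                for i, v in enumerate(rmse_values)]
        return cal.ExperimentResult("X", [], pd.DataFrame(rows))

    def test_identical_results_zero_change(self):
        a = self._result([2.0, 2.5])
        comp = cal.compare_schemes(a, self._result([2.0, 2.5]))
        assert comp["rmse_change_pct_mean"].iloc[0] == pytest.approx(0.0)

    def test_hand_relative_change(self):
        comp = cal.compare_schemes(self._result([2.28]), self._result([2.10]))
        assert comp["rmse_change_pct_mean"].iloc[0] == pytest.approx(
            100 * (2.10 - 2.28) / 2.28)
        # negative change means the second scheme has the lower error
        assert comp["rmse_change_pct_mean"].iloc[0] == pytest.approx(-7.9, abs=0.05)
        assert comp["b_win_fraction"].iloc[0] == 1.0

    def test_mismatched_counts_rejected(self):
        with pytest.raises(ValueError):
            cal.compare_schemes(self._result([2.0]), self._result([2.0, 2.1]))
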