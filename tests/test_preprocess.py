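"""QC filtering, daily aggregation, uWUE partitioning, season windows and
LAI interpolation."""

import numpy as np
import pandas as pd
import pytest

from twoleaf import preprocess as pp
from twoleaf import water_flux as wf
from twoleaf.gpp_model import GC_PER_UMOL


def _hh_frame(sw, **cols):
    n = len(sw)
    idx = pd.date_range("2001-06-01", periods=n, freq="30min")
    base = {"SW_IN": sw, "TA": np.full(n, 20.0), "RH": np.full(n, 0.6),
            "VPD": np.full(n, 1.0), "WS": np.full(n, 2.0), "CA": np.full(n, 400.0),
            "LE": np.zeros(n), "H": np.zeros(n), "G": np.zeros(n),
            "GPP": np.zeros(n)}
    base.update(cols)
    return pd.DataFrame(base, index=idx)


class TestQcFilter:
    def test_strict_shortwave_threshold(self):
        hh = _hh_frame(np.array([4.9, 5.0, 5.1, 300.0]))
        kept = pp.qc_filter_daytime(hh)
        np.testing.assert_array_equal(kept["SW_IN"].to_numpy(), [5.1, 300.0])

    def test_all_night_day_empty(self):
        hh = _hh_frame(np.zeros(48))
        assert len(pp.qc_filter_daytime(hh)) == 0

    def test_qc_flags_respected(self):
        hh = _hh_frame(np.array([300.0, 300.0, 300.0]), GPP_QC=np.array([0, 1, 2]))
        assert len(pp.qc_filter_daytime(hh)) == 2

    def test_order_preserved(self):
        sw = np.array([10.0, 2.0, 20.0, 3.0, 30.0])
        kept = pp.qc_filter_daytime(_hh_frame(sw))
        assert list(kept["SW_IN"]) == [10.0, 20.0, 30.0]


class TestAggregateDaily:
    def test_gpp_unit_conversion(self):
        # constant 10 umol/m2/s over 24 retained half-hours (12 h)
        hh = _hh_frame(np.full(24, 300.0), GPP=np.full(24, 10.0))
        daily = pp.aggregate_daily(hh)
        assert daily["GPP_obs"].iloc[0] == pytest.approx(10 * 12.011e-6 * 43200, rel=1e-12)
        assert daily["GPP_obs"].iloc[0] == pytest.approx(5.189, abs=1e-3)

    def test_le_to_mm(self):
        hh = _hh_frame(np.full(24, 300.0), LE=np.full(24, 200.0))
        daily = pp.aggregate_daily(hh)
        lam = wf.psychrometrics(20.0).lam
        assert daily["ET_obs"].iloc[0] == pytest.approx(200 * 43200 * 1e-6 / lam, rel=1e-12)

    def test_single_record_mean(self):
        hh = _hh_frame(np.array([300.0]), TA=np.array([17.3]))
        daily = pp.aggregate_daily(hh)
        assert daily["T_air"].iloc[0] == 17.3
        assert daily["daytime_s"].iloc[0] == 1800.0

    def test_mass_conservation(self, clean_site):
        _, daily, hh, _ = clean_site
        qc = pp.qc_filter_daytime(hh)
        redone = pp.aggregate_daily(qc)
        np.testing.assert_allclose(redone["GPP_obs"], daily["GPP_obs"], atol=1e-9)
        np.testing.assert_allclose(redone["ET_obs"], daily["ET_obs"], atol=1e-9)


class TestUwuePartition:
    def _daily(self, gpp, vpd, et):
        return pd.DataFrame({"GPP_obs": gpp, "VPD": vpd, "ET_obs": et})

    def test_degenerate_proportional_series_exact(self):
        # GPP*sqrt(VPD) = c * ET on every day -> uWUE_p = c, Tc = ET
        rng = np.random.default_rng(0)
        et = rng.uniform(0.5, 4.0, 100)
        vpd = rng.uniform(0.2, 2.5, 100)
        c = 7.3
        gpp = c * et / np.sqrt(vpd)
        daily = self._daily(gpp, vpd, et)
        assert pp.uwue_potential(gpp, vpd, et) == pytest.approx(c, rel=1e-12)
        tc = pp.partition_transpiration_uwue(daily)
        np.testing.assert_allclose(tc, et, rtol=1e-12)

    def test_ratio_clamped_to_one(self):
        rng = np.random.default_rng(1)
        et = rng.uniform(1, 3, 80)
        vpd = np.ones(80)
        gpp = 5.0 * et
        gpp[0] *= 3.0  # noisy day with apparent uWUE above potential
        tc = pp.partition_transpiration_uwue(self._daily(gpp, vpd, et))
        assert tc.iloc[0] == pytest.approx(et[0])
        assert ((tc / et) <= 1 + 1e-12).all()

    def test_nonpositive_et_flagged(self):
        et = np.r_[np.full(70, 2.0), 0.0]
        gpp = np.full(71, 6.0)
        tc = pp.partition_transpiration_uwue(self._daily(gpp, np.ones(71), et))
        assert np.isnan(tc.iloc[-1])

    def test_min_days_enforced(self):
        with pytest.raises(ValueError, match="60"):
            pp.uwue_potential(np.ones(10), np.ones(10), np.ones(10))

    def test_matches_statsmodels_quantile_regression(self):
        # independent route: IRLS quantile regression without intercept
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        et = rng.uniform(0.5, 4.0, 300)
        gpp_sqrt_vpd = et * rng.uniform(4.0, 9.0, 300)
        ours = pp.uwue_potential(gpp_sqrt_vpd, np.ones(300), et)
        theirs = float(sm.QuantReg(gpp_sqrt_vpd, et).fit(q=0.95).params[0])
        assert ours == pytest.approx(theirs, rel=2e-2)


class TestIdentifySeasons:
    @staticmethod
    def _sinusoid_daily(years=2, mean=9.0, amp=9.0):
        dates = pd.date_range("2001-01-01", periods=365 * years, freq="D")
        doy = dates.dayofyear.to_numpy()
        t = mean - amp * np.cos(2 * np.pi * (doy - 15) / 365.0)
        return pd.DataFrame({"T_air": t, "doy": doy}, index=dates)

    def test_sinusoid_ordering_and_contiguity(self):
        w = pp.identify_seasons(self._sinusoid_daily())
        assert w.spring[1] + 1 == w.summer[0]
        assert w.summer[1] + 1 == w.autumn[0]
        peak_doy = 15 + 365 // 2
        assert w.spring[1] < peak_doy < w.autumn[0]

    def test_sinusoid_crossings_match_closed_form(self):
        w = pp.identify_seasons(self._sinusoid_daily(), smooth_days=1)
        # P25/P75 of the sinusoid are at cos = +-sqrt(2)/2 approximately
        # (percentile of a sampled cosine); summer block spans the days
        # above P75, symmetric about the peak near doy 197-198
        t = self._sinusoid_daily()["T_air"]
        p75 = np.percentile(t, 75)
        doy = np.arange(1, 366)
        above = 9.0 - 9.0 * np.cos(2 * np.pi * (doy - 15) / 365.0) > p75
        first, last = doy[above][0], doy[above][-1]
        assert abs(w.summer[0] - first) <= 2
        assert abs(w.summer[1] - last) <= 2

    def test_constant_temperature_rejected(self):
        dates = pd.date_range("2001-01-01", periods=730, freq="D")
        daily = pd.DataFrame({"T_air": np.full(730, 10.0),
                              "doy": dates.dayofyear}, index=dates)
        with pytest.raises(ValueError, match="seasonal cycle"):
            pp.identify_seasons(daily)

    def test_synthetic_site_windows_contiguous(self, clean_site):
        _, _, _, w = clean_site
        assert w.spring[1] + 1 == w.summer[0]
        assert w.summer[1] + 1 == w.autumn[0]


class TestInterpolateLaiFpar:
    def test_linear_midpoint(self):
        eight = pd.DataFrame({"doy": [1, 9], "LAI": [1.0, 3.0], "FPAR": [0.3, 0.7]})
        daily = pp.interpolate_lai_fpar(eight)
        assert daily.loc[5, "LAI"] == pytest.approx(2.0)

    def test_constant_preserved_by_smoothing(self):
        doy = np.arange(1, 200, 8)
        eight = pd.DataFrame({"doy": doy, "LAI": np.full(len(doy), 4.0),
                              "FPAR": np.full(len(doy), 0.8)})
        daily = pp.interpolate_lai_fpar(eight)
        np.testing.assert_allclose(daily["LAI"], 4.0, rtol=1e-12)

    def test_quadratic_reproduced_exactly(self):
        # daily-spaced input makes interpolation the identity, so this
        # isolates the filter: Savitzky-Golay of order >= 2 is exact on
        # quadratics
        doy = np.arange(1, 130)
        lai = 1e-3 * (doy - 60.0) ** 2
        eight = pd.DataFrame({"doy": doy, "LAI": lai, "FPAR": np.clip(lai / 20, 0, 1)})
        daily = pp.interpolate_lai_fpar(eight, window=15, polyorder=2)
        np.testing.assert_allclose(daily["LAI"], lai, atol=1e-9)

    def test_nonmonotone_rejected(self):
        eight = pd.DataFrame({"doy": [1, 9, 9], "LAI": [1, 2, 3], "FPAR": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError):
            pp.interpolate_lai_fpar(eight)
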