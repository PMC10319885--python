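"""Light-response fitting, Penman-Monteith inversion, and the site-level EFPs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ecospectra import meteo
from ecospectra.efp import (LightResponseCurve, aggregate_gppsat, compute_efps,
                            ef_site, fit_light_response, gppsat_site, gsmax_site,
                            mean_annual_temperature, pnue, recomax_site, wuet_site)
from ecospectra.flux_io import SiteMeta
from ecospectra.preprocess import FilterConfig
from ecospectra.synthetic_data import MMOL_PER_MM, SW_TO_PPFD, light_response

from conftest import make_series

CFG = FilterConfig(growing_season_smooth_days=1)


class TestLightResponse:
    def test_noiseless_parameter_recovery(self):
        swin = np.linspace(110, 900, 60)
        gpp = light_response(SW_TO_PPFD * swin, 0.05, 40.0)
        res = LightResponseCurve(gpp, swin).fit()
        assert res.converged
        assert res.alpha == pytest.approx(0.05, rel=1e-6)
        assert res.beta == pytest.approx(40.0, rel=1e-6)
        # analytic hyperbola value at PPFD 2000
        assert res.gppsat == pytest.approx(0.05 * 40 * 2000 / (0.05 * 2000 + 40), rel=1e-6)

    def test_ppfd_is_2p11_times_swin(self):
        model = LightResponseCurve(np.array([10.0]), np.array([1000.0]))
        assert model.ppfd[0] == pytest.approx(2110.0)

    def test_window_below_minimum_points_skipped(self):
        window = pd.DataFrame({"GPP": np.ones(5), "SWin": np.full(5, 300.0)})
        assert fit_light_response(window, CFG) is None

    def test_summary_mentions_parameters(self):
        swin = np.linspace(110, 900, 30)
        res = LightResponseCurve(light_response(SW_TO_PPFD * swin, 0.04, 30), swin).fit()
        text = res.summary()
        assert "alpha" in text and "GPPsat" in text


class TestGppsatAggregation:
    def test_cap_is_exclusion_then_percentile(self):
        # estimates {50, 59, 61, 65}: cap 60 drops 61 and 65 (not clipped);
        # 95th percentile of {50, 59} = 58.55 under linear interpolation
        est = pd.DataFrame({"year": 2020, "gppsat": [50.0, 59.0, 61.0, 65.0]})
        assert aggregate_gppsat(est) == pytest.approx(58.55)

    def test_mean_over_yearly_percentiles(self):
        est = pd.DataFrame({"year": [2020] * 3 + [2021] * 3,
                            "gppsat": [20.0] * 3 + [30.0] * 3})
        assert aggregate_gppsat(est) == pytest.approx(25.0)

    def test_all_windows_identical(self):
        est = pd.DataFrame({"year": [2020] * 10, "gppsat": 30.0})
        assert aggregate_gppsat(est) == pytest.approx(30.0)

    def test_all_above_cap_gives_missing(self):
        est = pd.DataFrame({"year": [2020], "gppsat": [75.0]})
        assert np.isnan(aggregate_gppsat(est))


def _lit_series(n_days=7, alpha=0.05, beta=40.0):
    n = n_days * 48
    hour = (np.arange(n) % 48) / 2.0
    swin = np.clip(900 * np.sin(np.pi * (hour - 6) / 12), 0, None)
    gpp = light_response(SW_TO_PPFD * swin, alpha, beta)
    return make_series(n=n, SWin=swin, GPP=gpp, NEE=2.0 - gpp)


class TestGppsatSite:
    def test_recovers_analytic_value_on_clean_diurnal_cycle(self):
        series = _lit_series()
        expected = light_response(2000.0, 0.05, 40.0)
        assert gppsat_site(series, CFG) == pytest.approx(expected, rel=1e-4)

    def test_order_free_within_windows(self):
        # shuffling record values within each day leaves the fit unchanged
        series = _lit_series()
        rng = np.random.default_rng(3)
        df = series.data.copy()
        for _, day in df.groupby(df.index.normalize()):
            perm = rng.permutation(len(day))
            df.loc[day.index, ["GPP", "SWin"]] = day[["GPP", "SWin"]].to_numpy()[perm]
        shuffled = make_series(n=len(df), SWin=df["SWin"].to_numpy(),
                               GPP=df["GPP"].to_numpy(), NEE=df["NEE"].to_numpy())
        assert gppsat_site(shuffled, CFG) == pytest.approx(gppsat_site(series, CFG), rel=1e-9)

    def test_no_daytime_data_gives_missing(self):
        series = make_series(n=96, SWin=10.0, GPP=1.0)
        assert np.isnan(gppsat_site(series, CFG))


class TestRecomax:
    def test_90th_percentile_of_night_nee(self):
        # 10 night records with NEE 1..10 -> 9.1 under linear interpolation
        nee = np.concatenate([np.arange(1.0, 11.0), np.full(38, np.nan)])
        swin = np.concatenate([np.zeros(10), np.full(38, 300.0)])
        series = make_series(n=48, NEE=nee, SWin=swin, GPP=5.0)
        assert recomax_site(series, CFG) == pytest.approx(9.1)

    def test_constant_night_nee(self):
        series = make_series(n=48, NEE=5.0, SWin=0.0, GPP=1.0)
        assert recomax_site(series, CFG) == pytest.approx(5.0)

    def test_no_night_records_missing(self):
        series = make_series(n=48, NEE=5.0, SWin=300.0, GPP=1.0)
        assert np.isnan(recomax_site(series, CFG))


class TestEvaporativeFraction:
    def test_symmetric_partitioning(self):
        series = make_series(n=48, LE=150.0, H=150.0, SWin=400.0, GPP=5.0,
                             P=0.0, ustar=0.3)
        assert ef_site(series, CFG) == pytest.approx(0.5)

    def test_single_record_arithmetic(self):
        le = np.full(48, np.nan)
        h = np.full(48, np.nan)
        le[12], h[12] = 300.0, 100.0
        series = make_series(n=48, LE=le, H=h, SWin=400.0, GPP=5.0, P=0.0, ustar=0.3)
        assert ef_site(series, CFG) == pytest.approx(0.75)

    def test_zero_available_energy_skipped_not_nan(self):
        le = np.full(48, 100.0)
        h = np.full(48, 100.0)
        le[0], h[0] = 0.0, 0.0   # LE + H = 0 must be skipped
        series = make_series(n=48, LE=le, H=h, SWin=400.0, GPP=5.0, P=0.0, ustar=0.3)
        assert ef_site(series, CFG) == pytest.approx(0.5)

    def test_low_ustar_records_excluded(self):
        ustar = np.full(48, 0.1)
        ustar[:24] = 0.3
        le = np.where(np.arange(48) < 24, 100.0, 900.0)
        series = make_series(n=48, LE=le, H=100.0, SWin=400.0, GPP=5.0, P=0.0,
                             ustar=ustar)
        assert ef_site(series, CFG) == pytest.approx(0.5)


class TestAerodynamicConductance:
    def test_thom_formula_hand_value(self):
        # WS=2, u*=0.3: 1/(2/0.09 + 6.2*0.3^-0.67) ~ 0.0277
        assert meteo.aerodynamic_conductance(2.0, 0.3) == pytest.approx(0.0277, abs=5e-4)

    def test_monotonicity_in_wind_speed(self):
        assert (meteo.aerodynamic_conductance(4.0, 0.3)
                < meteo.aerodynamic_conductance(2.0, 0.3))

    def test_vanishes_with_turbulence(self):
        assert meteo.aerodynamic_conductance(2.0, 1e-4) < 1e-6

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            meteo.aerodynamic_conductance(0.0, 0.3)
        with pytest.raises(ValueError):
            meteo.aerodynamic_conductance(2.0, -0.1)


class TestSurfaceConductance:
    @given(st.floats(5, 35), st.floats(0.2, 3.0), st.floats(80, 102),
           st.floats(0.002, 0.04), st.floats(100, 700), st.floats(0.01, 0.08))
    def test_forward_inverse_round_trip(self, ta, vpd, pa, gs0, avail, ga):
        le = meteo.penman_monteith_le(gs0, ga, avail, ta, vpd, pa)
        h = avail - le
        gs = meteo.surface_conductance(le, h, ta, vpd, pa, ga)
        assert gs == pytest.approx(gs0, rel=1e-6)

    def test_zero_flux_zero_conductance(self):
        assert meteo.surface_conductance(0.0, 200.0, 20.0, 1.0, 100.0, 0.03) == 0.0

    def test_negative_vpd_invalid(self):
        assert np.isnan(meteo.surface_conductance(100.0, 100.0, 20.0, -0.5, 100.0, 0.03))


class TestGsmaxSite:
    def test_90th_percentile_of_inverted_conductances(self):
        # forward-model LE at Gs = 0.001*k for k=1..10 -> Gsmax = 0.0091
        gs_vals = 0.001 * np.arange(1, 11)
        ta, vpd, pa, avail = 20.0, 1.2, 100.0, 500.0
        ws, ustar = 2.0, 0.3
        ga = meteo.aerodynamic_conductance(ws, ustar)
        le = np.array([meteo.penman_monteith_le(g, ga, avail, ta, vpd, pa)
                       for g in gs_vals])
        n = 48
        le_col = np.full(n, np.nan)
        h_col = np.full(n, np.nan)
        le_col[:10], h_col[:10] = le, avail - le
        series = make_series(n=n, LE=le_col, H=h_col, SWin=400.0, GPP=5.0,
                             Ta=ta, VPD=vpd, PA=pa, WS=ws, ustar=ustar, P=0.0)
        assert gsmax_site(series, CFG) == pytest.approx(0.0091, rel=1e-6)

    def test_all_invalid_gives_missing(self):
        series = make_series(n=48, LE=100.0, H=100.0, SWin=400.0, GPP=5.0,
                             Ta=20.0, VPD=-1.0, PA=100.0, WS=2.0, ustar=0.3, P=0.0)
        assert np.isnan(gsmax_site(series, CFG))


class TestWUEt:
    def _series(self, gpp=10.0, t=0.05, qc=0.0, n_days=5):
        n = n_days * 48
        return make_series(n=n, GPP=gpp, T=t, SWin_pot=400.0, SWin=300.0,
                           NEE_QC=qc)

    def test_constant_ratio(self):
        series = self._series(gpp=10.0, t=0.05)
        # per-interval: 10 umol/m2/s * 1800 s over 0.05 mm * 55508 mmol/mm
        expected = (10.0 * 1800) / (0.05 * MMOL_PER_MM)
        assert wuet_site(series, CFG) == pytest.approx(expected, rel=1e-12)

    def test_poor_quality_day_dropped(self):
        n = 5 * 48
        qc = np.zeros(n)
        qc[:48] = 2.0            # day 1 fraction good = 0 <= 0.8 -> dropped
        t = np.full(n, 0.05)
        t[:48] = 0.5             # would distort the ratio if kept
        series = make_series(n=n, GPP=10.0, T=t, SWin_pot=400.0, SWin=300.0,
                             NEE_QC=qc)
        expected = (10.0 * 1800) / (0.05 * MMOL_PER_MM)
        assert wuet_site(series, CFG) == pytest.approx(expected, rel=1e-12)

    def test_outlier_ratio_day_dropped(self):
        n = 40 * 48
        t = np.full(n, 0.05)
        rng = np.random.default_rng(5)
        t *= np.repeat(1 + rng.normal(0, 0.005, 40), 48)
        t[:48] = 0.001            # day 1 GPP/T ratio far above mean + 3 sd
        series = make_series(n=n, GPP=10.0, T=t, SWin_pot=400.0, SWin=300.0)
        expected = (10.0 * 1800) / (0.05 * MMOL_PER_MM)
        assert wuet_site(series, CFG) == pytest.approx(expected, rel=1e-2)

    def test_no_transpiration_missing(self):
        series = make_series(n=96, GPP=10.0, SWin_pot=400.0, SWin=300.0)
        assert np.isnan(wuet_site(series, CFG))


class TestPnueAndTa:
    def test_pnue_arithmetic(self):
        assert pnue(30.0, 2.0, 5.0) == pytest.approx(3.0)

    def test_pnue_identity_scaling(self):
        assert pnue(7.5, 7.5, 1.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("wnarea,lai", [(0.0, 5.0), (2.0, 0.0), (np.nan, 5.0)])
    def test_pnue_guards(self, wnarea, lai):
        assert np.isnan(pnue(30.0, wnarea, lai))

    def test_mean_annual_temperature_average_of_years(self):
        n = 2 * 365 * 48
        idx_years = pd.date_range("2020-01-01", periods=n, freq="30min").year
        ta = np.where(idx_years == 2020, 10.0, 14.0)
        series = make_series(n=n, start="2020-01-01", Ta=ta, GPP=5.0)
        assert mean_annual_temperature(series, CFG) == pytest.approx(12.0)


def test_percentile_matches_sort_and_interpolate_oracle():
    rng = np.random.default_rng(17)
    for n in (5, 10, 37):
        x = rng.normal(size=n)
        for q in (0.90, 0.95):
            s = np.sort(x)
            pos = q * (n - 1)
            lo, frac = int(np.floor(pos)), pos - np.floor(pos)
            manual = s[lo] if lo == n - 1 else s[lo] * (1 - frac) + s[lo + 1] * frac
            assert np.percentile(x, 100 * q) == pytest.approx(manual, abs=1e-12)


def test_compute_efps_assembles_full_record(day_series):
    meta = SiteMeta(site_id="SYN-T", igbp="ENF", hc=12.0, lai_max=4.0, elevation=100.0)
    rec = compute_efps(day_series, meta, CFG,
                       community_traits={"wNmass": 2.0, "wLMA": 0.1, "wNarea": 2.0,
                                         "wLL": 12.0, "wSSD": 0.5})
    assert rec.site_id == "SYN-T"
    assert rec.EF == pytest.approx(0.5)
    assert rec.PNUE == pytest.approx(rec.GPPsat / (2.0 * 4.0), nan_ok=True)
    assert rec.wNmass == 2.0 and rec.IGBP == "ENF"
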