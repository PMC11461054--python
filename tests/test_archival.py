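"""Drift correction, daily profiles, MLD/SST estimation, QC and habitat
envelopes, each against constructed cases or generator ground truth."""

import numpy as np
import pandas as pd
import pytest

from psatkit import (
    REGIMES,
    DriftModel,
    TagScenario,
    build_daily_profile,
    build_envelopes,
    correct_depth,
    daily_profiles,
    estimate_mld,
    estimate_sst,
    fit_pressure_drift,
    generate_archival_series,
    qc_profile,
)
from psatkit.archival import DepthTempProfile

from conftest import make_series


class TestDriftFit:
    def test_zero_daily_minima_give_zero_polynomial(self):
        # five days, depth oscillating 0..6 m, minimum exactly 0 each day
        per_day = 1440
        pattern = 3.0 + 3.0 * np.sin(np.linspace(0, 8 * np.pi, per_day))
        pattern[0] = 0.0
        series = make_series(np.tile(pattern, 5))
        model = fit_pressure_drift(series)
        assert np.allclose(model.coeffs, 0.0, atol=1e-9)
        assert model.residual_rms == pytest.approx(0.0, abs=1e-9)

    def test_linear_daily_minima_recovered_exactly(self):
        # depth = 2 + 0.5 t (days): daily minimum lies on that line
        n = 6 * 1440
        t_days = np.arange(n) / 1440.0
        series = make_series(2.0 + 0.5 * t_days)
        model = fit_pressure_drift(series)
        tt = np.array([0.0, 1.5, 4.2])
        assert model(tt) == pytest.approx(2.0 + 0.5 * tt, abs=1e-8)
        assert model.residual_rms < 1e-9

    def test_recovers_injected_cubic_drift(self):
        scen = TagScenario(
            duration_days=100,
            regimes=(REGIMES["NOR"],),
            drift_coeffs=(0.02, -1e-4, 0.0),
            depth_noise_sd=0.0,
            temp_noise_sd=0.0,
            seed=13,
            sample_interval=60.0,
        )
        series, truth = generate_archival_series(scen)
        model = fit_pressure_drift(series)
        c1, c2, _ = truth.drift_coeffs
        assert model.coeffs[1] == pytest.approx(c1, rel=0.10)
        assert model.coeffs[2] == pytest.approx(c2, rel=0.10)

    def test_too_few_days_is_an_error(self):
        series = make_series(np.linspace(0, 5, 3 * 1440))
        with pytest.raises(ValueError, match="4 distinct days"):
            fit_pressure_drift(series)


class TestCorrectDepth:
    def test_zero_polynomial_is_identity(self):
        series = make_series(np.linspace(0, 50, 200))
        model = DriftModel((0.0, 0.0, 0.0, 0.0), 0.0)
        out = correct_depth(series, model)
        np.testing.assert_array_equal(out.depth_corrected, series.depth_raw)

    def test_constant_offset_subtracted(self):
        series = make_series(np.linspace(0, 50, 200))
        out = correct_depth(series, DriftModel((3.0, 0.0, 0.0, 0.0), 0.0))
        np.testing.assert_allclose(out.depth_corrected, series.depth_raw - 3.0)

    def test_roundtrip_restores_daily_minima(self, nor_corrected):
        """Fit-and-subtract recovers the true daily minimum (0 m, forced
        surfacing) within +/-0.2 m despite sensor noise."""
        series, truth, _ = nor_corrected
        daily_min = (
            pd.Series(series.depth_corrected, index=series.time.date)
            .groupby(level=0)
            .min()
        )
        assert daily_min.abs().max() <= 0.2


class TestDailyProfile:
    def test_isothermal_day(self):
        rng = np.random.default_rng(0)
        depth = rng.uniform(0, 100, 1440)
        series = make_series(depth, np.full(1440, 15.0))
        series = correct_depth(series, DriftModel((0, 0, 0, 0), 0.0))
        prof = build_daily_profile(series, series.time[0].date())
        assert np.allclose(prof.temp_grid, 15.0)
        assert np.all(np.diff(prof.depth_grid) == 1.0)

    def test_two_layer_column_node_value(self, sharp_thermocline_series):
        series, _ = sharp_thermocline_series
        prof = build_daily_profile(series, series.time.date[0])
        assert prof.temp_at(20.0) == pytest.approx(14.0, abs=0.2)

    def test_median_filter_removes_single_bin_spike(self):
        # uniform depth sweep; one 1 m bin 5 degC hotter than its neighbours
        depth = np.linspace(0, 100, 2000)
        temp = np.full(2000, 10.0)
        temp[(depth >= 49.5) & (depth < 50.5)] = 15.0
        series = make_series(depth, temp, interval_s=43.0)
        series = correct_depth(series, DriftModel((0, 0, 0, 0), 0.0))
        prof = build_daily_profile(series, series.time[0].date())
        assert prof.temp_at(50.0) == pytest.approx(10.0, abs=1e-9)

    def test_day_without_samples_is_an_error(self, sharp_thermocline_series):
        series, _ = sharp_thermocline_series
        from datetime import date

        with pytest.raises(ValueError, match="no samples"):
            build_daily_profile(series, date(1999, 1, 1))


class TestMld:
    @staticmethod
    def profile(depths, temps, dmin=None, dmax=None):
        depths = np.asarray(depths, float)
        return DepthTempProfile(
            tag_id="T",
            date=None,
            depth_grid=depths,
            temp_grid=np.asarray(temps, float),
            day_min_depth=depths.min() if dmin is None else dmin,
            day_max_depth=depths.max() if dmax is None else dmax,
            qc_pass=True,
        )

    def test_isothermal_profile_has_no_mld(self):
        prof = self.profile(np.arange(0, 101), np.full(101, 13.0))
        mld, t = estimate_mld(prof)
        assert mld is None and t is None
        assert prof.mld_reason == "no_threshold_crossing"

    def test_step_profile_forced_by_definition(self):
        depths = np.arange(0, 101)
        temps = np.where(depths < 40, 14.0, 13.7)
        mld, t = estimate_mld(self.profile(depths, temps))
        assert mld == 40.0
        assert t == pytest.approx(13.7)

    def test_missing_reference_node_flagged(self):
        prof = self.profile(np.arange(30, 101), np.linspace(14, 6, 71))
        mld, _ = estimate_mld(prof)
        assert mld is None
        assert prof.mld_reason == "no_reference_node"

    def test_recovery_on_two_layer_days(self, sharp_thermocline_series):
        """Median absolute recovery error against the injected 40 m
        mixed-layer base stays within 2 m across a 30-day record."""
        series, truth = sharp_thermocline_series
        prof = daily_profiles(series)
        err = (prof["mld_m"] - 40.0).abs().dropna()
        assert len(err) >= 25
        assert err.median() <= 2.0

    def test_equals_brute_force_scan(self, sharp_thermocline_series):
        series, _ = sharp_thermocline_series
        for d in series.dates()[:10]:
            prof = build_daily_profile(series, d)
            mld, _ = estimate_mld(prof)
            # brute force: first node >= 10 m colder than T(10) - 0.2
            t10 = prof.temp_at(10.0)
            brute = None
            for z, t in zip(prof.depth_grid, prof.temp_grid):
                if z >= 10.0 and t <= t10 - 0.2:
                    brute = z
                    break
            assert mld == brute


class TestSst:
    def test_constant_surface_swim(self):
        series = make_series(np.full(1440, 2.0), np.full(1440, 13.6))
        series = correct_depth(series, DriftModel((0, 0, 0, 0), 0.0))
        assert estimate_sst(series, series.time[0].date()) == pytest.approx(13.6)

    def test_median_of_mixed_surface_temps(self):
        temp = np.r_[np.full(720, 20.0), np.full(720, 21.0)]
        series = make_series(np.full(1440, 3.0), temp)
        series = correct_depth(series, DriftModel((0, 0, 0, 0), 0.0))
        assert estimate_sst(series, series.time[0].date()) == pytest.approx(20.5)

    def test_no_surface_samples_undefined(self):
        series = make_series(np.full(1440, 50.0), np.full(1440, 10.0))
        series = correct_depth(series, DriftModel((0, 0, 0, 0), 0.0))
        assert estimate_sst(series, series.time[0].date()) is None

    def test_warm_summer_mixed_layer_recovered(self):
        scen = TagScenario(duration_days=8, regimes=(REGIMES["Med"],), seed=3)
        series, _ = generate_archival_series(scen)
        series = correct_depth(series, fit_pressure_drift(series))
        ssts = daily_profiles(series)["sst_c"]
        assert ssts.notna().all()
        assert ssts.median() == pytest.approx(22.8, abs=0.1)


class TestQc:
    @pytest.mark.parametrize(
        "dmin,dmax,expected",
        [(0.0, 100.0, True), (30.0, 80.0, False), (2.0, 20.0, False)],
    )
    def test_rules(self, dmin, dmax, expected):
        prof = TestMld.profile(
            np.arange(int(dmin), int(dmax) + 1),
            np.full(int(dmax) - int(dmin) + 1, 12.0),
            dmin=dmin,
            dmax=dmax,
        )
        assert qc_profile(prof) is expected
        assert prof.qc_pass is expected


class TestEnvelopes:
    def test_single_sample_bin_placement(self):
        df = pd.DataFrame(
            {"depth_m": [3.1], "temp_c": [13.6], "hotspot": ["NOR"], "season": ["autumn"]}
        )
        (env,) = build_envelopes(df)
        row = env.table.iloc[0]
        assert (row["depth_bin"], row["temp_bin"], row["count"]) == (2.0, 13.5, 1)

    def test_counts_conserved(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "depth_m": rng.uniform(0, 300, 500),
                "temp_c": rng.uniform(5, 25, 500),
                "hotspot": rng.choice(["NOR", "NB"], 500),
                "season": rng.choice(["autumn", "winter"], 500),
            }
        )
        envs = build_envelopes(df)
        assert sum(e.n_samples for e in envs) == 500
        for e in envs:
            assert e.table["count"].sum() == e.n_samples

    def test_counts_invariant_under_batch_partition(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "depth_m": rng.uniform(0, 100, 400),
                "temp_c": rng.uniform(5, 20, 400),
                "hotspot": "NOR",
                "season": "autumn",
            }
        )
        (whole,) = build_envelopes(df)
        parts = [build_envelopes(chunk)[0].table for chunk in (df.iloc[:123], df.iloc[123:])]
        merged = (
            pd.concat(parts)
            .groupby(["depth_bin", "temp_bin"], as_index=False)["count"]
            .sum()
        )
        pd.testing.assert_frame_equal(
            whole.table.sort_values(["depth_bin", "temp_bin"]).reset_index(drop=True),
            merged.sort_values(["depth_bin", "temp_bin"]).reset_index(drop=True),
        )

    def test_nordic_autumn_mode_in_top_50m(self, nor_corrected):
        series, _, _ = nor_corrected
        df = pd.DataFrame(
            {
                "depth_m": series.depth_corrected,
                "temp_c": series.temp,
                "hotspot": "NOR",
                "season": "autumn",
            }
        )
        (env,) = build_envelopes(df)
        top50 = env.table[env.table["depth_bin"] < 50.0]["count"].sum()
        assert top50 / env.n_samples > 0.5
        mode_bin = env.table.loc[env.table["count"].idxmax(), "depth_bin"]
        assert mode_bin < 50.0
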