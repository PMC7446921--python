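"""Box-model dispersion chain against independently coded oracles."""

import numpy as np
import pandas as pd
import pytest

from shalehealth import dispersion as dp

from conftest import well_row, wells_at_distances


def make_weather(cloud, wind, year=2015):
    ts = pd.date_range(f"{year}-01-01", f"{year}-12-31 23:00", freq="h")
    n = len(ts)
    return pd.DataFrame(
        {
            "timestamp": ts,
            "cloud_cover": np.broadcast_to(cloud, n).copy(),
            "wind_speed_ms": np.broadcast_to(wind, n).copy(),
        }
    )


class TestUnitConversion:
    def test_zero_and_linearity(self):
        assert dp.tons_per_year_to_g_per_h(0.0) == 0.0
        x = 3.7
        assert dp.tons_per_year_to_g_per_h(2 * x) == pytest.approx(
            2 * dp.tons_per_year_to_g_per_h(x), rel=1e-12
        )

    def test_one_short_ton(self):
        # independent arithmetic: 907184.74 g over 8760 h
        assert dp.tons_per_year_to_g_per_h(1.0) == pytest.approx(907184.74 / 8760.0, rel=1e-12)
        assert dp.tons_per_year_to_g_per_h(1.0) == pytest.approx(103.560, abs=5e-4)

    def test_metric_switch(self):
        assert dp.tons_per_year_to_g_per_h(1.0, ton_g=dp.METRIC_TON_G) == pytest.approx(
            1e6 / 8760.0, rel=1e-12
        )

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            dp.tons_per_year_to_g_per_h(-1.0)


class TestStabilityClass:
    def test_stated_decision_table_examples(self):
        assert dp.stability_class(12, 0.1, 1.0) == "A"  # daytime strong insolation, light wind
        assert dp.stability_class(2, 3.0 / 8.0, 2.0) == "F"  # clear night, 2 m/s
        for hour in (3, 12):
            for cc in (0.0, 0.5, 1.0):
                assert dp.stability_class(hour, cc, 6.0) == "D"  # strong wind is neutral

    def test_total_and_deterministic_partition(self):
        hours = np.arange(24)
        cc = np.linspace(0, 1, 9)
        u = np.array([0.0, 1.9, 2.0, 2.9, 3.0, 4.9, 5.0, 5.9, 6.0, 12.0])
        H, C, U = np.meshgrid(hours, cc, u, indexing="ij")
        cls = dp.classify_hours(H.ravel(), C.ravel(), U.ravel())
        assert set(cls) <= set(dp.STABILITY_CLASSES)
        assert (cls != "").all()
        # deterministic: identical inputs map identically
        cls2 = dp.classify_hours(H.ravel(), C.ravel(), U.ravel())
        assert (cls == cls2).all()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            dp.stability_class(12, 1.5, 1.0)
        with pytest.raises(ValueError):
            dp.stability_class(12, 0.5, -1.0)


def oracle_concentration(q_g_per_h, u, cls, d_km):
    """Independent single-formula evaluation of the box-model kernel."""
    x = d_km * 1000.0
    sy_params, sz_params = dp.BRIGGS_OPEN_COUNTRY[cls]

    def sig(p):
        a, b, e = p
        return a * x if b == 0 else a * x * (1 + b * x) ** e

    q_ug_s = q_g_per_h * 1e6 / 3600.0
    return q_ug_s / (max(u, 0.5) * 2.0 * sig(sy_params) * sig(sz_params))


class TestHourlyConcentration:
    def test_zero_source(self):
        for d in (0.5, 1.0, 5.0):
            assert dp.hourly_concentration(0.0, 2.0, "D", d) == 0.0

    def test_wind_proportionality(self):
        c1 = dp.hourly_concentration(300.0, 1.0, "C", 2.0)
        c2 = dp.hourly_concentration(300.0, 2.0, "C", 2.0)
        assert c2 == pytest.approx(c1 / 2.0, rel=1e-12)

    def test_matches_formula_oracle_to_6_sig_digits(self):
        got = dp.hourly_concentration(300.0, 1.0, "F", 1.0)
        assert got == pytest.approx(oracle_concentration(300.0, 1.0, "F", 1.0), rel=1e-6)
        for cls in dp.STABILITY_CLASSES:
            for d in (0.5, 1.0, 2.0, 3.0, 5.0):
                for u in (0.2, 1.0, 4.0):
                    assert dp.hourly_concentration(120.0, u, cls, d) == pytest.approx(
                        oracle_concentration(120.0, u, cls, d), rel=1e-6
                    )

    def test_strictly_decreasing_in_distance(self):
        d = np.linspace(0.2, 5.0, 40)
        for cls in dp.STABILITY_CLASSES:
            c = np.array([dp.hourly_concentration(300.0, 2.0, cls, di) for di in d])
            assert np.all(np.diff(c) < 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            dp.hourly_concentration(300.0, 1.0, "D", 0.0)
        with pytest.raises(ValueError):
            dp.hourly_concentration(-1.0, 1.0, "D", 1.0)


class TestReferenceP90:
    def test_constant_weather_percentile(self):
        w = make_weather(0.1, 12.0)  # every hour class D at u=12
        table = dp.build_reference_p90(w)
        expected = dp.hourly_concentration(300.0, 12.0, "D", 1.0)
        assert table[(1.0, "NE")] == pytest.approx(expected, rel=1e-12)

    def test_nonincreasing_with_distance(self):
        rng = np.random.default_rng(5)
        w = make_weather(rng.uniform(0, 1, 8760), rng.gamma(2.0, 1.5, 8760))
        table = dp.build_reference_p90(w)
        for q in dp.QUADRANTS:
            vals = [table[(d, q)] for d in dp.DISTANCE_BINS_KM]
            assert np.all(np.diff(vals) <= 0)

    def test_two_regime_weather_bruteforce_percentile(self):
        # half the year calm clear nights (class F), half windy cloudy (D);
        # the sorted-series 90th percentile must come from the calm regime
        w = make_weather(0.0, 1.0)
        windy = np.arange(len(w)) % 2 == 1
        w.loc[windy, "wind_speed_ms"] = 9.0
        w.loc[windy, "cloud_cover"] = 0.9
        ts = pd.to_datetime(w["timestamp"])
        cls = dp.classify_hours(ts.dt.hour.to_numpy(), w["cloud_cover"].to_numpy(), w["wind_speed_ms"].to_numpy())
        table = dp.build_reference_p90(w)
        for d in dp.DISTANCE_BINS_KM:
            series = np.sort(dp.hourly_concentration(300.0, w["wind_speed_ms"].to_numpy(), cls, d))
            n = len(series)
            # linear-interpolation percentile oracle by direct order statistics
            h = 0.9 * (n - 1)
            lo, hi = int(np.floor(h)), int(np.ceil(h))
            expected = series[lo] + (h - lo) * (series[hi] - series[lo])
            assert table[(d, "SW")] == pytest.approx(expected, rel=1e-12)

    def test_empty_weather_rejected(self):
        with pytest.raises(ValueError):
            dp.build_reference_p90(make_weather(0.5, 2.0).iloc[:0])


class TestWellScaling:
    def test_total_rate(self):
        w = well_row("w", 40, -80, co=0, nox=0, pm25=0, voc=0)
        assert dp.well_total_emission_rate(w) == 0.0
        w = well_row("w", 40, -80)  # 1 ton/yr of each pollutant
        assert dp.well_total_emission_rate(w) == pytest.approx(4 * 907184.74 / 8760.0, rel=1e-12)
        assert dp.well_total_emission_rate(w) == pytest.approx(414.24, abs=5e-3)

    def test_methane_column_ignored(self):
        w = dict(well_row("w", 40, -80), methane_tpy=1000.0, co2_tpy=500.0)
        assert dp.well_total_emission_rate(w) == pytest.approx(4 * 907184.74 / 8760.0, rel=1e-12)

    def test_reference_identity_and_scaling(self, home):
        w = make_weather(0.2, 3.0)
        p90 = dp.build_reference_p90(w)
        # a well emitting exactly 300 g/h: tons/year = 300*8760/907184.74
        tpy = 300.0 * 8760.0 / 907184.74
        wells = wells_at_distances(home, [2.0], co=tpy, nox=0, pm25=0, voc=0)
        well = wells.iloc[0]
        got = dp.well_aec_contribution(well, home, p90)
        assert got == pytest.approx(p90[(2.0, "NE")], rel=1e-12)
        wells2x = wells_at_distances(home, [2.0], co=2 * tpy, nox=0, pm25=0, voc=0)
        assert dp.well_aec_contribution(wells2x.iloc[0], home, p90) == pytest.approx(2 * got, rel=1e-12)
        zero = wells_at_distances(home, [2.0], co=0, nox=0, pm25=0, voc=0)
        assert dp.well_aec_contribution(zero.iloc[0], home, p90) == 0.0

    def test_out_of_range_well_rejected(self, home):
        p90 = dp.build_reference_p90(make_weather(0.2, 3.0))
        far = wells_at_distances(home, [6.0]).iloc[0]
        with pytest.raises(ValueError):
            dp.well_aec_contribution(far, home, p90)


class TestResidenceAec:
    @pytest.fixture
    def p90(self):
        return dp.build_reference_p90(make_weather(0.3, 2.5))

    def test_no_wells(self, home, p90):
        none = wells_at_distances(home, [7.0])
        assert dp.residence_aec(home, none, p90) == 0.0

    def test_colocated_additivity(self, home, p90):
        one = wells_at_distances(home, [1.5])
        two = pd.concat([one, one], ignore_index=True)
        assert dp.residence_aec(home, two, p90) == pytest.approx(
            2 * dp.residence_aec(home, one, p90), rel=1e-12
        )

    def test_bruteforce_sum_oracle(self, home, p90, random_wells):
        from shalehealth import geo

        sub = geo.wells_within_radius(home, random_wells, 5.0)
        brute = sum(dp.well_aec_contribution(r, home, p90) for _, r in sub.iterrows())
        assert dp.residence_aec(home, random_wells, p90) == pytest.approx(brute, rel=1e-12)

    def test_linearity_in_emissions(self, home, p90, random_wells):
        scaled = random_wells.copy()
        for c in dp.POLLUTANT_COLUMNS:
            scaled[c] = 3.0 * scaled[c]
        assert dp.residence_aec(home, scaled, p90) == pytest.approx(
            3.0 * dp.residence_aec(home, random_wells, p90), rel=1e-12
        )

    def test_nonincreasing_when_well_moved_farther(self, home, p90):
        near = wells_at_distances(home, [0.9])
        far = wells_at_distances(home, [2.9])
        assert dp.residence_aec(home, far, p90) <= dp.residence_aec(home, near, p90)
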