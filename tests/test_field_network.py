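"""Trial-network stage: water input, envelope, classes and tolerance."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from phenosel.field_network import (
    EnvelopeFit,
    classify_environments,
    critical_period_rainfall,
    delta_y_slope,
    environment_summaries,
    fit_envelope,
    validate_trait,
    water_input,
    window_rainfall,
    yield_dsi,
)
from phenosel.synthetic_data import FieldSimConfig, simulate_field_network
from phenosel.tolerance_stats import dsi


def months_frame(pairs):
    return pd.DataFrame(pairs, columns=["month", "rainfall_mm"])


class TestRainfallWindows:
    def test_uniform_months_sum_exactly(self):
        rain = months_frame([(f"2020-{m:02d}", 100.0) for m in range(1, 7)])
        got = water_input(rain, sowing_date=dt.date(2020, 3, 1),
                          maturity_date=dt.date(2020, 5, 31))
        # window = Jan 1 .. May 31 -> five full months
        assert got == pytest.approx(500.0, rel=1e-12)

    def test_partial_month_pro_rated(self):
        rain = months_frame([("2020-04", 60.0)])
        got = window_rainfall(rain, dt.date(2020, 4, 16), dt.date(2020, 5, 1))
        assert got == pytest.approx(60.0 * 15 / 30, rel=1e-12)

    def test_zero_rainfall(self):
        rain = months_frame([(f"2020-{m:02d}", 0.0) for m in range(1, 7)])
        assert water_input(rain, dt.date(2020, 3, 1), dt.date(2020, 5, 31)) == 0.0

    def test_gap_error_names_month(self):
        rain = months_frame([("2020-01", 50.0), ("2020-03", 50.0)])
        with pytest.raises(ValueError, match="2020-02"):
            window_rainfall(rain, dt.date(2020, 1, 1), dt.date(2020, 4, 1))

    def test_critical_window_covers_two_months(self):
        rain = months_frame([(f"2021-{m:02d}", 100.0) for m in range(1, 7)])
        got = critical_period_rainfall(rain, maturity_date=dt.date(2021, 6, 1))
        # window [Mar 1, May 1): March + April
        assert got == pytest.approx(200.0, rel=1e-12)

    def test_rain_outside_critical_window_ignored(self):
        rain = months_frame([("2021-01", 300.0), ("2021-03", 0.0),
                             ("2021-04", 0.0), ("2021-05", 120.0)])
        assert critical_period_rainfall(rain, dt.date(2021, 6, 1)) == 0.0

    def test_pro_rating_matches_daily_resolution_oracle(self):
        rain = months_frame([("2021-02", 56.0), ("2021-03", 93.0), ("2021-04", 30.0)])
        start, end = dt.date(2021, 2, 10), dt.date(2021, 4, 21)
        got = window_rainfall(rain, start, end)
        # daily oracle: spread each month total uniformly over its days
        total = 0.0
        day = start
        rates = {"2021-02": 56.0 / 28, "2021-03": 93.0 / 31, "2021-04": 30.0 / 30}
        while day < end:
            total += rates[f"{day.year}-{day.month:02d}"]
            day += dt.timedelta(days=1)
        assert got == pytest.approx(total, rel=1e-9)


class TestEnvelope:
    def test_on_curve_points_recover_parameters(self):
        cfg = FieldSimConfig(seed=3, deviation_max_frac=0.0, on_curve_frac=1.0,
                             n_non_water_limited=1, yield_noise_sd=0.0,
                             n_environments=40)
        ds, truth = simulate_field_network(cfg)
        pts = environment_summaries(ds)
        wl = truth.environments["water_limited"].to_numpy()
        fit = fit_envelope(pts[wl])
        assert fit.a == pytest.approx(cfg.envelope_a, rel=0.02)
        assert fit.b == pytest.approx(cfg.envelope_b, rel=0.1)
        assert fit.c == pytest.approx(cfg.envelope_c, abs=20.0)
        assert fit.fraction_below == 1.0

    def test_zero_yield_at_minimum_water_input(self):
        fit = EnvelopeFit(a=5500.0, b=-0.004, c=150.0, fraction_below=1.0, n=80)
        assert fit.predict(150.0) == pytest.approx(0.0, abs=1e-9)
        assert fit.predict(1e9) == pytest.approx(5500.0)

    def test_generative_recovery_with_shortfalls(self):
        ds, truth = simulate_field_network(FieldSimConfig(seed=9))
        pts = environment_summaries(ds)
        fit = fit_envelope(pts)
        assert abs(fit.a - truth.config.envelope_a) / truth.config.envelope_a < 0.10
        assert fit.fraction_below >= 0.95
        # independent recount of the on-or-below fraction (points within
        # 0.1% of the yield scale count as on the curve)
        pred = fit.predict(pts["water_input"].to_numpy())
        yv = pts["mean_yield"].to_numpy()
        recount = np.mean(yv <= pred + 1e-3 * np.abs(yv).max())
        assert recount == pytest.approx(fit.fraction_below, abs=1e-9)

    def test_trace_fraction_weakly_increasing_in_weight(self):
        ds, _ = simulate_field_network(FieldSimConfig(seed=9))
        fit = fit_envelope(environment_summaries(ds))
        trace = sorted(fit.trace)
        fracs = [f for _, f in trace]
        assert all(b >= a - 1e-9 for a, b in zip(fracs, fracs[1:]))

    def test_degenerate_inputs_rejected(self):
        pts = pd.DataFrame({"water_input": [500.0] * 12,
                            "mean_yield": np.linspace(1000, 4000, 12)})
        with pytest.raises(ValueError, match="degenerate"):
            fit_envelope(pts)
        with pytest.raises(ValueError, match=">= 10"):
            fit_envelope(pts.head(5))


def summary_frame(water, yields, crit):
    return pd.DataFrame({
        "environment_id": [f"E{i}" for i in range(len(water))],
        "water_input": water, "critical_rainfall": crit,
        "mean_yield": yields, "n_genotypes": 4})


class TestClassification:
    FIT = EnvelopeFit(a=5000.0, b=-0.004, c=100.0, fraction_below=0.95, n=20)

    def test_band_is_closed_at_both_ends(self):
        pred = float(self.FIT.predict(600.0))
        summaries = summary_frame(
            [600.0] * 4, [pred, 0.80 * pred, 0.79 * pred, 1.20 * pred],
            [100.0] * 4)
        out = classify_environments(summaries, self.FIT)
        assert list(out["water_limited"]) == [True, True, False, True]
        assert out.loc[2, "moisture_class"] == "excluded"

    def test_moisture_thresholds(self):
        pred = float(self.FIT.predict(600.0))
        summaries = summary_frame(
            [600.0] * 4, [pred] * 4, [174.9, 175.0, 349.9, 350.0])
        out = classify_environments(summaries, self.FIT)
        assert list(out["moisture_class"]) == ["dry", "intermediate",
                                               "intermediate", "wet"]

    def test_partition_complete_and_matches_recount(self):
        ds, _ = simulate_field_network(FieldSimConfig(seed=5, n_environments=20))
        pts = environment_summaries(ds)
        fit = fit_envelope(pts)
        out = classify_environments(pts, fit, band=0.20, dry_mm=175.0)
        assert set(out["moisture_class"]) <= {"dry", "intermediate", "wet", "excluded"}
        # brute-force reclassification
        expected = []
        for r in out.itertuples(index=False):
            pred = fit.a * (1 - np.exp(fit.b * (r.water_input - fit.c)))
            if not (0.8 * pred <= r.mean_yield <= 1.2 * pred):
                expected.append("excluded")
            elif r.critical_rainfall < 175.0:
                expected.append("dry")
            elif r.critical_rainfall >= 350.0:
                expected.append("wet")
            else:
                expected.append("intermediate")
        assert list(out["moisture_class"]) == expected

    def test_idempotent(self):
        ds, _ = simulate_field_network(FieldSimConfig(seed=5, n_environments=20))
        pts = environment_summaries(ds)
        fit = fit_envelope(pts)
        once = classify_environments(pts, fit)
        twice = classify_environments(once, fit)
        assert list(once["moisture_class"]) == list(twice["moisture_class"])


def trials_frame(rows):
    return pd.DataFrame(rows, columns=["environment_id", "genotype", "yield_kg_ha",
                                       "sowing_date", "emergence_date",
                                       "maturity_date"])


class TestYieldDsi:
    def classes(self):
        return pd.DataFrame({
            "environment_id": ["D1", "W1"],
            "moisture_class": ["dry", "wet"],
        })

    def test_hand_ratios(self):
        rows = [("D1", "A", 600.0, "", "", ""), ("W1", "A", 1000.0, "", "", ""),
                ("D1", "B", 800.0, "", "", ""), ("W1", "B", 1000.0, "", "", "")]
        table, _ = yield_dsi(trials_frame(rows), self.classes())
        got = table.set_index("genotype")["dsi_yield"]
        assert got["A"] == pytest.approx(4 / 3, rel=1e-12)
        assert got["B"] == pytest.approx(2 / 3, rel=1e-12)

    def test_average_genotype_has_dsi_one(self):
        rows = [("D1", "A", 700.0, "", "", ""), ("W1", "A", 1000.0, "", "", ""),
                ("D1", "B", 700.0, "", "", ""), ("W1", "B", 1000.0, "", "", "")]
        table, _ = yield_dsi(trials_frame(rows), self.classes())
        assert np.allclose(table["dsi_yield"], 1.0)

    def test_dry_advantage_gives_negative_dsi(self):
        rows = [("D1", "A", 1100.0, "", "", ""), ("W1", "A", 1000.0, "", "", ""),
                ("D1", "B", 600.0, "", "", ""), ("W1", "B", 1000.0, "", "", "")]
        table, _ = yield_dsi(trials_frame(rows), self.classes())
        assert table.set_index("genotype")["dsi_yield"]["A"] < 0

    def test_shares_implementation_with_trait_dsi(self):
        rows = [("D1", "A", 620.0, "", "", ""), ("W1", "A", 980.0, "", "", ""),
                ("D1", "B", 700.0, "", "", ""), ("W1", "B", 1040.0, "", "", "")]
        table, _ = yield_dsi(trials_frame(rows), self.classes())
        x_wd, x_ww = (620 + 700) / 2, (980 + 1040) / 2
        for r in table.itertuples(index=False):
            assert r.dsi_yield == pytest.approx(
                dsi(r.mean_yield_wet, r.mean_yield_dry, x_ww, x_wd), rel=1e-12)

    def test_missing_class_coverage_excluded(self):
        rows = [("D1", "A", 600.0, "", "", ""), ("W1", "A", 1000.0, "", "", ""),
                ("D1", "B", 800.0, "", "", "")]
        table, diags = yield_dsi(trials_frame(rows), self.classes())
        assert list(table["genotype"]) == ["A"]
        assert any("B" in m for m in diags["message"])


class TestDeltaYSlope:
    def summaries(self, water):
        return pd.DataFrame({
            "environment_id": [f"E{i}" for i in range(len(water))],
            "water_input": water,
            "mean_yield": [1000.0] * len(water)})

    def test_on_mean_genotype_has_zero_slope(self):
        water = [300.0, 600.0, 900.0]
        rows = [(f"E{i}", "A", 1000.0, "", "", "") for i in range(3)]
        table, _ = delta_y_slope(trials_frame(rows), self.summaries(water))
        assert table["delta_y_slope"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_constructed_slope_recovered(self):
        water = [300.0, 500.0, 700.0, 900.0]
        rows = [(f"E{i}", "A", 1000.0 + 0.5 * (w - 600.0), "", "", "")
                for i, w in enumerate(water)]
        table, _ = delta_y_slope(trials_frame(rows), self.summaries(water))
        assert table["delta_y_slope"].iloc[0] == pytest.approx(0.5, rel=1e-9)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(4)
        water = rng.uniform(300, 1200, 8)
        dy = rng.normal(0, 50, 8)
        rows = [(f"E{i}", "A", 1000.0 + dy[i], "", "", "") for i in range(8)]
        table, _ = delta_y_slope(trials_frame(rows), self.summaries(water))
        expected = np.cov(dy, water, ddof=1)[0, 1] / np.var(water, ddof=1)
        assert table["delta_y_slope"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_too_few_environments_absent(self):
        water = [300.0, 600.0]
        rows = [(f"E{i}", "A", 1000.0, "", "", "") for i in range(2)]
        table, diags = delta_y_slope(trials_frame(rows), self.summaries(water))
        assert len(table) == 0 and len(diags) == 1


class TestValidateTrait:
    def test_perfect_anticorrelation(self):
        te = pd.Series([3.5, 3.6, 3.7, 3.8], index=list("ABCD"))
        tol = pd.Series([2.0, 1.5, 1.0, 0.5], index=list("ABCD"))
        r2, p, slope = validate_trait(te, tol)
        assert r2 == pytest.approx(1.0, rel=1e-9)
        assert slope < 0

    def test_r2_is_squared_pearson(self):
        rng = np.random.default_rng(6)
        idx = [f"G{i}" for i in range(7)]
        te = pd.Series(rng.normal(3.7, 0.2, 7), index=idx)
        tol = pd.Series(2 - 0.5 * te.to_numpy() + rng.normal(0, 0.1, 7), index=idx)
        r2, _, _ = validate_trait(te, tol)
        assert r2 == pytest.approx(np.corrcoef(te, tol)[0, 1] ** 2, rel=1e-10)


def test_dsi_and_slope_rankings_agree(platform_sim):
    """Built-in genotype sensitivity must make the two field tolerance
    estimates rank genotypes consistently."""
    from scipy.stats import spearmanr

    from phenosel.pipeline import run_field_analysis

    ds, truth = simulate_field_network(FieldSimConfig(seed=23))
    res = run_field_analysis(ds)
    tol = res["tolerance"].dropna(subset=["dsi_yield", "delta_y_slope"])
    rho = spearmanr(tol["dsi_yield"], tol["delta_y_slope"]).statistic
    assert rho > 0
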