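"""DSI and variance-component / repeatability estimators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenosel.tolerance_stats import (
    VarianceComponents,
    _reml_mixedlm,
    dsi,
    dsi_table,
    repeatability,
    repeatability_table,
    variance_components,
)


class TestDsiScalar:
    def test_average_susceptibility_is_one(self):
        assert dsi(10, 7, 10, 7) == pytest.approx(1.0, rel=1e-12)

    def test_hand_value(self):
        assert dsi(10, 6, 10, 8) == pytest.approx(2.0, rel=1e-12)

    def test_unaffected_genotype_is_zero(self):
        assert dsi(10, 10, 10, 8) == 0.0

    def test_population_unaffected_is_undefined(self):
        with pytest.raises(ValueError):
            dsi(10, 6, 10, 10)

    @given(scale=st.floats(0.01, 1e4),
           y_wd=st.floats(0.1, 9.9), x_wd=st.floats(0.1, 9.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, scale, y_wd, x_wd):
        base = dsi(10.0, y_wd, 10.0, x_wd)
        scaled = dsi(10.0 * scale, y_wd * scale, 10.0 * scale, x_wd * scale)
        assert scaled == pytest.approx(base, rel=1e-9)


def make_obs(ratios, ww=10.0, reps=2):
    rows = []
    for geno, ratio in ratios.items():
        for rep in range(1, reps + 1):
            rows.append(("T", 57, "WW", geno, rep, ww))
            rows.append(("T", 57, "WD", geno, rep, ww * ratio))
    return pd.DataFrame(rows, columns=["trait", "dae", "treatment",
                                       "genotype", "replicate", "value"])


class TestDsiTable:
    def test_homogeneous_population_all_one(self):
        table, _ = dsi_table(make_obs({"A": 0.7, "B": 0.7, "C": 0.7}), "T", 57)
        assert np.allclose(table["dsi"], 1.0)

    def test_hand_ratios(self):
        table, _ = dsi_table(make_obs({"A": 0.5, "B": 0.7, "C": 0.9}), "T", 57)
        got = table.set_index("genotype")["dsi"]
        assert got["A"] == pytest.approx(5 / 3, rel=1e-12)
        assert got["B"] == pytest.approx(1.0, rel=1e-12)
        assert got["C"] == pytest.approx(1 / 3, rel=1e-12)

    def test_genotype_missing_treatment_excluded_with_diagnostic(self):
        obs = make_obs({"A": 0.5, "B": 0.7, "C": 0.9})
        obs = obs[~((obs.genotype == "C") & (obs.treatment == "WD"))]
        table, diags = dsi_table(obs, "T", 57)
        assert set(table["genotype"]) == {"A", "B"}
        assert any("C" in m for m in diags["message"])
        # X means recomputed over the two complete genotypes only
        assert table["x_wd"].iloc[0] == pytest.approx(10 * 0.6)

    def test_numerator_mean_normalizes_to_denominator(self):
        """Unweighted mean of genotype reductions equals the population
        reduction when X is the mean of genotype means."""
        rng = np.random.default_rng(2)
        ratios = {f"G{i}": r for i, r in enumerate(rng.uniform(0.4, 0.95, 9))}
        table, _ = dsi_table(make_obs(ratios), "T", 57)
        num = (1 - table["y_wd"] / table["y_ww"]).mean()
        den = 1 - table["x_wd"].iloc[0] / table["x_ww"].iloc[0]
        assert num == pytest.approx(den, rel=1e-12)
        assert table["dsi"].mean() == pytest.approx(1.0, rel=1e-12)

    def test_matches_spreadsheet_style_recomputation(self):
        """Seven simulated genotypes against an independent cell-by-cell
        recomputation of genotype means, population means and the index."""
        rng = np.random.default_rng(42)
        rows = []
        for i in range(7):
            for trt, level in (("WW", 10 + i), ("WD", (10 + i) * (0.5 + 0.05 * i))):
                for rep in range(1, 5):
                    rows.append(("SDW", 57, trt, f"G{i}", rep,
                                 level + rng.normal(0, 0.3)))
        obs = pd.DataFrame(rows, columns=["trait", "dae", "treatment",
                                          "genotype", "replicate", "value"])
        table, _ = dsi_table(obs, "SDW", 57)

        # spreadsheet route: pivot means, then the formula cell by cell
        pivot = obs.pivot_table(index="genotype", columns="treatment",
                                values="value", aggfunc="mean")
        x_ww, x_wd = pivot["WW"].mean(), pivot["WD"].mean()
        expected = (1 - pivot["WD"] / pivot["WW"]) / (1 - x_wd / x_ww)
        got = table.set_index("genotype")["dsi"]
        assert np.allclose(got.sort_index(), expected.sort_index(), rtol=1e-12)


def balanced_one_way(rng, g=10, r=8, sg2=2.0, se2=1.0):
    geno = np.repeat([f"g{i:02d}" for i in range(g)], r)
    vals = (np.repeat(rng.normal(0, np.sqrt(sg2), g), r)
            + rng.normal(0, np.sqrt(se2), g * r))
    return pd.DataFrame({"genotype": geno, "value": vals})


def balanced_two_way(rng, g=6, t=3, r=4, sg2=2.0, sge2=0.5, se2=1.0):
    rows = []
    for i in range(g):
        gi = rng.normal(0, np.sqrt(sg2))
        for j in range(t):
            ge = rng.normal(0, np.sqrt(sge2))
            for k in range(r):
                rows.append((f"g{i}", f"e{j}", gi + ge + rng.normal(0, np.sqrt(se2))))
    return pd.DataFrame(rows, columns=["genotype", "environment", "value"])


class TestVarianceComponents:
    def test_constant_data_has_zero_components(self):
        df = pd.DataFrame({"genotype": list("AABB"), "value": [3.0] * 4})
        comp = variance_components(df, "one_way")
        assert comp.sigma2_g == comp.sigma2_e == 0.0

    def test_one_way_matches_manual_anova(self):
        df = pd.DataFrame({
            "genotype": ["A", "A", "B", "B", "C", "C"],
            "value": [1.0, 3.0, 4.0, 6.0, 8.0, 10.0]})
        comp = variance_components(df, "one_way")
        # manual: genotype means 2,5,9; grand 16/3; MSG=2*var; MSE=2 within each
        msg = 2 * ((2 - 16 / 3) ** 2 + (5 - 16 / 3) ** 2 + (9 - 16 / 3) ** 2) / 2
        mse = (2 * 3 * 1.0) / 3  # each pair deviates +-1 -> SS=2 per genotype
        assert comp.sigma2_e == pytest.approx(mse, rel=1e-12)
        assert comp.sigma2_g == pytest.approx((msg - mse) / 2, rel=1e-12)

    def test_negative_estimates_truncate_with_flag(self):
        rng = np.random.default_rng(0)
        df = balanced_one_way(rng, g=4, r=3, sg2=0.0, se2=5.0)
        comp = variance_components(df, "one_way")
        assert comp.sigma2_g >= 0.0
        # with zero true genotype variance truncation happens often; flag
        # must be consistent with the returned value
        assert comp.truncated == (comp.sigma2_g == 0.0)

    @pytest.mark.parametrize("maker,model", [
        (balanced_one_way, "one_way"), (balanced_two_way, "two_way")])
    def test_balanced_ems_equals_reml(self, maker, model):
        rng = np.random.default_rng(8)
        for _ in range(3):
            df = maker(rng)
            ems = variance_components(df, model)
            if ems.truncated:
                continue
            reml = _reml_mixedlm(df, model)
            assert ems.sigma2_g == pytest.approx(reml.sigma2_g, rel=2e-3, abs=1e-4)
            assert ems.sigma2_e == pytest.approx(reml.sigma2_e, rel=2e-3, abs=1e-4)
            if model == "two_way":
                assert ems.sigma2_ge == pytest.approx(reml.sigma2_ge,
                                                      rel=5e-3, abs=1e-3)

    def test_unbalanced_falls_back_to_reml(self):
        rng = np.random.default_rng(9)
        df = balanced_one_way(rng, g=8, r=6, sg2=3.0, se2=1.0).iloc[:-2]
        comp = variance_components(df, "one_way")
        assert comp.sigma2_g > 0

    def test_insufficient_structure_rejected(self):
        df = pd.DataFrame({"genotype": ["A", "A", "A"], "value": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="genotypes"):
            variance_components(df, "one_way")


class TestRepeatability:
    def test_hand_value(self):
        comp = VarianceComponents(1.0, 1.0, None, 4, None)
        assert repeatability(comp).w2 == pytest.approx(0.8, rel=1e-12)

    def test_limits(self):
        assert repeatability(VarianceComponents(0.0, 1.0, None, 4, None)).w2 == 0.0
        assert repeatability(VarianceComponents(2.0, 0.0, None, 4, None)).w2 == 1.0
        multi = VarianceComponents(2.0, 0.0, 0.0, 4, 2)
        assert repeatability(multi, "multi_env").w2 == 1.0

    def test_multi_env_formula(self):
        comp = VarianceComponents(2.0, 1.0, 0.5, 4, 2)
        expected = 2.0 / (2.0 + 1.0 / 8 + 0.5 / 2)
        assert repeatability(comp, "multi_env").w2 == pytest.approx(expected, rel=1e-12)

    @given(r=st.integers(2, 30), t=st.integers(2, 6))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_replication_and_environments(self, r, t):
        base = repeatability(VarianceComponents(1.0, 2.0, 0.5, r, t), "multi_env").w2
        more_r = repeatability(VarianceComponents(1.0, 2.0, 0.5, r + 1, t), "multi_env").w2
        more_t = repeatability(VarianceComponents(1.0, 2.0, 0.5, r, t + 1), "multi_env").w2
        assert more_r >= base and more_t >= base
        assert 0.0 <= base <= 1.0


def test_repeatability_table_switches_scope_at_onset(platform_sim):
    dataset, truth = platform_sim
    from phenosel.pipeline import extract_traits

    traits = extract_traits(dataset, fresh_weights=truth.fresh_weights)
    table = repeatability_table(traits, dataset.treatment_onset_dae)
    te = table[table["trait"] == "TE"].set_index("dae")
    assert te.loc[13, "scope"] == "single_env"
    assert te.loc[57, "scope"] == "multi_env"
    assert ((table["w2"].dropna() >= 0) & (table["w2"].dropna() <= 1)).all()
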