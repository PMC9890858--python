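"""Balanced ANOVA, variance components, heritability and correlations."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rootarch.stats import (
    AnovaTable,
    VarComponents,
    anova_cube,
    anova_ge,
    correlation_matrix,
    heritability,
    heritability_general,
    significance_stars,
    trait_summary,
    variance_components,
)
from rootarch.synthetic import SimulationConfig, generate_trait_dataset


def _long_from_cube(y: np.ndarray) -> pd.DataFrame:
    n_g, n_e, n_r = y.shape
    rows = []
    for g in range(n_g):
        for e, env in zip(range(n_e), ["HP", "LP"]):
            for r in range(n_r):
                rows.append((f"G{g:03d}", env, r + 1, y[g, e, r]))
    return pd.DataFrame(rows, columns=["genotype", "environment",
                                       "replication", "value"])


def _null_config(n_g: int, seed: int) -> SimulationConfig:
    """All systematic effects zero; the three-way term plays iid noise."""
    return SimulationConfig(n_genotypes=n_g, sigma_g=0.0, sigma_ge=0.0,
                            sigma_gr=0.0, sigma_ger=1.0,
                            type_separation=0.0, seed=seed)


class TestAnova:
    def test_sums_of_squares_match_statsmodels(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(42)
        y = rng.normal(size=(4, 2, 2))
        table = _long_from_cube(y)
        ours = anova_cube(y)

        fit = ols("value ~ C(genotype) * C(environment) * C(replication)",
                  data=table).fit()
        ref = sm.stats.anova_lm(fit, typ=1)
        pairs = {
            "G": "C(genotype)", "E": "C(environment)", "R": "C(replication)",
            "G:E": "C(genotype):C(environment)",
            "G:R": "C(genotype):C(replication)",
            "E:R": "C(environment):C(replication)",
            "G:E:R": "C(genotype):C(environment):C(replication)",
        }
        for eff, name in pairs.items():
            assert ours.loc[eff, "ss"] == pytest.approx(
                ref.loc[name, "sum_sq"], rel=1e-8), eff
            assert ours.loc[eff, "df"] == ref.loc[name, "df"], eff

    def test_total_ss_conserved(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            y = rng.normal(size=(10, 2, 2)) * rng.uniform(0.1, 30)
            t = anova_cube(y)
            total = ((y - y.mean()) ** 2).sum()
            assert t["ss"].sum() == pytest.approx(total, rel=1e-8)

    def test_df_sum_to_n_minus_1(self):
        t = anova_cube(np.random.default_rng(0).normal(size=(13, 2, 2)))
        assert t["df"].sum() == 13 * 2 * 2 - 1

    def test_constant_shift_of_lp_only_changes_e(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(20, 2, 2))
        base = anova_cube(y)
        shifted = y.copy()
        shifted[:, 1, :] += 5.0           # add delta to every LP value
        after = anova_cube(shifted)
        assert after.loc["E", "ss"] != pytest.approx(base.loc["E", "ss"])
        for eff in ["G", "R", "G:E", "G:R", "E:R", "G:E:R"]:
            assert after.loc[eff, "ss"] == pytest.approx(
                base.loc[eff, "ss"], abs=1e-9), eff

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(12)
        p_g = [anova_cube(rng.normal(size=(20, 2, 2))).loc["G", "p"]
               for _ in range(300)]
        assert sps.kstest(p_g, "uniform").pvalue > 0.01

    def test_unbalanced_design_lists_missing_cells(self):
        table = _long_from_cube(np.zeros((3, 2, 2)))
        table = table[~((table.genotype == "G001")
                        & (table.environment == "LP")
                        & (table.replication == 2))]
        with pytest.raises(ValueError, match="G001"):
            anova_ge(table)

    def test_long_table_path_equals_cube_path(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(6, 2, 2))
        a = anova_ge(_long_from_cube(y))
        b = anova_cube(y)
        pd.testing.assert_frame_equal(a.table, b)


class TestVarianceComponents:
    def test_identical_observations_give_zero_components(self):
        an = anova_ge(_long_from_cube(np.full((5, 2, 2), 3.7)))
        vc = variance_components(an)
        for val in (vc.sigma_g, vc.sigma_ge, vc.sigma_gr, vc.sigma_ger):
            assert val == pytest.approx(0.0, abs=1e-12)

    def test_negative_solution_truncated_and_flagged(self):
        # craft mean squares with MS_G < expectation under its own terms
        df = pd.DataFrame(
            {"df": [1, 4, 1, 4, 4, 1, 4],
             "ss": [1, 0.4, 1, 8, 8, 1, 8],
             "ms": [1.0, 0.1, 1.0, 2.0, 2.0, 1.0, 2.0],
             "F": np.nan, "p": np.nan},
            index=["E", "G", "R", "G:E", "G:R", "E:R", "G:E:R"])
        vc = variance_components(AnovaTable(table=df, n_G=5, n_E=2, n_R=2))
        assert vc.sigma_g == 0.0
        assert "sigma_g" in vc.truncated
        assert vc.sigma_ger == 2.0

    def test_component_recovery_within_10pct(self):
        truth = dict(sigma_g=1.0, sigma_ge=0.25, sigma_gr=0.25, sigma_ger=0.25)
        est = {k: [] for k in truth}
        for seed in range(100):
            cfg = SimulationConfig(n_genotypes=200, type_separation=0.0,
                                   seed=seed, **truth)
            table, _ = generate_trait_dataset(cfg)
            vc = variance_components(anova_ge(table))
            for k in truth:
                est[k].append(getattr(vc, k))
        for k, v in truth.items():
            assert np.mean(est[k]) == pytest.approx(v, rel=0.10), k


class TestHeritability:
    @pytest.mark.parametrize("components,expected", [
        ((2.0, 1.0, 1.0, 4.0), 0.5),
        ((1.0, 0.0, 0.0, 0.0), 1.0),
        ((1.0, 1.0, 1.0, 1.0), 1.0 / 2.25),
    ])
    def test_printed_formula_arithmetic(self, components, expected):
        vc = VarComponents(*components)
        assert heritability(vc) == pytest.approx(expected, rel=1e-12)

    def test_all_zero_components_undefined(self):
        assert math.isnan(heritability(VarComponents(0, 0, 0, 0)))

    def test_bounded_and_monotone(self):
        rng = np.random.default_rng(8)
        prev = None
        for sg in np.linspace(0.1, 5, 12):
            h = heritability(VarComponents(sg, 0.5, 0.5, 0.5))
            assert 0.0 <= h <= 1.0
            if prev is not None:
                assert h > prev          # increasing in genotype variance
            prev = h
        base = heritability(VarComponents(1.0, 0.5, 0.5, 0.5))
        assert heritability(VarComponents(1.0, 1.5, 0.5, 0.5)) < base
        assert heritability(VarComponents(1.0, 0.5, 1.5, 0.5)) < base
        assert heritability(VarComponents(1.0, 0.5, 0.5, 1.5)) < base

    def test_general_variant_matches_at_2x2(self):
        vc = VarComponents(1.3, 0.4, 0.2, 0.9)
        assert heritability_general(vc, 2, 2) == pytest.approx(heritability(vc))


class TestSummaryAndCorrelation:
    def test_mean_and_sample_sd(self):
        rows = [("G1", "HP", 1, "t", 1.0), ("G1", "HP", 2, "t", 2.0),
                ("G2", "HP", 1, "t", 3.0), ("G2", "HP", 2, "t", 4.0)]
        table = pd.DataFrame(rows, columns=["genotype", "environment",
                                            "replication", "trait", "value"])
        out = trait_summary(table)
        assert out.loc["t", "HP_mean"] == pytest.approx(2.5)
        assert out.loc["t", "HP_sd"] == pytest.approx(math.sqrt(5.0 / 3.0))

    def test_absent_environment_reported_missing(self):
        rows = [("G1", "HP", 1, "t", 1.0), ("G2", "HP", 1, "t", 2.0)]
        table = pd.DataFrame(rows, columns=["genotype", "environment",
                                            "replication", "trait", "value"])
        out = trait_summary(table)
        assert math.isnan(out.loc["t", "LP_mean"])
        assert math.isnan(out.loc["t", "LP_sd"])

    def test_constant_trait_zero_sd(self):
        rows = [("G1", "LP", r, "t", 7.0) for r in (1, 2)]
        table = pd.DataFrame(rows, columns=["genotype", "environment",
                                            "replication", "trait", "value"])
        assert trait_summary(table).loc["t", "LP_sd"] == 0.0

    @staticmethod
    def _table_from_matrix(X: np.ndarray, traits: list[str]) -> pd.DataFrame:
        rows = []
        for g in range(X.shape[0]):
            for j, t in enumerate(traits):
                rows.append((f"G{g:03d}", "HP", 1, t, X[g, j]))
        return pd.DataFrame(rows, columns=["genotype", "environment",
                                           "replication", "trait", "value"])

    def test_perfect_anticorrelation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        table = self._table_from_matrix(np.column_stack([x, -x]), ["a", "b"])
        cm = correlation_matrix(table)
        assert cm.r.loc["a_HP", "b_HP"] == pytest.approx(-1.0)
        assert cm.p.loc["a_HP", "b_HP"] < 0.001
        assert cm.stars.loc["a_HP", "b_HP"] == "***"
        assert cm.r.loc["a_HP", "a_HP"] == 1.0

    def test_null_correlations_calibrated(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 40))
        cm = correlation_matrix(
            self._table_from_matrix(X, [f"t{j:02d}" for j in range(40)]))
        iu = np.triu_indices(40, 1)
        r_off = cm.r.to_numpy()[iu]
        assert abs(r_off.mean()) < 0.02
        starred = (cm.p.to_numpy()[iu] < 0.05).mean()
        assert 0.02 < starred < 0.09      # ~5% false positives at alpha=.05

    def test_constant_column_flagged_na(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([rng.normal(size=50), np.full(50, 3.0)])
        cm = correlation_matrix(self._table_from_matrix(X, ["a", "b"]))
        assert math.isnan(cm.r.loc["a_HP", "b_HP"])
        assert cm.stars.loc["a_HP", "b_HP"] == "NA"
        assert "b_HP" in cm.dropped

    def test_stars_thresholds(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.2) == "NS"
        assert significance_stars(float("nan")) == "NA"
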