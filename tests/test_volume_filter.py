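import numpy as np
import pandas as pd
import pytest
from scipy import stats

from srsboot import study_tables
from srsboot.cohort import CohortConfig, generate_cohort
from srsboot.errors import DegenerateInputError, UndefinedMetricError
from srsboot.volume_filter import (
    DEFAULT_ALPHA,
    chi_squared_test,
    select_features_for_removal,
    site_dependence_filter,
    univariate_association_tests,
)
from srsboot.volume_filter import (
    test_categorical_volume_dependence as categorical_volume_dependence,
)
from srsboot.volume_filter import (
    test_continuous_volume_correlation as continuous_volume_correlation,
)


class TestCategoricalVolumeDependence:
    def test_complete_separation_binary(self, rng):
        volumes = np.concatenate([rng.uniform(0.1, 1, 20), rng.uniform(10, 30, 20)])
        feature = np.array(["low"] * 20 + ["high"] * 20)
        p = categorical_volume_dependence(feature, volumes)
        assert p < 1e-6

    def test_null_p_values_uniform(self):
        # feature independent of volume -> p approx uniform (KS check)
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(300):
            volumes = rng.lognormal(1, 1, 60)
            feature = rng.choice(["a", "b", "c"], 60)
            ps.append(categorical_volume_dependence(feature, volumes))
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_single_category_skipped(self):
        with pytest.raises(UndefinedMetricError):
            categorical_volume_dependence(["x"] * 10, np.arange(1.0, 11))

    def test_empty_category_dropped_with_warning(self, rng):
        vals = pd.Series(["a"] * 10 + ["b"] * 10)
        vols = rng.lognormal(1, 1, 20)
        # no empty category here; exercise the multi-level path
        p = categorical_volume_dependence(
            np.array(["a"] * 7 + ["b"] * 7 + ["c"] * 6), vols
        )
        assert 0 <= p <= 1
        _ = vals


class TestContinuousVolumeCorrelation:
    def test_self_correlation(self, rng):
        v = rng.lognormal(1, 1, 50)
        r_vol, p_vol, _, _ = continuous_volume_correlation(v, v)
        assert r_vol == pytest.approx(1.0)
        assert p_vol < 1e-10

    def test_cubic_root_exact_on_diameter_scale(self, rng):
        v = rng.lognormal(1, 1.2, 80)
        f = np.cbrt(v)
        r_vol, _, r_diam, _ = continuous_volume_correlation(f, v)
        assert r_diam == pytest.approx(1.0)
        assert r_vol < 1.0

    def test_planted_rho_direct_formula_oracle(self):
        rng = np.random.default_rng(42)
        n = 50
        z = rng.normal(size=n)
        v = np.exp(z)
        f = 0.7 * z + np.sqrt(1 - 0.49) * rng.normal(size=n)
        r_vol, p_vol, r_diam, p_diam = continuous_volume_correlation(f, v)
        # direct-sums oracle for r and its t-test p
        def pearson_oracle(x, y):
            x, y = np.asarray(x), np.asarray(y)
            xc, yc = x - x.mean(), y - y.mean()
            r = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
            t = r * np.sqrt((n - 2) / (1 - r**2))
            p = 2 * stats.t.sf(abs(t), n - 2)
            return r, p

        ro, po = pearson_oracle(f, v)
        assert r_vol == pytest.approx(ro, abs=1e-12)
        assert p_vol == pytest.approx(po, rel=1e-6)
        assert abs(r_diam - 0.7) < 0.2
        assert p_diam < 1e-4

    def test_constant_raises(self):
        with pytest.raises(DegenerateInputError):
            continuous_volume_correlation(np.ones(10), np.arange(1.0, 11))


class TestSelectFeaturesForRemoval:
    def test_threshold_one_removes_nothing(self, small_cohort):
        removed, decisions = select_features_for_removal(small_cohort, threshold=1.0)
        assert removed == set()
        assert decisions == []

    def test_volume_always_removed_below_one(self, small_cohort):
        removed, _ = select_features_for_removal(small_cohort, threshold=0.99)
        assert "gtv_volume" in removed

    def test_planted_proxies_rule_oracle(self):
        # 3 near-perfect volume proxies and 3 independent features
        p = 107
        rho = np.zeros(p)
        rho[:3] = 0.95
        cfg = CohortConfig(
            n_patients=300, seed=8, volume_corr_targets=rho,
            signal_loading=np.zeros(p),
        )
        cohort = generate_cohort(cfg)
        removed, decisions = select_features_for_removal(cohort, threshold=0.25)
        for f in ("f001", "f002", "f003", "gtv_volume"):
            assert f in removed
        # rule-by-rule oracle over all continuous decisions
        for d in decisions:
            if d.feature_class != "continuous" or d.feature == "gtv_volume":
                continue
            significant = d.p_volume < DEFAULT_ALPHA or d.p_diameter < DEFAULT_ALPHA
            magnitude = max(abs(d.r_volume), abs(d.r_diameter))
            assert d.removed == (significant and magnitude > 0.25), d.feature

    def test_threshold_zero_removes_all_significant(self):
        p = 107
        rho = np.zeros(p)
        rho[:5] = np.linspace(0.4, 0.9, 5)
        cfg = CohortConfig(n_patients=400, seed=9, volume_corr_targets=rho,
                           signal_loading=np.zeros(p))
        cohort = generate_cohort(cfg)
        removed0, dec0 = select_features_for_removal(cohort, threshold=0.0)
        for d in dec0:
            if d.feature_class == "continuous" and (
                d.p_volume < DEFAULT_ALPHA or d.p_diameter < DEFAULT_ALPHA
            ):
                assert d.feature in removed0

    def test_nested_across_thresholds(self, small_cohort):
        prev = None
        for t in (1.0, 0.85, 0.70, 0.55, 0.40, 0.25, 0.10, 0.0):
            removed, _ = select_features_for_removal(small_cohort, threshold=t)
            if prev is not None:
                assert removed >= prev  # lower threshold removes at least as much
            prev = removed

    def test_postcondition_retained_features(self, small_cohort):
        for t in (0.7, 0.4, 0.25):
            removed, decisions = select_features_for_removal(small_cohort, threshold=t)
            for d in decisions:
                if d.feature_class != "continuous" or d.feature in removed:
                    continue
                significant = d.p_volume < DEFAULT_ALPHA or d.p_diameter < DEFAULT_ALPHA
                if significant:
                    assert max(abs(d.r_volume), abs(d.r_diameter)) <= t


class TestThresholdSweep:
    def test_sweep_structure_and_nestedness(self):
        from srsboot.engine import EngineConfig
        from srsboot.volume_filter import threshold_sweep

        cohort = generate_cohort(CohortConfig(n_patients=40, seed=2))
        sweep = threshold_sweep(
            cohort,
            thresholds=(1.0, 0.55, 0.25),
            engine_config=EngineConfig(n_trees=10),
            n_reps=2,
            seed=0,
        )
        assert sweep.thresholds == [1.0, 0.55, 0.25]
        assert sweep.removal_sets[1.0] == set()
        assert sweep.removal_sets[0.25] >= sweep.removal_sets[0.55]
        for t in sweep.thresholds:
            assert "overall" in sweep.metrics[t]


class TestSiteDependenceFilter:
    def test_site_itself_always_removed(self, small_cohort):
        removed = site_dependence_filter(small_cohort)
        assert "primary_site" in removed

    def test_site_indicator_feature_removed(self, small_cohort):
        cohort = small_cohort.subset(np.ones(small_cohort.n_bms, dtype=bool))
        cohort.df["f001"] = (cohort.df["primary_site"] == "lung").astype(float)
        cohort.df["f001"] += 1e-6 * np.random.default_rng(0).normal(size=cohort.n_bms)
        removed = site_dependence_filter(cohort)
        assert "f001" in removed

    def test_constant_feature_retained(self, small_cohort):
        cohort = small_cohort.subset(np.ones(small_cohort.n_bms, dtype=bool))
        cohort.df["f002"] = 1.0
        removed = site_dependence_filter(cohort)
        assert "f002" not in removed


class TestChiSquared:
    def test_reconstructed_primary_active_table(self):
        _, p = chi_squared_test(study_tables.PRIMARY_ACTIVE)
        assert round(p, 3) == 0.002

    def test_perfect_independence(self):
        stat, p = chi_squared_test([[10, 10], [10, 10]])
        assert stat == 0.0
        assert p == 1.0

    def test_matches_oe_oracle_on_random_tables(self, rng):
        for _ in range(100):
            t = rng.integers(1, 30, size=(2, 3)).astype(float)
            stat, _ = chi_squared_test(t)
            expected = np.outer(t.sum(1), t.sum(0)) / t.sum()
            oracle = ((t - expected) ** 2 / expected).sum()
            assert stat == pytest.approx(oracle, abs=1e-10)

    def test_zero_marginal_rejected(self):
        with pytest.raises(DegenerateInputError):
            chi_squared_test([[0, 0], [5, 3]])


class TestUnivariateAssociation:
    def test_returns_all_testable_features(self, small_cohort):
        table = univariate_association_tests(small_cohort)
        assert {"age", "gtv_volume"} <= set(
            table.loc[table["test"] == "ranksum", "feature"]
        )
        assert (table["p_value"].between(0, 1)).all()

    def test_null_feature_p_uniform(self):
        rng = np.random.default_rng(3)
        cfg = CohortConfig(n_patients=60)
        ps = []
        for seed in range(120):
            cfg.seed = seed
            cohort = generate_cohort(cfg)
            # an outcome-independent categorical feature
            cohort.df["sex"] = rng.choice(["female", "male"], cohort.n_bms)
            table = univariate_association_tests(cohort)
            ps.append(float(table.loc[table["feature"] == "sex", "p_value"].iloc[0]))
        assert stats.kstest(ps, "uniform").pvalue > 0.005

    def test_constant_feature_skipped_with_warning(self, small_cohort):
        cohort = small_cohort.subset(np.ones(small_cohort.n_bms, dtype=bool))
        cohort.df["bm_location"] = "supratentorial"
        with pytest.warns(UserWarning, match="constant"):
            table = univariate_association_tests(cohort)
        assert "bm_location" not in set(table["feature"])
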