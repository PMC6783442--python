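"""GBLUP fitting, prediction abilities and resampling schemes."""

import numpy as np
import pandas as pd
import pytest

from heatmaize.datatypes import default_crossing_scheme
from heatmaize.diversity import KinshipMatrix, additive_kinship
from heatmaize.gwp import (
    ScenarioSpec,
    _proportional_counts,
    _reml_multi,
    between_population_scenarios,
    cross_validate,
    fit_and_ability,
    fit_gblup,
    genomic_heritability,
    marker_subsample_curve,
    prediction_ability,
    resolve_scenarios,
    within_population_bootstrap,
)


def _random_panel(seed=1, n=50, m=200):
    rng = np.random.default_rng(seed)
    calls = rng.integers(0, 3, size=(m, n)).astype(float)
    imp = pd.DataFrame(calls, index=[f"m{i}" for i in range(m)], columns=[f"I{j}" for j in range(n)])
    return imp, additive_kinship(imp), rng


class TestFitGBLUP:
    def test_interpolation_limit_fits_training_exactly(self):
        imp, ka, rng = _random_panel(seed=2)
        w = imp.to_numpy() - imp.to_numpy().mean(axis=1, keepdims=True)
        y = pd.Series(w.T @ rng.normal(0, 1, len(imp)), index=imp.columns)
        fit = fit_gblup(y, [ka], fixed_variances={"additive": 1.0, "residual": 1e-9})
        assert np.max(np.abs(fit.predictions - y)) < 1e-5

    def test_identity_kinship_predicts_intercept_for_outsiders(self):
        ids = [f"I{j}" for j in range(20)]
        k = KinshipMatrix(pd.DataFrame(np.eye(20), index=ids, columns=ids), "additive", 1)
        rng = np.random.default_rng(3)
        y = pd.Series(rng.normal(5, 1, 15), index=ids[:15])
        fit = fit_gblup(y, [k], train_ids=ids[:15])
        assert np.allclose(fit.genetic_values[ids[15:]], 0.0)
        assert np.allclose(fit.predictions[ids[15:]], fit.mu)

    def test_single_and_multi_kinship_reml_paths_agree(self):
        imp, ka, rng = _random_panel(seed=4, n=60)
        w = imp.to_numpy() - imp.to_numpy().mean(axis=1, keepdims=True)
        g = w.T @ rng.normal(0, 0.1, len(imp))
        y = g + rng.normal(0, np.sqrt(np.var(g) / 2), 60)
        K = ka.to_numpy()
        s_multi, s2e_multi, _ = _reml_multi(y, [K], np.ones(60))
        fit = fit_gblup(pd.Series(y, index=imp.columns), [ka])
        assert fit.variances["additive"] == pytest.approx(s_multi[0], rel=1e-3, abs=1e-6)
        assert fit.variances["residual"] == pytest.approx(s2e_multi, rel=1e-3, abs=1e-6)

    def test_genomic_heritability_recovery(self):
        ests = []
        for seed in range(5):
            imp, ka, rng = _random_panel(seed=10 + seed, n=200, m=500)
            w = imp.to_numpy() - imp.to_numpy().mean(axis=1, keepdims=True)
            g = w.T @ rng.normal(0, 1, len(imp))
            g = g / g.std() * np.sqrt(0.6)
            y = pd.Series(g + rng.normal(0, np.sqrt(0.4), 200), index=imp.columns)
            ests.append(genomic_heritability(fit_gblup(y, [ka]), ka))
        assert np.median(ests) == pytest.approx(0.6, abs=0.12)

    def test_zero_variance_training_rejected(self):
        _, ka, _ = _random_panel(seed=5)
        y = pd.Series(1.0, index=ka.ids)
        with pytest.raises(ValueError, match="variance"):
            fit_gblup(y, [ka])

    def test_non_psd_kinship_rejected(self):
        ids = ["a", "b", "c"]
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        k = KinshipMatrix(pd.DataFrame(bad, index=ids, columns=ids), "additive", 1)
        y = pd.Series([1.0, 2.0, 3.0], index=ids)
        with pytest.raises(ValueError, match="semidefinite"):
            fit_gblup(y, [k])


class TestPredictionAbility:
    def test_perfect_and_inverted(self):
        x = np.arange(10.0)
        assert prediction_ability(x, x) == pytest.approx(1.0)
        assert prediction_ability(x, -x) == pytest.approx(-1.0)

    def test_null_pairs_small(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(40):
            r = prediction_ability(rng.normal(0, 1, 1000), rng.normal(0, 1, 1000))
            hits += abs(r) < 0.08
        assert hits >= 36

    def test_constant_vector_returns_nan(self):
        assert np.isnan(prediction_ability([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            prediction_ability([1.0, 2.0], [1.0, 2.0])


class TestCrossValidation:
    def test_deterministic_given_seed(self, small_hsi):
        tab, ka, _, pops = small_hsi
        y = tab[tab["trait"] == "LL"].set_index("genotype")["hsi"]
        a = cross_validate(y, [ka], pops, reps=2, seed=11)
        b = cross_validate(y, [ka], pops, reps=2, seed=11)
        assert a[0] == b[0]
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_stratified_fold_proportions(self, small_hsi):
        tab, ka, _, pops = small_hsi
        y = tab[tab["trait"] == "LL"].set_index("genotype")["hsi"]
        _, _, per_round = cross_validate(y, [ka], pops, folds=5, reps=1, seed=12)
        # per population 30 members over 5 folds -> exactly 6 per fold
        from heatmaize.gwp import _stratified_folds

        rng = np.random.default_rng(0)
        lab = _stratified_folds(list(y.index), pops, 5, rng)
        counts = pd.crosstab(pops.loc[y.index].to_numpy(), lab)
        assert (counts == 6).all().all()

    def test_high_heritability_trait_predicts_well(self, small_hsi):
        tab, ka, _, pops = small_hsi
        y = tab[tab["trait"] == "LL"].set_index("genotype")["hsi"]
        r_a_cv, r_pop_cv, _ = cross_validate(y, [ka], pops, reps=2, seed=13)
        assert r_a_cv > 0.5

    def test_pure_noise_trait_predicts_nothing(self, small_hsi):
        _, ka, _, pops = small_hsi
        rng = np.random.default_rng(14)
        y = pd.Series(rng.normal(0, 1, len(ka.ids)), index=ka.ids)
        r_a_cv, _, _ = cross_validate(y, [ka], pops, reps=2, seed=15)
        assert abs(r_a_cv) < 0.15

    def test_small_population_rejected(self, small_hsi):
        tab, ka, _, pops = small_hsi
        y = tab[tab["trait"] == "LL"].set_index("genotype")["hsi"]
        tiny = pops.copy()
        tiny.iloc[:2] = "tiny_pop"
        with pytest.raises(ValueError, match="tiny_pop"):
            cross_validate(y, [ka], tiny, folds=5, reps=1, seed=16)


class TestWithinPopulationBootstrap:
    def test_zero_heritability_trait_flat_at_zero(self, small_hsi):
        _, ka, _, pops = small_hsi
        rng = np.random.default_rng(17)
        y = pd.Series(rng.normal(0, 1, len(ka.ids)), index=ka.ids)
        s = within_population_bootstrap(
            y, [ka], "P_D1D2", pops, sizes=[10, 20], rounds=20, seed=18
        )
        med = s.meta["medians"]
        assert (med.abs() < 0.25).all()

    def test_oversized_training_set_skips_rounds(self, small_hsi, caplog):
        tab, ka, _, pops = small_hsi
        y = tab[tab["trait"] == "LL"].set_index("genotype")["hsi"]
        s = within_population_bootstrap(
            y, [ka], "P_D1D2", pops, sizes=[200], rounds=10, seed=19
        )
        assert 200 not in s.meta["medians"].index or np.isnan(s.meta["medians"].loc[200])

    def test_seed_determinism(self, small_hsi):
        tab, ka, _, pops = small_hsi
        y = tab[tab["trait"] == "LL"].set_index("genotype")["hsi"]
        a = within_population_bootstrap(y, [ka], "P_F1F2", pops, sizes=[15], rounds=10, seed=20)
        b = within_population_bootstrap(y, [ka], "P_F1F2", pops, sizes=[15], rounds=10, seed=20)
        pd.testing.assert_frame_equal(a.per_round, b.per_round)


class TestScenarios:
    def test_intra_pool_scenario_structure(self):
        scheme = default_crossing_scheme()
        scen = {s.name: s.constituents for s in resolve_scenarios(scheme, "P_D1D2")}
        assert scen["TS1"] == ["P_D3D4"]
        assert scen["TS2c"] == ["P_F1F2", "P_F3F4"]
        assert scen["TS3sr"] == ["P_D1F1"]
        assert scen["TS3su"] == ["P_D4F4"]
        assert scen["TS3c"] == ["P_D1F1", "P_D4F4"]

    def test_inter_pool_scenario_structure(self):
        scheme = default_crossing_scheme()
        scen = {s.name: s.constituents for s in resolve_scenarios(scheme, "P_D1F1")}
        assert scen["TS1"] == ["P_D4F4"]
        assert sorted(scen["TS2"]) == ["P_D3D4", "P_F3F4"]
        assert sorted(scen["TS3"]) == ["P_D1D2", "P_F1F2"]

    def test_validation_overlap_rejected(self, small_hsi):
        tab, ka, _, pops = small_hsi
        y = tab[tab["trait"] == "LL"].set_index("genotype")["hsi"]
        bad = ScenarioSpec("bad", "P_D1D2", ["P_D1D2"], 10, 2)
        with pytest.raises(ValueError, match="disjoint"):
            between_population_scenarios(y, [ka], pops, [bad], seed=1)

    def test_proportional_counts_even_split(self):
        assert _proportional_counts(np.array([100, 100]), 50).tolist() == [25, 25]
        assert _proportional_counts(np.array([30, 60]), 30).tolist() == [10, 20]

    def test_between_population_medians_deterministic(self, small_hsi):
        tab, ka, _, pops = small_hsi
        y = tab[tab["trait"] == "LL"].set_index("genotype")["hsi"]
        scheme = default_crossing_scheme()
        scen = resolve_scenarios(scheme, "P_D1D2", size=20, rounds=5)
        a = between_population_scenarios(y, [ka], pops, scen, seed=21)
        b = between_population_scenarios(y, [ka], pops, scen, seed=21)
        pd.testing.assert_frame_equal(a, b)


class TestMarkerCurve:
    def test_full_set_equals_single_shot(self, small_hsi):
        tab, ka, imp, pops = small_hsi
        y = tab[tab["trait"] == "LL"].set_index("genotype")["hsi"]
        curve = marker_subsample_curve(y, imp, pops, sizes=[imp.shape[0]], reps=3, seed=22)
        r_a, _, _ = fit_and_ability(y, [additive_kinship(imp)], pops)
        assert curve["median_r_a"].iloc[0] == pytest.approx(r_a, abs=1e-10)
        assert curve["sd"].iloc[0] == 0.0

    def test_deterministic_given_seed(self, small_hsi):
        tab, _, imp, pops = small_hsi
        y = tab[tab["trait"] == "LL"].set_index("genotype")["hsi"]
        a = marker_subsample_curve(y, imp, pops, sizes=[50, 100], reps=3, seed=23)
        b = marker_subsample_curve(y, imp, pops, sizes=[50, 100], reps=3, seed=23)
        pd.testing.assert_frame_equal(a, b)
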