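"""GA wrapper feature selection: splits, fitness, search, frequency protocol."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LinearRegression
from sklearn.metrics import mean_absolute_error

from tdmstate import (
    CohortConfig,
    GAConfig,
    GeneticSubsetSelector,
    frequency_analysis,
    generate_cohort,
    run_scenario,
    split_patients,
    sweep_k,
)
from tdmstate.prep import prepare_cohort
from tdmstate.selection import fitness, grouped_fold_indices


def _planted_data(seed, n_groups=40, days=6, n_informative=4, n_noise=8, noise=0.5):
    """Regression rows grouped by patient: target = sum of planted features."""
    rng = np.random.default_rng(seed)
    n = n_groups * days
    X = rng.normal(size=(n, n_informative + n_noise))
    y = X[:, :n_informative].sum(axis=1) + noise * rng.normal(size=n)
    groups = np.repeat([f"P{i}" for i in range(n_groups)], days)
    cols = [f"f{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=cols), y, groups


class TestSplitPatients:
    def test_study_scale_partition(self):
        cfg = CohortConfig(seed=1)
        df = generate_cohort(cfg)  # 248 patients
        holdout, train, test = split_patients(df, holdout_n=10, train_fraction=0.8)
        assert len(holdout) == 10
        assert len(train) + len(test) == 238
        assert len(train) == round(0.8 * 238)

    def test_partitions_disjoint_and_by_patient(self, small_cohort):
        holdout, train, test = split_patients(small_cohort, holdout_n=5, seed=3)
        parts = [set(holdout), set(train), set(test)]
        assert sum(len(p) for p in parts) == len(set().union(*parts))
        all_ids = set(small_cohort["patient_id"])
        assert set().union(*parts) == all_ids

    def test_same_seed_same_split(self, small_cohort):
        a = split_patients(small_cohort, seed=9)
        b = split_patients(small_cohort, seed=9)
        assert a == b

    def test_too_few_patients_rejected(self):
        df = pd.DataFrame({"patient_id": list("abcdef")})
        with pytest.raises(ValueError, match="too few"):
            split_patients(df, holdout_n=10)


class TestGroupedFolds:
    def test_folds_never_split_a_patient(self):
        groups = np.repeat([f"P{i}" for i in range(20)], 4)
        for tr, va in grouped_fold_indices(groups, 5, seed=0):
            assert set(groups[tr]).isdisjoint(set(groups[va]))
            assert len(tr) + len(va) == len(groups)


class TestFitness:
    def test_constant_target_perfect(self):
        X, y, groups = _planted_data(0)
        y_const = np.full_like(y, 5.0)
        score = fitness(X, y_const, groups, ("f0", "f1"), cv_folds=4)
        assert score == pytest.approx(0.0, abs=1e-9)

    def test_exact_linear_relationship_near_zero_mae(self):
        X, y, groups = _planted_data(1, noise=0.0)
        score = fitness(X, y, groups, tuple(f"f{i}" for i in range(4)), cv_folds=4)
        assert abs(score) < 1e-6

    def test_unknown_feature_rejected(self):
        X, y, groups = _planted_data(2)
        with pytest.raises(ValueError, match="unknown"):
            fitness(X, y, groups, ("nope",))

    def test_fast_linear_path_matches_sklearn(self):
        """Internal lstsq CV agrees with an independent sklearn CV loop."""
        X, y, groups = _planted_data(3)
        subset = ("f0", "f2", "f5")
        score = fitness(X, y, groups, subset, cv_folds=5, seed=42)
        folds = grouped_fold_indices(groups, 5, seed=42)
        ref_scores = []
        for tr, va in folds:
            model = LinearRegression().fit(X.iloc[tr][list(subset)], y[tr])
            pred = model.predict(X.iloc[va][list(subset)])
            ref_scores.append(-mean_absolute_error(y[va], pred))
        assert score == pytest.approx(np.mean(ref_scores), abs=1e-9)

    def test_informative_subset_beats_noise(self):
        wins = 0
        for seed in range(20):
            X, y, groups = _planted_data(seed)
            good = fitness(X, y, groups, ("f0", "f1", "f2", "f3"))
            bad = fitness(X, y, groups, ("f4", "f5", "f6", "f7"))
            wins += good > bad
        assert wins >= 19


class TestGeneticSearch:
    def test_k_equal_to_feature_count_returns_full_set(self):
        X, y, groups = _planted_data(4)
        sel = GeneticSubsetSelector(k=X.shape[1], generations=3).fit(X, y, groups)
        assert sel.best_features_ == tuple(X.columns)

    def test_zero_generations_best_of_initial_population(self):
        X, y, groups = _planted_data(5)
        sel = GeneticSubsetSelector(
            k=3, population_size=10, generations=0, random_state=1
        ).fit(X, y, groups)
        assert len(sel.best_features_) == 3
        assert len(sel.trace_) == 1
        assert sel.best_score_ == sel.trace_[0]

    def test_k_too_large_rejected(self):
        X, y, groups = _planted_data(6)
        with pytest.raises(ValueError, match="exceeds"):
            GeneticSubsetSelector(k=X.shape[1] + 1).fit(X, y, groups)

    def test_trace_monotone_and_support_consistent(self):
        X, y, groups = _planted_data(7)
        sel = GeneticSubsetSelector(
            k=4, population_size=16, generations=10, random_state=2
        ).fit(X, y, groups)
        assert np.all(np.diff(sel.trace_) >= 0)
        assert sel.support_.sum() == 4
        assert sel.transform(X).shape[1] == 4

    def test_reproducible_with_fixed_seed(self):
        X, y, groups = _planted_data(8)
        a = GeneticSubsetSelector(k=4, population_size=12, generations=6,
                                  random_state=5).fit(X, y, groups)
        b = GeneticSubsetSelector(k=4, population_size=12, generations=6,
                                  random_state=5).fit(X, y, groups)
        assert a.best_features_ == b.best_features_
        assert np.array_equal(a.trace_, b.trace_)

    def test_recovers_planted_subset(self):
        hits = 0
        for seed in range(10):
            X, y, groups = _planted_data(seed, n_informative=4, n_noise=10)
            sel = GeneticSubsetSelector(
                k=4, population_size=24, generations=15, random_state=seed
            ).fit(X, y, groups)
            hits += sel.best_features_ == ("f0", "f1", "f2", "f3")
        assert hits >= 9


class TestSweepK:
    def test_curve_shape_and_fold_accounting(self):
        X, y, groups = _planted_data(9, n_groups=30)
        cfg = GAConfig(population_size=10, generations=3, subset_size=2,
                       repetitions=1, seed=0)
        curve = sweep_k(X, y, groups, cfg, k_range=range(1, 4))
        assert len(curve) == 3
        assert (curve["n_scores"] == 30).all()  # 10 splits x 3 repeats
        assert list(curve["k"]) == [1, 2, 3]

    def test_elbow_at_planted_size(self):
        """Adding the last informative feature helps more than a noise one."""
        wins = 0
        for seed in range(10):
            X, y, groups = _planted_data(
                seed, n_groups=40, n_informative=3, n_noise=6, noise=0.2
            )
            cfg = GAConfig(population_size=20, generations=10, subset_size=3,
                           repetitions=1, seed=seed)
            curve = sweep_k(X, y, groups, cfg, k_range=range(2, 5))
            s = curve.set_index("k")["mean_score"]
            wins += (s[3] - s[2]) > (s[4] - s[3])
        assert wins >= 8


class TestFrequencyAnalysis:
    def test_threshold_rule(self):
        subsets = [("a",)] * 13 + [("b",)] * 87
        cfg = GAConfig(population_size=10, frequency_threshold=0.10, subset_size=2)
        report = frequency_analysis(subsets, ["a", "b", "c"], cfg)
        assert report.frequencies["a"] == pytest.approx(0.13)
        assert report.frequencies["c"] == 0.0
        assert set(report.chosen) == {"a", "b"}

    def test_single_repetition_frequencies_binary(self):
        report = frequency_analysis(
            [("a", "b")], ["a", "b", "c"],
            GAConfig(population_size=10, subset_size=2),
        )
        assert sorted(report.frequencies.unique()) == [0.0, 1.0]

    def test_empty_pool_falls_back_to_top_k(self):
        # every frequency (0.5) sits below the threshold -> empty pool
        subsets = [("a",)] * 50 + [("b",)] * 50
        cfg = GAConfig(population_size=10, frequency_threshold=0.6,
                       subset_size=2)
        with pytest.warns(UserWarning, match="falling back"):
            report = frequency_analysis(subsets, ["a", "b", "c"], cfg)
        assert report.fallback_used
        assert "a" in report.chosen

    def test_no_repetitions_rejected(self):
        with pytest.raises(ValueError):
            frequency_analysis([], ["a"], GAConfig(population_size=10))


class TestScenarios:
    @pytest.fixture(scope="class")
    def prepared(self):
        cfg = CohortConfig(
            n_tdm=20, n_control=20, n_continuous=8, n_discrete=4,
            n_pathogen=2, n_informative=8, max_days=6,
            death_hazard_scale=0.0, discharge_sofa_threshold=-1, seed=21,
        )
        clean, schema, _ = prepare_cohort(generate_cohort(cfg))
        return clean, schema

    def _fast_cfg(self, **kw):
        base = dict(population_size=8, generations=3, repetitions=2,
                    subset_size=3, cv_folds=3, forest_size=8, seed=0)
        base.update(kw)
        return GAConfig(**base)

    def test_unknown_scenario_rejected(self, prepared):
        clean, schema = prepared
        with pytest.raises(ValueError, match="scenario"):
            run_scenario(clean, 5, self._fast_cfg(), schema)

    @pytest.mark.parametrize("scenario", [1, 2, 3, 4])
    def test_all_scenarios_run_and_report(self, prepared, scenario):
        clean, schema = prepared
        report = run_scenario(
            clean, scenario, self._fast_cfg(), schema, holdout_n=4
        )
        assert report.scenario_id == scenario
        assert set(report.chosen) <= set(schema.all_features)
        assert ((report.frequencies >= 0) & (report.frequencies <= 1)).all()
        assert len(report.holdout_ids) == 4

    def test_grouped_scenario_without_pathogens(self):
        cfg = CohortConfig(
            n_tdm=15, n_control=15, n_continuous=6, n_discrete=3,
            n_pathogen=0, n_informative=6, max_days=5,
            death_hazard_scale=0.0, discharge_sofa_threshold=-1, seed=5,
        )
        clean, schema, _ = prepare_cohort(generate_cohort(cfg))
        report = run_scenario(clean, 3, self._fast_cfg(), schema, holdout_n=3)
        assert schema.pathogen == ()
        assert len(report.chosen) > 0

    def test_scenario_reproducible(self, prepared):
        clean, schema = prepared
        a = run_scenario(clean, 2, self._fast_cfg(), schema, holdout_n=4)
        b = run_scenario(clean, 2, self._fast_cfg(), schema, holdout_n=4)
        assert a.chosen == b.chosen
        pd.testing.assert_series_equal(a.frequencies, b.frequencies)
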