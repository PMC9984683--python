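"""Classification machinery: aggregation, grouped CV, ROC metrics, backward
elimination, McNemar, FDR, IMPACT baseline — on fast synthetic tables."""

import numpy as np
import pandas as pd
import pytest

import icueeg as q
from icueeg.predict import backward_elimination, crossvalidate, roc_metrics


def synth_table(n_patients=40, n_features=6, informative=2, effect=2.0,
                n_segments=3, seed=0):
    """Segment-level feature table with planted class separation."""
    rng = np.random.default_rng(seed)
    labels = rng.permutation([0, 1] * (n_patients // 2))
    rows = []
    for i, y in enumerate(labels):
        centre = rng.normal(0, 1, n_features)
        centre[:informative] += effect * y
        for s in range(n_segments):
            rows.append({"patient_id": f"P{i:03d}", "segment_id": s,
                         "outcome": int(y),
                         **{f"f{j}": centre[j] + rng.normal(0, 0.3)
                            for j in range(n_features)}})
    return pd.DataFrame(rows), [f"f{j}" for j in range(n_features)]


class TestAggregateFeatures:
    def _features(self, n_patients=10, timepoints=(24.0, 48.0)):
        rows = []
        for i in range(n_patients):
            for tp in timepoints:
                for s in range(3):
                    rows.append({"patient_id": f"P{i:03d}", "timepoint_h": tp,
                                 "segment_id": s, "a": 1.0 * i, "b": 2.0 * i})
        return pd.DataFrame(rows)

    def test_single_timepoint_three_rows_per_patient(self):
        out = q.aggregate_features(self._features(), 24.0)
        assert len(out) == 30
        assert {"a", "b"} <= set(out.columns)

    def test_concatenation_doubles_feature_columns(self):
        out = q.aggregate_features(self._features(), [24.0, 48.0])
        cols = [c for c in out.columns if "@" in c]
        assert len(cols) == 4  # 2 features x 2 timepoints
        assert "a@24h" in cols and "b@48h" in cols

    def test_missing_timepoint_left_nan_for_fold_imputation(self):
        feats = self._features()
        feats = feats[~((feats.patient_id == "P003") & (feats.timepoint_h == 48.0))]
        out = q.aggregate_features(feats, [24.0, 48.0])
        row = out[(out.patient_id == "P003")]
        assert row["a@48h"].isna().all()
        assert row["a@24h"].notna().all()


class TestRandomForest:
    def test_separating_feature_tops_importance(self):
        table, cols = synth_table(effect=4.0, informative=1, seed=1)
        clf = q.train_random_forest(table[cols].to_numpy(),
                                    table["outcome"].to_numpy(), seed=0)
        assert clf.oob_score_ > 0.95
        assert np.argmax(clf.feature_importances_) == 0

    def test_label_shuffle_gives_prior_error(self):
        """Permutation null: OOB accuracy stays near the majority-class rate."""
        table, cols = synth_table(effect=3.0, seed=2)
        X = table[cols].to_numpy()
        y = table["outcome"].to_numpy()
        rng = np.random.default_rng(0)
        accs = []
        for s in range(20):
            ys = rng.permutation(y)
            accs.append(q.train_random_forest(X, ys, seed=s).oob_score_)
        prior = max(y.mean(), 1 - y.mean())
        assert np.mean(accs) == pytest.approx(prior, abs=0.1)

    def test_seeded_determinism(self):
        table, cols = synth_table(seed=3)
        X, y = table[cols].to_numpy(), table["outcome"].to_numpy()
        a = q.train_random_forest(X, y, seed=5).predict_proba(X)
        b = q.train_random_forest(X, y, seed=5).predict_proba(X)
        np.testing.assert_array_equal(a, b)

    def test_oob_error_curve_decreasing(self):
        table, cols = synth_table(effect=2.0, seed=4)
        curve = q.oob_error_curve(table[cols].to_numpy(),
                                  table["outcome"].to_numpy(), max_trees=200)
        assert curve["n_trees"].iloc[-1] == 200
        assert curve["oob_error"].iloc[-1] <= curve["oob_error"].iloc[0]


class TestCrossValidate:
    def test_separable_cohort_high_auc(self):
        table, cols = synth_table(effect=3.0, seed=5)
        res = crossvalidate(table, cols, seed=0)
        assert res.mean_auc >= 0.95
        assert len(res.fold_auc) == 5
        assert len(res.patients) == 40

    def test_null_cohort_chance_level(self):
        table, cols = synth_table(effect=0.0, seed=6)
        aucs = [crossvalidate(table, cols, seed=s).mean_auc for s in range(3)]
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_patient_grouping_prevents_duplication_leakage(self):
        """Duplicating each patient's rows 3x never inflates the grouped,
        patient-level AUC of a no-signal cohort (averaged over datasets:
        individual small datasets carry spurious finite-sample signal, but
        duplication must not add to it)."""
        bases, augs = [], []
        for s in range(5):
            table, cols = synth_table(effect=0.0, n_segments=1, seed=70 + s)
            dup = pd.concat([table] * 3, ignore_index=True)
            bases.append(crossvalidate(table, cols, seed=s, n_trees=100).mean_auc)
            augs.append(crossvalidate(dup, cols, seed=s, n_trees=100).mean_auc)
        assert np.mean(augs) <= np.mean(bases) + 0.05
        assert 0.35 <= np.mean(augs) <= 0.65

    def test_each_patient_in_one_test_fold(self):
        table, cols = synth_table(seed=8)
        res = crossvalidate(table, cols, seed=1)
        counts = res.patients.groupby("patient_id")["fold"].nunique()
        assert (counts == 1).all()

    def test_single_class_rejected(self):
        table, cols = synth_table(seed=9)
        table["outcome"] = 1
        with pytest.raises(ValueError):
            crossvalidate(table, cols)

    def test_missing_values_imputed(self):
        table, cols = synth_table(effect=3.0, seed=10)
        table.loc[table.index[::7], cols[0]] = np.nan
        res = crossvalidate(table, cols, seed=0)
        assert np.isfinite(res.mean_auc)


class TestROCMetrics:
    def test_perfect_separation(self):
        auc, sens, spec, _ = roc_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0 and sens == 1.0 and spec == 1.0

    def test_perfectly_wrong(self):
        auc, _, _, _ = roc_metrics([0.3, 0.9], [1, 0])
        assert auc == 0.0

    def test_ties_counted_half(self):
        """Brute-force pair counting: 3 concordant + 1 tie of 4 pairs."""
        auc, _, _, _ = roc_metrics([0.9, 0.5, 0.5, 0.1], [1, 1, 0, 0])
        assert auc == pytest.approx(0.875)

    def test_auc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(0)
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        a1, *_ = roc_metrics(scores, labels)
        a2, *_ = roc_metrics(np.exp(5 * scores), labels)
        assert a1 == pytest.approx(a2)


class TestBackwardElimination:
    def test_noise_features_eliminated_first(self):
        """5 informative + 20 noise features: every noise feature leaves the
        model before any informative one in >= 90% of seeds."""
        wins = 0
        n_seeds = 10
        for s in range(n_seeds):
            table, cols = synth_table(n_patients=30, n_features=25,
                                      informative=5, effect=2.5, seed=100 + s)
            trace = backward_elimination(table, cols, k=3, n_trees=60, seed=s)
            removed = [r for r in trace.steps["removed"] if r]
            informative = {f"f{j}" for j in range(5)}
            first_informative = next((i for i, r in enumerate(removed)
                                      if r in informative), len(removed))
            wins += first_informative >= 20
        assert wins / n_seeds >= 0.9

    def test_single_feature_trace(self):
        table, cols = synth_table(n_features=1, informative=1, seed=11)
        trace = backward_elimination(table, cols[:1], k=3, n_trees=40, seed=0)
        assert len(trace.steps) == 1
        assert trace.chosen == cols[:1]

    def test_importance_tie_drops_lexicographically_last(self):
        """Two identical (duplicated) zero-variance features tie at zero
        importance; the lexicographically last name is dropped first."""
        table, cols = synth_table(n_features=2, informative=1, effect=3.0,
                                  seed=12)
        table["zz_dup"] = 1.0
        table["aa_dup"] = 1.0
        trace = backward_elimination(table, ["f0", "aa_dup", "zz_dup"], k=3,
                                     n_trees=40, seed=0)
        removed = list(trace.steps["removed"])
        assert removed[0] == "zz_dup"

    def test_stop_rule_smallest_subset_within_tolerance(self):
        table, cols = synth_table(n_patients=30, n_features=8, informative=2,
                                  effect=3.0, seed=13)
        trace = backward_elimination(table, cols, k=3, n_trees=60, seed=0)
        chosen_auc = trace.steps.loc[
            trace.steps["n_features"] == len(trace.chosen), "auc"].iloc[0]
        assert chosen_auc >= trace.best_auc - 0.02
        smaller = trace.steps[trace.steps["n_features"] < len(trace.chosen)]
        assert (smaller["auc"] < trace.best_auc - 0.02).all()


class TestMcNemar:
    def test_identical_predictions(self):
        stat, p = q.mcnemar_compare([1, 0, 1], [1, 0, 1], [1, 0, 0])
        assert p == 1.0

    def test_ten_zero_discordants_exact(self):
        """10 vs 0 discordant pairs: exact two-sided p = 2 * 0.5^10."""
        labels = np.ones(12, int)
        a = np.ones(12, int)          # all correct
        b = np.concatenate([np.zeros(10, int), np.ones(2, int)])
        _, p = q.mcnemar_compare(a, b, labels)
        assert p == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_fifteen_five_discordants_exact(self):
        labels = np.ones(25, int)
        a = np.concatenate([np.ones(20, int), np.zeros(5, int)])
        b = np.concatenate([np.zeros(15, int), np.ones(10, int)])
        _, p = q.mcnemar_compare(a, b, labels)
        from scipy import stats
        expected = 2 * stats.binom.cdf(5, 20, 0.5)
        assert p == pytest.approx(expected, rel=1e-9)
        assert p == pytest.approx(0.041, abs=0.001)

    def test_many_discordants_use_chi_square(self):
        labels = np.ones(80, int)
        a = np.concatenate([np.ones(50, int), np.zeros(30, int)])
        b = np.concatenate([np.zeros(20, int), np.ones(60, int)])
        stat, p = q.mcnemar_compare(a, b, labels)
        assert stat > 0 and 0 < p < 1


class TestFDR:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(q.fdr_adjust([0.04]), [0.04])

    def test_step_up_by_hand(self):
        np.testing.assert_allclose(q.fdr_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_allclose(q.fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(0)
        p = rng.random(20)
        adj = q.fdr_adjust(p)
        assert (np.argsort(np.argsort(adj)) <= np.argsort(np.argsort(p)) + 19).all()
        # monotone: sorting p sorts adj
        assert (np.diff(adj[np.argsort(p)]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()


class TestImpactScore:
    def test_zero_coefficients_give_half(self):
        cov = pd.DataFrame({"age": [40.0, 70.0]})
        p = q.impact_score(cov, {"intercept": 0.0, "age": 0.0})
        np.testing.assert_allclose(p, 0.5)

    def test_extreme_negative_intercept_tail(self):
        cov = pd.DataFrame({"age": [40.0]})
        p = q.impact_score(cov, {"intercept": -50.0, "age": 0.0})
        assert p[0] < 1e-12

    def test_monotone_in_age_with_positive_coefficient(self):
        coef = q.load_impact_coefficients()
        ages = np.linspace(20, 90, 10)
        cov = pd.DataFrame({k: np.full(10, 1.0) for k in coef if k != "intercept"})
        cov["age"] = ages
        p = q.impact_score(cov, coef)
        assert (np.diff(p) > 0).all()

    def test_missing_covariate_named_in_error(self):
        with pytest.raises(KeyError, match="age"):
            q.impact_score(pd.DataFrame({"glucose": [8.0]}),
                           {"intercept": 0.0, "age": 0.1})


class TestShufflePatientLabels:
    def test_segments_stay_consistent_within_patient(self):
        table, _ = synth_table(seed=14)
        shuffled = q.shuffle_patient_labels(table, seed=1)
        per_patient = shuffled.groupby("patient_id")["outcome"].nunique()
        assert (per_patient == 1).all()
        assert shuffled["outcome"].sum() == table["outcome"].sum()
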