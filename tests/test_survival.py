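"""Survival statistics oracles and the latent-feature subgroup pipeline."""

import warnings

import numpy as np
import pandas as pd
import pytest

from omicsvae.survival import (SurvivalTable, brier_score, choose_k,
                               concordance_index, cox_multivariate,
                               cox_univariate_per_lf, infer_subgroups,
                               km_logrank, predict_subgroups,
                               run_survival_pipeline)


def table(times, events, **cols):
    n = len(times)
    data = {"sample_id": [f"s{i}" for i in range(n)],
            "os_time": times, "os_event": events,
            "age": cols.get("age", np.full(n, 60.0)),
            "stage": cols.get("stage", np.full(n, 3)),
            "grade": cols.get("grade", np.full(n, 3))}
    return SurvivalTable(pd.DataFrame(data))


def weibull_table(risk, seed=0, censoring=0.0, lam=1000.0, k=1.2):
    rng = np.random.default_rng(seed)
    n = len(risk)
    t = lam * (-np.log(rng.uniform(size=n)) * np.exp(-risk)) ** (1 / k)
    if censoring > 0:
        c = rng.exponential(np.quantile(t, 1 - censoring) * 2, size=n)
        obs, ev = np.minimum(t, c), (t <= c).astype(int)
    else:
        obs, ev = t, np.ones(n, dtype=int)
    rng2 = np.random.default_rng(seed + 1)
    return table(obs, ev, age=np.clip(rng2.normal(60, 10, n), 30, 90),
                 stage=rng2.integers(1, 5, n), grade=rng2.integers(1, 4, n))


class TestConcordanceIndex:
    def test_perfectly_concordant_hand_example(self):
        t = table([1.0, 2.0, 3.0], [1, 1, 1])
        assert concordance_index(np.array([3.0, 2.0, 1.0]), t) == 1.0

    def test_perfectly_reversed(self):
        t = table([1.0, 2.0, 3.0], [1, 1, 1])
        assert concordance_index(np.array([1.0, 2.0, 3.0]), t) == 0.0

    def test_two_of_three_pairs_correct(self):
        t = table([1.0, 2.0, 3.0], [1, 1, 1])
        assert concordance_index(np.array([3.0, 1.0, 2.0]), t) == pytest.approx(2 / 3)

    def test_random_risks_near_half_at_n500(self):
        rng = np.random.default_rng(0)
        t = weibull_table(np.zeros(500), seed=1)
        c = concordance_index(rng.normal(size=500), t)
        assert c == pytest.approx(0.5, abs=0.05)


class TestBrierScore:
    def test_oracle_predictions_score_zero_without_censoring(self):
        t = table([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        grid = np.array([2.5])
        oracle = (t.time[:, None] > grid[None, :]).astype(float)
        assert brier_score(oracle, grid, t) == 0.0

    def test_constant_half_prediction_scores_quarter(self):
        t = table([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        grid = np.array([2.5])
        assert brier_score(np.full((4, 1), 0.5), grid, t) == pytest.approx(0.25)

    def test_score_bounded_in_unit_interval(self):
        rng = np.random.default_rng(2)
        t = weibull_table(rng.normal(size=80), seed=3, censoring=0.3)
        grid = np.quantile(t.time, [0.25, 0.5, 0.75])
        probs = rng.uniform(size=(80, 3))
        s = brier_score(probs, grid, t)
        assert 0.0 <= s <= 1.0

    def test_times_beyond_followup_rejected(self):
        t = table([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="follow-up"):
            brier_score(np.ones((2, 1)), np.array([5.0]), t)


class TestKMLogRank:
    def test_identical_groups_give_zero_statistic(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        events = [1, 0, 1, 1, 0]
        t = table(times + times, events + events)
        groups = np.array([0] * 5 + [1] * 5)
        fits, stat, p = km_logrank(groups, t)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_km_curve_starts_at_one_and_is_nonincreasing(self):
        t = weibull_table(np.zeros(60), seed=4, censoring=0.2)
        fits, _, _ = km_logrank(np.repeat([0, 1], 30), t)
        for km in fits.values():
            sf = km.survival_function_.iloc[:, 0].to_numpy()
            assert sf[0] == 1.0
            assert np.all(np.diff(sf) <= 1e-12)

    def test_planted_hazard_ratio_three_detected(self):
        groups = np.repeat([0, 1], 150)
        risk = groups * np.log(3.0)
        t = weibull_table(risk, seed=5, censoring=0.2)
        _, _, p = km_logrank(groups, t)
        assert p < 0.01

    def test_single_group_rejected(self):
        t = table([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="2 groups"):
            km_logrank(np.array([0, 0]), t)


class TestCoxUnivariate:
    def test_null_lf_coefficient_within_two_se(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            lf = rng.normal(size=(300, 1))
            t = weibull_table(np.zeros(300), seed=seed)
            sel = cox_univariate_per_lf(lf, t)
            # |coef| < 2 SE ~ p > 0.05 for a single Wald-equivalent test
            hits += sel.p_values[0] > 0.05
        assert hits >= 9

    def test_planted_coefficient_recovered(self):
        rng = np.random.default_rng(7)
        lf = rng.normal(size=(500, 1))
        t = weibull_table(lf[:, 0], seed=8, censoring=0.2)
        sel = cox_univariate_per_lf(lf, t)
        assert sel.coefficients[0] == pytest.approx(1.0, abs=0.2)
        assert 0 in sel.selected

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(9)
        lfs = rng.normal(size=(400, 40))
        t = weibull_table(np.zeros(400), seed=10)
        sel = cox_univariate_per_lf(lfs, t)
        # Binomial(40, 0.05): 0..7 selections covers > 99.9% of the mass.
        assert len(sel.selected) <= 7

    def test_constant_lf_flagged_not_fatal(self):
        rng = np.random.default_rng(11)
        lfs = np.hstack([np.ones((100, 1)), rng.normal(size=(100, 1))])
        t = weibull_table(np.zeros(100), seed=12)
        sel = cox_univariate_per_lf(lfs, t)
        assert 0 in sel.failed

    def test_zero_events_rejected(self):
        t = table([1.0, 2.0, 3.0], [0, 0, 0])
        with pytest.raises(ValueError, match="events"):
            cox_univariate_per_lf(np.zeros((3, 2)), t)


class TestSubgroups:
    @staticmethod
    def planted_clusters(k, n_per=40, seed=0, spread=0.4):
        rng = np.random.default_rng(seed)
        centers = rng.normal(0, 4, (k, 3))
        X = np.vstack([c + rng.normal(0, spread, (n_per, 3)) for c in centers])
        labels = np.repeat(np.arange(k), n_per)
        return X, labels

    @pytest.mark.parametrize("k", [2, 3])
    def test_choose_k_finds_planted_count(self, k):
        X, _ = self.planted_clusters(k, seed=k)
        assert choose_k(X, seed=0) == k

    def test_infer_subgroups_orders_labels_by_size(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.3, (50, 2)), rng.normal(6, 0.3, (20, 2))])
        labels = infer_subgroups(X, 2, seed=0)
        assert (labels[:50] == 0).all() and (labels[50:] == 1).all()

    def test_infer_rejects_k_below_two(self):
        with pytest.raises(ValueError, match="at least 2"):
            infer_subgroups(np.zeros((5, 2)), 1)

    def test_kmeans_beats_random_assignment(self):
        X, _ = self.planted_clusters(3, seed=5)
        labels = infer_subgroups(X, 3, seed=0)

        def wss(assign):
            return sum(((X[assign == c] - X[assign == c].mean(axis=0)) ** 2).sum()
                       for c in np.unique(assign))

        rng = np.random.default_rng(0)
        random_wss = [wss(rng.integers(0, 3, len(X))) for _ in range(100)]
        assert wss(labels) <= min(random_wss)

    def test_predict_subgroups_split_sizes_and_accuracy(self):
        X, labels = self.planted_clusters(2, n_per=50, seed=2)
        train_idx, test_idx, predicted, _ = predict_subgroups(X, labels, seed=0)
        assert len(train_idx) == 60 and len(test_idx) == 40
        assert np.mean(predicted == labels[test_idx]) == 1.0

    def test_predict_agrees_with_nearest_centroid_oracle(self):
        X, labels = self.planted_clusters(2, n_per=50, seed=3, spread=1.0)
        train_idx, test_idx, predicted, _ = predict_subgroups(X, labels, seed=0)
        centroids = np.stack([X[train_idx][labels[train_idx] == c].mean(axis=0)
                              for c in (0, 1)])
        d = np.linalg.norm(X[test_idx][:, None, :] - centroids[None], axis=2)
        oracle = d.argmin(axis=1)
        assert np.mean(predicted == oracle) >= 0.9


class TestCoxMultivariate:
    def test_nested_model_likelihood_ordering(self):
        rng = np.random.default_rng(4)
        n = 200
        t = weibull_table(rng.normal(size=n), seed=5, censoring=0.2)
        cov = t.data[["age", "stage", "grade"]].copy()
        cov["subgroup"] = rng.integers(0, 2, n)
        clin, _ = cox_multivariate(cov, t, formula="clinical")
        comb, _ = cox_multivariate(cov, t, formula="combined")
        assert comb.log_likelihood_ >= clin.log_likelihood_ - 1e-9

    def test_planted_subgroup_effect_detected(self):
        rng = np.random.default_rng(6)
        n = 300
        subgroup = rng.integers(0, 2, n)
        t = weibull_table(subgroup * np.log(3.0), seed=7, censoring=0.4)
        cov = t.data[["age", "stage", "grade"]].copy()
        cov["subgroup"] = subgroup
        _, p = cox_multivariate(cov, t, formula="combined")
        assert p < 0.01

    def test_constant_covariate_dropped_with_warning(self):
        t = weibull_table(np.zeros(100), seed=8)
        cov = t.data[["age", "stage", "grade"]].copy()
        cov["grade"] = 3
        with pytest.warns(UserWarning, match="constant"):
            fit, _ = cox_multivariate(cov, t, formula="clinical")
        assert "grade" not in fit.params_.index


def test_full_pipeline_recovers_planted_subgroups():
    """End-to-end on CRLFs: screening, K-means, SVM transfer, evaluation."""
    rng = np.random.default_rng(0)
    n = 240
    group = np.repeat([0, 1], n // 2)
    lfs = rng.normal(size=(n, 12))
    lfs[:, 0] += group * 3.0  # survival-linked, separates the groups
    t = weibull_table(group * np.log(3.0), seed=1, censoring=0.3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_survival_pipeline(lfs, t, seed=0, K=2)
    assert res.metrics["logrank_p_test"] < 0.05
    assert res.metrics["cindex_combined_test"] > res.metrics["cindex_clinical_test"]
    assert 0.0 <= res.metrics["brier_combined_test"] <= 1.0
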