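"""Planted-structure guarantees of the synthetic-data generator."""

import numpy as np
import pytest
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import cross_val_score

from omicsvae.synthetic import (BlockSpec, SurvivalSpec, SyntheticSpec,
                                generate_multiomics, generate_survival)


def make_spec(**overrides):
    base = dict(
        n_samples=200, latent_dim_true=6, n_classes=4,
        class_proportions=(0.25,) * 4,
        block_specs=[BlockSpec("cnv", 30),
                     BlockSpec("methylation", 30, n_chromosomes=3)],
        class_separation=3.0, seed=0)
    base.update(overrides)
    return SyntheticSpec(**base)


class TestSpecValidation:
    @pytest.mark.parametrize("overrides,msg", [
        (dict(class_proportions=(0.5, 0.5, 0.1, 0.1)), "sum to 1"),
        (dict(n_classes=3, class_proportions=(0.3, 0.3, 0.4)), "2 or 4"),
        (dict(class_separation=-1.0), "separation"),
        (dict(block_specs=[BlockSpec("methylation", 2, n_chromosomes=5)]),
         "n_chromosomes"),
        (dict(survival=SurvivalSpec(censoring_rate=1.0)), "censoring_rate"),
    ])
    def test_invalid_specs_name_the_field(self, overrides, msg):
        with pytest.raises(ValueError, match=msg):
            make_spec(**overrides)


class TestGenerateMultiomics:
    def test_zero_samples_yields_empty_dataset(self):
        ds, truth = generate_multiomics(make_spec(n_samples=0))
        assert all(b.values.shape == (0, b.n_features) for b in ds.blocks)
        assert truth.true_latents.shape == (0, 6)
        assert len(truth.class_labels) == 0

    def test_identical_seed_gives_bit_identical_output(self):
        ds1, t1 = generate_multiomics(make_spec(seed=5))
        ds2, t2 = generate_multiomics(make_spec(seed=5))
        for b1, b2 in zip(ds1.blocks, ds2.blocks):
            np.testing.assert_array_equal(b1.values, b2.values)
        np.testing.assert_array_equal(t1.true_latents, t2.true_latents)

    def test_different_seed_differs(self):
        ds1, _ = generate_multiomics(make_spec(seed=5))
        ds2, _ = generate_multiomics(make_spec(seed=6))
        assert not np.array_equal(ds1.blocks[0].values, ds2.blocks[0].values)

    def test_class_counts_within_binomial_99_band(self):
        spec = make_spec(n_samples=400, seed=1)
        _, truth = generate_multiomics(spec)
        counts = np.bincount(truth.class_labels, minlength=4)
        lo, hi = stats.binom.ppf([0.005, 0.995], 400, 0.25)
        assert np.all(counts >= lo) and np.all(counts <= hi)

    def test_proportions_converge_at_large_n(self):
        spec = make_spec(n_samples=2000, class_proportions=(0.1, 0.2, 0.3, 0.4),
                         seed=2)
        _, truth = generate_multiomics(spec)
        freqs = np.bincount(truth.class_labels, minlength=4) / 2000
        np.testing.assert_allclose(freqs, [0.1, 0.2, 0.3, 0.4], atol=0.03)

    def test_methylation_in_open_unit_interval_with_chromosomes(self):
        ds, _ = generate_multiomics(make_spec())
        meth = next(b for b in ds.blocks if b.modality == "methylation")
        assert meth.values.min() > 0 and meth.values.max() < 1
        assert len(set(meth.chromosome_of.values())) == 3

    def test_cnv_unbounded_exercises_normalization(self):
        ds, _ = generate_multiomics(make_spec())
        cnv = next(b for b in ds.blocks if b.modality == "cnv")
        assert cnv.values.min() < 0 or cnv.values.max() > 1

    def test_zero_separation_gives_chance_level_latent_classifier(self):
        spec = make_spec(n_samples=400, class_separation=0.0, seed=3)
        _, truth = generate_multiomics(spec)
        acc = cross_val_score(LogisticRegression(max_iter=200),
                              truth.true_latents, truth.class_labels, cv=5).mean()
        assert acc == pytest.approx(0.25, abs=0.1)

    def test_high_separation_gives_separable_latents(self):
        _, truth = generate_multiomics(
            make_spec(n_samples=400, class_separation=6.0, seed=3))
        acc = cross_val_score(LogisticRegression(max_iter=200),
                              truth.true_latents, truth.class_labels, cv=5).mean()
        assert acc > 0.95

    def test_risk_scores_are_latents_dot_hazard_coefficients(self):
        coefs = np.array([1.0, -0.5, 0, 0, 0, 0.25])
        spec = make_spec(survival=SurvivalSpec(hazard_coefficients=coefs))
        _, truth = generate_multiomics(spec)
        np.testing.assert_allclose(truth.risk_scores, truth.true_latents @ coefs)


class TestGenerateSurvival:
    def test_zero_censoring_rate_gives_all_events(self):
        spec = make_spec(survival=SurvivalSpec(censoring_rate=0.0))
        _, truth = generate_multiomics(spec)
        table = generate_survival(truth, spec)
        assert (table.event == 1).all()

    def test_censoring_rate_approximately_achieved(self):
        spec = make_spec(n_samples=500, survival=SurvivalSpec(censoring_rate=0.4),
                         seed=4)
        _, truth = generate_multiomics(spec)
        table = generate_survival(truth, spec)
        assert np.mean(table.event == 0) == pytest.approx(0.4, abs=0.05)

    def test_null_hazard_times_uncorrelated_with_risk(self):
        spec = make_spec(n_samples=500, seed=5,
                         survival=SurvivalSpec(hazard_coefficients=np.zeros(6),
                                               censoring_rate=0.0))
        _, truth = generate_multiomics(spec)
        table = generate_survival(truth, spec)
        tau = stats.kendalltau(truth.true_latents[:, 0], table.time).statistic
        assert abs(tau) < 0.1

    def test_positive_hazard_entry_shortens_event_times(self):
        coefs = np.zeros(6)
        coefs[0] = 1.5
        spec = make_spec(n_samples=500, class_separation=0.0, seed=6,
                         survival=SurvivalSpec(hazard_coefficients=coefs,
                                               censoring_rate=0.0))
        _, truth = generate_multiomics(spec)
        table = generate_survival(truth, spec)
        tau = stats.kendalltau(truth.true_latents[:, 0], table.time).statistic
        assert tau < -0.2

    def test_hazard_coefficient_shape_checked(self):
        spec = make_spec()
        _, truth = generate_multiomics(spec)
        spec.survival.hazard_coefficients = np.ones(3)
        with pytest.raises(ValueError, match="length"):
            generate_survival(truth, spec)

    def test_clinical_covariates_present_and_ordinal(self):
        spec = make_spec()
        _, truth = generate_multiomics(spec)
        table = generate_survival(truth, spec)
        assert set(table.data["stage"]).issubset({1, 2, 3, 4})
        assert set(table.data["grade"]).issubset({1, 2, 3})
        assert table.data["age"].between(30, 90).all()


def test_univariate_cox_recovers_planted_coefficient():
    """Parameter recovery: planted log-hazard slope 1.0 within 2 SE at n=500."""
    from omicsvae.benchmarks import cox_coefficient_recovery

    res = cox_coefficient_recovery(seed=0)
    assert res["estimated_coefficient"] == pytest.approx(1.0, abs=0.2)
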