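"""Architecture contracts, training behavior and latent extraction."""

import numpy as np
import pytest

from omicsvae.autodiff import Tensor
from omicsvae import models
from omicsvae.models import (BlockSchema, ModelSpec, TrainedModel, build_model,
                             extract_latent, reparameterize, train)


class TestArchitecture:
    def test_mono_mrna_widths_match_design(self):
        spec = ModelSpec(latent_dim=128, seed=0)
        model = build_model(spec, [BlockSchema("mrna", 12_043)])
        desc = model.describe_architecture()
        assert desc["blocks"]["mrna"]["widths"] == [12_043, 2048, 1024]
        assert desc["fused_width"] == 512
        assert desc["latent_dim"] == 128

    def test_methylation_has_one_branch_per_chromosome(self):
        chroms = [(f"chr{i}", [2 * i, 2 * i + 1]) for i in range(5)]
        spec = ModelSpec(latent_dim=4, hidden_widths=(16, 8), chromosome_width=6,
                         fused_width=8, seed=0)
        model = build_model(spec, [BlockSchema("methylation", 10, chroms)])
        desc = model.describe_architecture()
        assert desc["blocks"]["methylation"]["branches"] == 5
        assert desc["blocks"]["methylation"]["branch_width"] == 6

    def test_classifier_head_widths(self):
        spec = ModelSpec(latent_dim=128, beta=1.0, n_classes=4, seed=0)
        model = build_model(spec, [BlockSchema("mrna", 500)])
        assert model.describe_architecture()["classifier"] == [128, 64, 4]

    def test_beta_zero_builds_no_classifier(self):
        spec = ModelSpec(latent_dim=8, hidden_widths=(16, 8), fused_width=8, seed=0)
        model = build_model(spec, [BlockSchema("cnv", 30)])
        assert model.network.cls_out is None
        with pytest.raises(ValueError, match="beta = 0"):
            model.network.classify_logits(Tensor(np.zeros((2, 8))))

    def test_methylation_without_partition_rejected(self):
        spec = ModelSpec(latent_dim=4, hidden_widths=(8, 4), fused_width=4, seed=0)
        with pytest.raises(ValueError, match="chromosome"):
            build_model(spec, [BlockSchema("methylation", 10)])

    def test_latent_must_be_smaller_than_input(self):
        spec = ModelSpec(latent_dim=64, hidden_widths=(8, 4), fused_width=4, seed=0)
        with pytest.raises(ValueError, match="smaller"):
            build_model(spec, [BlockSchema("cnv", 10)])

    def test_decoder_outputs_in_unit_interval(self, trained_tiny_model, tiny_inputs):
        net = trained_tiny_model.network
        net.eval()
        mu, _ = net.encode([Tensor(b) for b in tiny_inputs])
        recons = net.decode(mu)
        flat = np.concatenate(
            [r.data.ravel() for r in recons[1]] + [recons[0].data.ravel()])
        assert np.all(flat > 0) and np.all(flat < 1)


class TestReparameterize:
    def test_zero_epsilon_returns_mu(self):
        mu = np.array([[1.0, -2.0]])
        z = reparameterize(mu, np.ones_like(mu), np.zeros_like(mu))
        np.testing.assert_array_equal(z, mu)

    def test_forced_arithmetic(self):
        z = reparameterize(np.array([1.0]), np.array([2.0]), np.array([0.5]))
        np.testing.assert_allclose(z, [2.0])

    def test_sample_mean_converges_to_mu(self):
        rng = np.random.default_rng(0)
        mu, sigma = 0.3, 1.7
        n = 100_000
        z = reparameterize(np.full(n, mu), np.full(n, sigma), rng.standard_normal(n))
        assert abs(z.mean() - mu) < 3 * sigma / np.sqrt(n)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            reparameterize(np.zeros(2), np.array([1.0, -1.0]), np.zeros(2))


class TestTraining:
    def test_zero_epochs_leaves_parameters_and_history_empty(self, tiny_schemas,
                                                             tiny_inputs):
        spec = ModelSpec(latent_dim=3, hidden_widths=(8, 6), chromosome_width=4,
                         fused_width=5, epochs=0, seed=1)
        model = build_model(spec, tiny_schemas)
        before = [p.data.copy() for p in model.network.parameters()]
        train(model, tiny_inputs)
        assert model.history == []
        for p, b in zip(model.network.parameters(), before):
            np.testing.assert_array_equal(p.data, b)

    def test_unsupervised_run_ignores_labels_entirely(self, tiny_schemas, tiny_inputs):
        spec = ModelSpec(latent_dim=3, hidden_widths=(8, 6), chromosome_width=4,
                         fused_width=5, epochs=2, batch_size=6, seed=1,
                         loss_kind="mmd", mmd_bandwidth=1.0)
        model = build_model(spec, tiny_schemas)
        train(model, tiny_inputs, labels=None)
        assert len(model.history) == 2
        assert all(h.classification == 0.0 for h in model.history)

    def test_supervised_without_labels_rejected(self, tiny_schemas, tiny_inputs):
        spec = ModelSpec(latent_dim=3, hidden_widths=(8, 6), chromosome_width=4,
                         fused_width=5, epochs=1, beta=1.0, n_classes=2, seed=1)
        model = build_model(spec, tiny_schemas)
        with pytest.raises(ValueError, match="label"):
            train(model, tiny_inputs)

    def test_same_seed_reproduces_identical_history(self, tiny_schemas, tiny_inputs):
        def run():
            spec = ModelSpec(latent_dim=3, hidden_widths=(8, 6), chromosome_width=4,
                             fused_width=5, epochs=3, batch_size=6, seed=11)
            model = build_model(spec, tiny_schemas)
            train(model, tiny_inputs)
            return [h.total for h in model.history]

        assert run() == run()

    def test_supervised_training_reduces_classification_loss(self, trained_tiny_model):
        hist = trained_tiny_model.history
        assert hist[-1].classification < hist[0].classification

    def test_history_records_loss_breakdown_components(self, trained_tiny_model):
        h = trained_tiny_model.history[0]
        assert h.recon_methylation > 0
        assert len(h.recon_other) == 1 and h.recon_other[0] > 0
        assert h.total == pytest.approx(
            h.recon_methylation + h.recon_other[0] + h.regularizer
            + h.classification, rel=1e-9)


class TestLatentExtraction:
    def test_mean_extraction_is_deterministic(self, trained_tiny_model, tiny_inputs):
        a = extract_latent(trained_tiny_model, tiny_inputs, use_mean=True)
        b = extract_latent(trained_tiny_model, tiny_inputs, use_mean=True)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (12, 3)

    def test_sampling_is_seed_deterministic(self, trained_tiny_model, tiny_inputs):
        a = extract_latent(trained_tiny_model, tiny_inputs, use_mean=False, seed=5)
        b = extract_latent(trained_tiny_model, tiny_inputs, use_mean=False, seed=5)
        c = extract_latent(trained_tiny_model, tiny_inputs, use_mean=False, seed=6)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_mean_of_many_samples_approaches_mu(self, trained_tiny_model, tiny_inputs):
        mu = extract_latent(trained_tiny_model, tiny_inputs, use_mean=True)
        codes = models.encode_dataset(trained_tiny_model, tiny_inputs)
        draws = np.stack([
            extract_latent(trained_tiny_model, tiny_inputs, use_mean=False, seed=s)
            for s in range(400)
        ])
        tol = 4 * codes.sigma / np.sqrt(400)
        assert np.all(np.abs(draws.mean(axis=0) - mu) < tol + 1e-9)

    def test_schema_mismatch_reports_offending_block(self, trained_tiny_model,
                                                     tiny_inputs):
        bad = [tiny_inputs[0], tiny_inputs[1][:, :3]]
        with pytest.raises(ValueError, match="methylation"):
            extract_latent(trained_tiny_model, bad)


def test_checkpoint_roundtrip_preserves_inference(tmp_path, trained_tiny_model,
                                                  tiny_inputs):
    path = tmp_path / "model.npz"
    trained_tiny_model.save(path)
    reloaded = TrainedModel.load(path)
    a = extract_latent(trained_tiny_model, tiny_inputs)
    b = extract_latent(reloaded, tiny_inputs)
    np.testing.assert_allclose(a, b, atol=1e-12)
    assert len(reloaded.history) == len(trained_tiny_model.history)


def test_gradient_check_full_objective(tiny_schemas, tiny_inputs):
    """Analytic gradients of the total loss match central differences."""
    spec = ModelSpec(latent_dim=3, hidden_widths=(8, 6), chromosome_width=4,
                     fused_width=5, loss_kind="elbo", beta=1.0, n_classes=2,
                     seed=3, epochs=1, batch_size=12)
    model = build_model(spec, tiny_schemas)
    net = model.network
    labels = np.tile([0, 1], 6)

    def loss_value():
        rng = np.random.default_rng(99)
        loss, _ = models._batch_loss(net, [Tensor(b) for b in tiny_inputs],
                                     labels, spec, rng)
        return loss

    net.train()
    loss = loss_value()
    net.zero_grad()
    loss.backward()
    rng_pick = np.random.default_rng(1)
    for p in net.parameters():
        flat, gflat = p.data.ravel(), p.grad.ravel()
        for i in rng_pick.choice(flat.size, size=min(3, flat.size), replace=False):
            h = 1e-6 * max(1.0, abs(flat[i]))
            old = flat[i]
            flat[i] = old + h
            fp = float(loss_value().data)
            flat[i] = old - h
            fm = float(loss_value().data)
            flat[i] = old
            num = (fp - fm) / (2 * h)
            assert num == pytest.approx(gflat[i], rel=1e-4, abs=1e-7)
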