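"""VAE contracts: shapes, loss closed forms, reparameterization, split plans,
determinism, training sanity, perturb-and-decode, unit bookkeeping.

Cheap tests use a miniature input shape (64 x 2/6); training-dependent checks
reuse the session-scoped reduced model from conftest.
"""

import numpy as np
import pytest

from gaitvae.vae import (LatentCode, VaeConfig, build_model, encode,
                         make_split_plan, perturb_and_decode, reconstruct,
                         reconstruction_error_by_group, reconstruction_mae_units,
                         train, vae_loss)

TINY = dict(input_shape=(64, 6), filters=(4, 8, 16), latent_dim=5, seed=0)


def tiny_model(**kw):
    return build_model(VaeConfig(**{**TINY, **kw}))


class TestArchitecture:
    def test_forward_shapes(self):
        m = build_model(VaeConfig(seed=1))
        x = np.zeros((2, 512, 6), dtype=np.float32)
        x_hat, mu, logvar, z, _ = m.forward(x)
        assert x_hat.shape == (2, 512, 6)
        assert mu.shape == logvar.shape == z.shape == (2, 12)
        assert m.config.encoder_layer_nodes == (256, 128, 64)

    def test_output_within_tanh_range(self):
        m = tiny_model()
        x_hat, *_ = m.forward(np.random.default_rng(0).normal(size=(3, 64, 6)))
        assert np.all(np.abs(x_hat) <= 1.0)

    def test_reparameterization(self):
        m = tiny_model()
        x = np.random.default_rng(1).normal(size=(4, 64, 6)).astype(np.float32)
        _, mu, logvar, z0, _ = m.forward(x, eps=np.zeros((4, 5)))
        np.testing.assert_array_equal(z0, mu)
        eps = np.ones((4, 5), dtype=np.float32)
        _, mu, logvar, z1, _ = m.forward(x, eps=eps)
        np.testing.assert_allclose(z1, mu + np.exp(0.5 * logvar), rtol=1e-6)

    def test_untrained_forward_deterministic(self):
        a = tiny_model(seed=3)
        b = tiny_model(seed=3)
        x = np.random.default_rng(2).normal(size=(2, 64, 6))
        np.testing.assert_array_equal(a.forward(x)[0], b.forward(x)[0])

    def test_bad_shape_config_rejected(self):
        with pytest.raises(ValueError):
            VaeConfig(input_shape=(100, 6))
        with pytest.raises(ValueError):
            VaeConfig(latent_dim=0)

    def test_save_load_roundtrip(self, tmp_path):
        m = tiny_model(seed=9)
        x = np.random.default_rng(0).normal(size=(2, 64, 6))
        path = tmp_path / "model.npz"
        m.save(path)
        from gaitvae.vae import VaeModel
        m2 = VaeModel.load(path)
        np.testing.assert_array_equal(m.forward(x)[0], m2.forward(x)[0])


class TestLoss:
    def test_identity_zero(self):
        x = np.random.default_rng(0).normal(size=(3, 8, 2))
        lb = vae_loss(x, x, np.zeros((3, 4)), np.zeros((3, 4)))
        assert lb.mse == 0.0 and lb.kl == 0.0 and lb.total == 0.0

    def test_standard_normal_posterior_kl_zero(self):
        x = np.random.default_rng(1).normal(size=(2, 8, 2))
        lb = vae_loss(x, x + 1.0, np.zeros((2, 4)), np.zeros((2, 4)))
        assert lb.kl == 0.0
        assert lb.mse == pytest.approx(1.0)

    def test_kl_closed_form_half(self):
        mu = np.zeros((1, 12))
        mu[0, 0] = 1.0
        lb = vae_loss(np.zeros((1, 4, 6)), np.zeros((1, 4, 6)), mu, np.zeros((1, 12)))
        assert lb.kl == pytest.approx(0.5)

    def test_kl_nonnegative_property(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            mu = rng.normal(size=(4, 12))
            logvar = rng.normal(size=(4, 12))
            lb = vae_loss(np.zeros((4, 4, 6)), np.zeros((4, 4, 6)), mu, logvar,
                          kl_weight=0.7)
            assert lb.kl >= 0.0
            assert lb.total == pytest.approx(lb.mse + 0.7 * lb.kl)


class TestSplitPlan:
    def test_ten_subjects_one_per_fold(self):
        ids = [f"s{i}" for i in range(10)]
        plans = make_split_plan(ids, seed=0)
        assert len(plans) == 10
        for p in plans:
            assert len(p.validation_subjects) == 1
        assert sorted(v for p in plans for v in p.validation_subjects) == sorted(ids)

    def test_validation_union_no_repeats_107(self):
        ids = [f"s{i}" for i in range(107)]
        plans = make_split_plan(ids, seed=1)
        sizes = [len(p.validation_subjects) for p in plans]
        assert set(sizes) <= {10, 11}
        flat = [v for p in plans for v in p.validation_subjects]
        assert sorted(flat) == sorted(ids)

    def test_no_leakage_and_ratio(self):
        ids = [f"s{i}" for i in range(50)]
        for p in make_split_plan(ids, seed=2):
            assert not set(p.train_subjects) & set(p.test_subjects)
            assert not set(p.train_subjects) & set(p.validation_subjects)
            assert not set(p.test_subjects) & set(p.validation_subjects)
            assert len(p.train_subjects) == pytest.approx(35, abs=1)

    def test_leakage_rejected(self):
        from gaitvae.vae import SplitPlan
        with pytest.raises(ValueError, match="leakage"):
            SplitPlan(0, ("a", "b"), ("b",), ("c",))


class TestTrainingTiny:
    def test_loss_decreases_and_is_reproducible(self):
        rng = np.random.default_rng(0)
        x = np.tanh(rng.normal(size=(128, 64, 6)) * 0.3).astype(np.float32)
        cfg = VaeConfig(**{**TINY, "max_epochs": 5, "batch_size": 32, "seed": 4})
        m, rep = train(build_model(cfg), x[:96], x[96:], cfg)
        assert rep.train_mse[-1] < rep.train_mse[0]
        m2, rep2 = train(build_model(cfg), x[:96], x[96:], cfg)
        assert rep2.train_total[-1] == pytest.approx(rep.train_total[-1], abs=1e-6)

    def test_empty_training_set_rejected(self):
        cfg = VaeConfig(**{**TINY, "max_epochs": 1})
        with pytest.raises(ValueError, match="empty training set"):
            train(build_model(cfg), np.empty((0, 64, 6)), np.empty((0, 64, 6)), cfg)


class TestInference:
    def test_encode_deterministic(self):
        m = tiny_model()
        x = np.random.default_rng(3).normal(size=(64, 6))
        np.testing.assert_array_equal(encode(m, x).mu, encode(m, x).mu)
        assert encode(m, x).score is encode(m, x).mu or \
            np.array_equal(encode(m, x).score, encode(m, x).mu)

    def test_perturb_zero_delta_equals_reconstruct(self):
        m = tiny_model()
        x = np.random.default_rng(4).normal(size=(64, 6))
        code = encode(m, x)
        np.testing.assert_allclose(perturb_and_decode(m, code, dim=2, delta=0.0),
                                   reconstruct(m, x), atol=1e-7)

    def test_perturb_changes_output(self):
        m = tiny_model()
        x = np.random.default_rng(4).normal(size=(64, 6))
        code = encode(m, x)
        out = perturb_and_decode(m, code, dim=0, delta=3.0)
        assert not np.allclose(out, reconstruct(m, x))

    def test_mae_unit_bookkeeping(self):
        x = np.zeros((1, 8, 6))
        x_hat = np.full((1, 8, 6), 0.1)
        mae = reconstruction_mae_units(x, x_hat)
        assert mae["mae_normalized"] == pytest.approx(0.1)
        assert mae["mae_acc_g"] == pytest.approx(0.8)  # 0.1 x 8 g
        assert mae["mae_gyro_dps"] == pytest.approx(50.0)  # 0.1 x 500 deg/s

    def test_group_error_table_contract(self):
        m = tiny_model()
        x = np.random.default_rng(6).normal(size=(10, 64, 6)) * 0.2
        table, summary = reconstruction_error_by_group(
            m, x, ["a"] * 5 + ["b"] * 5, z_normalize=True)
        assert len(table) == 10
        assert set(summary.index) == {"a", "b"}
        assert table.groupby("group")["mse_z"].mean().abs().max() < 1e-12
        with pytest.raises(ValueError, match="empty group|match"):
            reconstruction_error_by_group(m, x, ["a"] * 9)


class TestTrainedModel:
    """Checks on the session-scoped reduced model (trained once)."""

    def test_reconstruction_better_than_mean_predictor(self, trained_vae):
        x = trained_vae["x_test"]
        m = trained_vae["model"]
        x_hat = reconstruct(m, x[:200])
        mse = np.mean((x[:200] - x_hat) ** 2)
        baseline = np.mean((x[:200] - x[:200].mean(axis=0)) ** 2)
        assert mse < 0.5 * baseline

    def test_kl_active_not_collapsed(self, trained_vae):
        rep = trained_vae["report"]
        assert 0.1 < rep.train_kl[-1] < 30.0

    def test_latent_scores_approximately_standard_normal(self, trained_vae):
        mu = encode(trained_vae["model"], trained_vae["x_train"]).mu
        assert np.abs(mu.mean(axis=0)).max() < 0.3
        sd = mu.std(axis=0)
        assert sd.min() >= 0.5 and sd.max() <= 1.5

    def test_early_stopping_restores_best(self, trained_vae):
        rep = trained_vae["report"]
        assert rep.best_epoch >= 0
        assert rep.objective[rep.best_epoch] == pytest.approx(min(rep.objective))
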