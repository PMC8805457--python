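"""Autoencoder components, adversarial losses, and the joint training loop."""

import numpy as np
import pytest

from seizalign import (AaeParams, KernelConfig, adversarial_step,
                       reconstruction_loss, sample_prior, total_objective,
                       train)
from seizalign.aae import _forward, _init_mlp, load_model, save_model
from seizalign.autodiff import Adam, Tensor


def _blob_data(rng, n=120, d=20, shift=2.0, n_domains=2):
    """Separable two-class blobs split across synthetic domains."""
    data = {}
    for k in range(n_domains):
        X0 = rng.standard_normal((n // 2, d)) + k * 0.5
        X1 = rng.standard_normal((n // 2, d)) + k * 0.5
        X1[:, 0] += shift
        X = np.vstack([X0, X1])
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
        data[f"dom{k}"] = (X, y)
    return data


SMALL = AaeParams(latent_dim=4, encoder_widths=(16,), disc_widths=(8,),
                  epochs=5, batch_per_domain=16, seed=0,
                  lambdas=(0.01, 0.5, 0.5))


class TestEncodeDecode:
    def _model(self, rng):
        return train(_blob_data(rng), SMALL)

    def test_shapes_and_determinism(self, rng):
        m = self._model(rng)
        X = rng.standard_normal((7, 20))
        z = m.encode(X)
        assert z.shape == (7, 4)
        np.testing.assert_array_equal(z, m.encode(X))
        assert m.decode(z).shape == (7, 20)

    def test_shape_mismatch_rejected(self, rng):
        m = self._model(rng)
        with pytest.raises(ValueError, match="features"):
            m.encode(rng.standard_normal((3, 9)))
        with pytest.raises(ValueError, match="latent"):
            m.decode(rng.standard_normal((3, 9)))

    def test_zero_weights_give_zero_latents(self):
        rng = np.random.default_rng(0)
        layers = _init_mlp(rng, [6, 5, 3])
        for w, b in layers:
            w.value[:] = 0.0
            b.value[:] = 0.0
        out = _forward(layers, Tensor(rng.standard_normal((4, 6))))
        np.testing.assert_array_equal(out.value, np.zeros((4, 3)))

    def test_single_sample_overfit(self):
        """An autoencoder trained on one sample reconstructs it closely."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal((1, 12))
        enc = _init_mlp(rng, [12, 16, 4])
        dec = _init_mlp(rng, [4, 16, 12])
        params = [t for l in (enc, dec) for pair in l for t in pair]
        opt = Adam(params, lr=1e-2)
        for _ in range(2000):
            opt.zero_grad()
            xt = _forward(dec, _forward(enc, Tensor(x)))
            reconstruction_loss(Tensor(x), xt).backward()
            opt.step()
        err = np.abs(_forward(dec, _forward(enc, Tensor(x))).value - x)
        assert err.max() < 1e-2


class TestReconstructionLoss:
    def test_zero_at_identity(self, rng):
        x = rng.standard_normal((3, 8))
        assert reconstruction_loss(x, x.copy()) == 0.0

    def test_all_ones_gives_pixel_count(self):
        x = np.zeros((4, 30))
        assert reconstruction_loss(x, np.ones_like(x)) == pytest.approx(30.0)

    def test_matches_loop_sum(self, rng):
        x = rng.standard_normal((5, 7))
        xt = rng.standard_normal((5, 7))
        loop = sum((xt[i, j] - x[i, j]) ** 2 for i in range(5)
                   for j in range(7)) / 5
        assert reconstruction_loss(x, xt) == pytest.approx(loop, abs=1e-10)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            reconstruction_loss(rng.standard_normal((2, 3)),
                                rng.standard_normal((3, 2)))


class TestPriorSampler:
    def test_moments_match_laplace(self):
        z = sample_prior(100_000, 1, eta=1.0, rng=0)
        assert -0.02 < z.mean() < 0.02
        assert 1.9 < z.var() < 2.1            # Var = 2 eta^2

    def test_scale_two_variance(self):
        z = sample_prior(100_000, 1, eta=2.0, rng=1)
        assert abs(z.var() - 8.0) <= 0.4      # within 5%

    def test_reproducible_and_shaped(self):
        a = sample_prior(10, 3, 1.0, rng=42)
        b = sample_prior(10, 3, 1.0, rng=42)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (10, 3)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            sample_prior(0, 3, 1.0, rng=0)
        with pytest.raises(ValueError):
            sample_prior(5, 3, -1.0, rng=0)


class TestAdversarialStep:
    def _half_disc(self):
        rng = np.random.default_rng(0)
        disc = _init_mlp(rng, [4, 8, 1])
        for w, b in disc:
            w.value[:] = 0.0
            b.value[:] = 0.0                   # logits 0 -> D = 1/2
        return disc

    def test_closed_form_at_half(self, rng):
        disc = self._half_disc()
        z = rng.standard_normal((16, 4))
        d_loss, g_loss = adversarial_step(z, rng.standard_normal((16, 4)), disc)
        assert float(d_loss.value) == pytest.approx(2 * np.log(2), abs=1e-12)
        assert float(g_loss.value) == pytest.approx(np.log(2), abs=1e-12)

    def test_perfect_discriminator_limit(self):
        # linear disc scoring 5*z0: reals at z0=+10 -> D ~ 1,
        # fakes at z0=-10 -> D ~ 0, so d_loss -> 0
        rng = np.random.default_rng(0)
        disc = _init_mlp(rng, [4, 1])
        disc[0][0].value[:] = 0.0
        disc[0][0].value[0, 0] = 5.0
        disc[0][1].value[:] = 0.0
        z_f = np.full((8, 4), -10.0)
        z_r = np.full((8, 4), 10.0)
        d_loss, _ = adversarial_step(z_f, z_r, disc)
        assert float(d_loss.value) < 1e-6

    def test_discriminator_trains_to_chance_on_prior_vs_prior(self):
        rng = np.random.default_rng(0)
        disc = _init_mlp(rng, [4, 16, 1])
        opt = Adam([t for pair in disc for t in pair], lr=1e-3)
        for _ in range(500):
            z_r = sample_prior(32, 4, 1.0, rng)
            z_f = sample_prior(32, 4, 1.0, rng)
            opt.zero_grad()
            d_loss, _ = adversarial_step(z_f, z_r, disc)
            d_loss.backward()
            opt.step()
        probe = sample_prior(1000, 4, 1.0, rng)
        from seizalign.aae import _forward_np
        d = 1 / (1 + np.exp(-_forward_np(disc, probe)))
        assert 0.45 < d.mean() < 0.55


class TestObjectiveAndTraining:
    def test_total_objective_intracranial_weights(self):
        assert total_objective(1, 1, 1, 1, (1.05, 120.0, 0.7)) == \
            pytest.approx(122.75)

    def test_all_zero_lambdas_returns_classification_loss(self):
        assert total_objective(9.0, 9.0, 9.0, 3.5, (0, 0, 0)) == 3.5

    def test_scalp_weight_set_accepted(self):
        p = AaeParams(lambdas=(1.0, 110.0, 0.6))
        assert p.lambdas == (1.0, 110.0, 0.6)

    def test_same_seed_identical_weights(self, rng):
        data = _blob_data(rng)
        m1 = train(data, SMALL)
        m2 = train(data, SMALL)
        for l1, l2 in zip(m1.encoder, m2.encoder):
            np.testing.assert_array_equal(l1[0].value, l2[0].value)
        assert m1.history["total"] == m2.history["total"]

    def test_history_lengths_and_finiteness(self, rng):
        m = train(_blob_data(rng), SMALL)
        for key in ("Lrec", "Jadv", "Rdis", "Lcla"):
            assert len(m.history[key]) == SMALL.epochs
            assert np.all(np.isfinite(m.history[key]))
            assert np.all(np.asarray(m.history[key]) >= 0)

    def test_ablation_records_but_does_not_backprop(self, rng):
        p = AaeParams(latent_dim=4, encoder_widths=(16,), disc_widths=(8,),
                      epochs=8, batch_per_domain=16, seed=0,
                      lambdas=(0.05, 0.0, 0.0))
        m = train(_blob_data(rng), p)
        assert len(m.history["Jadv"]) == p.epochs        # recorded
        assert len(m.history["Rdis"]) == p.epochs
        assert m.history["Lrec"][-1] < m.history["Lrec"][0]
        # discriminator untouched: optimizer never stepped its weights
        rng2 = np.random.default_rng(p.seed)
        enc0 = _init_mlp(rng2, [20, 16, 4])
        dec0 = _init_mlp(rng2, [4, 16, 20])
        disc0 = _init_mlp(rng2, [4, 8, 1])
        for (w, b), (w0, b0) in zip(m.discriminator, disc0):
            np.testing.assert_array_equal(w.value, w0.value)

    def test_domain_missing_class_rejected(self, rng):
        X = rng.standard_normal((10, 5))
        with pytest.raises(ValueError, match="lacks"):
            train({"a": (X, np.zeros(10, dtype=int))}, SMALL)

    def test_checkpoint_round_trip(self, rng, tmp_path):
        m = train(_blob_data(rng), SMALL)
        save_model(m, tmp_path / "model.npz")
        back = load_model(tmp_path / "model.npz")
        X = rng.standard_normal((5, 20))
        np.testing.assert_array_equal(back.encode(X), m.encode(X))
        assert back.params == m.params
        assert back.history["Lcla"] == pytest.approx(m.history["Lcla"])
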