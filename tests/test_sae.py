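"""Autoencoder training, reconstruction loss, encoding and latent fusion."""

import numpy as np
import pytest

from wsifuse.sae import (AEConfig, build_autoencoder, encode, fuse,
                         load_autoencoder, reconstruction_loss,
                         save_autoencoder, train_autoencoder)


def _identity_ae(d, rng):
    """Linear AE whose decoder inverts the (orthonormal) encoder exactly."""
    model = build_autoencoder(d, AEConfig(activation="identity"), seed=0)
    q, _ = np.linalg.qr(rng.normal(size=(d, d)))
    model.encoder.layers[0].params[0][...] = q.astype(np.float32)
    model.encoder.layers[0].params[1][...] = 0
    model.decoder.layers[0].params[0][...] = q.T.astype(np.float32)
    model.decoder.layers[0].params[1][...] = 0
    model.trained = True
    return model


class TestReconstructionLoss:
    def test_identity_autoencoder_has_zero_loss(self, rng):
        model = _identity_ae(16, rng)
        x = rng.normal(size=(32, 16)).astype(np.float32)
        assert reconstruction_loss([x], [model]) < 1e-9

    def test_zero_inputs_zero_bias_gives_zero_loss(self, rng):
        model = build_autoencoder(8, AEConfig(), seed=1)
        x = np.zeros((4, 8), np.float32)
        model.trained = True
        assert reconstruction_loss([x], [model]) == 0.0

    def test_unit_residual_gives_loss_one(self):
        d = 8
        model = build_autoencoder(d, AEConfig(activation="identity"), seed=0)
        model.encoder.layers[0].params[0][...] = np.eye(d, dtype=np.float32)
        model.encoder.layers[0].params[1][...] = 0
        model.decoder.layers[0].params[0][...] = np.eye(d, dtype=np.float32)
        bias = np.zeros(d, np.float32)
        bias[0] = 1.0  # dhat - d = (1, 0, ..., 0)
        model.decoder.layers[0].params[1][...] = bias
        x = np.zeros((5, d), np.float32)
        assert reconstruction_loss([x], [model]) == pytest.approx(1.0)

    def test_dimension_mismatch_names_descriptor(self, rng):
        model = build_autoencoder(8, AEConfig(), seed=0, descriptor="hog")
        with pytest.raises(ValueError, match="hog"):
            reconstruction_loss({"hog": rng.normal(size=(4, 9))}, {"hog": model})


class TestTrainAutoencoder:
    def test_low_rank_data_trains_to_small_fraction_of_initial_loss(self, rng):
        factors = rng.normal(size=(512, 5)) @ rng.normal(size=(5, 64))
        x = factors.astype(np.float32)
        config = AEConfig(epochs=200, learning_rate=1e-3, batch_size=64)
        model = train_autoencoder(x, config, seed=0)
        assert model.history[-1] < 0.1 * model.history[0]

    def test_linear_ae_reaches_pca_residual(self, rng):
        # rank-4 structure plus isotropic noise, zero-mean
        x = (rng.normal(size=(256, 4)) @ rng.normal(size=(4, 32))
             + rng.normal(0, 0.5, (256, 32))).astype(np.float32)
        x -= x.mean(axis=0)
        k = 4
        config = AEConfig(epochs=500, learning_rate=3e-3, batch_size=64,
                          activation="identity", latent_override=k)
        model = train_autoencoder(x, config, seed=0)
        recon = model.reconstruct(x)
        ae_err = float(((recon - x) ** 2).sum(axis=1).mean())
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(x.T, bias=True)))[::-1]
        pca_err = float(eigvals[k:].sum())  # closed-form PCA-k residual
        assert ae_err <= 1.05 * pca_err

    def test_double_mode_doubles_latent_dimension(self, rng):
        x = rng.normal(size=(64, 64)).astype(np.float32)
        config = AEConfig(epochs=1, neuron_mode="double", batch_size=32)
        model = train_autoencoder(x, config, seed=0)
        assert model.latent_dim == 128
        assert encode(model, x).shape == (64, 128)

    def test_constant_dataset_memorized(self, rng):
        x = np.tile(rng.normal(size=(1, 16)).astype(np.float32), (64, 1))
        config = AEConfig(epochs=300, learning_rate=1e-2, batch_size=32)
        model = train_autoencoder(x, config, seed=0)
        assert model.history[-1] < 1e-3

    def test_smoothed_loss_is_nonincreasing_at_default_learning_rate(self, rng):
        factors = rng.normal(size=(256, 5)) @ rng.normal(size=(5, 64))
        x = factors.astype(np.float32)
        config = AEConfig(epochs=60, learning_rate=1e-4, batch_size=64)
        model = train_autoencoder(x, config, seed=0)
        history = np.asarray(model.history)
        smoothed = np.convolve(history, np.ones(10) / 10, mode="valid")
        assert (np.diff(smoothed) <= 1e-6 * smoothed[:-1] + 1e-12).all()

    def test_nonfinite_features_rejected(self):
        x = np.full((64, 8), np.nan, np.float32)
        with pytest.raises(ValueError, match="finite"):
            train_autoencoder(x, AEConfig(batch_size=32))


class TestEncode:
    def test_untrained_model_rejected(self, rng):
        model = build_autoencoder(8, AEConfig(), seed=0)
        with pytest.raises(RuntimeError, match="train"):
            encode(model, rng.normal(size=(4, 8)))

    def test_same_mode_preserves_dimension_and_order(self, rng):
        x = rng.normal(size=(64, 16)).astype(np.float32)
        model = train_autoencoder(x, AEConfig(epochs=2, batch_size=32), seed=0)
        z = encode(model, x)
        assert z.shape == (64, 16)
        perm = rng.permutation(64)
        assert np.allclose(encode(model, x[perm]), z[perm])

    def test_encoding_is_deterministic(self, rng):
        x = rng.normal(size=(64, 16)).astype(np.float32)
        model = train_autoencoder(x, AEConfig(epochs=2, batch_size=32), seed=0)
        assert np.array_equal(encode(model, x), encode(model, x))


class TestFuse:
    def test_reference_dims_fuse_to_5118_with_offsets(self, rng):
        latents = {"raw": rng.normal(size=(6, 4800)),
                   "hog": rng.normal(size=(6, 64)),
                   "lbp": rng.normal(size=(6, 254))}
        fused = fuse(latents)
        assert fused.dim == 5118
        assert fused.offsets == {"raw": (0, 4800), "hog": (4800, 4864),
                                 "lbp": (4864, 5118)}
        assert np.array_equal(fused.component("hog"), latents["hog"])

    def test_single_descriptor_fusion_is_identity(self, rng):
        z = rng.normal(size=(4, 10))
        fused = fuse({"raw": z})
        assert np.array_equal(fused.data, z)

    def test_row_permutation_commutes_with_fusion(self, rng):
        latents = {"raw": rng.normal(size=(8, 5)),
                   "hog": rng.normal(size=(8, 3))}
        perm = rng.permutation(8)
        fused = fuse(latents)
        fused_perm = fuse({k: v[perm] for k, v in latents.items()})
        assert np.array_equal(fused_perm.data, fused.data[perm])

    def test_batch_size_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="batch"):
            fuse({"raw": rng.normal(size=(4, 5)),
                  "hog": rng.normal(size=(5, 3))})


class TestCheckpoint:
    def test_autoencoder_roundtrip_preserves_encodings(self, rng, tmp_path):
        x = rng.normal(size=(64, 16)).astype(np.float32)
        model = train_autoencoder(x, AEConfig(epochs=2, batch_size=32), seed=0)
        path = tmp_path / "ae.h5"
        save_autoencoder(model, path)
        loaded = load_autoencoder(path)
        assert np.array_equal(encode(loaded, x), encode(model, x))
        assert loaded.history == model.history
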