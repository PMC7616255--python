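"""Network building blocks: shapes, determinism, modulation identities,
reparameterisation statistics, and checkpoint round-trips."""

import numpy as np
import pytest

from lesionsynth import autodiff as ad
from lesionsynth.autodiff import Tensor
from lesionsynth.model import (
    ConditionEmbedding,
    Critic,
    Encoder,
    LesionDecoder,
    MaskDecoder,
    NetworkConfig,
    StageModel,
    load_checkpoint,
    nearest_downsample,
    save_checkpoint,
)
from lesionsynth.nn import instance_norm

from conftest import toy_network


@pytest.fixture()
def cfg():
    return toy_network()


class TestEncoder:
    def test_latent_length_and_determinism_given_eps(self, cfg, rng):
        enc = Encoder(cfg, rng)
        x = Tensor(rng.uniform(size=(1, 3, 16, 16, 16)).astype(np.float32))
        eps = rng.standard_normal((3, cfg.latent_dim)).astype(np.float32)
        a = enc(x, eps=eps)
        b = enc(x, eps=eps)
        assert a.mu.shape == (3, cfg.latent_dim)
        assert np.array_equal(a.z.data, b.z.data)

    def test_finite_for_all_zero_input(self, cfg, rng):
        enc = Encoder(cfg, rng)
        x = Tensor(np.zeros((1, 2, 16, 16, 16), np.float32))
        lat = enc(x, rng=rng)
        assert np.isfinite(lat.mu.data).all() and np.isfinite(lat.logvar.data).all()

    def test_wrong_side_raises(self, cfg, rng):
        enc = Encoder(cfg, rng)
        with pytest.raises(ValueError, match="encoder expects"):
            enc(Tensor(np.zeros((1, 1, 8, 8, 8))), rng=rng)

    def test_reparameterisation_mean_converges_to_mu(self, cfg, rng):
        enc = Encoder(cfg, rng)
        x = Tensor(rng.uniform(size=(1, 1, 16, 16, 16)).astype(np.float32))
        n = 4000
        draws = []
        base = enc(x, eps=np.zeros((1, cfg.latent_dim), np.float32))
        sigma = np.exp(0.5 * base.logvar.data)
        for _ in range(n // 400):
            eps = rng.standard_normal((400, cfg.latent_dim)).astype(np.float32)
            z = base.mu.data + sigma * eps
            draws.append(z)
        zbar = np.concatenate(draws).mean(axis=0)
        tol = 3.0 * sigma[0] / np.sqrt(n)
        assert np.all(np.abs(zbar - base.mu.data[0]) < tol + 1e-6)


class TestDecoders:
    def test_mask_decoder_sigmoid_range_and_determinism(self, cfg, rng):
        dec = MaskDecoder(cfg, rng)
        z = Tensor(rng.standard_normal((2, cfg.latent_dim)).astype(np.float32))
        c = np.array([[0.4], [0.7]])
        out1, out2 = dec(z, c), dec(z, c)
        assert out1.shape == (1, 2, 16, 16, 16)
        assert np.all(out1.data > 0) and np.all(out1.data < 1)
        assert np.array_equal(out1.data, out2.data)

    def test_condition_length_mismatch_raises(self, cfg, rng):
        dec = MaskDecoder(cfg, rng)
        z = Tensor(np.zeros((1, cfg.latent_dim), np.float32))
        with pytest.raises(ValueError, match="condition"):
            dec(z, np.array([[0.1, 0.2]]))

    def test_lesion_decoder_shape_and_determinism(self, cfg, rng):
        dec = LesionDecoder(cfg, rng)
        z = Tensor(rng.standard_normal((1, cfg.latent_dim)).astype(np.float32))
        mask = (rng.uniform(size=(16, 16, 16)) > 0.8).astype(np.float32)
        a, b = dec(z, mask), dec(z, mask)
        assert a.shape == (1, 1, 16, 16, 16)
        assert np.array_equal(a.data, b.data)
        assert np.all(a.data > 0) and np.all(a.data < 1)

    def test_lesion_decoder_mask_side_mismatch_raises(self, cfg, rng):
        dec = LesionDecoder(cfg, rng)
        z = Tensor(np.zeros((1, cfg.latent_dim), np.float32))
        with pytest.raises(ValueError, match="side"):
            dec(z, np.zeros((8, 8, 8)))


class TestModulationBlocks:
    def test_ceb_zero_init_is_identity_on_normalised_features(self, cfg, rng):
        ceb = ConditionEmbedding(cfg, channels=6, rng=rng)
        feats = Tensor(rng.normal(size=(6, 2, 8, 8, 8)).astype(np.float32))
        c = Tensor(np.array([[0.3], [0.9]]))
        out = ceb(feats, c)
        assert np.allclose(out.data, instance_norm(feats).data, atol=1e-6)

    def test_ceb_constant_channel_maps_to_beta(self, cfg, rng):
        ceb = ConditionEmbedding(cfg, channels=3, rng=rng)
        # give the beta head a nonzero weight so beta(c) != 0
        ceb.beta_head.weight.data = rng.normal(size=ceb.beta_head.weight.shape).astype(np.float32)
        feats = Tensor(np.full((3, 1, 8, 8, 8), 5.0, dtype=np.float32))
        c = Tensor(np.array([[0.5]]))
        out = ceb(feats, c)
        h = np.maximum(ceb.shared(c).data, 0) + 0.2 * np.minimum(ceb.shared(c).data, 0)
        beta = h @ ceb.beta_head.weight.data + ceb.beta_head.bias.data
        # constant channel normalises to ~0, so output = beta per channel
        for ch in range(3):
            assert np.allclose(out.data[ch], beta[0, ch], atol=1e-3)

    def test_normalised_features_have_zero_mean_unit_variance(self, rng):
        feats = Tensor(rng.normal(2.0, 3.0, size=(4, 3, 8, 8, 8)))
        normed = instance_norm(feats).data
        means = normed.mean(axis=(2, 3, 4))
        variances = normed.var(axis=(2, 3, 4))
        assert np.abs(means).max() < 1e-4
        assert np.abs(variances - 1).max() < 1e-4

    def test_meb_zero_init_is_identity(self, cfg, rng):
        from lesionsynth.model import MaskEmbedding

        meb = MaskEmbedding(cfg, channels=5, rng=rng)
        feats = Tensor(rng.normal(size=(5, 2, 8, 8, 8)).astype(np.float32))
        mask = np.zeros((2, 16, 16, 16), np.float32)
        out = meb(feats, mask)
        assert np.allclose(out.data, instance_norm(feats).data, atol=1e-6)

    def test_meb_gamma_beta_shapes_match_features(self, cfg, rng):
        from lesionsynth.model import MaskEmbedding

        meb = MaskEmbedding(cfg, channels=5, rng=rng)
        mask = (np.random.default_rng(1).uniform(size=(2, 16, 16, 16)) > 0.7).astype(np.float32)
        feats = Tensor(np.random.default_rng(2).normal(size=(5, 2, 8, 8, 8)).astype(np.float32))
        out = meb(feats, mask)
        assert out.shape == feats.shape


class TestNearestDownsample:
    def test_two_cube_block_maps_to_single_voxel(self):
        mask = np.zeros((16, 16, 16))
        mask[4:6, 4:6, 4:6] = 1
        down = nearest_downsample(mask, 8)
        assert down.sum() == 1
        assert down[2, 2, 2] == 1

    def test_matches_brute_force_index_grid(self):
        rng = np.random.default_rng(3)
        mask = (rng.uniform(size=(16, 16, 16)) > 0.5).astype(float)
        down = nearest_downsample(mask, 8)
        factor = 2.0
        for i in range(8):
            for j in range(8):
                for l in range(8):
                    src = tuple(int(np.floor((t + 0.5) * factor)) for t in (i, j, l))
                    assert down[i, j, l] == mask[src]

    def test_identity_when_sides_match(self):
        mask = np.ones((8, 8, 8))
        assert nearest_downsample(mask, 8) is mask


class TestCritic:
    def test_finite_scores_for_degenerate_inputs(self, cfg, rng):
        critic = Critic(cfg, rng)
        for fill in (0.0, 1.0):
            s = critic(Tensor(np.full((1, 2, 16, 16, 16), fill, np.float32)))
            assert np.isfinite(s.data).all()

    def test_batch_of_b_inputs_gives_b_scores(self, cfg, rng):
        critic = Critic(cfg, rng)
        s = critic(Tensor(rng.uniform(size=(1, 5, 16, 16, 16)).astype(np.float32)))
        assert s.shape == (5,)

    def test_deterministic_for_fixed_weights(self, cfg, rng):
        critic = Critic(cfg, rng)
        x = Tensor(rng.uniform(size=(1, 2, 16, 16, 16)).astype(np.float32))
        assert np.array_equal(critic(x).data, critic(x).data)

    def test_shape_mismatch_raises(self, cfg, rng):
        critic = Critic(cfg, rng)
        with pytest.raises(ValueError, match="critic expects"):
            critic(Tensor(np.zeros((1, 1, 8, 8, 8))))


class TestRoundTrips:
    def test_encode_decode_shape_preserving(self, rng):
        for side, levels in ((16, 2), (32, 3)):
            cfg = NetworkConfig(
                side=side, base_channels=4, n_levels=levels, latent_dim=16, embed_hidden=4
            )
            model = StageModel.create("mask", cfg, rng)
            x = Tensor(rng.uniform(size=(1, 2, side, side, side)).astype(np.float32))
            lat = model.encoder(x, rng=rng)
            out = model.decoder(lat.z, np.array([[0.5], [0.5]]))
            assert out.shape == x.shape

    def test_checkpoint_roundtrip_preserves_weights(self, cfg, rng, tmp_path):
        model = StageModel.create("lesion", cfg, rng)
        save_checkpoint(tmp_path / "m.npz", model, extra={"note": 1})
        loaded, extra = load_checkpoint(tmp_path / "m.npz")
        assert extra == {"note": 1}
        for (n1, p1), (n2, p2) in zip(
            sorted(model.state_dict().items()), sorted(loaded.state_dict().items())
        ):
            assert n1 == n2 and np.array_equal(p1, p2)
        z = Tensor(rng.standard_normal((1, cfg.latent_dim)).astype(np.float32))
        mask = np.ones((16, 16, 16), np.float32)
        assert np.array_equal(model.decoder(z, mask).data, loaded.decoder(z, mask).data)

    def test_checkpoint_config_mismatch_names_field(self, cfg, rng, tmp_path):
        model = StageModel.create("mask", cfg, rng)
        save_checkpoint(tmp_path / "m.npz", model)
        other = NetworkConfig(
            side=16, base_channels=4, n_levels=2, latent_dim=64, embed_hidden=4
        )
        with pytest.raises(ValueError, match="latent_dim"):
            load_checkpoint(tmp_path / "m.npz", expected_cfg=other)

    def test_invalid_network_config_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            NetworkConfig(side=20, n_levels=3)
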