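"""Loss-function oracles: closed forms, brute-force loops, sampling and
finite-difference cross-checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lesionsynth import autodiff as ad
from lesionsynth.losses import (
    LossWeights,
    critic_loss,
    generator_loss,
    gradient_penalty,
    kl_loss,
    reconstruction_loss,
)


class TestReconstruction:
    def test_identity_is_zero(self):
        x = np.random.default_rng(0).uniform(size=(3, 4, 4, 4))
        assert reconstruction_loss(x, x).item() == 0.0

    def test_two_voxel_example(self):
        # one sample with two voxels: (1,1) vs (0,0) -> 1^2 + 1^2 = 2
        assert reconstruction_loss(np.array([[1.0, 1.0]]), np.array([[0.0, 0.0]])).item() == 2.0

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(1)
        xg = rng.uniform(size=(5, 8, 8, 8))
        xr = rng.uniform(size=(5, 8, 8, 8))
        total = 0.0
        for i in range(5):
            s = 0.0
            for v_g, v_r in zip(xg[i].ravel(), xr[i].ravel()):
                s += (v_g - v_r) ** 2
            total += s
        assert reconstruction_loss(xg, xr).item() == pytest.approx(total / 5, abs=1e-6)
        assert reconstruction_loss(xg, xr, reduction="sum").item() == pytest.approx(
            total, abs=1e-6
        )

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            reconstruction_loss(np.zeros((2, 3)), np.zeros((2, 4)))


class TestKL:
    def test_prior_equals_posterior_is_zero(self):
        assert kl_loss(np.zeros((1, 4)), np.zeros((1, 4))).item() == 0.0

    def test_closed_form_example(self):
        # mu=(1,0), logvar=(0,0): 0.5*(1+1-1-0) + 0.5*(0+1-1-0) = 0.5
        assert kl_loss(np.array([[1.0, 0.0]]), np.array([[0.0, 0.0]])).item() == 0.5

    def test_matches_monte_carlo_estimate(self):
        rng = np.random.default_rng(2)
        mu = rng.normal(size=(1, 2)) * 0.5
        logvar = rng.normal(size=(1, 2)) * 0.3
        std = np.exp(0.5 * logvar)
        z = mu + std * rng.standard_normal((100_000, 2))
        log_q = -0.5 * (((z - mu) / std) ** 2 + np.log(2 * np.pi) + logvar).sum(axis=1)
        log_p = -0.5 * (z**2 + np.log(2 * np.pi)).sum(axis=1)
        mc = float(np.mean(log_q - log_p))
        assert kl_loss(mu, logvar).item() == pytest.approx(mc, rel=0.02)

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-3, 3), min_size=2, max_size=6))
    def test_nonnegative(self, vals):
        k = len(vals) // 2
        mu = np.array([vals[:k]])
        logvar = np.array([vals[k : 2 * k]])
        assert kl_loss(mu, logvar).item() >= -1e-12

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError, match="finite"):
            kl_loss(np.array([[np.nan]]), np.array([[0.0]]))


class TestCriticLoss:
    def test_balanced_scores_zero(self):
        s = np.array([1.0, -2.0])
        assert critic_loss(s, s, 0.0).item() == 0.0

    def test_example(self):
        assert critic_loss(np.array([2.0]), np.array([5.0]), 40.0).item() == 37.0

    def test_monotone_in_real_scores(self):
        fake = np.array([0.5, 1.5])
        low = critic_loss(fake, np.array([3.0, 3.0]), 0.0).item()
        high = critic_loss(fake, np.array([1.0, 1.0]), 0.0).item()
        assert high > low


def _linear_critic(weight: np.ndarray):
    wt = ad.Tensor(weight, requires_grad=True)

    def critic(x):
        flat = ad.reshape(x, (x.shape[0], -1))
        return ad.matmul(flat, ad.reshape(wt, (-1, 1)))

    return critic


class TestGradientPenalty:
    def test_unit_norm_linear_critic_gives_zero(self):
        rng = np.random.default_rng(3)
        w = rng.normal(size=64)
        w /= np.linalg.norm(w)
        xr = rng.uniform(size=(4, 4, 4, 4))
        xf = rng.uniform(size=(4, 4, 4, 4))
        gp = gradient_penalty(_linear_critic(w), xr, xf, gp_lambda=10.0, rng=rng)
        assert gp.item() == pytest.approx(0.0, abs=1e-9)

    def test_norm_three_linear_critic_gives_forty(self):
        rng = np.random.default_rng(4)
        w = rng.normal(size=64)
        w *= 3.0 / np.linalg.norm(w)
        xr = rng.uniform(size=(2, 4, 4, 4))
        xf = rng.uniform(size=(2, 4, 4, 4))
        gp = gradient_penalty(_linear_critic(w), xr, xf, gp_lambda=10.0, rng=rng)
        assert gp.item() == pytest.approx(40.0, abs=1e-5)

    def test_matches_finite_difference_gradient_norms(self):
        rng = np.random.default_rng(5)
        conv_w = ad.Tensor(rng.normal(size=(2, 1, 3, 3, 3)) * 0.3, requires_grad=True)

        def tiny_critic(x):
            h = ad.leaky_relu(ad.conv3d(x, conv_w, stride=1, pad=1), 0.2)
            return ad.transpose(ad.tmean(h, axis=(0, 2, 3, 4)), (0,))

        # critic consumes CNDHW volumes: batch on axis 1
        xr = rng.uniform(size=(1, 2, 4, 4, 4))
        xf = rng.uniform(size=(1, 2, 4, 4, 4))
        u = np.array([0.3, 0.7])
        gp = gradient_penalty(tiny_critic, xr, xf, gp_lambda=10.0, u=u, batch_axis=1)

        xhat = (u.reshape(1, 2, 1, 1, 1) * xr + (1 - u.reshape(1, 2, 1, 1, 1)) * xf)
        eps = 1e-6
        norms = []
        for n in range(2):
            g = np.zeros(64)
            base = tiny_critic(ad.Tensor(xhat)).data[n]
            for flat in range(64):
                xp = xhat.copy()
                xp[0, n].ravel()[flat] += eps
                g[flat] = (tiny_critic(ad.Tensor(xp)).data[n] - base) / eps
            norms.append(np.linalg.norm(g))
        expected = 10.0 * np.mean((np.array(norms) - 1.0) ** 2)
        assert gp.item() == pytest.approx(expected, abs=1e-3)

    def test_symmetric_under_real_fake_exchange(self):
        rng = np.random.default_rng(6)
        w = rng.normal(size=27)
        critic = _linear_critic(w)
        xr = rng.uniform(size=(3, 3, 3, 3))
        xf = rng.uniform(size=(3, 3, 3, 3))
        u = np.array([0.2, 0.5, 0.9])
        a = gradient_penalty(critic, xr, xf, u=u).item()
        b = gradient_penalty(critic, xf, xr, u=1.0 - u).item()
        assert a == pytest.approx(b, rel=1e-10)


class TestGeneratorLoss:
    def test_zero_weights(self):
        w = LossWeights(w_rec=0.0, w_kl=0.0, w_adv=0.0)
        assert generator_loss(np.array([3.0]), 0.0, 0.0, w).item() == 0.0

    def test_pure_adversarial(self):
        w = LossWeights(w_rec=0.0, w_kl=0.0, w_adv=1.0)
        assert generator_loss(np.array([4.0]), 0.0, 0.0, w).item() == -4.0

    def test_additive_in_kl(self):
        w = LossWeights(w_rec=1.0, w_kl=0.25, w_adv=0.5)
        base = generator_loss(np.array([1.0]), 2.0, 3.0, w).item()
        bumped = generator_loss(np.array([1.0]), 2.0, 3.0 + 4.0, w).item()
        assert bumped - base == pytest.approx(0.25 * 4.0, rel=1e-6)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(w_rec=-1.0)


def test_all_losses_finite_on_unit_range_inputs():
    rng = np.random.default_rng(7)
    xg = rng.uniform(size=(2, 4, 4, 4))
    xr = rng.uniform(size=(2, 4, 4, 4))
    mu = rng.normal(size=(2, 8))
    lv = rng.normal(size=(2, 8))
    w = LossWeights()
    vals = [
        reconstruction_loss(xg, xr).item(),
        kl_loss(mu, lv).item(),
        critic_loss(rng.normal(size=2), rng.normal(size=2), 1.0).item(),
        generator_loss(rng.normal(size=2), 1.0, 1.0, w).item(),
    ]
    assert all(np.isfinite(v) for v in vals)
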