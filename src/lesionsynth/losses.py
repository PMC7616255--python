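"""Training losses: MSE reconstruction, closed-form KL, and WGAN-GP terms.

The generator (encoder + decoder) minimises

    w_rec * L_rec + w_kl * L_kl + w_adv * (-E[D(x_g)])

and the critic minimises

    E[D(x_g)] - E[D(x_r)] + lambda * E[(||grad_xhat D(xhat)||_2 - 1)^2]

where ``xhat`` is a per-sample uniform interpolation between real and
generated inputs.  Reconstruction and KL are summed within a sample and, by
default, averaged over the batch so magnitudes do not depend on batch size
(``reduction="sum"`` restores the raw batch sum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, scalar

__all__ = [
    "LossWeights",
    "reconstruction_loss",
    "kl_loss",
    "critic_loss",
    "gradient_penalty",
    "generator_loss",
]


@dataclass
class LossWeights:
    """Relative weights of the generator's loss terms.

    A too-small KL weight leaves the posterior unregularised, so latents
    drawn from the prior at inference fall outside what the decoder has
    seen and the conditioning signals lose their grip; w_kl = 0.1 keeps
    prior samples usable while preserving reconstruction quality.
    """

    w_rec: float = 1.0
    w_kl: float = 0.1
    w_adv: float = 1e-2
    gp_lambda: float = 10.0

    def __post_init__(self):
        for name in ("w_rec", "w_kl", "w_adv", "gp_lambda"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _batch_reduce(per_sample: Tensor, reduction: str) -> Tensor:
    if reduction == "mean":
        return ad.tmean(per_sample)
    if reduction == "sum":
        return ad.tsum(per_sample)
    raise ValueError(f"unknown reduction {reduction!r}")


def reconstruction_loss(x_g, x_r, reduction: str = "mean", batch_axis: int = 0) -> Tensor:
    """Per-sample squared Euclidean distance, reduced over the batch.

    ``batch_axis`` names the sample axis (0 for the usual batch-first
    arrays; the channel-first volume layout used internally has it at 1).
    """
    x_g, x_r = ad.as_tensor(x_g), ad.as_tensor(x_r)
    if x_g.shape != x_r.shape:
        raise ValueError(f"shape mismatch: generated {x_g.shape} vs real {x_r.shape}")
    diff = ad.sub(x_g, x_r)
    if x_g.ndim > 1:
        axes = tuple(ax for ax in range(x_g.ndim) if ax != batch_axis % x_g.ndim)
        per_sample = ad.tsum(ad.mul(diff, diff), axis=axes)
    else:
        per_sample = ad.mul(diff, diff)
    return _batch_reduce(per_sample, reduction)


def kl_loss(mu, logvar, reduction: str = "mean") -> Tensor:
    """KL( N(mu, diag(exp(logvar))) || N(0, I) ), closed form per sample."""
    mu, logvar = ad.as_tensor(mu), ad.as_tensor(logvar)
    if mu.shape != logvar.shape:
        raise ValueError(f"shape mismatch: mu {mu.shape} vs logvar {logvar.shape}")
    if not (np.isfinite(mu.data).all() and np.isfinite(logvar.data).all()):
        raise ValueError("kl_loss requires finite mu and logvar")
    half = scalar(0.5)
    one = scalar(1.0)
    term = ad.sub(ad.sub(ad.add(ad.mul(mu, mu), ad.exp(logvar)), one), logvar)
    axes = tuple(range(1, mu.ndim))
    per_sample = ad.mul(half, ad.tsum(term, axis=axes)) if mu.ndim > 1 else ad.mul(
        half, ad.tsum(term)
    )
    return _batch_reduce(per_sample, reduction)


def critic_loss(scores_fake, scores_real, gp) -> Tensor:
    """Wasserstein critic objective: E[D(x_g)] − E[D(x_r)] + penalty."""
    scores_fake, scores_real = ad.as_tensor(scores_fake), ad.as_tensor(scores_real)
    gp = ad.as_tensor(gp)
    return ad.add(ad.sub(ad.tmean(scores_fake), ad.tmean(scores_real)), gp)


def gradient_penalty(
    critic,
    x_real,
    x_fake,
    gp_lambda: float = 10.0,
    rng: np.random.Generator | None = None,
    u: np.ndarray | None = None,
    batch_axis: int = 0,
) -> Tensor:
    """Two-sided gradient penalty on random real/fake interpolates.

    ``critic`` is any callable mapping a batch tensor to per-sample scores.
    The returned tensor stays differentiable with respect to the critic's
    parameters (double backprop), so it can be added to the critic loss.
    """
    xr = np.asarray(x_real.data if isinstance(x_real, Tensor) else x_real)
    xf = np.asarray(x_fake.data if isinstance(x_fake, Tensor) else x_fake)
    if xr.shape != xf.shape:
        raise ValueError(f"shape mismatch: real {xr.shape} vs fake {xf.shape}")
    batch_axis = batch_axis % xr.ndim
    n = xr.shape[batch_axis]
    u_shape = tuple(n if ax == batch_axis else 1 for ax in range(xr.ndim))
    if u is None:
        if rng is None:
            rng = np.random.default_rng()
        u = rng.uniform(size=u_shape)
    u = np.asarray(u, dtype=np.float64).reshape(u_shape)
    xhat = Tensor((u * xr + (1.0 - u) * xf).astype(xr.dtype), requires_grad=True)
    scores = critic(xhat)
    scores = ad.as_tensor(scores)
    if not scores.requires_grad:
        raise ValueError("critic output is not differentiable w.r.t. its input")
    (g,) = ad.grad(ad.tsum(scores), [xhat], create_graph=True)
    axes = tuple(ax for ax in range(xr.ndim) if ax != batch_axis)
    norm = ad.sqrt(ad.tsum(ad.mul(g, g), axis=axes))
    dev = ad.sub(norm, scalar(1.0))
    return ad.mul(scalar(float(gp_lambda)), ad.tmean(ad.mul(dev, dev)))


def generator_loss(scores_fake, rec, kl, w: LossWeights) -> Tensor:
    """w_adv·(−E[D(x_g)]) + w_rec·L_rec + w_kl·L_kl."""
    scores_fake = ad.as_tensor(scores_fake)
    rec, kl = ad.as_tensor(rec), ad.as_tensor(kl)
    adv = ad.neg(ad.tmean(scores_fake))
    total = ad.mul(scalar(w.w_adv), adv)
    total = ad.add(total, ad.mul(scalar(w.w_rec), rec))
    return ad.add(total, ad.mul(scalar(w.w_kl), kl))
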