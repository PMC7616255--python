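"""Two-stage adversarial VAE networks for 3D lesion synthesis.

The generative model splits lesion simulation into two cascaded stages:

* a *mask stage* — a 3D VAE over binary lesion masks whose decoder ``D_S`` is
  conditioned on a lesion-size vector through a condition embedding block
  (CEB): the condition is mapped by linear layers to per-channel scale and
  bias that modulate instance-normalised decoder features;
* a *lesion stage* — a 3D VAE over intensity cubes whose decoder ``D_I`` is
  guided by a binary mask through a mask embedding block (MEB): the mask is
  nearest-neighbour-resized to each feature resolution and mapped by 3×3×3
  convolutions to voxel-wise scale and bias fields (SPADE-style spatially
  adaptive modulation).

All convolutions are 3×3×3; every encoder convolution is followed by
instance normalisation and leaky rectification; decoder outputs pass through
a sigmoid so values live in (0, 1).  Each stage has a WGAN critic — a plain
convolutional stack with no normalisation (normalisation would couple batch
statistics into the gradient penalty).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Conv3d, Linear, Module, instance_norm

__all__ = [
    "NetworkConfig",
    "LatentSample",
    "Encoder",
    "ConditionEmbedding",
    "MaskEmbedding",
    "MaskDecoder",
    "LesionDecoder",
    "Critic",
    "StageModel",
    "nearest_downsample",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class NetworkConfig:
    side: int = 64
    base_channels: int = 16
    n_levels: int = 4
    latent_dim: int = 128
    leaky_slope: float = 0.2
    condition_dim: int = 1
    embed_hidden: int = 32

    def __post_init__(self):
        if self.side % (2**self.n_levels) != 0:
            raise ValueError(
                f"side {self.side} must be divisible by 2^n_levels = {2 ** self.n_levels}"
            )
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")

    @property
    def bottleneck_side(self) -> int:
        return self.side // (2**self.n_levels)

    @property
    def bottleneck_channels(self) -> int:
        return self.base_channels * (2**self.n_levels)


@dataclass
class LatentSample:
    """Encoder output: posterior parameters and a reparameterised draw."""

    mu: Tensor
    logvar: Tensor
    z: Tensor
    eps: np.ndarray


def _level_channels(cfg: NetworkConfig) -> list[int]:
    # channels after each stride-2 level: base, 2*base, ..., base*2^(n-1)... up
    return [cfg.base_channels * (2**i) for i in range(cfg.n_levels + 1)]


def nearest_downsample(mask: np.ndarray, out_side: int) -> np.ndarray:
    """Nearest-neighbour resampling of a cubic volume to ``out_side``³.

    Target voxel ``i`` reads source voxel ``floor((i + 0.5) * factor)`` —
    centre-aligned sampling on the index grid.
    """
    side = mask.shape[-1]
    if side == out_side:
        return mask
    factor = side / out_side
    idx = np.floor((np.arange(out_side) + 0.5) * factor).astype(int)
    idx = np.clip(idx, 0, side - 1)
    return mask[..., idx[:, None, None], idx[None, :, None], idx[None, None, :]]


class Encoder(Module):
    """Stride-2 convolutional stack producing a diagonal Gaussian posterior."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.cfg = cfg
        chans = _level_channels(cfg)
        self.convs = [
            Conv3d(1 if i == 0 else chans[i - 1], chans[i], rng, stride=2, slope=cfg.leaky_slope)
            for i in range(cfg.n_levels)
        ]
        flat = chans[cfg.n_levels - 1] * cfg.bottleneck_side**3
        self.mu_head = Linear(flat, cfg.latent_dim, rng)
        self.logvar_head = Linear(flat, cfg.latent_dim, rng)

    def __call__(
        self,
        x: Tensor,
        rng: np.random.Generator | None = None,
        eps: np.ndarray | None = None,
    ) -> LatentSample:
        if x.ndim != 5 or x.shape[0] != 1 or x.shape[2:] != (self.cfg.side,) * 3:
            raise ValueError(
                f"encoder expects (1,N,{self.cfg.side},{self.cfg.side},{self.cfg.side}) "
                f"(channel-first volumes), got {x.shape}"
            )
        h = x
        for conv in self.convs:
            h = ad.leaky_relu(instance_norm(conv(h)), self.cfg.leaky_slope)
        h = ad.reshape(ad.transpose(h, (1, 0, 2, 3, 4)), (x.shape[1], -1))
        mu = self.mu_head(h)
        logvar = self.logvar_head(h)
        if eps is None:
            if rng is None:
                raise ValueError("encoder needs either an rng or an explicit eps draw")
            eps = rng.standard_normal(mu.shape).astype(np.float32)
        std = ad.exp(ad.mul(logvar, ad.scalar(0.5)))
        z = ad.add(mu, ad.mul(std, Tensor(eps)))
        return LatentSample(mu=mu, logvar=logvar, z=z, eps=eps)


class ConditionEmbedding(Module):
    """CEB: condition vector → per-channel (gamma, beta) via linear layers.

    The gamma/beta heads start at zero, so an untrained block is the identity
    on instance-normalised features: out = norm(x)·(1+gamma) + beta.
    """

    def __init__(self, cfg: NetworkConfig, channels: int, rng: np.random.Generator):
        self.shared = Linear(cfg.condition_dim, cfg.embed_hidden, rng, slope=cfg.leaky_slope)
        self.gamma_head = Linear(cfg.embed_hidden, channels, rng, zero_init=True)
        self.beta_head = Linear(cfg.embed_hidden, channels, rng, zero_init=True)
        self.slope = cfg.leaky_slope

    def __call__(self, features: Tensor, c: Tensor) -> Tensor:
        if c.ndim != 2:
            raise ValueError(f"condition must be (N, C), got {c.shape}")
        h = ad.leaky_relu(self.shared(c), self.slope)
        # (N, C) -> (C, N, 1, 1, 1) to modulate CNDHW features per channel
        gamma = ad.reshape(ad.transpose(self.gamma_head(h), (1, 0)), features.shape[:2] + (1, 1, 1))
        beta = ad.reshape(ad.transpose(self.beta_head(h), (1, 0)), features.shape[:2] + (1, 1, 1))
        normed = instance_norm(features)
        scale = ad.broadcast_to(ad.add(ad.scalar(1.0), gamma), features.shape)
        shift = ad.broadcast_to(beta, features.shape)
        return ad.add(ad.mul(normed, scale), shift)


class MaskEmbedding(Module):
    """MEB: mask → voxel-wise (gamma, beta) fields via 3×3×3 convolutions.

    The mask is nearest-neighbour-resized to the feature resolution, passed
    through one shared convolution + leaky rectification, then two parallel
    zero-initialised convolutions produce the modulation fields.
    """

    def __init__(self, cfg: NetworkConfig, channels: int, rng: np.random.Generator):
        self.shared = Conv3d(1, cfg.embed_hidden, rng, slope=cfg.leaky_slope)
        self.gamma_head = Conv3d(cfg.embed_hidden, channels, rng, zero_init=True)
        self.beta_head = Conv3d(cfg.embed_hidden, channels, rng, zero_init=True)
        self.slope = cfg.leaky_slope

    def __call__(self, features: Tensor, mask: np.ndarray) -> Tensor:
        res = features.shape[-1]
        m = np.asarray(mask, dtype=np.float32)
        if m.ndim == 3:
            m = m[None, None]
        elif m.ndim == 4:
            m = m[None, :]  # (N, S, S, S) -> (1, N, S, S, S)
        if m.shape[-1] < res:
            raise ValueError(f"mask side {m.shape[-1]} below feature resolution {res}")
        m = nearest_downsample(m, res)
        if m.shape[1] == 1 and features.shape[1] > 1:
            m = np.repeat(m, features.shape[1], axis=1)
        mt = Tensor(m)
        h = ad.leaky_relu(self.shared(mt), self.slope)
        gamma = self.gamma_head(h)
        beta = self.beta_head(h)
        normed = instance_norm(features)
        return ad.add(ad.mul(normed, ad.add(ad.scalar(1.0), gamma)), beta)


class _DecoderBase(Module):
    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.cfg = cfg
        chans = _level_channels(cfg)
        bott_ch = chans[cfg.n_levels - 1]
        self.project = Linear(cfg.latent_dim, bott_ch * cfg.bottleneck_side**3, rng)
        # upsampling path halves channels per level
        self.convs = [
            Conv3d(
                chans[cfg.n_levels - 1 - i],
                chans[max(cfg.n_levels - 2 - i, 0)],
                rng,
                slope=cfg.leaky_slope,
            )
            for i in range(cfg.n_levels)
        ]
        self.out_conv = Conv3d(chans[0], 1, rng)

    def _embed(self, level: int, features: Tensor, guidance) -> Tensor:
        raise NotImplementedError

    def _forward(self, z: Tensor, guidance) -> Tensor:
        cfg = self.cfg
        if z.ndim != 2 or z.shape[1] != cfg.latent_dim:
            raise ValueError(f"latent must be (N, {cfg.latent_dim}), got {z.shape}")
        n = z.shape[0]
        chans = _level_channels(cfg)
        h = self.project(z)
        h = ad.reshape(h, (n, chans[cfg.n_levels - 1]) + (cfg.bottleneck_side,) * 3)
        h = ad.transpose(h, (1, 0, 2, 3, 4))
        for i, conv in enumerate(self.convs):
            h = ad.upsample_nearest(h, 2)
            h = conv(h)
            h = self._embed(i, h, guidance)
            h = ad.leaky_relu(h, cfg.leaky_slope)
        return ad.sigmoid(self.out_conv(h))


class MaskDecoder(_DecoderBase):
    """``D_S``: latent + size condition → soft lesion mask in (0,1)."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__(cfg, rng)
        chans = _level_channels(cfg)
        self.cebs = [
            ConditionEmbedding(cfg, chans[max(cfg.n_levels - 2 - i, 0)], rng)
            for i in range(cfg.n_levels)
        ]

    def _embed(self, level: int, features: Tensor, c: Tensor) -> Tensor:
        return self.cebs[level](features, c)

    def __call__(self, z: Tensor, c) -> Tensor:
        c = ad.as_tensor(c)
        if c.ndim == 1:
            c = ad.reshape(c, (1, -1))
        if c.shape[1] != self.cfg.condition_dim:
            raise ValueError(
                f"condition length {c.shape[1]} != condition_dim {self.cfg.condition_dim}"
            )
        if c.shape[0] != z.shape[0]:
            raise ValueError(f"batch mismatch: z {z.shape[0]} vs condition {c.shape[0]}")
        return self._forward(z, c)


class LesionDecoder(_DecoderBase):
    """``D_I``: latent + binary mask → intensity cube in (0,1)."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__(cfg, rng)
        chans = _level_channels(cfg)
        self.mebs = [
            MaskEmbedding(cfg, chans[max(cfg.n_levels - 2 - i, 0)], rng)
            for i in range(cfg.n_levels)
        ]

    def _embed(self, level: int, features: Tensor, mask) -> Tensor:
        return self.mebs[level](features, mask)

    def __call__(self, z: Tensor, mask: np.ndarray) -> Tensor:
        m = np.asarray(mask)
        if m.shape[-1] != self.cfg.side:
            raise ValueError(f"mask side {m.shape[-1]} != configured side {self.cfg.side}")
        return self._forward(z, m)


class Critic(Module):
    """WGAN critic: stride-2 convolutions, leaky rectification, no
    normalisation, global average pool and a linear score head."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.cfg = cfg
        chans = _level_channels(cfg)
        self.convs = [
            Conv3d(1 if i == 0 else chans[i - 1], chans[i], rng, stride=2, slope=cfg.leaky_slope)
            for i in range(cfg.n_levels)
        ]
        self.head = Linear(chans[cfg.n_levels - 1], 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim != 5 or x.shape[0] != 1 or x.shape[2:] != (self.cfg.side,) * 3:
            raise ValueError(
                f"critic expects (1,N,{self.cfg.side},{self.cfg.side},{self.cfg.side}) "
                f"(channel-first volumes), got {x.shape}"
            )
        h = x
        for conv in self.convs:
            h = ad.leaky_relu(conv(h), self.cfg.leaky_slope)
        h = ad.transpose(ad.tmean(h, axis=(2, 3, 4)), (1, 0))
        return ad.reshape(self.head(h), (x.shape[1],))


@dataclass
class StageModel:
    """Generator (encoder + decoder) and critic for one stage."""

    stage: str
    cfg: NetworkConfig
    encoder: Encoder
    decoder: Module
    critic: Critic

    @classmethod
    def create(cls, stage: str, cfg: NetworkConfig, rng: np.random.Generator) -> "StageModel":
        if stage not in ("mask", "lesion"):
            raise ValueError(f"unknown stage {stage!r}; expected 'mask' or 'lesion'")
        decoder = MaskDecoder(cfg, rng) if stage == "mask" else LesionDecoder(cfg, rng)
        return cls(
            stage=stage,
            cfg=cfg,
            encoder=Encoder(cfg, rng),
            decoder=decoder,
            critic=Critic(cfg, rng),
        )

    def generator_parameters(self) -> list[Tensor]:
        return self.encoder.parameters() + self.decoder.parameters()

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for prefix, module in (
            ("encoder", self.encoder),
            ("decoder", self.decoder),
            ("critic", self.critic),
        ):
            for name, arr in module.state_dict().items():
                out[f"{prefix}.{name}"] = arr
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for prefix, module in (
            ("encoder", self.encoder),
            ("decoder", self.decoder),
            ("critic", self.critic),
        ):
            sub = {
                name[len(prefix) + 1 :]: arr
                for name, arr in state.items()
                if name.startswith(prefix + ".")
            }
            module.load_state_dict(sub)


def save_checkpoint(path, model: StageModel, extra: dict | None = None) -> None:
    """Serialise a stage model (weights + config + optional extras) to .npz."""
    meta = {"stage": model.stage, "config": asdict(model.cfg)}
    payload = {f"param/{k}": v for k, v in model.state_dict().items()}
    payload["meta.json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    if extra:
        payload["extra.json"] = np.frombuffer(
            json.dumps(extra, default=_json_np).encode(), dtype=np.uint8
        )
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def _json_np(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def load_checkpoint(path, expected_cfg: NetworkConfig | None = None):
    """Load a stage model; returns ``(model, extra_dict)``."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta.json"]).decode())
        cfg = NetworkConfig(**meta["config"])
        if expected_cfg is not None:
            mism = [
                f"{k}: checkpoint {v} vs requested {getattr(expected_cfg, k)}"
                for k, v in asdict(cfg).items()
                if getattr(expected_cfg, k) != v
            ]
            if mism:
                raise ValueError("network config mismatch — " + "; ".join(mism))
        model = StageModel.create(meta["stage"], cfg, np.random.default_rng(0))
        state = {
            k[len("param/") :]: data[k] for k in data.files if k.startswith("param/")
        }
        model.load_state_dict(state)
        extra = (
            json.loads(bytes(data["extra.json"]).decode()) if "extra.json" in data.files else {}
        )
    return model, extra
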