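"""Alternating generator/critic optimisation for the two synthesis stages.

Each stage (mask simulation, lesion synthesis) is trained independently:
per batch, ``critic_steps`` critic updates (Wasserstein loss plus gradient
penalty) are followed by one generator update (reconstruction + KL +
adversarial).  Encoder and decoder are optimised jointly as the generator;
generator and critic each have their own Adam optimiser at the same learning
rate.  All randomness — shuffling, posterior draws, interpolation draws —
derives from ``TrainConfig.seed``, and checkpoints carry the optimiser
moments and RNG state so a resumed run is bitwise identical to an
uninterrupted one on the same machine.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .losses import (
    LossWeights,
    critic_loss,
    generator_loss,
    gradient_penalty,
    kl_loss,
    reconstruction_loss,
)
from .model import NetworkConfig, StageModel, load_checkpoint, save_checkpoint
from .nn import Adam
from .phantom import condition_of
from .volumes_io import CubeRecord

__all__ = ["TrainConfig", "TrainState", "train_stage", "resume", "save_state", "load_state"]

logger = logging.getLogger("lesionsynth.train")

_HISTORY_KEYS = ("rec", "kl", "adv", "gen_total", "critic", "gp")


@dataclass
class TrainConfig:
    learning_rate: float = 5e-5
    batch_size: int = 13
    epochs: int = 1000
    critic_steps: int = 5
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    stage: str = "mask"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.critic_steps < 1:
            raise ValueError("critic_steps must be >= 1")
        if self.stage not in ("mask", "lesion"):
            raise ValueError(f"stage must be 'mask' or 'lesion', got {self.stage!r}")
        if isinstance(self.weights, dict):
            self.weights = LossWeights(**self.weights)


@dataclass
class TrainState:
    epoch: int
    history: dict[str, list[float]]
    model: StageModel
    gen_opt: Adam
    critic_opt: Adam
    rng: np.random.Generator
    train_cfg: TrainConfig


def _stage_inputs(record: CubeRecord, stage: str):
    """Real input tensor and guidance for one record under a given stage."""
    if stage == "mask":
        x = record.mask_cube.astype(np.float32)
        guidance = condition_of(record.mask_cube)
    else:
        x = record.cube.astype(np.float32)
        guidance = record.mask_cube.astype(np.float32)
    return x, guidance


def _check_finite(value: float, component: str, epoch: int) -> None:
    if not np.isfinite(value):
        raise RuntimeError(
            f"training diverged: {component} loss became non-finite at epoch {epoch}"
        )


def _decode(model: StageModel, z: Tensor, guidance_batch) -> Tensor:
    # mask stage: guidance is a (B, C) condition; lesion stage: a (B, S³) mask
    return model.decoder(z, np.stack(guidance_batch))


def _run_epochs(state: TrainState, dataset: list[CubeRecord], target_epochs: int) -> TrainState:
    cfg = state.train_cfg
    model = state.model
    w = cfg.weights
    side = model.cfg.side
    for rec in dataset:
        if rec.cube.shape[-1] != side:
            raise ValueError(
                f"dataset cube side {rec.cube.shape[-1]} != network side {side}"
            )

    gen_params = model.generator_parameters()
    critic_params = model.critic.parameters()

    n = len(dataset)
    bs = min(cfg.batch_size, n)
    while state.epoch < target_epochs:
        epoch = state.epoch + 1
        order = state.rng.permutation(n)
        sums = {k: 0.0 for k in _HISTORY_KEYS}
        n_batches = 0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            xs, guides = [], []
            for i in idx:
                x, g = _stage_inputs(dataset[i], model.stage)
                xs.append(x)
                guides.append(g)
            x_real = np.stack(xs)[None]  # channel-first volumes: (1,B,S,S,S)

            # one generator forward per iteration; its detached output feeds
            # the critic updates and its graph is reused for the generator step
            eps = state.rng.standard_normal((len(idx), model.cfg.latent_dim)).astype(np.float32)
            lat = model.encoder(Tensor(x_real), eps=eps)
            x_fake = _decode(model, lat.z, guides)

            # -- critic updates ------------------------------------------
            for _ in range(cfg.critic_steps):
                u = state.rng.uniform(size=(len(idx),))
                gp = gradient_penalty(
                    model.critic, x_real, x_fake.data, gp_lambda=w.gp_lambda, u=u,
                    batch_axis=1,
                )
                s_fake = model.critic(Tensor(x_fake.data))
                s_real = model.critic(Tensor(x_real))
                d_loss = critic_loss(s_fake, s_real, gp)
                grads = ad.grad(d_loss, critic_params)
                state.critic_opt.step(grads)
                _check_finite(d_loss.item(), "critic", epoch)
            sums["critic"] += d_loss.item()
            sums["gp"] += gp.item()

            # -- generator update ----------------------------------------
            rec_l = reconstruction_loss(x_fake, Tensor(x_real), batch_axis=1)
            kl_l = kl_loss(lat.mu, lat.logvar)
            s_fake = model.critic(x_fake)
            g_loss = generator_loss(s_fake, rec_l, kl_l, w)
            grads = ad.grad(g_loss, gen_params)
            state.gen_opt.step(grads)

            for name, val in (
                ("rec", rec_l.item()),
                ("kl", kl_l.item()),
                ("adv", -float(np.mean(s_fake.data))),
                ("gen_total", g_loss.item()),
            ):
                _check_finite(val, name, epoch)
                sums[name] += val
            n_batches += 1

        for k in _HISTORY_KEYS:
            state.history[k].append(sums[k] / max(n_batches, 1))
        state.epoch = epoch
        logger.info(
            "stage=%s epoch=%d rec=%.4f kl=%.4f adv=%.4f critic=%.4f",
            model.stage,
            epoch,
            state.history["rec"][-1],
            state.history["kl"][-1],
            state.history["adv"][-1],
            state.history["critic"][-1],
        )
    return state


def train_stage(
    dataset: list[CubeRecord],
    cfg: TrainConfig,
    net_cfg: NetworkConfig,
) -> TrainState:
    """Train one stage from scratch on a list of cube records."""
    if not dataset:
        raise ValueError("cannot train on an empty dataset")
    rng = np.random.default_rng(cfg.seed)
    model = StageModel.create(cfg.stage, net_cfg, rng)
    state = TrainState(
        epoch=0,
        history={k: [] for k in _HISTORY_KEYS},
        model=model,
        gen_opt=Adam(model.generator_parameters(), cfg.learning_rate),
        critic_opt=Adam(model.critic.parameters(), cfg.learning_rate),
        rng=rng,
        train_cfg=cfg,
    )
    return _run_epochs(state, dataset, cfg.epochs)


def save_state(state: TrainState, path) -> None:
    """Checkpoint the full training state (weights, moments, RNG, history)."""
    extra = {
        "epoch": state.epoch,
        "history": state.history,
        "train_cfg": {**asdict(state.train_cfg), "weights": asdict(state.train_cfg.weights)},
        "rng_state": state.rng.bit_generator.state,
        "gen_opt_t": state.gen_opt.t,
        "critic_opt_t": state.critic_opt.t,
    }
    save_checkpoint(path, state.model, extra=extra)
    moments = {}
    for tag, opt in (("gen", state.gen_opt), ("critic", state.critic_opt)):
        for i, (m, v) in enumerate(zip(opt.m, opt.v)):
            moments[f"{tag}/m/{i}"] = m
            moments[f"{tag}/v/{i}"] = v
    with open(str(path) + ".opt", "wb") as fh:
        np.savez(fh, **moments)


def load_state(path, net_cfg: NetworkConfig | None = None) -> TrainState:
    model, extra = load_checkpoint(path, expected_cfg=net_cfg)
    tc = dict(extra["train_cfg"])
    tc["weights"] = LossWeights(**tc["weights"])
    cfg = TrainConfig(**tc)
    gen_opt = Adam(model.generator_parameters(), cfg.learning_rate)
    critic_opt = Adam(model.critic.parameters(), cfg.learning_rate)
    with np.load(str(path) + ".opt") as data:
        for tag, opt, t in (
            ("gen", gen_opt, extra["gen_opt_t"]),
            ("critic", critic_opt, extra["critic_opt_t"]),
        ):
            opt.t = int(t)
            opt.m = [data[f"{tag}/m/{i}"].copy() for i in range(len(opt.params))]
            opt.v = [data[f"{tag}/v/{i}"].copy() for i in range(len(opt.params))]
    rng = np.random.default_rng()
    rng.bit_generator.state = extra["rng_state"]
    return TrainState(
        epoch=int(extra["epoch"]),
        history={k: list(v) for k, v in extra["history"].items()},
        model=model,
        gen_opt=gen_opt,
        critic_opt=critic_opt,
        rng=rng,
        train_cfg=cfg,
    )


def resume(
    state_path,
    dataset: list[CubeRecord],
    cfg: TrainConfig,
    net_cfg: NetworkConfig | None = None,
) -> TrainState:
    """Continue training from a checkpoint up to ``cfg.epochs`` total epochs."""
    if not dataset:
        raise ValueError("cannot resume on an empty dataset")
    state = load_state(state_path, net_cfg=net_cfg)
    if cfg.stage != state.train_cfg.stage:
        raise ValueError(
            f"stage mismatch: checkpoint {state.train_cfg.stage!r} vs requested {cfg.stage!r}"
        )
    state.train_cfg = cfg
    return _run_epochs(state, dataset, cfg.epochs)


def history_to_csv(history: dict[str, list[float]], path) -> None:
    keys = list(history)
    with open(path, "w") as fh:
        fh.write("epoch," + ",".join(keys) + "\n")
        for i in range(len(history[keys[0]])):
            fh.write(f"{i + 1}," + ",".join(f"{history[k][i]:.8g}" for k in keys) + "\n")
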