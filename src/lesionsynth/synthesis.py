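"""Inference: sample masks from the mask stage, lesions from the lesion stage.

New lesions are generated in two Gaussian-sampling steps: a shape latent
``z_shape ~ N(0, I)`` plus a size condition drive the mask decoder; the
binarised mask plus an intensity latent ``z_int ~ N(0, I)`` drive the lesion
decoder.  Every output is fully reproducible from (checkpoints, condition,
seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .autodiff import Tensor, no_grad
from .model import StageModel

__all__ = ["SynthesisResult", "sample_mask", "sample_lesion", "synthesize_cohort"]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SynthesisResult:
    mask_soft: np.ndarray
    mask_bin: np.ndarray
    lesion: np.ndarray | None
    condition: np.ndarray
    z_shape: np.ndarray
    z_intensity: np.ndarray | None
    seed: int
    empty: bool = False

    @property
    def volume(self) -> int:
        return int(self.mask_bin.sum())


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_STRUCT26)
    if n <= 1:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return (labels == counts.argmax()).astype(np.uint8)


def sample_mask(
    mask_model: StageModel,
    c,
    seed: int,
    threshold: float = 0.5,
    keep_largest: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one mask: z ~ N(0, I) → decoder → threshold (→ largest CC).

    Returns ``(mask_soft, mask_bin)``; an all-background result after
    thresholding yields an empty ``mask_bin`` (callers may resample).
    """
    if mask_model.stage != "mask":
        raise ValueError(f"expected a mask-stage model, got stage {mask_model.stage!r}")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((1, mask_model.cfg.latent_dim)).astype(np.float32)
    c = np.atleast_2d(np.asarray(c, dtype=np.float64))
    with no_grad():
        soft = mask_model.decoder(Tensor(z), c)
    mask_soft = soft.data[0, 0].astype(np.float32)
    mask_bin = (mask_soft > threshold).astype(np.uint8)
    if keep_largest and mask_bin.any():
        mask_bin = _largest_component(mask_bin)
    return mask_soft, mask_bin


def sample_lesion(lesion_model: StageModel, mask: np.ndarray, seed: int) -> np.ndarray:
    """Draw one intensity cube for a given mask: z ~ N(0, I) → decoder."""
    if lesion_model.stage != "lesion":
        raise ValueError(f"expected a lesion-stage model, got stage {lesion_model.stage!r}")
    mask = np.asarray(mask)
    if not (mask > 0).any():
        raise ValueError("cannot synthesise a lesion for an empty mask")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((1, lesion_model.cfg.latent_dim)).astype(np.float32)
    with no_grad():
        cube = lesion_model.decoder(Tensor(z), mask.astype(np.float32)[None])
    return cube.data[0, 0].astype(np.float32)


def uniform_condition_sampler(low: float, high: float):
    """Default inference-time condition sampler: uniform over a size range."""

    def sampler(rng: np.random.Generator) -> np.ndarray:
        return np.array([rng.uniform(low, high)], dtype=np.float64)

    return sampler


def synthesize_cohort(
    mask_model: StageModel,
    lesion_model: StageModel | None,
    n: int,
    condition_sampler,
    seed: int,
    threshold: float = 0.5,
    max_retries: int = 5,
) -> list[SynthesisResult]:
    """Generate ``n`` lesions; per-item seeds derive from the master seed.

    Items whose mask comes out empty are resampled up to ``max_retries``
    times with fresh sub-seeds, then flagged ``empty`` if still degenerate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    master = np.random.default_rng(seed)
    results = []
    for _ in range(n):
        condition = condition_sampler(master)
        result = None
        for _attempt in range(max_retries + 1):
            item_seed = int(master.integers(0, 2**31 - 1))
            mask_soft, mask_bin = sample_mask(
                mask_model, condition, item_seed, threshold=threshold
            )
            if mask_bin.any():
                lesion = None
                z_int = None
                if lesion_model is not None:
                    lesion_seed = int(master.integers(0, 2**31 - 1))
                    lesion = sample_lesion(lesion_model, mask_bin, lesion_seed)
                    z_int = np.random.default_rng(lesion_seed).standard_normal(
                        lesion_model.cfg.latent_dim
                    )
                result = SynthesisResult(
                    mask_soft=mask_soft,
                    mask_bin=mask_bin,
                    lesion=lesion,
                    condition=condition,
                    z_shape=np.random.default_rng(item_seed).standard_normal(
                        mask_model.cfg.latent_dim
                    ),
                    z_intensity=z_int,
                    seed=item_seed,
                )
                break
        if result is None:
            result = SynthesisResult(
                mask_soft=mask_soft,
                mask_bin=mask_bin,
                lesion=None,
                condition=condition,
                z_shape=np.random.default_rng(item_seed).standard_normal(
                    mask_model.cfg.latent_dim
                ),
                z_intensity=None,
                seed=item_seed,
                empty=True,
            )
        results.append(result)
    return results
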