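"""Synthetic lesion phantoms: ellipsoid-lobed masks with textured interiors.

The real training data for thermal-ablation lesion synthesis are private
patient scans, so every runnable example here is built on phantoms that
reproduce the statistical structure the two-stage model assumes: a compact,
single-connected-component binary mask of controllable volume; an intensity
cube whose lesion interior is offset from a smooth, brain-like background by
a contrast term carrying multiplicative speckle texture.

The generator is fully deterministic given ``PhantomSpec.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .volumes_io import CubeRecord

__all__ = ["PhantomSpec", "generate_mask", "generate_pair", "generate_dataset", "condition_of"]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class PhantomSpec:
    side: int = 64
    volume_range: tuple[int, int] = (500, 8000)
    n_lobes: int = 3
    texture_contrast: float = 0.35
    background_smoothness: float = 4.0
    seed: int = 0
    max_tries: int = 200

    def __post_init__(self):
        if self.side < 8:
            raise ValueError("side must be >= 8")
        lo, hi = self.volume_range
        if lo < 1:
            raise ValueError("volume_range minimum must be >= 1")
        if hi > self.side**3:
            raise ValueError(f"volume_range maximum {hi} exceeds side³ = {self.side ** 3}")
        if lo > hi:
            raise ValueError("volume_range must be (min, max) with min <= max")
        if not 0.0 <= self.texture_contrast <= 1.0:
            raise ValueError("texture_contrast must be in [0, 1]")
        if self.n_lobes < 1:
            raise ValueError("n_lobes must be >= 1")


def _ellipsoid(side: int, center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    grid = np.indices((side, side, side), dtype=np.float64)
    d2 = sum(((grid[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    return d2 <= 1.0


def generate_mask(spec: PhantomSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw one binary lesion mask with voxel count inside ``volume_range``.

    A lesion is the union of 1..n_lobes overlapping ellipsoids; each extra
    lobe is centred on a voxel of the current foreground so the union stays a
    single 26-connected component.  Draws are rejected until the voxel count
    falls inside ``volume_range``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    side = spec.side
    lo, hi = spec.volume_range
    for _ in range(spec.max_tries):
        target = rng.uniform(lo, hi)
        k = int(rng.integers(1, spec.n_lobes + 1))
        per_lobe = target / k
        mask = np.zeros((side,) * 3, dtype=bool)
        center = side / 2.0 + rng.uniform(-side / 8.0, side / 8.0, size=3)
        for lobe in range(k):
            ratios = rng.uniform(0.6, 1.6, size=3)
            ratios /= ratios.prod() ** (1.0 / 3.0)
            r = (3.0 * per_lobe / (4.0 * math.pi)) ** (1.0 / 3.0)
            semi = np.maximum(r * ratios, 0.6)
            mask |= _ellipsoid(side, center, semi)
            if lobe + 1 < k:
                fg = np.argwhere(mask)
                center = fg[rng.integers(len(fg))] + rng.uniform(-1.0, 1.0, size=3)
        count = int(mask.sum())
        if not (lo <= count <= hi):
            continue
        labels, n_comp = ndimage.label(mask, structure=_STRUCT26)
        if n_comp != 1:
            continue
        return mask.astype(np.uint8)
    raise RuntimeError(
        f"could not draw a mask with volume in {spec.volume_range} "
        f"after {spec.max_tries} tries (side={side})"
    )


def generate_pair(spec: PhantomSpec) -> CubeRecord:
    """One phantom: smooth background in ~[0.3, 0.7], textured lesion inside
    the mask (offset ``texture_contrast`` with multiplicative speckle)."""
    rng = np.random.default_rng(spec.seed)
    side = spec.side
    mask = generate_mask(spec, rng)

    field = rng.uniform(size=(side,) * 3)
    field = ndimage.gaussian_filter(field, spec.background_smoothness)
    span = field.max() - field.min()
    if span > 0:
        field = (field - field.min()) / span
    bg = 0.3 + 0.4 * field

    speckle = ndimage.gaussian_filter(rng.standard_normal((side,) * 3), 1.0)
    shift = spec.texture_contrast * (1.0 + 0.5 * speckle)
    cube = bg.copy()
    fg = mask.astype(bool)
    cube[fg] = bg[fg] + shift[fg]
    cube = np.clip(cube, 0.0, 1.0).astype(np.float32)
    return CubeRecord(
        cube=cube,
        mask_cube=mask,
        origin=(0, 0, 0),
        intensity_window=(0.0, 1.0),
    )


def generate_dataset(n: int, spec: PhantomSpec) -> list[CubeRecord]:
    """``n`` independent phantoms with per-item seeds derived from the spec
    seed (kept within the 32-bit range)."""
    base = np.random.default_rng(spec.seed)
    seeds = base.integers(0, 2**31 - 1, size=n)
    return [generate_pair(replace(spec, seed=int(s))) for s in seeds]


def condition_of(mask: np.ndarray) -> np.ndarray:
    """Lesion-size condition: normalised log-volume c = log(V)/log(side³).

    Returns a length-1 float vector; c = 0 for a single-voxel lesion and
    c = 1 for a mask filling the whole cube.
    """
    mask = np.asarray(mask)
    volume = int((mask > 0.5).sum())
    if volume == 0:
        raise ValueError("condition undefined for an empty mask")
    side = mask.shape[-1]
    return np.array([math.log(volume) / math.log(side**3)], dtype=np.float64)
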