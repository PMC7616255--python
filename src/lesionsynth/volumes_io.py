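"""NIfTI volume I/O and lesion-centred cube extraction / paste-back.

The networks operate on fixed-size cubes (64³ by default) cut from full
scans around the lesion.  This module reads image/mask pairs, extracts a
cube centred on the mask's foreground centroid (zero-padded at volume
borders, shifted minimally when the centroid sits off-centre inside the
bounding box), min–max normalises intensities to [0, 1] while recording the
window for exact inversion, and pastes synthesised cubes back into a host
volume with optional Gaussian feathering at the mask boundary.

Conventions: voxel indices are 0-based, the cube origin is the inclusive
lower corner, all ranges are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VolumePair",
    "CubeRecord",
    "load_volume_pair",
    "save_volume_pair",
    "extract_cube",
    "paste_cube",
]


@dataclass
class VolumePair:
    """A 3D scan and its binary lesion mask on the same voxel grid."""

    image: np.ndarray
    mask: np.ndarray
    voxel_spacing: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask)
        if self.image.ndim != 3:
            raise ValueError(f"image must be 3D, got shape {self.image.shape}")
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}"
            )
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask must be binary after load, found values {vals}")


@dataclass
class CubeRecord:
    """A fixed-size cube cut from a volume, normalised to [0, 1]."""

    cube: np.ndarray
    mask_cube: np.ndarray
    origin: tuple[int, int, int]
    intensity_window: tuple[float, float]

    @property
    def side(self) -> int:
        return self.cube.shape[0]

    @property
    def condition(self) -> np.ndarray:
        from .phantom import condition_of

        return condition_of(self.mask_cube)


def load_volume_pair(image_path, mask_path) -> VolumePair:
    """Read an image/mask NIfTI pair; the mask is binarised (>0.5 → 1)."""
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    image = np.asanyarray(img.dataobj).astype(np.float64)
    mask = (np.asanyarray(msk.dataobj) > 0.5).astype(np.uint8)
    if image.ndim != 3:
        raise ValueError(f"expected a 3D image, got shape {image.shape}")
    if image.shape != mask.shape:
        raise ValueError(
            f"image shape {image.shape} does not match mask shape {mask.shape}"
        )
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    return VolumePair(image=image, mask=mask, voxel_spacing=spacing, affine=img.affine)


def save_volume_pair(pair: VolumePair, image_path, mask_path) -> None:
    """Write the pair as NIfTI, preserving affine; mask as uint8."""
    nib.save(nib.Nifti1Image(pair.image.astype(np.float32), pair.affine), str(image_path))
    nib.save(nib.Nifti1Image(pair.mask.astype(np.uint8), pair.affine), str(mask_path))


def _mask_bbox(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    fg = np.argwhere(mask > 0)
    return fg.min(axis=0), fg.max(axis=0)


def extract_cube(pair: VolumePair, side: int = 64) -> CubeRecord:
    """Cut a ``side``³ cube containing the whole lesion.

    The cube is centred on the foreground centroid (rounded to the voxel
    grid) and zero-padded where it overhangs the volume.  If centroid
    centring would leave part of the lesion bounding box outside, the origin
    is shifted by the minimal amount that restores containment.
    """
    if (pair.mask > 0).sum() == 0:
        raise ValueError("cannot extract a cube around an empty mask")
    lo, hi = _mask_bbox(pair.mask)
    extent = hi - lo + 1
    if (extent > side).any():
        needed = int(extent.max())
        raise ValueError(
            f"mask bounding box extent {tuple(extent)} exceeds side {side}; "
            f"need side >= {needed}"
        )
    centroid = np.argwhere(pair.mask > 0).mean(axis=0)
    origin = np.round(centroid).astype(int) - side // 2
    # minimal shift so [origin, origin+side) covers [lo, hi]
    origin = np.minimum(np.maximum(origin, hi + 1 - side), lo)

    shape = np.array(pair.image.shape)
    src_lo = np.maximum(origin, 0)
    src_hi = np.minimum(origin + side, shape)
    dst_lo = src_lo - origin
    dst_hi = dst_lo + (src_hi - src_lo)
    src_sl = tuple(slice(a, b) for a, b in zip(src_lo, src_hi))
    dst_sl = tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))

    raw = np.zeros((side,) * 3, dtype=np.float64)
    mask_cube = np.zeros((side,) * 3, dtype=np.uint8)
    raw[dst_sl] = pair.image[src_sl]
    mask_cube[dst_sl] = pair.mask[src_sl]

    in_volume = pair.image[src_sl]
    low, high = float(in_volume.min()), float(in_volume.max())
    if high > low:
        cube = np.zeros((side,) * 3, dtype=np.float32)
        cube[dst_sl] = (raw[dst_sl] - low) / (high - low)
    else:
        cube = np.zeros((side,) * 3, dtype=np.float32)
    return CubeRecord(
        cube=cube,
        mask_cube=mask_cube,
        origin=tuple(int(o) for o in origin),
        intensity_window=(low, high),
    )


def paste_cube(
    pair: VolumePair,
    record: CubeRecord,
    new_cube: np.ndarray,
    new_mask: np.ndarray,
    blend_sigma: float = 1.0,
) -> VolumePair:
    """Insert a synthesised lesion cube back into a host volume.

    Inside the new mask, intensities are replaced by the de-normalised cube
    values (the inverse of the recorded min–max window).  With
    ``blend_sigma > 0`` the transition just outside the mask is feathered by
    a Gaussian-smoothed alpha map (hard inside the mask); with
    ``blend_sigma = 0`` replacement is exact.  Voxels away from the (blurred)
    mask are untouched.  The host's mask is replaced by ``new_mask`` inside
    the cube region.
    """
    side = record.side
    new_cube = np.asarray(new_cube, dtype=np.float64)
    new_mask = (np.asarray(new_mask) > 0.5).astype(np.uint8)
    if new_cube.shape != (side,) * 3 or new_mask.shape != (side,) * 3:
        raise ValueError(
            f"new cube/mask must be {side}³; got {new_cube.shape} and {new_mask.shape}"
        )
    origin = np.asarray(record.origin)
    shape = np.array(pair.image.shape)
    if ((origin + side) < 1).any() or (origin >= shape).any():
        raise ValueError(f"cube origin {record.origin} lies outside volume {pair.image.shape}")

    low, high = record.intensity_window
    denorm = low + new_cube * (high - low)

    alpha = new_mask.astype(np.float64)
    if blend_sigma > 0 and new_mask.any():
        alpha = ndimage.gaussian_filter(alpha, blend_sigma)
        alpha = np.clip(alpha / max(alpha.max(), 1e-12), 0.0, 1.0)
        alpha[new_mask > 0] = 1.0
        # keep strictly untouched outside a 3-sigma dilation of the mask
        reach = int(np.ceil(3.0 * blend_sigma))
        dilated = ndimage.binary_dilation(new_mask > 0, iterations=reach)
        alpha[~dilated] = 0.0

    src_lo = np.maximum(origin, 0)
    src_hi = np.minimum(origin + side, shape)
    dst_lo = src_lo - origin
    dst_hi = dst_lo + (src_hi - src_lo)
    src_sl = tuple(slice(a, b) for a, b in zip(src_lo, src_hi))
    dst_sl = tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))

    image = pair.image.astype(np.float64, copy=True)
    a = alpha[dst_sl]
    image[src_sl] = a * denorm[dst_sl] + (1.0 - a) * image[src_sl]
    mask = pair.mask.copy()
    mask[src_sl] = new_mask[dst_sl]
    return replace(pair, image=image, mask=mask)
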