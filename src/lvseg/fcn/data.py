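"""Slice-based data pipeline for the coarse segmentation stage.

3D volumes are sliced along the Z axis into 2D images (with the matching
mask planes), multiplying the number of training samples by the Z extent and
letting a 2D network segment volumetric data plane by plane.  Gray slices
are replicated to 3 channels to match the input layout of networks designed
for RGB images.  Classical augmentation (random rotation and resizing, with
the identical geometric transform applied to image and mask) further
multiplies the sample count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ..core import LabelMask, Volume

__all__ = ["SliceStack", "slice_volume", "restack", "to_three_channel", "augment",
           "apply_transform"]


@dataclass
class SliceStack:
    """Aligned 2D slices and binary masks along Z.

    ``images`` is (Z, H, W) float; ``masks`` is (Z, H, W) in {0,1} or None
    for unlabeled stacks; ``z_index`` records each slice's source plane
    (augmented copies keep the index of their source).
    """

    images: np.ndarray
    masks: np.ndarray | None
    z_index: np.ndarray
    provenance: str = ""
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        if self.images.ndim != 3:
            raise ValueError("images must be (Z, H, W)")
        if self.masks is not None:
            self.masks = np.asarray(self.masks)
            if self.masks.shape != self.images.shape:
                raise ValueError("masks must align one-to-one with images")
            self.masks = (self.masks > 0.5).astype(np.uint8)
        self.z_index = np.asarray(self.z_index, dtype=int)
        if len(self.z_index) != len(self.images):
            raise ValueError("z_index must have one entry per slice")

    def __len__(self) -> int:
        return len(self.images)


def slice_volume(vol: Volume, mask: LabelMask | None = None, provenance: str = "") -> SliceStack:
    """Slice a volume (and its mask) along Z into ordered 2D planes."""
    if mask is not None and not mask.matches(vol):
        raise ValueError("volume and mask must share shape and spacing")
    z = vol.shape[2]
    images = np.moveaxis(np.asarray(vol.data, dtype=np.float64), 2, 0)
    masks = np.moveaxis(mask.data, 2, 0) if mask is not None else None
    return SliceStack(images, masks, np.arange(z), provenance, vol.spacing, vol.origin)


def restack(stack: SliceStack) -> tuple[Volume, LabelMask | None]:
    """Inverse of :func:`slice_volume` for an unaugmented stack."""
    if len(np.unique(stack.z_index)) != len(stack.z_index):
        raise ValueError("stack contains augmented duplicates; cannot restack")
    order = np.argsort(stack.z_index)
    vol = Volume(np.moveaxis(stack.images[order], 0, 2), stack.spacing, stack.origin)
    msk = None
    if stack.masks is not None:
        msk = LabelMask(np.moveaxis(stack.masks[order], 0, 2), stack.spacing, stack.origin)
    return vol, msk


def to_three_channel(img: np.ndarray) -> np.ndarray:
    """Replicate a single-channel 2D image into 3 identical channels (3, H, W)."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected a single-channel 2D image, got shape {img.shape}")
    return np.repeat(img[None, :, :], 3, axis=0)


def apply_transform(img: np.ndarray, angle_deg: float, scale: float,
                    order: int = 1) -> np.ndarray:
    """Rotate by ``angle_deg`` and scale by ``scale`` about the image center.

    Bilinear interpolation by default (``order=1``).  Exact multiples of 90
    degrees at scale 1 map the pixel grid onto itself and are computed by
    array rotation, bypassing interpolation entirely.
    """
    img = np.asarray(img, dtype=np.float64)
    if scale == 1.0 and angle_deg % 90.0 == 0.0 and img.shape[0] == img.shape[1]:
        return np.rot90(img, k=-int(angle_deg // 90) % 4).copy()
    th = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    mat = rot / scale  # output->input mapping
    center = (np.asarray(img.shape) - 1) / 2.0
    offset = center - mat @ center
    return ndimage.affine_transform(np.asarray(img, dtype=np.float64), mat,
                                    offset=offset, order=order, mode="constant")


def augment(
    stack: SliceStack,
    n_augments: int = 10,
    rotation_range: float = 30.0,
    scale_range: float = 0.1,
    seed: int = 0,
) -> SliceStack:
    """Random rotation/resizing augmentation; output size = input x (1 + n).

    Each augmented copy applies one random (angle, scale) draw to the image
    and the identical transform to the mask, which is re-binarized at 0.5
    after interpolation.  ``n_augments=0`` returns the stack unchanged.
    """
    if rotation_range < 0 or not 0 <= scale_range < 1:
        raise ValueError("invalid augmentation ranges")
    if n_augments == 0:
        return stack
    rng = np.random.default_rng(seed)
    images = [stack.images]
    masks = [stack.masks] if stack.masks is not None else None
    zidx = [stack.z_index]
    for _ in range(n_augments):
        ang = rng.uniform(-rotation_range, rotation_range, size=len(stack))
        sc = rng.uniform(1 - scale_range, 1 + scale_range, size=len(stack))
        imgs = np.stack([apply_transform(im, a, s)
                         for im, a, s in zip(stack.images, ang, sc)])
        images.append(imgs)
        if masks is not None:
            ms = np.stack([apply_transform(m.astype(float), a, s) > 0.5
                           for m, a, s in zip(stack.masks, ang, sc)])
            masks.append(ms.astype(np.uint8))
        zidx.append(stack.z_index)
    return SliceStack(
        np.concatenate(images),
        np.concatenate(masks) if masks is not None else None,
        np.concatenate(zidx),
        stack.provenance + "+aug",
        stack.spacing,
        stack.origin,
    )
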