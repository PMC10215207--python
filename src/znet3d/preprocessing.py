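"""Intensity normalization, resizing, tumor-mask derivation and channel stacking.

The target representation for the network is a pair of tensors per case:
a ``(4, D, H, W)`` image stack (Flair, T1, T1ce, T2, min-max normalized
per modality) and a ``(3, D, H, W)`` binary mask stack (WT, TC, ET)
derived from the 4-valued ground-truth labeling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .brats_io import MRICase, VolumeIntegrityError

log = logging.getLogger(__name__)

#: Default network resolution.
DEFAULT_TARGET_SHAPE = (128, 128, 128)

#: Label sets defining the three nested evaluation regions.
WT_LABELS = (1, 2, 4)
TC_LABELS = (1, 4)
ET_LABELS = (4,)

MASK_CHANNELS = ("WT", "TC", "ET")


@dataclass
class ModalityStack:
    """Normalized 4-channel image tensor, channel order (Flair, T1, T1ce, T2)."""

    data: np.ndarray  # (4, D, H, W) float32 in [0, 1]
    case_id: str

    @property
    def shape(self):
        return tuple(self.data.shape)


@dataclass
class MaskStack:
    """Binary 3-channel target tensor, channel order (WT, TC, ET)."""

    data: np.ndarray  # (3, D, H, W) uint8 in {0, 1}
    case_id: str

    @property
    def shape(self):
        return tuple(self.data.shape)

    def nesting_holds(self) -> bool:
        wt, tc, et = self.data
        return bool(np.all(et <= tc) and np.all(tc <= wt))


def minmax_normalize(volume: np.ndarray) -> np.ndarray:
    """Map intensities linearly onto [0, 1]; a constant volume maps to zeros."""
    volume = np.asarray(volume, dtype=np.float32)
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains NaN or Inf")
    lo = volume.min()
    hi = volume.max()
    if hi == lo:
        return np.zeros_like(volume)
    return (volume - lo) / (hi - lo)


def resize_volume(volume, target_shape, mode: str = "image") -> np.ndarray:
    """Resample a 3D volume to ``target_shape``.

    ``mode="image"`` uses trilinear interpolation; ``mode="label"`` uses
    nearest-neighbour so the output value set is a subset of the input's.
    Output voxel centers are mapped onto input voxel centers (the
    half-pixel convention), which handles anisotropic changes such as
    155 -> 128 along one axis the same way as isotropic ones.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={volume.ndim}")
    target_shape = tuple(int(t) for t in target_shape)
    if len(target_shape) != 3 or any(t <= 0 for t in target_shape):
        raise ValueError(f"invalid target shape {target_shape}")
    if mode not in ("image", "label"):
        raise ValueError(f"mode must be 'image' or 'label', got {mode!r}")
    if tuple(volume.shape) == target_shape:
        return volume.copy()

    coords = np.meshgrid(
        *(
            (np.arange(t, dtype=np.float64) + 0.5) * (s / t) - 0.5
            for s, t in zip(volume.shape, target_shape)
        ),
        indexing="ij",
    )
    order = 1 if mode == "image" else 0
    out = ndimage.map_coordinates(
        volume.astype(np.float32 if mode == "image" else volume.dtype),
        np.stack(coords),
        order=order,
        mode="nearest",
    )
    return out


def derive_masks(seg: np.ndarray, case_id: str = "") -> MaskStack:
    """Derive the nested (WT, TC, ET) binary masks from a label volume.

    Label 3 ("missing label") is treated as background, with a warning so
    the information loss is visible in logs.  Any label outside {0..4}
    raises.
    """
    seg = np.asarray(seg)
    values = set(np.unique(seg).tolist())
    if not values <= {0, 1, 2, 3, 4}:
        raise VolumeIntegrityError(
            f"seg contains invalid label values {sorted(values - {0, 1, 2, 3, 4})}"
        )
    if 3 in values:
        log.warning(
            "case %s: label 3 (missing label) present in seg; treating as background",
            case_id or "<unnamed>",
        )
    wt = np.isin(seg, WT_LABELS)
    tc = np.isin(seg, TC_LABELS)
    et = np.isin(seg, ET_LABELS)
    data = np.stack([wt, tc, et]).astype(np.uint8)
    return MaskStack(data=data, case_id=case_id)


def stack_case(
    case: MRICase, target_shape=DEFAULT_TARGET_SHAPE
) -> Tuple[ModalityStack, Optional[MaskStack]]:
    """Normalize, resize and stack one case's modalities (and masks if labeled).

    Each modality is min-max normalized per case, then trilinearly
    resized, so values remain in [0, 1].  The label volume, when present,
    is resized first (nearest-neighbour) and the three masks are derived
    from the resized labels — this keeps the mask channels mutually
    consistent.
    """
    case.validate()
    channels = [
        resize_volume(minmax_normalize(vol), target_shape, mode="image")
        for vol in case.modalities()
    ]
    stack = ModalityStack(
        data=np.stack(channels).astype(np.float32), case_id=case.case_id
    )
    masks = None
    if case.seg is not None:
        seg_r = resize_volume(case.seg, target_shape, mode="label")
        masks = derive_masks(seg_r, case_id=case.case_id)
    return stack, masks
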