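"""Rotation-based training-set expansion.

Each case contributes the original pair plus one rotated copy per angle
in the plan; the default four angles inside [-5, +15] degrees give the
5x expansion (369 cases -> 1845 pairs).  Rotations are in-plane: every
axial slice is rotated about its center, so volume shape is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .preprocessing import MaskStack, ModalityStack

#: Angles allowed by the augmentation protocol.
ANGLE_RANGE = (-5.0, 15.0)

#: Default rotation angles; together with the original this yields the
#: 5-fold expansion.
DEFAULT_ANGLES = (-5.0, 5.0, 10.0, 15.0)


@dataclass
class AugmentationPlan:
    """Set of in-plane rotation angles applied to every training case."""

    angles_deg: Tuple[float, ...] = DEFAULT_ANGLES
    include_original: bool = True

    def __post_init__(self):
        self.angles_deg = tuple(float(a) for a in self.angles_deg)
        for a in self.angles_deg:
            if a == 0.0:
                raise ValueError("plan angles must be nonzero (0 is the original)")
            if not (ANGLE_RANGE[0] <= a <= ANGLE_RANGE[1]):
                raise ValueError(
                    f"angle {a} outside the allowed range {ANGLE_RANGE}"
                )
        if not self.angles_deg and not self.include_original:
            raise ValueError("empty plan: no angles and originals excluded")

    @property
    def expansion_factor(self) -> int:
        return len(self.angles_deg) + (1 if self.include_original else 0)


def rotate_volume(volume: np.ndarray, angle_deg: float, mode: str = "image") -> np.ndarray:
    """Rotate every axial slice of a 3D volume about the slice center.

    The rotation acts in the plane of the first two axes.  Image mode
    interpolates bilinearly; label mode uses nearest-neighbour so the
    value set is preserved.  Exposed corners are filled with 0.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={volume.ndim}")
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains non-finite values")
    if abs(angle_deg) > 180:
        raise ValueError(f"|angle| must be <= 180, got {angle_deg}")
    if mode not in ("image", "label"):
        raise ValueError(f"mode must be 'image' or 'label', got {mode!r}")
    if angle_deg == 0.0:
        return volume.copy()
    order = 1 if mode == "image" else 0
    return ndimage.rotate(
        volume,
        angle_deg,
        axes=(0, 1),
        reshape=False,
        order=order,
        mode="constant",
        cval=0,
    )


def rotate_case(
    stack: ModalityStack, masks: MaskStack, angle_deg: float
) -> Tuple[ModalityStack, MaskStack]:
    """Rotate a paired image/mask stack by one angle.

    All channels share the same transform; nearest-neighbour resampling
    of the masks picks the same source voxel for every channel, so the
    ET <= TC <= WT nesting is preserved.
    """
    if stack.data.shape[1:] != masks.data.shape[1:]:
        raise ValueError(
            f"paired shapes differ: {stack.data.shape[1:]} vs {masks.data.shape[1:]}"
        )
    img = np.stack(
        [rotate_volume(ch, angle_deg, mode="image") for ch in stack.data]
    ).astype(np.float32)
    msk = np.stack(
        [rotate_volume(ch, angle_deg, mode="label") for ch in masks.data]
    ).astype(np.uint8)
    return (
        ModalityStack(data=img, case_id=stack.case_id),
        MaskStack(data=msk, case_id=masks.case_id),
    )


def expand_dataset(
    cases: Sequence[Tuple[ModalityStack, MaskStack]],
    plan: AugmentationPlan = None,
) -> List[Tuple[ModalityStack, MaskStack]]:
    """Expand a list of (image, mask) pairs according to the plan.

    Deterministic order: each original (when included) is followed by its
    rotated copies in plan order.  Output length is exactly
    ``len(cases) * plan.expansion_factor``.
    """
    if plan is None:
        plan = AugmentationPlan()
    out: List[Tuple[ModalityStack, MaskStack]] = []
    for stack, masks in cases:
        if plan.include_original:
            out.append((stack, masks))
        for angle in plan.angles_deg:
            out.append(rotate_case(stack, masks, angle))
    return out
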