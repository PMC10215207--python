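"""Reading and writing BraTS-layout cases stored as NIfTI volumes.

A case is a directory ``<root>/<case_id>/`` containing one file per
modality named ``<anything>_<modality>.nii`` or ``.nii.gz`` with modality
in ``{flair, t1, t1ce, t2, seg}``.  The ``seg`` label volume is optional
(inference-only cases).  Voxel order on disk is preserved verbatim; no
axis reordering or reorientation is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import nibabel as nib
import numpy as np

log = logging.getLogger(__name__)

MODALITIES = ("flair", "t1", "t1ce", "t2")
SEG_SUFFIX = "seg"

#: Admissible ground-truth label values.  3 marks a missing label and is
#: remapped to background downstream.
VALID_SEG_VALUES = frozenset({0, 1, 2, 3, 4})


class MissingModalityError(FileNotFoundError):
    """A required modality file is absent from a case directory."""


class VolumeIntegrityError(ValueError):
    """Volumes within one case disagree on shape or content."""


@dataclass
class MRICase:
    """One subject: four modality volumes plus an optional label volume."""

    case_id: str
    flair: np.ndarray
    t1: np.ndarray
    t1ce: np.ndarray
    t2: np.ndarray
    seg: Optional[np.ndarray] = None
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(self.flair.shape)

    def modalities(self):
        """Modality volumes in the fixed channel order (Flair, T1, T1ce, T2)."""
        return (self.flair, self.t1, self.t1ce, self.t2)

    def validate(self) -> None:
        for name, vol in zip(MODALITIES, self.modalities()):
            if vol.ndim != 3:
                raise VolumeIntegrityError(f"{name} is not 3D: ndim={vol.ndim}")
            if tuple(vol.shape) != self.shape:
                raise VolumeIntegrityError(
                    f"shape mismatch: {name} has {vol.shape}, flair has {self.shape}"
                )
        if self.seg is not None:
            if tuple(self.seg.shape) != self.shape:
                raise VolumeIntegrityError(
                    f"shape mismatch: seg has {self.seg.shape}, flair has {self.shape}"
                )
            values = set(np.unique(self.seg).tolist())
            if not values <= VALID_SEG_VALUES:
                raise VolumeIntegrityError(
                    f"seg contains invalid label values {sorted(values - VALID_SEG_VALUES)}"
                )


def _find_modality_file(case_dir: Path, suffix: str) -> Optional[Path]:
    # prefer the compressed form when both exist
    for ext in (".nii.gz", ".nii"):
        hits = sorted(case_dir.glob(f"*_{suffix}{ext}"))
        if hits:
            return hits[0]
    return None


def load_case(case_dir) -> MRICase:
    """Load one BraTS-layout case directory into an :class:`MRICase`.

    Raises :class:`MissingModalityError` if an image modality file is
    absent (a missing ``_seg`` file is allowed) and
    :class:`VolumeIntegrityError` if the volumes disagree on shape.
    """
    case_dir = Path(case_dir)
    if not case_dir.is_dir():
        raise FileNotFoundError(f"case directory not found: {case_dir}")

    volumes = {}
    spacing = (1.0, 1.0, 1.0)
    affine = None
    for suffix in MODALITIES:
        path = _find_modality_file(case_dir, suffix)
        if path is None:
            raise MissingModalityError(
                f"no file matching '*_{suffix}.nii[.gz]' in {case_dir}"
            )
        img = nib.load(str(path))
        volumes[suffix] = np.asarray(img.dataobj, dtype=np.float32)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        affine = np.asarray(img.affine)

    seg = None
    seg_path = _find_modality_file(case_dir, SEG_SUFFIX)
    if seg_path is not None:
        seg = np.rint(np.asarray(nib.load(str(seg_path)).dataobj)).astype(np.int16)
        if np.any(seg == 3):
            log.warning(
                "case %s: seg contains label 3 (missing label); it will be "
                "treated as background during mask derivation",
                case_dir.name,
            )

    case = MRICase(
        case_id=case_dir.name,
        flair=volumes["flair"],
        t1=volumes["t1"],
        t1ce=volumes["t1ce"],
        t2=volumes["t2"],
        seg=seg,
        spacing=spacing,
        affine=affine,
    )
    case.validate()
    return case


def save_volume(volume, path, spacing=(1.0, 1.0, 1.0), create_parents=False) -> None:
    """Write a 3D array as a NIfTI file.

    Integer arrays round-trip exactly; floats are stored as float32.
    The affine is a diagonal scaling by ``spacing`` (no rotation).
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={volume.ndim}")
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains non-finite values")
    path = Path(path)
    if create_parents:
        path.parent.mkdir(parents=True, exist_ok=True)
    elif not path.parent.is_dir():
        raise IOError(f"parent directory does not exist: {path.parent}")
    if np.issubdtype(volume.dtype, np.integer):
        data = volume.astype(np.int16)
    else:
        data = volume.astype(np.float32)
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def discover_cases(root) -> list:
    """Sorted list of subdirectories of ``root`` that contain a flair file."""
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"case root not found: {root}")
    return sorted(
        d
        for d in root.iterdir()
        if d.is_dir() and _find_modality_file(d, "flair") is not None
    )
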