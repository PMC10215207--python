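"""Synthetic BraTS-layout brain phantoms.

Each phantom is a smooth brain ellipsoid on a zero background with an
optional nested spherical lesion: edema shell (label 2) around a
non-enhancing core shell (label 1) around an enhancing core (label 4).
The four pseudo-modalities share geometry but differ in region contrast
(edema brightest on pseudo-Flair, enhancing core brightest on
pseudo-T1ce), so the segmentation task is well-posed but synthetic.

Region mean intensities (before additive Gaussian noise):

============  ======  ====  ======  ====
region        flair   t1    t1ce    t2
============  ======  ====  ======  ====
background    0.00    0.00  0.00    0.00
brain tissue  0.40    0.50  0.45    0.40
edema (2)     0.90    0.30  0.40    0.80
NET (1)       0.60    0.35  0.30    0.60
ET (4)        0.70    0.70  0.95    0.50
============  ======  ====  ======  ====
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Tuple

import numpy as np

from .brats_io import MODALITIES, MRICase, save_volume

#: region -> (flair, t1, t1ce, t2) mean intensity
CONTRASTS = {
    "tissue": (0.40, 0.50, 0.45, 0.40),
    2: (0.90, 0.30, 0.40, 0.80),
    1: (0.60, 0.35, 0.30, 0.60),
    4: (0.70, 0.70, 0.95, 0.50),
}

#: fraction of the edema radius taken by the NET and ET spheres
NET_RADIUS_FRACTION = 0.70
ET_RADIUS_FRACTION = 0.40


@dataclass
class PhantomSpec:
    """Parameters of one synthetic case."""

    shape: Tuple[int, int, int] = (32, 32, 32)
    tumor_probability: float = 1.0
    tumor_radius_range: Tuple[float, float] = None
    noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if self.tumor_radius_range is None:
            # default: lesion diameter roughly 35-55% of the smallest axis
            m = min(self.shape)
            self.tumor_radius_range = (0.18 * m, 0.28 * m)
        if not (0.0 <= self.tumor_probability <= 1.0):
            raise ValueError("tumor_probability must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        semi_axes = tuple(0.42 * s for s in self.shape)
        if self.tumor_radius_range[1] >= min(semi_axes):
            raise ValueError(
                f"tumor radius {self.tumor_radius_range[1]:.1f} does not fit "
                f"inside the brain ellipsoid (semi-axes {semi_axes})"
            )


def generate_phantom(spec: PhantomSpec) -> MRICase:
    """Generate one phantom case; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    center = np.array([(s - 1) / 2.0 for s in shape])
    semi_axes = np.array([0.42 * s for s in shape])

    grids = np.indices(shape, dtype=np.float32)
    # normalized ellipsoid coordinate: <1 inside the brain
    rho = np.sqrt(
        sum(
            ((grids[i] - center[i]) / semi_axes[i]) ** 2
            for i in range(3)
        )
    )
    brain = rho < 1.0

    seg = np.zeros(shape, dtype=np.int16)
    has_tumor = rng.random() < spec.tumor_probability
    if has_tumor:
        r_ed = rng.uniform(*spec.tumor_radius_range)
        # place the lesion so the edema sphere stays inside the brain
        for _ in range(100):
            offset = rng.uniform(-0.5, 0.5, size=3) * semi_axes
            tumor_center = center + offset
            # conservative containment check in ellipsoid-normalized units
            margin = np.sqrt(np.sum((offset / semi_axes) ** 2)) + r_ed / semi_axes.min()
            if margin < 0.95:
                break
        else:
            tumor_center = center
        dist = np.sqrt(
            sum((grids[i] - tumor_center[i]) ** 2 for i in range(3))
        )
        seg[dist < r_ed] = 2
        seg[dist < NET_RADIUS_FRACTION * r_ed] = 1
        seg[dist < ET_RADIUS_FRACTION * r_ed] = 4

    volumes = []
    for m_idx in range(4):
        vol = np.zeros(shape, dtype=np.float32)
        vol[brain] = CONTRASTS["tissue"][m_idx]
        for label in (2, 1, 4):
            vol[seg == label] = CONTRASTS[label][m_idx]
        if spec.noise_sigma > 0:
            vol += rng.normal(0.0, spec.noise_sigma, shape).astype(np.float32)
        volumes.append(vol)

    return MRICase(
        case_id=f"phantom_{spec.seed:05d}",
        flair=volumes[0],
        t1=volumes[1],
        t1ce=volumes[2],
        t2=volumes[3],
        seg=seg,
    )


def generate_dataset(n: int, spec: PhantomSpec, out_root) -> List[Path]:
    """Write ``n`` phantom cases (seeds ``spec.seed + i``) as BraTS-layout
    directories under ``out_root``; returns the sorted case paths."""
    if n < 0:
        raise ValueError("n must be >= 0")
    out_root = Path(out_root)
    out_root.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(n):
        case_spec = PhantomSpec(
            shape=spec.shape,
            tumor_probability=spec.tumor_probability,
            tumor_radius_range=spec.tumor_radius_range,
            noise_sigma=spec.noise_sigma,
            seed=spec.seed + i,
        )
        case = generate_phantom(case_spec)
        case_dir = out_root / case.case_id
        case_dir.mkdir(exist_ok=True)
        for name, vol in zip(MODALITIES, case.modalities()):
            save_volume(vol, case_dir / f"{case.case_id}_{name}.nii.gz")
        save_volume(case.seg, case_dir / f"{case.case_id}_seg.nii.gz")
        paths.append(case_dir)
    return sorted(paths)
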