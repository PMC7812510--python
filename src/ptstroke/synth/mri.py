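"""Synthetic ex-vivo T2-weighted volumes with a hyperintense cortical lesion.

A bilateral noisy background carries one ipsilateral half-ellipsoid lesion
near the cortical surface whose true volume is drawn from the group
calibration (urethane ~12.9 mm^3, ketamine ~5.3 mm^3 medians).  The default
geometry matches the acquisition: 256 x 256 in-plane over a 25.6 mm field of
view and 84 axial slices of 0.25 mm (a scaled-down shape is accepted for
tests).
"""

from __future__ import annotations

import numpy as np

from ..config import ScenarioConfig
from ..lesion_mri import MRIVolume
from .truth import GroundTruthLog

_DOMAIN_MRI = 303


def generate_mri(
    config: ScenarioConfig,
    shape: tuple[int, int, int] = (256, 256, 84),
    voxel_size_mm: tuple[float, float, float] = (0.1, 0.1, 0.25),
    background: float = 100.0,
    noise_sd: float = 5.0,
    contrast_sd: float = 5.0,
) -> tuple[MRIVolume, GroundTruthLog]:
    """Generate one T2-weighted volume and its lesion ground truth."""
    rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, _DOMAIN_MRI])
    nx, ny, nz = shape
    data = background + rng.normal(0.0, noise_sd, size=shape)
    truth = GroundTruthLog(group=config.group.value, seed=config.seed)
    truth.lesion_volume_mm3 = 0.0

    if config.group.has_pt:
        target_mm3 = config.draw("lesion_volume_mm3")
        vx, vy, vz = voxel_size_mm
        hemisphere_mm3 = (nx / 2) * ny * nz * vx * vy * vz
        if target_mm3 >= hemisphere_mm3:
            raise ValueError("lesion volume exceeds the hemisphere")
        # half-ellipsoid under the cortical surface: volume (2/3) pi a a b
        c_mm = (target_mm3 * 3.0 / (2.0 * np.pi * 1.0 * 1.2)) ** (1.0 / 3.0)
        a_mm, b_mm = c_mm, 1.2 * c_mm       # in-plane x/y, axial z scaled
        cx = int(round(nx * 0.75))
        cy = int(round(ny * 0.25))          # near the dorsal (cortical) surface
        cz = nz // 2
        xs = (np.arange(nx) - cx) * vx
        ys = (np.arange(ny) - cy) * vy
        zs = (np.arange(nz) - cz) * vz

        def build(scale: float) -> np.ndarray:
            ex = (xs[:, None, None] / (a_mm * scale)) ** 2
            ey = (ys[None, :, None] / (a_mm * scale)) ** 2
            ez = (zs[None, None, :] / (b_mm * scale)) ** 2
            return (ex + ey + ez <= 1.0) & (ys[None, :, None] >= 0.0)

        mask = build(1.0)
        # one correction pass against voxelization/cut-plane bias
        actual = mask.sum() * vx * vy * vz
        if actual > 0:
            mask = build((target_mm3 / actual) ** (1.0 / 3.0))
        data[mask] += contrast_sd * noise_sd
        truth.lesion_mask = mask
        truth.lesion_volume_mm3 = float(mask.sum()) * vx * vy * vz

    vol = MRIVolume(data=data, voxel_size_mm=voxel_size_mm)
    return vol, truth
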