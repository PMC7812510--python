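"""Ex-vivo T2-weighted MRI lesion volumetry.

The cortical photothrombotic lesion appears hyperintense on T2-weighted
images.  Volume is quantified by summing hyperintense voxels relative to the
mirrored contralateral hemisphere: per axial slice, an ipsilateral voxel is
hyperintense when its intensity exceeds the contralateral mirror region's
mean + k·SD (k = 2 by default); connected components smaller than 20 voxels
are discarded as noise.  Manually outlined masks can be ingested for
comparison, and paired segmentations are compared by Spearman correlation of
volumes plus per-subject Dice overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import spearmanr


@dataclass
class MRIVolume:
    """Intensity volume with (x, y, z) = (sagittal, coronal-in-plane, axial)."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (0.1, 0.1, 0.25)
    midline_x: float | None = None        # sagittal midline plane, voxel units
    ipsilateral: str = "right"            # lesion side: x above/below midline

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("MRI volume must be 3-D")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if self.midline_x is None:
            self.midline_x = (self.data.shape[0] - 1) / 2.0
        if not (0 < self.midline_x < self.data.shape[0] - 1):
            raise ValueError("midline plane must lie inside the volume")

    @property
    def voxel_volume_mm3(self) -> float:
        vx, vy, vz = self.voxel_size_mm
        return vx * vy * vz


@dataclass
class LesionSegmentation:
    mask: np.ndarray
    voxel_volume_mm3: float
    method: str                          # "automated" | "manual_ingest"
    k_sd_threshold: float | None = None

    @property
    def volume_mm3(self) -> float:
        return float(self.mask.sum()) * self.voxel_volume_mm3


def _hemisphere_indices(vol: MRIVolume) -> tuple[np.ndarray, np.ndarray]:
    """Ipsilateral x indices and their contralateral mirrors."""
    nx = vol.data.shape[0]
    xs = np.arange(nx)
    ipsi = xs[xs > vol.midline_x] if vol.ipsilateral == "right" else xs[xs < vol.midline_x]
    mirror = np.round(2.0 * vol.midline_x - ipsi).astype(int)
    ok = (mirror >= 0) & (mirror < nx)
    if not ok.all() or ipsi.size == 0:
        raise ValueError("midline too close to the volume edge: no contralateral data")
    return ipsi, mirror


def segment_lesion(
    vol: MRIVolume, k: float = 2.0, min_component_voxels: int = 20
) -> LesionSegmentation:
    """Automated hyperintense-lesion segmentation against the mirror hemisphere.

    Slice-wise (axial) contralateral statistics tolerate intensity drift along
    the rostro-caudal axis.  The threshold is distribution-relative, so the
    segmentation is invariant to global affine intensity rescaling.
    """
    ipsi, mirror = _hemisphere_indices(vol)
    data = vol.data
    mask = np.zeros(data.shape, dtype=bool)
    contra = data[mirror, :, :]                     # (n_ipsi, ny, nz)
    mean = contra.mean(axis=(0, 1))                 # per axial slice z
    sd = contra.std(axis=(0, 1))
    thr = mean + k * sd                             # (nz,)
    mask[ipsi, :, :] = data[ipsi, :, :] > thr[None, None, :]
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n:
        sizes = np.bincount(labels.ravel())
        keep = np.flatnonzero(sizes >= min_component_voxels)
        keep = keep[keep > 0]
        mask = np.isin(labels, keep)
    return LesionSegmentation(
        mask=mask, voxel_volume_mm3=vol.voxel_volume_mm3, method="automated", k_sd_threshold=k
    )


def ingest_manual_mask(vol: MRIVolume, mask: np.ndarray) -> LesionSegmentation:
    """Wrap a manually outlined 0/1 lesion mask for the same volume."""
    m = np.asarray(mask)
    if m.shape != vol.data.shape:
        raise ValueError("mask shape does not match the volume")
    return LesionSegmentation(
        mask=m.astype(bool), voxel_volume_mm3=vol.voxel_volume_mm3, method="manual_ingest"
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks (1.0 for two empty masks)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(a, b).sum()) / float(denom)


def compare_segmentations(
    seg_a: list[LesionSegmentation], seg_b: list[LesionSegmentation]
) -> tuple[float, float, list[float]]:
    """Cross-method agreement: Spearman rho (volumes), p value, per-pair Dice."""
    if len(seg_a) != len(seg_b):
        raise ValueError("paired segmentations required")
    if len(seg_a) < 3:
        raise ValueError("need at least 3 pairs for a volume correlation")
    va = [s.volume_mm3 for s in seg_a]
    vb = [s.volume_mm3 for s in seg_b]
    rho, p = spearmanr(va, vb)
    dices = [dice(x.mask, y.mask) for x, y in zip(seg_a, seg_b)]
    return float(rho), float(p), dices
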