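"""Synthetic histology: injured/intact neuron point patterns on nine sections.

Nine coronal sections spaced 160 µm apart sample the lesion.  The true
injured total per brain is drawn from the group calibration (urethane
~3.68e5, ketamine ~2.65e5); the sampled sections carry a section sampling
fraction (20/160) of that total, allocated across sections with a smooth
lesion profile and placed uniformly within the ROI polygon (a rectangle of
ipsilateral gray matter).  Intact neurons are a uniform background pattern.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon, box

from ..config import ScenarioConfig
from ..stereology import SliceSample, StereologyDesign
from .truth import GroundTruthLog

_DOMAIN_HISTOLOGY = 404

DEFAULT_ROI_UM = (3000.0, 2000.0)


def _uniform_in_roi(
    rng: np.random.Generator, roi: Polygon, n: int
) -> np.ndarray:
    """Rejection-sample n uniform points inside a polygon."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = roi.bounds
    out: list[np.ndarray] = []
    need = n
    while need > 0:
        m = max(int(need * 1.6) + 16, 32)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        if roi.equals(box(*roi.bounds)):
            keep = np.ones(m, dtype=bool)
        else:
            from shapely import contains_xy

            keep = contains_xy(roi, xs, ys)
        pts = np.column_stack([xs, ys])[keep][:need]
        out.append(pts)
        need -= len(pts)
    return np.concatenate(out)


def generate_histology(
    config: ScenarioConfig,
    design: StereologyDesign = StereologyDesign(),
    roi: Polygon | None = None,
    intact_per_slice: int = 3000,
) -> tuple[list[SliceSample], GroundTruthLog]:
    """Generate the nine-section point patterns and injured-total ground truth."""
    rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, _DOMAIN_HISTOLOGY])
    if roi is None:
        roi = box(0.0, 0.0, *DEFAULT_ROI_UM)
    truth = GroundTruthLog(group=config.group.value, seed=config.seed)
    n_slices = design.n_slices
    if config.group.has_pt:
        total = config.draw("injured_neurons_total")
    else:
        total = 0.0
    sampled_expectation = total * design.ssf
    # smooth lesion profile across sections, peaked at the middle one
    centers = np.arange(n_slices) - (n_slices - 1) / 2.0
    weights = np.maximum(1.0 - (centers / (n_slices / 2.0 + 0.5)) ** 2, 0.05)
    weights /= weights.sum()
    slices: list[SliceSample] = []
    per_slice_true: list[int] = []
    for i in range(n_slices):
        n_inj = int(rng.poisson(sampled_expectation * weights[i]))
        inj_pts = _uniform_in_roi(rng, roi, n_inj)
        intact_pts = _uniform_in_roi(rng, roi, intact_per_slice)
        pts = np.concatenate([inj_pts, intact_pts]) if (n_inj or intact_per_slice) else np.empty((0, 2))
        flags = np.concatenate(
            [np.ones(n_inj, dtype=bool), np.zeros(intact_per_slice, dtype=bool)]
        )
        slices.append(SliceSample(roi=roi, points_um=pts, injured=flags))
        per_slice_true.append(n_inj)
    truth.injured_per_slice = per_slice_true
    # the fractionator's estimand: sampled sections stand for 1/ssf of the brain
    truth.injured_total = float(sum(per_slice_true)) / design.ssf
    return slices, truth
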