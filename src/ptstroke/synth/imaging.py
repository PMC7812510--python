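"""Synthetic intravital fluorescence imaging with ground truth.

Per timepoint (pre-PT, 1-4 h post-PT) the generator emits a 5 Hz x 306 s
fluorescein bolus stack: arterial pixels along a vessel band carry a
gamma-variate first pass plus a slowly decaying intravascular plateau,
perfused tissue follows a delayed, scaled copy, the ischemic core (a disc
that grows with time after PT) is nearly signal-free, and a peri-lesional
annulus leaks dye with a per-pixel transfer constant k (signal proportional
to the running integral of the arterial curve), so the measured permeability
index is monotone in k.  PI average images carry Gaussian spots on a smooth
background, with fewer spots under ketamine; a pre/during-SD bright-field
pair encodes the intrinsic-optical-signal front as a bright annulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from ..config import ScenarioConfig
from ..imaging import FrameStack
from .truth import GroundTruthLog

_DOMAIN_IMAGING = 202

TIMEPOINTS = ("pre", "1h", "2h", "3h", "4h")

#: ischemic-core radius (µm) per timepoint; the perfusion deficit as defined
#: at 1 h expands into initially well-perfused cortex.
CORE_RADIUS_UM = {"pre": 0.0, "1h": 150.0, "2h": 180.0, "3h": 210.0, "4h": 240.0}


@dataclass
class ImagingBundle:
    """All image products of one animal across timepoints."""

    fluorescein: dict[str, FrameStack]
    pi: dict[str, np.ndarray]
    brightfield_pre: np.ndarray
    brightfield_during_sd: np.ndarray
    pi_reference_label: str = "pre"


def _gamma_variate(t: np.ndarray, t0: float, tp: float, alpha: float = 3.0) -> np.ndarray:
    """Unit-peak gamma-variate bolus shape starting at ``t0``, peaking at t0+tp."""
    x = np.maximum(t - t0, 0.0) / tp
    return x**alpha * np.exp(alpha * (1.0 - x))


def generate_imaging(
    config: ScenarioConfig,
    shape: tuple[int, int] = (64, 64),
    pixel_size_um: float = 10.0,
    duration_s: float = 306.0,
    frame_rate_hz: float = 5.0,
    timepoints: tuple[str, ...] = TIMEPOINTS,
    noise_sd: float = 1.0,
) -> tuple[ImagingBundle, GroundTruthLog]:
    """Generate fluorescein/PI/bright-field imaging for one animal."""
    n_frames = int(round(duration_s * frame_rate_hz))
    inj = int(round(6.0 * frame_rate_hz))
    if n_frames <= inj + int(60.0 * frame_rate_hz):
        raise ValueError("stack shorter than the first-pass duration")
    rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, _DOMAIN_IMAGING])
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    r_um = np.hypot(yy - cy, xx - cx) * pixel_size_um

    truth = GroundTruthLog(
        group=config.group.value,
        seed=config.seed,
        pt_time_s=config.pt_time_s,
        fourap_time_s=config.fourap_time_s,
    )
    truth.core_center_px = (cy, cx)

    # arterial band: a horizontal vessel strip near the top edge
    arterial = np.zeros(shape, dtype=bool)
    arterial[2:4, 4: nx - 4] = True
    truth.arterial_mask = arterial

    t = (np.arange(n_frames) - inj) / frame_rate_hz
    aif_curve = 100.0 * _gamma_variate(t, 2.0, 8.0) + 12.0 * (
        1.0 - np.exp(-np.maximum(t - 2.0, 0.0) / 20.0)
    ) * np.exp(-np.maximum(t - 2.0, 0.0) / 400.0)
    tissue_curve = 0.45 * 100.0 * _gamma_variate(t, 3.5, 9.0) + 5.0 * (
        1.0 - np.exp(-np.maximum(t - 3.5, 0.0) / 20.0)
    ) * np.exp(-np.maximum(t - 3.5, 0.0) / 400.0)
    aif_int = np.cumsum(np.where(t > 0, aif_curve, 0.0)) / frame_rate_hz  # running ∫AIF dt

    has_pt = config.group.has_pt
    # per-pixel leakage constant at 4 h: Gaussian annulus just outside the core
    r4 = CORE_RADIUS_UM["4h"] if has_pt else 0.0
    k_field_4h = 2.0e-3 * np.exp(-(((r_um - (r4 + 60.0)) / 80.0) ** 2)) if has_pt else np.zeros(shape)
    truth.permeability_k = k_field_4h

    fluorescein: dict[str, FrameStack] = {}
    pi_images: dict[str, np.ndarray] = {}
    ketamine_factor = 0.6 if config.group.is_ketamine else 1.0
    # background structure kept well below the noise floor so the wide-Gaussian
    # correction removes it even at small synthetic frame sizes
    pi_background = 20.0 + 0.5 * noise_sd * np.sin(2 * np.pi * xx / nx) * np.cos(2 * np.pi * yy / ny)

    for i_tp, label in enumerate(timepoints):
        core_r = CORE_RADIUS_UM.get(label, 0.0) if has_pt else 0.0
        truth.core_radius_um[label] = core_r
        core = r_um <= core_r
        growth = i_tp / max(len(timepoints) - 1, 1)
        k_field = k_field_4h * growth if (has_pt and label != "pre") else np.zeros(shape)

        stack = np.empty((n_frames, ny, nx), dtype=np.float32)
        base = np.float32(10.0)
        tissue = np.where(core, 0.08 * aif_curve[:, None, None], tissue_curve[:, None, None])
        frames = base + tissue + k_field[None, :, :] * aif_int[:, None, None]
        frames[:, arterial] = base + aif_curve[:, None]
        stack[:] = frames
        stack += rng.normal(0.0, noise_sd, size=stack.shape).astype(np.float32)
        fluorescein[label] = FrameStack(
            frames=stack,
            frame_rate_hz=frame_rate_hz,
            injection_frame_index=inj,
            pixel_size_um=pixel_size_um,
            timepoint_label=label,
            modality="fluorescein",
        )

        # PI average image: spots accumulate with time, fewer under ketamine
        n_spots = 0 if (label == "pre" or not has_pt) else int(round(12 * i_tp * ketamine_factor))
        spot_field = np.zeros(shape)
        coords: list[tuple[float, float]] = []
        for _ in range(n_spots):
            rad = np.abs(rng.normal(core_r + 40.0, 50.0))
            ang = rng.uniform(0, 2 * np.pi)
            sy = cy + rad / pixel_size_um * np.sin(ang)
            sx = cx + rad / pixel_size_um * np.cos(ang)
            if not (2 <= sy < ny - 2 and 2 <= sx < nx - 2):
                continue
            coords.append((float(sy), float(sx)))
            spot_field += 40.0 * np.exp(-(((yy - sy) ** 2 + (xx - sx) ** 2) / (2 * 3.0**2)))
        truth.pi_spots[label] = coords
        # ground truth = spot pixels standing >2 noise SDs above background
        # after the same wide-Gaussian correction, evaluated noise-free
        corr_spots = spot_field - gaussian_filter(spot_field, 50.0, mode="nearest")
        truth.pi_true_mask[label] = corr_spots > 2.0 * noise_sd
        pi_images[label] = (
            pi_background + spot_field + rng.normal(0.0, noise_sd, size=shape)
        )

    # bright-field pair: SD front as a bright annulus at the core border
    bf_pre = 50.0 + 0.02 * r_um + rng.normal(0.0, 0.5, size=shape)
    front_r = (CORE_RADIUS_UM["1h"] if has_pt else 0.3 * r_um.max()) + 40.0
    front = 5.0 * np.exp(-(((r_um - front_r) / 30.0) ** 2))
    bf_during = bf_pre + front
    truth.core_radius_um["ios_front"] = front_r

    bundle = ImagingBundle(
        fluorescein=fluorescein,
        pi=pi_images,
        brightfield_pre=bf_pre,
        brightfield_during_sd=bf_during,
    )
    return bundle, truth
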