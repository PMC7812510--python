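"""Intravital fluorescence imaging analysis.

Repeated intravenous fluorescein boluses are imaged at 5 Hz for 306 s per
injection.  The arterial input function (AIF) — the maximal intra-arterial
first-pass intensity — normalizes tissue kinetics: pixels whose first-pass
peak stays under 30% of the AIF peak are hypoperfused, and the blood-brain
barrier permeability index of a pixel is the integral of its fluorescein
signal after the first pass divided by the time-matched AIF integral.
Propidium-iodide (PI) positive pixels mark membrane-compromised cells after
wide-Gaussian background correction.  Spatial read-outs are reduced to
profiles of signed distance from an equivalent-area circular estimate of the
lesion border fitted to the 1 h post-PT hypoperfusion mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter


@dataclass
class FrameStack:
    """One image time series (fluorescein bolus, PI average or bright-field)."""

    frames: np.ndarray               # (n_frames, ny, nx)
    frame_rate_hz: float = 5.0
    injection_frame_index: int = 30  # 6 s pre-injection lead at 5 Hz
    pixel_size_um: float = 10.0
    timepoint_label: str = "pre"
    modality: str = "fluorescein"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (time, y, x)")
        if not (0 <= self.injection_frame_index < self.frames.shape[0]):
            raise ValueError("injection index outside the stack")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def time_s(self) -> np.ndarray:
        return (np.arange(self.frames.shape[0]) - self.injection_frame_index) / self.frame_rate_hz


@dataclass
class AIFTrace:
    """Arterial input function and its first-pass window."""

    time_s: np.ndarray
    intensity: np.ndarray
    source_pixels: np.ndarray        # (k, 2) array of (y, x)
    peak_value: float
    peak_time_s: float
    first_pass_window_s: tuple[float, float]


@dataclass
class PerfusionMap:
    hypoperfused_mask: np.ndarray
    threshold_fraction: float
    pixel_size_um: float

    @property
    def hypoperfused_area_um2(self) -> float:
        return float(self.hypoperfused_mask.sum()) * self.pixel_size_um**2


@dataclass
class PermeabilityMap:
    index: np.ndarray                # dimensionless, >= 0
    window_s: tuple[float, float]
    pixel_size_um: float


@dataclass
class LesionCircle:
    center_px: tuple[float, float]   # (y, x)
    radius_um: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius must be positive")


@dataclass
class DistanceProfile:
    bin_edges_um: np.ndarray         # signed distance to border, negative inside
    mean_value: np.ndarray
    counts: np.ndarray


# ---------------------------------------------------------------------------


def _baseline_subtracted(stack: FrameStack) -> np.ndarray:
    pre = stack.frames[: max(stack.injection_frame_index, 1)]
    return stack.frames - pre.mean(axis=0)


def select_aif(stack: FrameStack, arterial_hint: np.ndarray | None = None) -> AIFTrace:
    """Select the arterial input function from a fluorescein stack.

    Among pixels whose first-pass peak occurs in the earliest-arrival
    quartile, the 0.1% with the largest peak (at least one pixel) are
    averaged.  An explicit ``arterial_hint`` mask restricts the candidate set
    instead.  The first-pass window runs from the AIF exceeding 10% of its
    peak to its decay below 20% of peak, capped at 60 s.
    """
    sig = _baseline_subtracted(stack)
    t = stack.time_s
    search = (t >= 0) & (t <= 60.0)
    seg = sig[search]
    peaks = seg.max(axis=0)
    peak_idx = seg.argmax(axis=0)
    noise = sig[: stack.injection_frame_index].std(axis=0).mean() + 1e-12
    eligible = peaks > 5.0 * noise
    if not eligible.any():
        raise ValueError("no pixel shows a first pass (flat stack)")
    if arterial_hint is not None:
        cand = eligible & np.asarray(arterial_hint, dtype=bool)
        if not cand.any():
            raise ValueError("arterial hint mask contains no first-pass pixels")
    else:
        arrival_cut = np.quantile(peak_idx[eligible], 0.25)
        cand = eligible & (peak_idx <= arrival_cut)
    k = max(1, int(round(0.001 * cand.sum())))
    flat = np.where(cand.ravel())[0]
    order = flat[np.argsort(peaks.ravel()[flat])[::-1][:k]]
    ys, xs = np.unravel_index(order, peaks.shape)
    trace = sig[:, ys, xs].mean(axis=1)
    ipk = int(np.argmax(np.where(search, trace, -np.inf)))
    peak = float(trace[ipk])
    above10 = np.flatnonzero((trace[: ipk + 1] >= 0.1 * peak) & (t[: ipk + 1] >= 0))
    i_start = int(above10[0]) if above10.size else ipk
    below20 = np.flatnonzero(trace[ipk:] < 0.2 * peak)
    i_end = ipk + int(below20[0]) if below20.size else len(trace) - 1
    t_start = float(t[i_start])
    t_end = min(float(t[i_end]), t_start + 60.0)
    return AIFTrace(
        time_s=t,
        intensity=trace,
        source_pixels=np.column_stack([ys, xs]),
        peak_value=peak,
        peak_time_s=float(t[ipk]),
        first_pass_window_s=(t_start, t_end),
    )


def perfusion_mask(
    stack: FrameStack, aif: AIFTrace, threshold_fraction: float = 0.30
) -> PerfusionMap:
    """Hypoperfused pixels: first-pass peak below 30% of the AIF peak."""
    sig = _baseline_subtracted(stack)
    t = stack.time_s
    lo, hi = aif.first_pass_window_s
    win = (t >= lo) & (t <= hi)
    peaks = sig[win].max(axis=0)
    mask = peaks < threshold_fraction * aif.peak_value
    return PerfusionMap(
        hypoperfused_mask=mask,
        threshold_fraction=threshold_fraction,
        pixel_size_um=stack.pixel_size_um,
    )


def permeability_index(stack: FrameStack, aif: AIFTrace) -> PermeabilityMap:
    """Per-pixel BBB permeability index.

    ``index = ∫ S dt / ∫ AIF dt`` with both trapezoidal integrals over the
    post-first-pass tail ``(first_pass_end, stack end]``; negative pixel
    integrals (noise) clip to 0.
    """
    sig = _baseline_subtracted(stack)
    t = stack.time_s
    tail = t > aif.first_pass_window_s[1]
    if tail.sum() < 2:
        raise ValueError("stack does not extend beyond the first-pass window")
    denom = float(np.trapezoid(aif.intensity[tail], t[tail]))
    if denom <= 0:
        raise ValueError("AIF integral over the analysis window is not positive")
    num = np.trapezoid(sig[tail], t[tail], axis=0)
    index = np.maximum(num / denom, 0.0)
    return PermeabilityMap(
        index=index,
        window_s=(aif.first_pass_window_s[1], float(t[-1])),
        pixel_size_um=stack.pixel_size_um,
    )


def pi_quantify(
    pi_image: np.ndarray,
    pre_pt_reference: np.ndarray | None,
    background_sigma_px: float = 50.0,
    n_sd: float = 2.0,
) -> tuple[int, np.ndarray]:
    """Count propidium-iodide-positive pixels after background correction.

    Both the 10-frame-average PI image and the pre-PT reference are corrected
    by subtracting their wide-Gaussian low-pass (sigma 50 px); a pixel is
    positive when its corrected value exceeds the corrected reference's
    mean + 2 SD.
    """
    if pre_pt_reference is None:
        raise ValueError("pre-PT reference image is required")
    img = np.asarray(pi_image, dtype=float)
    ref = np.asarray(pre_pt_reference, dtype=float)
    corr = img - gaussian_filter(img, background_sigma_px, mode="nearest")
    ref_corr = ref - gaussian_filter(ref, background_sigma_px, mode="nearest")
    thr = float(ref_corr.mean()) + n_sd * float(ref_corr.std())
    mask = corr > thr
    return int(mask.sum()), mask


def pi_at_electrode(
    pi_mask: np.ndarray,
    electrode_xy_px: tuple[float, float],
    pixel_size_um: float,
    diameter_um: float = 100.0,
) -> float:
    """Positive-pixel fraction within a 100 µm disc around an electrode tip."""
    mask = np.asarray(pi_mask, dtype=bool)
    cy, cx = float(electrode_xy_px[0]), float(electrode_xy_px[1])
    r_px = diameter_um / 2.0 / pixel_size_um
    ny, nx = mask.shape
    if cy - r_px < -0.5 or cx - r_px < -0.5 or cy + r_px > ny - 0.5 or cx + r_px > nx - 0.5:
        raise ValueError("electrode disc extends outside the frame")
    yy, xx = np.mgrid[0:ny, 0:nx]
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
    return float(mask[disc].sum()) / float(disc.sum())


def lesion_circle(perfusion_1h: PerfusionMap) -> LesionCircle:
    """Equivalent-area circular estimate of the lesion border.

    Center = hypoperfused-mask centroid; radius = sqrt(area / pi).
    """
    mask = perfusion_1h.hypoperfused_mask
    if not mask.any():
        raise ValueError("empty hypoperfused mask")
    ys, xs = np.nonzero(mask)
    area_um2 = perfusion_1h.hypoperfused_area_um2
    return LesionCircle(
        center_px=(float(ys.mean()), float(xs.mean())),
        radius_um=float(np.sqrt(area_um2 / np.pi)),
        pixel_size_um=perfusion_1h.pixel_size_um,
    )


def distance_profile(
    value_map: np.ndarray,
    circle: LesionCircle,
    pixel_size_um: float,
    bin_width_um: float = 100.0,
) -> DistanceProfile:
    """Average a per-pixel map in contiguous bins of signed border distance.

    Signed distance of a pixel is ``|pixel - center| - radius`` (µm; negative
    inside the lesion circle).  Bin counts sum to the pixel total.
    """
    vals = np.asarray(value_map, dtype=float)
    ny, nx = vals.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = circle.center_px
    dist = np.hypot(yy - cy, xx - cx) * pixel_size_um - circle.radius_um
    lo = np.floor(dist.min() / bin_width_um) * bin_width_um
    hi = np.ceil(dist.max() / bin_width_um) * bin_width_um
    edges = np.arange(lo, hi + bin_width_um, bin_width_um)
    idx = np.clip(np.digitize(dist.ravel(), edges) - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    sums = np.bincount(idx, weights=vals.ravel(), minlength=len(edges) - 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return DistanceProfile(bin_edges_um=edges, mean_value=means, counts=counts)


def ios_difference(pre_sd: np.ndarray, during_sd: np.ndarray) -> np.ndarray:
    """Intrinsic optical signal: bright-field during-SD minus pre-SD."""
    pre = np.asarray(pre_sd, dtype=float)
    dur = np.asarray(during_sd, dtype=float)
    if pre.shape != dur.shape:
        raise ValueError("bright-field image shapes differ")
    return dur - pre
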