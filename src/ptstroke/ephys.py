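"""Electrophysiology analysis: band splitting, Nernst conversion, SD and
seizure detection, propagation direction and laser-Doppler responses.

The raw electrocorticogram of each electrode is DC-coupled and wideband; it
is separated into a DC band (<= 0.5 Hz, carrying the spreading-depolarization
potential shift), an AC band (0.5-45 Hz, spontaneous activity and seizures)
and a smoothed AC power trace.  Ion-sensitive electrode potentials are mapped
to extracellular potassium with the Nernst relation anchored at a 3 mM
baseline.  A spreading depolarization (SD) is a large transient negative DC
shift with a concomitant potassium surge; electrographic seizures are
sustained AC-power elevations with only a small DC shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, sosfiltfilt

GAS_CONSTANT = 8.314462618      # J / (mol K)
FARADAY = 96485.33212           # C / mol


# ---------------------------------------------------------------------------
# containers


@dataclass
class MultimodalRecording:
    """Time-aligned two-electrode DC/ion traces plus one LDF trace.

    ``ecog_mV`` and ``ion_mV`` are ``(n_electrodes, n_samples)`` arrays on the
    shared ``time_s`` grid.  ``electrode_distance_to_border_um`` orders the
    electrodes relative to the lesion border (electrode 0 proximal).
    """

    time_s: np.ndarray
    ecog_mV: np.ndarray
    ion_mV: np.ndarray
    ldf_au: np.ndarray
    electrode_distance_to_border_um: tuple[float, ...] = (340.0, 870.0)
    pt_time_s: float | None = None
    fourap_time_s: float | None = None
    dye_injection_times_s: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.ecog_mV = np.atleast_2d(np.asarray(self.ecog_mV, dtype=float))
        self.ion_mV = np.atleast_2d(np.asarray(self.ion_mV, dtype=float))
        self.ldf_au = np.asarray(self.ldf_au, dtype=float)
        n = self.time_s.size
        if self.ecog_mV.shape[1] != n or self.ion_mV.shape[1] != n or self.ldf_au.size != n:
            raise ValueError("all channels must share one time base")
        if any(d < 0 for d in self.electrode_distance_to_border_um):
            raise ValueError("electrode distances must be >= 0")
        if self.pt_time_s is not None and not (
            self.time_s[0] <= self.pt_time_s <= self.time_s[-1]
        ):
            raise ValueError("pt_time_s outside the record")

    @property
    def fs(self) -> float:
        return 1.0 / float(self.time_s[1] - self.time_s[0])

    @property
    def n_electrodes(self) -> int:
        return self.ecog_mV.shape[0]


@dataclass
class KTrace:
    """Extracellular potassium, mM, per electrode on the recording time base."""

    time_s: np.ndarray
    k_mM: np.ndarray  # (n_electrodes, n_samples)
    baseline_mM: float = 3.0


@dataclass
class SDEvent:
    """One detected spreading depolarization (possibly on both electrodes)."""

    onsets_s: dict[int, float]
    dc_amp_mV: float                  # most negative DC excursion across electrodes
    k_peak_mM: float
    duration_s: float                 # DC below half amplitude (max over electrodes)
    k_recovery_s: float | None = None
    dc_amp_by_electrode: dict[int, float] = field(default_factory=dict)
    sd_class: str | None = None       # "onset" | "delayed"
    direction: str = "undetermined"   # "outward" | "reverse" | "undetermined"
    flag: str | None = None
    associated_seizure: int | None = None

    @property
    def onset_s(self) -> float:
        return min(self.onsets_s.values())


@dataclass
class SeizureEvent:
    """One detected electrographic seizure."""

    start_s: float
    end_s: float
    dc_shift_mV: float
    k_peak_mM: float
    power_mV2s: float
    interrupted_by_sd: bool = False

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class SDSettings:
    dc_threshold_mV: float = -10.0
    min_duration_s: float = 10.0
    merge_gap_s: float = 60.0
    match_window_s: float = 120.0
    baseline_s: float = 60.0
    k_ratio: float = 2.0
    k_window_s: float = 30.0
    direction_min_lead_s: float = 2.0
    detection_hz: float = 10.0


@dataclass(frozen=True)
class SeizureSettings:
    mad_multiplier: float = 5.0
    min_duration_s: float = 10.0
    merge_gap_s: float = 5.0
    dc_veto_mV: float = 10.0
    detection_hz: float = 10.0


# ---------------------------------------------------------------------------
# band splitting


def split_bands(
    signal_mV: np.ndarray, fs: float, power_window_s: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Separate a wideband DC-coupled ECoG into DC, AC and AC-power.

    DC is the zero-phase 4th-order low-pass at 0.5 Hz, AC the matching
    0.5-45 Hz band-pass, and AC power the squared AC signal smoothed with a
    moving window of ``power_window_s``.

    Parameters
    ----------
    signal_mV
        ``(n_samples,)`` or ``(n_channels, n_samples)`` raw traces in mV.
    fs
        Sampling rate in Hz; must exceed 90 Hz to resolve the 45 Hz band.
    """
    if fs <= 90.0:
        raise ValueError(f"sampling rate {fs} Hz too low for the 0.5-45 Hz band")
    x = np.asarray(signal_mV, dtype=float)
    sos_lo = butter(4, 0.5, btype="lowpass", fs=fs, output="sos")
    sos_bp = butter(4, (0.5, 45.0), btype="bandpass", fs=fs, output="sos")
    dc = sosfiltfilt(sos_lo, x, axis=-1)
    ac = sosfiltfilt(sos_bp, x, axis=-1)
    win = max(1, int(round(power_window_s * fs)))
    ac_power = uniform_filter1d(ac * ac, size=win, axis=-1, mode="nearest")
    return dc, ac, ac_power


def lowpass_dc(signal_mV: np.ndarray, fs: float) -> np.ndarray:
    """0.5 Hz zero-phase low-pass used for the ion-potential channel."""
    sos = butter(4, 0.5, btype="lowpass", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(signal_mV, dtype=float), axis=-1)


# ---------------------------------------------------------------------------
# Nernst conversion


def nernst_slope_mV(temperature_C: float = 37.0) -> float:
    """mV per decade of concentration: ln(10) R T / F (~61.54 mV at 37 C)."""
    t_kelvin = temperature_C + 273.15
    return math.log(10.0) * GAS_CONSTANT * t_kelvin / FARADAY * 1000.0


def nernst_to_k(
    delta_v_mV: np.ndarray | float,
    baseline_mM: float = 3.0,
    temperature_C: float = 37.0,
) -> np.ndarray | float:
    """Map an ion-potential deviation to potassium concentration.

    ``k = baseline * 10**(dV / s)`` with the Nernst slope ``s``; ``dV`` is the
    ion potential relative to its pre-event baseline, so ``dV = 0`` returns
    the assumed 3 mM resting level.
    """
    if baseline_mM <= 0:
        raise ValueError("baseline concentration must be positive")
    s = nernst_slope_mV(temperature_C)
    return baseline_mM * 10.0 ** (np.asarray(delta_v_mV, dtype=float) / s)


def k_to_nernst(
    k_mM: np.ndarray | float, baseline_mM: float = 3.0, temperature_C: float = 37.0
) -> np.ndarray | float:
    """Inverse of :func:`nernst_to_k`: potential deviation for a concentration."""
    s = nernst_slope_mV(temperature_C)
    return s * np.log10(np.asarray(k_mM, dtype=float) / baseline_mM)


def k_trace(
    rec: MultimodalRecording,
    baseline_mM: float = 3.0,
    temperature_C: float = 37.0,
    reference_window_s: tuple[float, float] | None = None,
) -> KTrace:
    """Potassium traces from the (low-passed) ion channels of a recording.

    The reference potential anchoring the 3 mM baseline is the median ion
    potential over ``reference_window_s`` (default: the pre-PT window, or the
    first five minutes when no PT marker exists).
    """
    if reference_window_s is None:
        end = rec.pt_time_s if rec.pt_time_s is not None else min(300.0, rec.time_s[-1])
        reference_window_s = (rec.time_s[0], end)
    lo, hi = reference_window_s
    sel = (rec.time_s >= lo) & (rec.time_s < hi)
    if not sel.any():
        raise ValueError("empty reference window for Nernst conversion")
    ion = lowpass_dc(rec.ion_mV, rec.fs)
    ref = np.median(ion[:, sel], axis=1, keepdims=True)
    k = nernst_to_k(ion - ref, baseline_mM, temperature_C)
    return KTrace(time_s=rec.time_s, k_mM=np.asarray(k), baseline_mM=baseline_mM)


# ---------------------------------------------------------------------------
# SD detection


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True in a boolean vector."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def _rolling_pre_median(x: np.ndarray, window: int) -> np.ndarray:
    """Median of the ``window`` samples strictly before each sample."""
    s = pd.Series(x).rolling(window, min_periods=max(1, window // 10)).median().shift(1)
    return s.bfill().to_numpy()


def _detect_sds_one_electrode(
    t: np.ndarray, dc: np.ndarray, k: np.ndarray, st: SDSettings
) -> list[dict]:
    """SD candidates on a single electrode (decimated DC + potassium traces).

    Threshold crossings against a rolling pre-event median seed candidates;
    per candidate the baseline is frozen at the 60 s pre-onset median, the
    amplitude is the trough relative to that baseline, and the event interval
    is the contiguous region below half amplitude.
    """
    fs_d = 1.0 / (t[1] - t[0])
    w = int(round(st.baseline_s * fs_d))
    dev = dc - _rolling_pre_median(dc, w)
    raw = _runs(dev < st.dc_threshold_mV)
    merged: list[list[int]] = []
    for s, e in raw:
        if merged and (
            t[s] - t[merged[-1][0]] < st.merge_gap_s      # onsets closer than 60 s
            or t[s] - t[merged[-1][1] - 1] < 10.0          # brief noise split
        ):
            merged[-1][1] = e
        else:
            merged.append([s, e])
    events: list[dict] = []
    pad = int(round(st.k_window_s * fs_d))
    for i0, i1 in merged:
        if events and t[i0] <= events[-1]["t_end"]:
            continue  # run already covered by the previous event's interval
        # upper-quantile baseline: robust against the recovery tail of a
        # preceding SD still decaying inside the pre-event window
        b = float(np.quantile(dc[max(0, i0 - w): i0], 0.9)) if i0 > 0 else float(dc[0])
        # trough lies within the threshold run (the DC stays below threshold
        # through the plateau); a short extension guards truncated runs
        hi = min(t.size, i1 + int(round(30.0 * fs_d)))
        i_min = i0 + int(np.argmin(dc[i0:hi]))
        amp = float(dc[i_min] - b)
        if amp >= st.dc_threshold_mV:
            continue
        half = b + amp / 2.0
        s = i_min
        while s > 0 and dc[s - 1] < half:
            s -= 1
        e = i_min
        while e < t.size - 1 and dc[e + 1] < half:
            e += 1
        duration = float(t[e] - t[s])
        if duration < st.min_duration_s:
            continue
        # onset refinement: last crossing of 10% amplitude before the trough
        j = s
        while j > 0 and dc[j - 1] < b + 0.1 * amp:
            j -= 1
        kbase = float(np.median(k[max(0, j - w): max(1, j)]))
        kseg = k[max(0, j - pad): min(k.size, e + pad)]
        kpeak = float(kseg.max()) if kseg.size else 0.0
        if kpeak <= st.k_ratio * kbase:
            continue
        # potassium recovery: time from peak to within 10% of pre-event level
        ipk = max(0, j - pad) + int(np.argmax(kseg))
        target = kbase + 0.1 * (kpeak - kbase)
        rec_idx = np.flatnonzero(k[ipk:] <= target)
        events.append(
            {
                "t_onset": float(t[j]),
                "t_end": float(t[e]),
                "amp": amp,
                "duration": duration,
                "k_peak": kpeak,
                "k_recovery": float(rec_idx[0] / fs_d) if rec_idx.size else None,
            }
        )
    return events


def detect_sds(
    time_s: np.ndarray,
    dc_by_electrode: np.ndarray,
    k_by_electrode: np.ndarray,
    settings: SDSettings = SDSettings(),
) -> list[SDEvent]:
    """Detect spreading depolarizations on one or two electrodes.

    An SD is reported where the DC band falls below −10 mV relative to a 60 s
    local pre-event baseline for at least 10 s and the potassium trace exceeds
    twice its local baseline nearby.  Events closer than 60 s on one electrode
    are merged; events are matched across electrodes within a 120 s window.
    Detection runs on a 10 Hz decimated copy of the (already band-limited)
    DC and potassium traces.
    """
    t = np.asarray(time_s, dtype=float)
    dc = np.atleast_2d(np.asarray(dc_by_electrode, dtype=float))
    k = np.atleast_2d(np.asarray(k_by_electrode, dtype=float))
    if t.size == 0:
        return []
    fs = 1.0 / (t[1] - t[0]) if t.size > 1 else 1.0
    step = max(1, int(round(fs / settings.detection_hz)))
    td, dcd, kd = t[::step], dc[:, ::step], k[:, ::step]
    per_electrode = [
        _detect_sds_one_electrode(td, dcd[e], kd[e], settings) for e in range(dc.shape[0])
    ]
    # cross-electrode matching (greedy in time)
    events: list[SDEvent] = []
    used: set[tuple[int, int]] = set()
    all_evs = sorted(
        ((e, i, ev) for e, evs in enumerate(per_electrode) for i, ev in enumerate(evs)),
        key=lambda x: x[2]["t_onset"],
    )
    for e, i, ev in all_evs:
        if (e, i) in used:
            continue
        used.add((e, i))
        group = {e: ev}
        for e2, evs2 in enumerate(per_electrode):
            if e2 == e or e2 in group:
                continue
            for i2, ev2 in enumerate(evs2):
                if (e2, i2) in used:
                    continue
                if abs(ev2["t_onset"] - ev["t_onset"]) <= settings.match_window_s:
                    group[e2] = ev2
                    used.add((e2, i2))
                    break
        recov = [g["k_recovery"] for g in group.values() if g.get("k_recovery") is not None]
        events.append(
            SDEvent(
                onsets_s={el: g["t_onset"] for el, g in group.items()},
                dc_amp_mV=min(g["amp"] for g in group.values()),
                k_peak_mM=max(g["k_peak"] for g in group.values()),
                duration_s=max(g["duration"] for g in group.values()),
                k_recovery_s=max(recov) if recov else None,
                dc_amp_by_electrode={el: g["amp"] for el, g in group.items()},
            )
        )
    events.sort(key=lambda ev: ev.onset_s)
    return events


def classify_sds(
    events: list[SDEvent],
    pt_time_s: float | None,
    fourap_time_s: float | None = None,
    delayed_after_min: float = 70.0,
) -> list[SDEvent]:
    """Assign onset/delayed classes by the 70 min post-PT (or 4-AP) rule.

    An SD is *delayed* iff its earliest onset is at or after PT + 70 min, or
    at or after the 4-AP start when that marker exists; otherwise it belongs
    to the onset complex.  Events preceding PT in a PT recording are flagged
    rather than classified.
    """
    cut = None
    if pt_time_s is not None:
        cut = pt_time_s + delayed_after_min * 60.0
    if fourap_time_s is not None:
        cut = fourap_time_s if cut is None else min(cut, fourap_time_s)
    for ev in events:
        if pt_time_s is not None and ev.onset_s < pt_time_s:
            ev.flag = "pre_pt"
            ev.sd_class = None
        elif cut is None:
            ev.flag = "no_markers"
            ev.sd_class = None
        else:
            ev.sd_class = "delayed" if ev.onset_s >= cut else "onset"
    return events


def propagation_direction(
    event: SDEvent,
    distances_um: tuple[float, ...],
    min_lead_s: float = 2.0,
) -> str:
    """Direction of spread from inter-electrode onset delay.

    *outward* (core to periphery) if the electrode nearer the lesion border
    leads by more than ``min_lead_s``; *reverse* if it lags by more than that;
    *undetermined* otherwise or when only one electrode saw the event.
    """
    if len(event.onsets_s) < 2:
        return "undetermined"
    order = np.argsort(distances_um)
    near, far = int(order[0]), int(order[-1])
    if near not in event.onsets_s or far not in event.onsets_s:
        return "undetermined"
    lead = event.onsets_s[far] - event.onsets_s[near]
    if lead > min_lead_s:
        return "outward"
    if lead < -min_lead_s:
        return "reverse"
    return "undetermined"


# ---------------------------------------------------------------------------
# seizure detection


def detect_seizures(
    time_s: np.ndarray,
    ac_power: np.ndarray,
    dc: np.ndarray,
    baseline_window_s: tuple[float, float],
    ac: np.ndarray | None = None,
    k: np.ndarray | None = None,
    settings: SeizureSettings = SeizureSettings(),
    sd_events: list[SDEvent] | None = None,
) -> list[SeizureEvent]:
    """Detect electrographic seizures from the AC-power trace of one electrode.

    A seizure is an interval where AC power exceeds the pre-4-AP baseline
    median plus five baseline MADs for at least 10 s while the concurrent DC
    excursion stays below 10 mV in magnitude (larger shifts are attributed to
    SDs and excised).  Gaps shorter than 5 s are merged.  ``power_mV2s``
    integrates the squared AC signal over the event; overlap with a detected
    SD sets ``interrupted_by_sd``.
    """
    t = np.asarray(time_s, dtype=float)
    p = np.asarray(ac_power, dtype=float)
    d = np.asarray(dc, dtype=float)
    lo, hi = baseline_window_s
    sel = (t >= lo) & (t < hi)
    if not sel.any():
        raise ValueError("missing pre-4-AP baseline window")
    med = float(np.median(p[sel]))
    mad = float(np.median(np.abs(p[sel] - med)))
    thr = med + settings.mad_multiplier * mad
    fs = 1.0 / (t[1] - t[0])
    step = max(1, int(round(fs / settings.detection_hz)))
    td, pdw, dd = t[::step], p[::step], d[::step]
    fs_d = 1.0 / (td[1] - td[0])
    w = int(round(60.0 * fs_d))
    dev = dd - _rolling_pre_median(dd, w)
    mask = pdw > thr
    # close short gaps
    gap = int(round(settings.merge_gap_s * fs_d))
    for s, e in _runs(~mask):
        if 0 < s and e < mask.size and (e - s) <= gap:
            mask[s:e] = True
    # excise samples dominated by an SD-scale DC shift
    mask &= np.abs(dev) < settings.dc_veto_mV
    events: list[SeizureEvent] = []
    for s, e in _runs(mask):
        if (td[e - 1] - td[s]) < settings.min_duration_s:
            continue
        t0, t1 = float(td[s]), float(td[e - 1])
        i0, i1 = int(np.searchsorted(t, t0)), int(np.searchsorted(t, t1))
        if ac is not None:
            seg = np.asarray(ac, dtype=float)[i0:i1]
            power = float(np.trapezoid(seg * seg, t[i0:i1]))
        else:
            power = float(np.trapezoid(p[i0:i1], t[i0:i1]))
        kseg = np.asarray(k, dtype=float)[i0:i1] if k is not None else None
        kpk = float(kseg.max()) if kseg is not None and kseg.size else float("nan")
        dseg = dev[s:e]
        events.append(
            SeizureEvent(
                start_s=t0,
                end_s=t1,
                dc_shift_mV=float(dseg.min()) if dseg.size else 0.0,
                k_peak_mM=kpk,
                power_mV2s=power,
            )
        )
    if sd_events:
        for idx, ev in enumerate(events):
            for sd in sd_events:
                sd_end = sd.onset_s + sd.duration_s
                if sd.onset_s <= ev.end_s and sd_end >= ev.start_s:
                    ev.interrupted_by_sd = True
                    sd.associated_seizure = idx
                    break
    return events


def cumulative_seizure_metrics(
    events: list[SeizureEvent], fourap_time_s: float | None = None
) -> tuple[float, float, float | None]:
    """Total seizure duration (min), total power (mV^2 s) and latency of the
    first seizure from 4-AP start (min; None without seizures)."""
    total_min = sum(ev.duration_s for ev in events) / 60.0
    total_power = sum(ev.power_mV2s for ev in events)
    latency = None
    if events and fourap_time_s is not None:
        latency = (min(ev.start_s for ev in events) - fourap_time_s) / 60.0
    return total_min, total_power, latency


# ---------------------------------------------------------------------------
# LDF and baseline potassium


def ldf_response(
    time_s: np.ndarray,
    ldf_au: np.ndarray,
    event_onset_s: float,
    baseline_window_s: tuple[float, float],
    response_window_s: float = 180.0,
) -> float:
    """Event-locked laser-Doppler response, percent of pre-PT baseline.

    ``100 * max(LDF in [onset, onset + 3 min]) / median(LDF in baseline)``.
    """
    t = np.asarray(time_s, dtype=float)
    ldf = np.asarray(ldf_au, dtype=float)
    lo, hi = baseline_window_s
    sel = (t >= lo) & (t < hi)
    if not sel.any():
        raise ValueError("empty LDF baseline window")
    base = float(np.median(ldf[sel]))
    win = (t >= event_onset_s) & (t <= event_onset_s + response_window_s)
    if not win.any():
        raise ValueError("event response window outside the record")
    return 100.0 * float(ldf[win].max()) / base


def interevent_baseline_k(
    time_s: np.ndarray,
    k_mM: np.ndarray,
    window_s: tuple[float, float],
    sd_events: list[SDEvent] | None = None,
    seizures: list[SeizureEvent] | None = None,
    pad_s: float = 120.0,
) -> float:
    """Median potassium over event-free stretches of a time window.

    Samples within ``pad_s`` of any SD (onset to onset + duration) or inside
    any seizure interval are excluded; the median of the remainder estimates
    the inter-event baseline (used for the 4th-hour potassium drift).
    """
    t = np.asarray(time_s, dtype=float)
    k = np.asarray(k_mM, dtype=float)
    sel = (t >= window_s[0]) & (t < window_s[1])
    for ev in sd_events or []:
        end = ev.onset_s + ev.duration_s + (ev.k_recovery_s or 0.0)
        sel &= ~((t >= ev.onset_s - pad_s) & (t <= end + pad_s))
    for sz in seizures or []:
        sel &= ~((t >= sz.start_s - pad_s) & (t <= sz.end_s + pad_s))
    if not sel.any():
        raise ValueError("no event-free samples in the requested window")
    return float(np.median(k[sel]))
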