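"""End-to-end electrophysiology analysis of one recording, and cohort runs.

``analyze_recording`` chains band splitting, Nernst conversion, SD detection
and classification, propagation direction, seizure detection and the derived
per-recording summary quantities used in the group tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import Group
from .config import ScenarioConfig
from .ephys import (
    KTrace,
    MultimodalRecording,
    SDEvent,
    SDSettings,
    SeizureEvent,
    SeizureSettings,
    classify_sds,
    cumulative_seizure_metrics,
    detect_sds,
    detect_seizures,
    interevent_baseline_k,
    k_trace,
    ldf_response,
    propagation_direction,
    split_bands,
)


@dataclass
class RecordingAnalysis:
    """Detected events and summary quantities for one recording."""

    sds: list[SDEvent]
    seizures: list[SeizureEvent]
    ktrace: KTrace
    first_sd_latency_min: float | None = None
    n_onset_sds: int = 0
    n_delayed_sds: int = 0
    max_sd_dc_amp_mV: float | None = None
    max_sd_k_peak_mM: float | None = None
    max_seizure_k_peak_mM: float | None = None
    cum_seizure_duration_min: float = 0.0
    cum_seizure_power_mV2s: float = 0.0
    seizure_latency_min: float | None = None
    ldf_first_onset_pct: float | None = None
    interevent_k_hour4_mM: float | None = None
    summary: dict = field(default_factory=dict)


def analyze_recording(
    rec: MultimodalRecording,
    sd_settings: SDSettings = SDSettings(),
    sz_settings: SeizureSettings = SeizureSettings(),
) -> RecordingAnalysis:
    """Run the full detection/quantification chain on one recording."""
    dc, ac, ac_power = split_bands(rec.ecog_mV, rec.fs)
    kt = k_trace(rec)
    sds = detect_sds(rec.time_s, dc, kt.k_mM, sd_settings)
    classify_sds(sds, rec.pt_time_s, rec.fourap_time_s)
    for ev in sds:
        ev.direction = propagation_direction(
            ev, rec.electrode_distance_to_border_um, sd_settings.direction_min_lead_s
        )
    seizures: list[SeizureEvent] = []
    if rec.fourap_time_s is not None:
        base_end = rec.pt_time_s if rec.pt_time_s is not None else rec.fourap_time_s
        seizures = detect_seizures(
            rec.time_s,
            ac_power[0],
            dc[0],
            baseline_window_s=(rec.time_s[0], base_end),
            ac=ac[0],
            k=kt.k_mM[0],
            settings=sz_settings,
            sd_events=sds,
        )

    out = RecordingAnalysis(sds=sds, seizures=seizures, ktrace=kt)
    onset = [ev for ev in sds if ev.sd_class == "onset"]
    delayed = [ev for ev in sds if ev.sd_class == "delayed"]
    out.n_onset_sds = len(onset)
    out.n_delayed_sds = len(delayed)
    if rec.pt_time_s is not None and sds:
        valid = [ev for ev in sds if ev.flag is None]
        if valid:
            out.first_sd_latency_min = (min(ev.onset_s for ev in valid) - rec.pt_time_s) / 60.0
    if sds:
        out.max_sd_dc_amp_mV = min(ev.dc_amp_mV for ev in sds)
        out.max_sd_k_peak_mM = max(ev.k_peak_mM for ev in sds)
    if seizures:
        peaks = [sz.k_peak_mM for sz in seizures if np.isfinite(sz.k_peak_mM)]
        out.max_seizure_k_peak_mM = max(peaks) if peaks else None
    dur, power, lat = cumulative_seizure_metrics(seizures, rec.fourap_time_s)
    out.cum_seizure_duration_min = dur
    out.cum_seizure_power_mV2s = power
    out.seizure_latency_min = lat
    if rec.pt_time_s is not None and onset:
        out.ldf_first_onset_pct = ldf_response(
            rec.time_s,
            rec.ldf_au,
            min(ev.onset_s for ev in onset),
            baseline_window_s=(rec.time_s[0], rec.pt_time_s),
        )
    if rec.pt_time_s is not None:
        h4 = (rec.pt_time_s + 180.0 * 60.0, rec.pt_time_s + 240.0 * 60.0)
        if h4[0] < rec.time_s[-1]:
            try:
                out.interevent_k_hour4_mM = interevent_baseline_k(
                    rec.time_s, kt.k_mM[0], (h4[0], min(h4[1], rec.time_s[-1])), sds, seizures
                )
            except ValueError:
                pass
    return out


def analyze_scenario(
    group: Group | str, seed: int, **config_kwargs
) -> tuple[RecordingAnalysis, "object"]:
    """Generate one scenario recording and analyze it (round-trip helper)."""
    from .synth.ephys import generate_ephys

    config = ScenarioConfig(group=Group(group), seed=seed, **config_kwargs)
    rec, truth = generate_ephys(config)
    return analyze_recording(rec), truth


def cohort_summaries(
    members: list[tuple[Group | str, int]], **config_kwargs
) -> list[RecordingAnalysis]:
    """Analyze a list of ``(group, seed)`` scenario recordings."""
    return [analyze_scenario(g, s, **config_kwargs)[0] for g, s in members]
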