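"""Synthetic two-electrode DC/ion/LDF recordings with ground truth.

The generator writes phenomenological waveforms, not a biophysical tissue
model: each spreading depolarization (SD) is a smooth negative DC ramp
(10 s fall), a plateau, and an exponential recovery, with a matched
potassium surge expressed through the Nernst relation on the ion channel,
AC-power depression, and a hyperemic laser-Doppler transient.  Seizures are
band-limited oscillations with a small DC shift and moderate potassium rise.
Event statistics (latencies, counts, amplitude envelopes, seizure burden,
4th-hour potassium drift) follow the group calibration tables.

Electrode 0 sits nearer the lesion border than electrode 1; onset SDs travel
outward (electrode 0 leads) and delayed SDs in reverse, with a configurable
inter-electrode conduction delay (default 20 s).
"""

from __future__ import annotations

import numpy as np

from ..calibration import Group
from ..config import ScenarioConfig
from ..ephys import MultimodalRecording, k_to_nernst
from .truth import GroundTruthLog, TrueEvent

_DOMAIN_EPHYS = 101  # rng stream tag, keeps the four generators independent


def _rng(config: ScenarioConfig) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, _DOMAIN_EPHYS])


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _sd_shape(
    t_rel: np.ndarray, fall_s: float, plateau_s: float, tau_s: float
) -> np.ndarray:
    """Unit-amplitude SD envelope: smooth fall, plateau, exponential recovery."""
    y = np.zeros_like(t_rel)
    rising = (t_rel >= 0) & (t_rel < fall_s)
    y[rising] = _smoothstep(t_rel[rising] / fall_s)
    plateau = (t_rel >= fall_s) & (t_rel < fall_s + plateau_s)
    y[plateau] = 1.0
    rec = t_rel >= fall_s + plateau_s
    y[rec] = np.exp(-(t_rel[rec] - fall_s - plateau_s) / tau_s)
    return y


def _bump(t_rel: np.ndarray, rise_s: float, tau_s: float) -> np.ndarray:
    """Unit-peak hyperemia transient: smooth rise then exponential decay."""
    y = np.zeros_like(t_rel)
    up = (t_rel >= 0) & (t_rel < rise_s)
    y[up] = _smoothstep(t_rel[up] / rise_s)
    down = t_rel >= rise_s
    y[down] = np.exp(-(t_rel[down] - rise_s) / tau_s)
    return y


def _sd_half_duration(amp_frac_fall_s: float, plateau_s: float, tau_s: float) -> float:
    """Analytic width of the DC excursion below half amplitude."""
    return amp_frac_fall_s / 2.0 + plateau_s + tau_s * np.log(2.0)


def _place_onset_sds(config: ScenarioConfig, rng: np.random.Generator) -> list[float]:
    pt = config.pt_time_s
    latency_min = config.draw("first_sd_latency_min")
    n = int(np.clip(round(config.draw("n_onset_sds")), 1, 8))
    times = [pt + latency_min * 60.0]
    limit = pt + 65.0 * 60.0
    for _ in range(n - 1):
        t_next = times[-1] + rng.uniform(2.0, 10.0) * 60.0
        if t_next > limit:
            break
        times.append(t_next)
    return times


def _place_seizures(
    config: ScenarioConfig,
    rng: np.random.Generator,
    t_end: float,
    sd_exclusions: list[float] | None = None,
) -> tuple[list[tuple[float, float]], float]:
    """Seizure (start, end) intervals and the common AC amplitude (mV).

    Intervals are shifted past exclusion zones around already-placed SDs
    (their slow potassium tails) so event amplitudes stay attributable.
    """
    fourap = config.fourap_time_s
    latency_s = config.draw("seizure_latency_after_4ap_min") * 60.0
    window = t_end - 120.0 - (fourap + latency_s)
    if window < 120.0:  # short test recordings: pull the first seizure earlier
        latency_s = max(120.0, 0.25 * (t_end - fourap))
        window = t_end - 120.0 - (fourap + latency_s)
    total_s = config.draw("cum_seizure_duration_min") * 60.0
    total_s = min(total_s, 0.6 * max(window, 120.0))
    power_total = config.draw("cum_seizure_power_1e4_mV2s") * 1e4
    amp = float(np.sqrt(2.0 * power_total / total_s))
    n = int(np.clip(round(np.exp(rng.normal(np.log(6.0), 0.3))), 2, 10))
    min_len = 30.0
    while n > 1 and total_s < n * min_len * 1.5:
        n -= 1
    lengths = total_s * rng.dirichlet(np.full(n, 6.0))
    lengths = np.maximum(lengths, min_len)
    lengths *= total_s / lengths.sum()
    free = max(window - total_s, 15.0 * n)
    gaps = np.maximum(free * rng.dirichlet(np.full(n, 2.0)), 15.0)
    if gaps.sum() > free:
        gaps *= free / gaps.sum()
    zones = [(t0 - 120.0, t0 + 600.0) for t0 in (sd_exclusions or [])]
    start = fourap + latency_s
    intervals = []
    for i in range(n):
        for z0, z1 in zones:
            if start < z1 and start + lengths[i] > z0:
                start = z1
        end = start + lengths[i]
        if end > t_end - 30.0:
            break
        intervals.append((float(start), float(end)))
        start = end + gaps[i]
    return intervals, amp


def _place_delayed_sds(
    config: ScenarioConfig,
    rng: np.random.Generator,
    t_end: float,
    seizures: list[tuple[float, float]],
    onset_times: list[float],
) -> list[float]:
    n = int(np.clip(round(config.draw("n_delayed_sds")), 0, 6))
    start = config.pt_time_s + 70.0 * 60.0
    if config.fourap_time_s is not None:
        start = max(start, config.fourap_time_s)
    start += 120.0
    stop = t_end - 360.0
    if stop <= start:
        return []
    times: list[float] = []
    for _ in range(n):
        for _try in range(200):
            t = rng.uniform(start, stop)
            # keep the slow potassium tail of a delayed SD (~8 min) clear of
            # seizure windows so seizure potassium peaks stay uncontaminated
            if any(t - 120.0 < e and t + 600.0 > s for s, e in seizures):
                continue
            if any(abs(t - u) < 300.0 for u in times + onset_times):
                continue
            times.append(t)
            break
    return sorted(times)


def generate_ephys(config: ScenarioConfig) -> tuple[MultimodalRecording, GroundTruthLog]:
    """Generate one synthetic multimodal recording plus its ground truth.

    Returns two-electrode wideband ECoG and ion-potential traces plus one LDF
    trace at ``config.sampling_hz``.  Identical ``(config, seed)`` pairs give
    bit-identical outputs.
    """
    rng = _rng(config)
    fs = config.sampling_hz
    n = int(round(config.duration_min * 60.0 * fs))
    t = np.arange(n) / fs
    t_end = t[-1]
    group = config.group

    truth = GroundTruthLog(
        group=group.value,
        seed=config.seed,
        pt_time_s=config.pt_time_s,
        fourap_time_s=config.fourap_time_s,
    )

    # ---- event schedule -------------------------------------------------
    onset_times: list[float] = []
    delayed_times: list[float] = []
    seizure_iv: list[tuple[float, float]] = []
    sz_amp = 0.0
    if group.has_pt:
        onset_times = _place_onset_sds(config, rng)
    if group.has_4ap:
        seizure_iv, sz_amp = _place_seizures(config, rng, t_end, sd_exclusions=onset_times)
    if group.has_pt:
        delayed_times = _place_delayed_sds(config, rng, t_end, seizure_iv, onset_times)

    # ---- baseline potassium path ---------------------------------------
    k_base = np.full(n, 3.0)
    b4 = 3.0
    if group.has_pt:
        b4 = config.draw("baseline_k_4th_hour_mM")
        pt = config.pt_time_s
        ramp = _smoothstep((t - (pt + 60.0 * 60.0)) / (110.0 * 60.0))
        k_base = 3.0 + (b4 - 3.0) * ramp
    truth.baseline_k_4th_hour_mM = b4

    # ---- channel scaffolds ----------------------------------------------
    dc = np.zeros((2, n))
    k = np.tile(k_base, (2, 1))
    ac_gain = np.ones((2, n))          # suppression multiplier for background AC
    osc = np.zeros(n)                  # seizure oscillation (common to electrodes)
    ldf = np.ones(n)

    def add_segment(arr: np.ndarray, t0: float, values: np.ndarray) -> None:
        i0 = int(round(t0 * fs))
        if i0 >= n:
            return
        m = min(values.size, n - i0)
        arr[i0: i0 + m] += values[:m]

    def mul_segment(arr: np.ndarray, t0: float, values: np.ndarray) -> None:
        i0 = int(round(t0 * fs))
        if i0 >= n:
            return
        m = min(values.size, n - i0)
        arr[i0: i0 + m] *= values[:m]

    # ---- spreading depolarizations --------------------------------------
    sd_amp_env = config.draw("sd_dc_amp_mV") if (onset_times or delayed_times) else 0.0
    sd_k_env = config.draw("sd_k_peak_mM") if (onset_times or delayed_times) else 0.0
    onset_gain = config.draw("onset_sd_rcbf_pct") / 100.0
    delayed_gain = config.draw("delayed_sd_rcbf_pct") / 100.0
    delay = config.inter_electrode_delay_s

    all_sds = [(tt, "onset") for tt in onset_times] + [(tt, "delayed") for tt in delayed_times]
    all_sds.sort()
    for idx, (t0, sd_class) in enumerate(all_sds):
        frac = 1.0 if idx == 0 else rng.uniform(0.78, 0.98)
        amp = sd_amp_env * frac
        k_peak = sd_k_env * frac
        plateau = rng.uniform(30.0, 60.0)
        tau_dc = 20.0
        tau_k = 25.0 if sd_class == "onset" else 75.0
        fall = 10.0
        span = fall + plateau + 8.0 * max(tau_dc, tau_k)
        t_rel = np.arange(0.0, span, 1.0 / fs)
        dc_shape = _sd_shape(t_rel, fall, plateau, tau_dc)
        k_shape = _sd_shape(t_rel, fall * 1.5, plateau, tau_k)
        # outward SDs reach the proximal electrode 0 first; reverse SDs lag it
        onsets = {0: t0, 1: t0 + delay} if sd_class == "onset" else {0: t0 + delay, 1: t0}
        for e in (0, 1):
            e_frac = 1.0 if e == (0 if sd_class == "onset" else 1) else rng.uniform(0.90, 0.99)
            add_segment(dc[e], onsets[e], amp * e_frac * dc_shape)
            i0 = int(round(onsets[e] * fs))
            kb_local = k_base[min(i0, n - 1)]
            add_segment(k[e], onsets[e], (k_peak * e_frac - kb_local) * k_shape)
            # AC depression after the depolarization, slow recovery
            supp = 1.0 - 0.8 * _sd_shape(t_rel, fall, plateau, 120.0)
            mul_segment(ac_gain[e], onsets[e], supp)
        n_before = sum(1 for tt, cc in all_sds[:idx] if cc == sd_class)
        top_gain = onset_gain if sd_class == "onset" else delayed_gain
        gain = top_gain if n_before == 0 else 1.0 + (top_gain - 1.0) * rng.uniform(0.7, 0.95)
        t_ldf = np.arange(0.0, 240.0, 1.0 / fs)
        add_segment(ldf, t0 + 5.0, (gain - 1.0) * _bump(t_ldf, 15.0, 45.0))
        truth.events.append(
            TrueEvent(
                kind="sd",
                onsets_s=onsets,
                end_s=t0 + fall + plateau + 5.0 * tau_dc,
                dc_amp_mV=amp,
                k_peak_mM=k_peak,
                duration_s=_sd_half_duration(fall, plateau, tau_dc),
                sd_class=sd_class,
                direction="outward" if sd_class == "onset" else "reverse",
                ldf_gain=gain,
            )
        )

    # ---- seizures --------------------------------------------------------
    if seizure_iv:
        sz_dc_env = config.draw("seizure_dc_amp_mV")
        sz_k_env = config.draw("seizure_k_peak_mM")
        early_gain = config.draw("seizure_rcbf_early_pct") / 100.0
        late_gain = config.draw("seizure_rcbf_late_pct") / 100.0
        for j, (s0, s1) in enumerate(seizure_iv):
            frac = 1.0 if j == 0 else rng.uniform(0.80, 0.98)
            d = s1 - s0
            t_rel = np.arange(0.0, d, 1.0 / fs)
            env = _smoothstep(t_rel / 2.0) * _smoothstep((d - t_rel) / 2.0)
            f = rng.uniform(5.0, 12.0)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            wave = sz_amp * env * np.sin(2.0 * np.pi * f * t_rel + phase)
            add_segment(osc, s0, wave)
            # small DC plateau
            dc_shape = _smoothstep(t_rel / 5.0) * _smoothstep((d - t_rel) / 5.0)
            i0 = int(round(s0 * fs))
            kb_local = k_base[min(i0, n - 1)]
            k_shape = _sd_shape(t_rel, 20.0, max(d - 50.0, 5.0), 30.0)
            for e in (0, 1):
                add_segment(dc[e], s0, sz_dc_env * frac * dc_shape)
                add_segment(k[e], s0, (sz_k_env * frac - kb_local) * k_shape)
            gain = early_gain if j == 0 else late_gain
            add_segment(ldf, s0, (gain - 1.0) * _smoothstep(t_rel / 20.0)
                        * _smoothstep((d + 40.0 - t_rel) / 40.0))
            truth.events.append(
                TrueEvent(
                    kind="seizure",
                    onsets_s={0: s0, 1: s0},
                    end_s=s1,
                    dc_amp_mV=sz_dc_env * frac,
                    k_peak_mM=sz_k_env * frac,
                    duration_s=d,
                    ldf_gain=gain,
                    power_mV2s=0.5 * sz_amp**2 * d,
                )
            )

    # ---- assemble channels with noise ------------------------------------
    k = np.maximum(k, 1.0)
    ion = np.asarray(k_to_nernst(k, 3.0, 37.0)) + rng.normal(0.0, 0.1, size=(2, n))
    drift = 0.5 * np.sin(2.0 * np.pi * t / (30.0 * 60.0) + rng.uniform(0, 2 * np.pi))
    ecog = (
        dc
        + drift
        + ac_gain * rng.normal(0.0, 0.05, size=(2, n))
        + osc
        + rng.normal(0.0, 0.02, size=(2, n))
    )
    ldf_trace = ldf + rng.normal(0.0, 0.01, size=n)

    rec = MultimodalRecording(
        time_s=t,
        ecog_mV=ecog,
        ion_mV=ion,
        ldf_au=ldf_trace,
        pt_time_s=config.pt_time_s,
        fourap_time_s=config.fourap_time_s,
    )
    truth.events.sort(key=lambda ev: ev.onset_s)
    return rec, truth
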