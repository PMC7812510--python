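"""SD/seizure detection, classification, direction, LDF and burden metrics."""

import numpy as np
import pytest

from conftest import short_config
from ptstroke.calibration import Group
from ptstroke.ephys import (
    SDEvent,
    SeizureEvent,
    classify_sds,
    cumulative_seizure_metrics,
    detect_sds,
    detect_seizures,
    interevent_baseline_k,
    ldf_response,
    propagation_direction,
    split_bands,
)
from ptstroke.pipeline import analyze_recording
from ptstroke.synth.ephys import generate_ephys

FS = 10.0  # detection-rate traces are sufficient for the DC/K criteria
DIST = (340.0, 870.0)


def _trace(duration_s=1200.0, fs=FS):
    t = np.arange(int(duration_s * fs)) / fs
    return t, np.zeros_like(t), np.full_like(t, 3.0)


def _inject_sd(t, dc, k, onset, amp=-20.0, k_peak=39.5, plateau=40.0):
    rise = (t >= onset) & (t < onset + 10.0)
    dc[rise] += amp * (t[rise] - onset) / 10.0
    k[rise] += (k_peak - 3.0) * (t[rise] - onset) / 10.0
    top = (t >= onset + 10.0) & (t < onset + 10.0 + plateau)
    dc[top] += amp
    k[top] += k_peak - 3.0
    rec = t >= onset + 10.0 + plateau
    decay = np.exp(-(t[rec] - onset - 10.0 - plateau) / 20.0)
    dc[rec] += amp * decay
    k[rec] += (k_peak - 3.0) * decay


class TestDetectSds:
    def test_single_injected_sd_recovered(self):
        t, dc, k = _trace()
        _inject_sd(t, dc, k, onset=600.0, amp=-20.0)
        events = detect_sds(t, dc, k)
        assert len(events) == 1
        assert events[0].dc_amp_mV == pytest.approx(-20.0, rel=0.05)
        assert events[0].k_peak_mM == pytest.approx(39.5, rel=0.05)
        assert events[0].onset_s == pytest.approx(600.0, abs=10.0)

    def test_flat_trace_gives_no_events(self):
        t, dc, k = _trace()
        assert detect_sds(t, dc, k) == []

    def test_empty_trace_gives_empty_list(self):
        assert detect_sds(np.array([]), np.array([]), np.array([])) == []

    def test_seizure_scale_dc_shift_is_not_an_sd(self):
        # a -3.7 mV shift with a potassium rise stays below the SD threshold
        t, dc, k = _trace()
        _inject_sd(t, dc, k, onset=600.0, amp=-3.7, k_peak=9.1)
        assert detect_sds(t, dc, k) == []

    def test_close_events_merge(self):
        t, dc, k = _trace()
        _inject_sd(t, dc, k, onset=500.0, plateau=20.0)
        _inject_sd(t, dc, k, onset=540.0, plateau=20.0)
        assert len(detect_sds(t, dc, k)) == 1

    def test_distant_events_stay_separate(self):
        t, dc, k = _trace()
        _inject_sd(t, dc, k, onset=400.0, amp=-14.0, plateau=40.0)
        _inject_sd(t, dc, k, onset=530.0, amp=-21.0, plateau=40.0)
        events = detect_sds(t, dc, k)
        assert len(events) == 2
        assert events[0].dc_amp_mV == pytest.approx(-14.0, rel=0.05)
        assert events[1].dc_amp_mV == pytest.approx(-21.0, rel=0.05)

    def test_two_electrode_matching_and_amplitude(self):
        t, dc0, k0 = _trace()
        _, dc1, k1 = _trace()
        _inject_sd(t, dc0, k0, onset=600.0, amp=-22.0)
        _inject_sd(t, dc1, k1, onset=620.0, amp=-20.0)
        events = detect_sds(t, np.vstack([dc0, dc1]), np.vstack([k0, k1]))
        assert len(events) == 1
        assert set(events[0].onsets_s) == {0, 1}
        assert events[0].dc_amp_mV == pytest.approx(-22.0, rel=0.05)

    def test_potassium_confirmation_required(self):
        t, dc, k = _trace()
        rise = (t >= 600.0) & (t < 700.0)
        dc[rise] -= 20.0  # DC dip without any potassium surge
        assert detect_sds(t, dc, k) == []


class TestClassification:
    def _event(self, onset):
        return SDEvent(onsets_s={0: onset}, dc_amp_mV=-20.0, k_peak_mM=39.5, duration_s=60.0)

    def test_early_sd_is_onset(self):
        ev = self._event(1800.0 + 5.6 * 60.0)
        classify_sds([ev], pt_time_s=1800.0)
        assert ev.sd_class == "onset"

    def test_late_sd_is_delayed(self):
        ev = self._event(1800.0 + 80.0 * 60.0)
        classify_sds([ev], pt_time_s=1800.0)
        assert ev.sd_class == "delayed"

    def test_70_min_boundary_is_delayed(self):
        ev = self._event(1800.0 + 70.0 * 60.0)
        classify_sds([ev], pt_time_s=1800.0)
        assert ev.sd_class == "delayed"

    def test_4ap_marker_shifts_the_rule(self):
        ev = self._event(1800.0 + 40.0 * 60.0)
        classify_sds([ev], pt_time_s=1800.0, fourap_time_s=1800.0 + 30.0 * 60.0)
        assert ev.sd_class == "delayed"

    def test_pre_pt_event_flagged_not_classified(self):
        ev = self._event(600.0)
        classify_sds([ev], pt_time_s=1800.0)
        assert ev.flag == "pre_pt" and ev.sd_class is None


class TestDirection:
    def _event(self, lead_s):
        return SDEvent(
            onsets_s={0: 1000.0, 1: 1000.0 + lead_s},
            dc_amp_mV=-20.0, k_peak_mM=39.5, duration_s=60.0,
        )

    def test_near_electrode_leading_is_outward(self):
        assert propagation_direction(self._event(20.0), DIST) == "outward"

    def test_near_electrode_lagging_is_reverse(self):
        assert propagation_direction(self._event(-20.0), DIST) == "reverse"

    def test_small_lead_undetermined(self):
        assert propagation_direction(self._event(1.0), DIST) == "undetermined"

    def test_single_electrode_undetermined(self):
        ev = SDEvent(onsets_s={0: 1000.0}, dc_amp_mV=-20.0, k_peak_mM=39.5, duration_s=60.0)
        assert propagation_direction(ev, DIST) == "undetermined"


class TestDetectSeizures:
    def _signal(self, fs=200.0, duration=1800.0):
        t = np.arange(int(duration * fs)) / fs
        return t, np.zeros_like(t)

    def test_quiet_trace_has_no_seizures(self, rng):
        t, x = self._signal()
        x += rng.normal(0, 0.05, x.size)
        dc, ac, power = split_bands(x, 200.0)
        assert detect_seizures(t, power, dc, (0.0, 600.0), ac=ac) == []

    def test_unit_oscillation_power(self, rng):
        t, x = self._signal()
        x += rng.normal(0, 0.05, x.size)
        burst = (t >= 900.0) & (t < 960.0)
        x[burst] += np.sin(2 * np.pi * 10.0 * t[burst])
        dc, ac, power = split_bands(x, 200.0)
        events = detect_seizures(t, power, dc, (0.0, 600.0), ac=ac)
        assert len(events) == 1
        # 0.5 mV^2 mean power x 60 s
        assert events[0].power_mV2s == pytest.approx(30.0, rel=0.10)
        assert events[0].duration_s == pytest.approx(60.0, abs=5.0)

    def test_missing_baseline_window_errors(self):
        t, x = self._signal()
        dc, ac, power = split_bands(x, 200.0)
        with pytest.raises(ValueError):
            detect_seizures(t, power, dc, (-100.0, -50.0), ac=ac)

    def test_sd_scale_dc_shift_excised(self, rng):
        # an oscillation riding on a -20 mV DC shift belongs to the SD
        t, x = self._signal()
        x += rng.normal(0, 0.05, x.size)
        burst = (t >= 900.0) & (t < 960.0)
        x[burst] += np.sin(2 * np.pi * 10.0 * t[burst]) - 20.0
        dc, ac, power = split_bands(x, 200.0)
        events = detect_seizures(t, power, dc, (0.0, 600.0), ac=ac)
        assert sum(ev.duration_s for ev in events) < 30.0

    def test_interrupted_by_sd_flag(self, rng):
        t, x = self._signal()
        x += rng.normal(0, 0.05, x.size)
        burst = (t >= 900.0) & (t < 1000.0)
        x[burst] += np.sin(2 * np.pi * 10.0 * t[burst])
        dc, ac, power = split_bands(x, 200.0)
        sd = SDEvent(onsets_s={0: 950.0}, dc_amp_mV=-20.0, k_peak_mM=39.5, duration_s=30.0)
        events = detect_seizures(t, power, dc, (0.0, 600.0), ac=ac, sd_events=[sd])
        assert events and events[0].interrupted_by_sd
        assert sd.associated_seizure == 0

    def test_count_matches_ground_truth_on_ketamine_scenario(self, ketamine_short):
        rec, truth = ketamine_short
        res = analyze_recording(rec)
        assert len(res.seizures) == len(truth.seizures)


class TestBurdenAndLdf:
    def test_durations_add(self):
        events = [
            SeizureEvent(0.0, 300.0, -3.0, 9.0, 10.0),
            SeizureEvent(600.0, 900.0, -3.0, 9.0, 10.0),
        ]
        dur, power, lat = cumulative_seizure_metrics(events, fourap_time_s=0.0)
        assert dur == pytest.approx(10.0)
        assert power == pytest.approx(20.0)
        assert lat == pytest.approx(0.0)

    def test_empty_events(self):
        assert cumulative_seizure_metrics([], 0.0) == (0.0, 0.0, None)

    def test_flat_ldf_is_100pct(self):
        t = np.arange(0, 3600.0, 0.1)
        ldf = np.ones_like(t)
        assert ldf_response(t, ldf, 1800.0, (0.0, 600.0)) == pytest.approx(100.0)

    def test_gain_recovered(self):
        t = np.arange(0, 3600.0, 0.1)
        ldf = np.ones_like(t)
        win = (t >= 1810) & (t < 1880)
        ldf[win] += 1.8 * np.sin(np.pi * (t[win] - 1810) / 70.0)
        assert ldf_response(t, ldf, 1800.0, (0.0, 600.0)) == pytest.approx(280.0, rel=0.01)

    def test_empty_baseline_errors(self):
        t = np.arange(0, 100.0, 0.1)
        with pytest.raises(ValueError):
            ldf_response(t, np.ones_like(t), 50.0, (200.0, 300.0))

    def test_interevent_baseline_excludes_events(self):
        t = np.arange(0, 3600.0, 0.1)
        k = np.full_like(t, 4.5)
        k[(t >= 1000) & (t < 1100)] = 40.0
        sd = SDEvent(onsets_s={0: 1000.0}, dc_amp_mV=-20.0, k_peak_mM=40.0, duration_s=100.0)
        est = interevent_baseline_k(t, k, (0.0, 3600.0), sd_events=[sd])
        assert est == pytest.approx(4.5)


class TestDetectorOracleEquivalence:
    """Detector vs generator ground truth on short 4-AP scenario recordings."""

    N_RECORDINGS = 50

    def test_all_strong_sds_recovered_and_no_seizure_mislabelled(self):
        missed, amp_errs, extra = 0, [], 0
        n_true = 0
        for seed in range(1, self.N_RECORDINGS + 1):
            group = Group.URETHANE_4AP if seed % 2 else Group.KETAMINE_4AP
            rec, truth = generate_ephys(short_config(group, seed))
            res = analyze_recording(rec)
            matched = set()
            for gt in truth.sds:
                if gt.dc_amp_mV > -12.0:
                    continue
                n_true += 1
                hit = None
                for i, ev in enumerate(res.sds):
                    if i not in matched and abs(ev.onset_s - gt.onset_s) < 60.0:
                        hit = i
                        break
                if hit is None:
                    missed += 1
                else:
                    matched.add(hit)
                    amp_errs.append(
                        abs(res.sds[hit].dc_amp_mV - gt.dc_amp_mV) / abs(gt.dc_amp_mV)
                    )
            # detections of weaker true SDs (> -12 mV) are hits, not extras
            for gt in truth.sds:
                if gt.dc_amp_mV <= -12.0:
                    continue
                for i, ev in enumerate(res.sds):
                    if i not in matched and abs(ev.onset_s - gt.onset_s) < 60.0:
                        matched.add(i)
                        break
            extra += len(res.sds) - len(matched)
            # no detected SD may coincide with a pure seizure interval
            for ev in res.sds:
                for sz in truth.seizures:
                    inside = sz.onset_s + 5.0 < ev.onset_s < sz.end_s - 5.0
                    assert not (inside and ev.dc_amp_mV > -12.0), "seizure labelled as SD"
        assert n_true > 50
        assert missed == 0
        assert max(amp_errs) <= 0.05
        assert extra <= 0.05 * n_true
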