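"""Group calibration tables for the three experimental arms.

The monitored cohorts are: photothrombosis (PT) under urethane anesthesia,
PT + topical 4-aminopyridine (4-AP) under urethane, and PT + 4-AP under
ketamine/xylazine.  A fourth arm (4-AP without PT, ketamine) serves as the
no-stroke control.  Each entry stores the published median and IQR of a
group-level quantity; draws are realized via :mod:`ptstroke.distributions`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

from .distributions import LogNormalMedianIQR, NormalMedianIQR, cohort_draw


class Group(str, Enum):
    URETHANE = "urethane"
    URETHANE_4AP = "urethane_4ap"
    KETAMINE_4AP = "ketamine_4ap"
    NO_PT_4AP = "no_pt_4ap"

    @property
    def has_4ap(self) -> bool:
        return self in (Group.URETHANE_4AP, Group.KETAMINE_4AP, Group.NO_PT_4AP)

    @property
    def has_pt(self) -> bool:
        return self is not Group.NO_PT_4AP

    @property
    def is_ketamine(self) -> bool:
        return self in (Group.KETAMINE_4AP, Group.NO_PT_4AP)


# Latency to first SD after Rose Bengal injection, min.  Under ketamine the
# upper quartile is far from the median; draws are truncated so the first SD
# stays within the onset window (< 70 min post-PT by definition).
_LATENCY = {
    "urethane": LogNormalMedianIQR(5.6, 4.6, 7.3, lo=0.5, hi=65.0),
    "ketamine": LogNormalMedianIQR(9.1, 7.2, 35.9, lo=0.5, hi=65.0),
}

# Number of SDs in the onset complex (first SD plus followers within minutes).
_N_ONSET = {
    "urethane": LogNormalMedianIQR(3.0, 2.0, 5.0),
    "ketamine": LogNormalMedianIQR(1.0, 1.0, 2.0),
}

# Delayed SDs (after 70 min / 4-AP start); quartiles include 0 so a normal
# law on the count scale is used.
_N_DELAYED = {
    Group.URETHANE: NormalMedianIQR(1.0, 0.0, 4.0, lo=0.0, hi=6.0),
    Group.URETHANE_4AP: NormalMedianIQR(1.0, 0.25, 2.0, lo=0.0, hi=6.0),
    Group.KETAMINE_4AP: NormalMedianIQR(1.0, 0.5, 3.5, lo=0.0, hi=6.0),
}

_SEIZURE_LATENCY = {  # min after 4-AP start
    "urethane": LogNormalMedianIQR(51.1, 38.0, 58.9, lo=2.0, hi=100.0),
    "ketamine": LogNormalMedianIQR(18.5, 17.4, 24.6, lo=2.0, hi=100.0),
}
_CUM_SEIZURE_MIN = {  # cumulative ictal time, min
    "urethane": LogNormalMedianIQR(12.5, 8.0, 16.8, lo=2.0),
    "ketamine": LogNormalMedianIQR(19.1, 15.3, 21.9, lo=2.0),
}
_CUM_SEIZURE_POWER = {  # cumulative AC power, 1e4 mV^2 s
    "urethane": LogNormalMedianIQR(0.13, 0.12, 1.16),
    "ketamine": LogNormalMedianIQR(1.02, 0.88, 4.88),
}

_LESION_MM3 = {
    Group.URETHANE: LogNormalMedianIQR(12.9, 10.7, 16.2),
    Group.URETHANE_4AP: LogNormalMedianIQR(12.1, 11.0, 16.8),
    Group.KETAMINE_4AP: LogNormalMedianIQR(5.3, 4.8, 8.0),
}

_INJURED_NEURONS = {
    Group.URETHANE: LogNormalMedianIQR(3.68e5, 3.04e5, 4.20e5),
    Group.URETHANE_4AP: LogNormalMedianIQR(3.89e5, 3.09e5, 5.60e5),
    Group.KETAMINE_4AP: LogNormalMedianIQR(2.65e5, 2.12e5, 2.86e5),
}


@dataclass(frozen=True)
class CalibrationTable:
    """Per-group distributions of the monitored quantities.

    Every field is a median/IQR distribution object; per-recording values are
    drawn with :meth:`draw`, keyed by the recording seed and the field name so
    consecutive-seed cohorts are quantile-balanced (see
    :mod:`ptstroke.distributions`).
    """

    group: Group
    first_sd_latency_min: LogNormalMedianIQR = None  # type: ignore[assignment]
    n_onset_sds: LogNormalMedianIQR = None  # type: ignore[assignment]
    n_delayed_sds: NormalMedianIQR = None  # type: ignore[assignment]
    # Per-recording maximal SD amplitude envelope; truncated to the detector's
    # validated regime (<= -12 mV).
    sd_dc_amp_mV: NormalMedianIQR = NormalMedianIQR(-21.1, -22.8, -17.2, hi=-12.0)
    sd_k_peak_mM: LogNormalMedianIQR = LogNormalMedianIQR(39.5, 36.2, 44.4, lo=15.0)
    seizure_dc_amp_mV: NormalMedianIQR = NormalMedianIQR(-3.7, -5.5, -2.3, hi=-0.5)
    seizure_k_peak_mM: LogNormalMedianIQR = LogNormalMedianIQR(9.1, 7.5, 11.1, lo=4.0)
    onset_sd_rcbf_pct: LogNormalMedianIQR = LogNormalMedianIQR(280.0, 242.0, 382.0, lo=120.0)
    delayed_sd_rcbf_pct: LogNormalMedianIQR = LogNormalMedianIQR(173.0, 111.0, 297.0, lo=100.0)
    seizure_rcbf_early_pct: LogNormalMedianIQR = LogNormalMedianIQR(143.0, 117.0, 188.0, lo=100.0)
    seizure_rcbf_late_pct: LogNormalMedianIQR = LogNormalMedianIQR(136.0, 105.0, 173.0, lo=100.0)
    seizure_latency_after_4ap_min: LogNormalMedianIQR = None  # type: ignore[assignment]
    cum_seizure_duration_min: LogNormalMedianIQR = None  # type: ignore[assignment]
    cum_seizure_power_1e4_mV2s: LogNormalMedianIQR = None  # type: ignore[assignment]
    baseline_k_4th_hour_mM: LogNormalMedianIQR = LogNormalMedianIQR(4.5, 4.0, 6.5, lo=3.0)
    lesion_volume_mm3: LogNormalMedianIQR = None  # type: ignore[assignment]
    injured_neurons_total: LogNormalMedianIQR = None  # type: ignore[assignment]

    def draw(self, name: str, seed: int) -> float:
        dist = getattr(self, name)
        if dist is None:
            raise ValueError(f"{name} is not calibrated for group {self.group.value}")
        return cohort_draw(dist, seed, name)


def default_calibration(group: Group) -> CalibrationTable:
    """Calibration table for one experimental arm."""
    anesthetic = "ketamine" if group.is_ketamine else "urethane"
    table = CalibrationTable(
        group=group,
        first_sd_latency_min=_LATENCY[anesthetic],
        n_onset_sds=_N_ONSET[anesthetic],
        n_delayed_sds=_N_DELAYED.get(group),
        seizure_latency_after_4ap_min=_SEIZURE_LATENCY[anesthetic] if group.has_4ap else None,
        cum_seizure_duration_min=_CUM_SEIZURE_MIN[anesthetic] if group.has_4ap else None,
        cum_seizure_power_1e4_mV2s=_CUM_SEIZURE_POWER[anesthetic] if group.has_4ap else None,
        lesion_volume_mm3=_LESION_MM3.get(group),
        injured_neurons_total=_INJURED_NEURONS.get(group),
    )
    if not group.has_pt:  # no stroke: no SDs (baseline drift is skipped by the generator)
        table = replace(table, first_sd_latency_min=None, n_onset_sds=None, n_delayed_sds=None)
    return table
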