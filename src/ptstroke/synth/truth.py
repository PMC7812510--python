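"""Ground-truth containers written by the synthetic-data generators."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass
class TrueEvent:
    """One injected electrophysiological event (SD or seizure)."""

    kind: str                       # "sd" | "seizure"
    onsets_s: dict[int, float]      # per-electrode true onset (seizures: same)
    end_s: float
    dc_amp_mV: float
    k_peak_mM: float
    duration_s: float
    sd_class: str | None = None     # "onset" | "delayed" for SDs
    direction: str | None = None    # "outward" | "reverse" for SDs
    ldf_gain: float | None = None   # peak LDF as multiple of baseline
    power_mV2s: float | None = None  # seizures: injected integral of ac^2

    @property
    def onset_s(self) -> float:
        return min(self.onsets_s.values())


@dataclass
class GroundTruthLog:
    """Everything a downstream test needs to score the pipeline."""

    group: str
    seed: int
    events: list[TrueEvent] = field(default_factory=list)
    pt_time_s: float | None = None
    fourap_time_s: float | None = None
    baseline_k_4th_hour_mM: float | None = None
    # imaging
    core_center_px: tuple[float, float] | None = None
    core_radius_um: dict[str, float] = field(default_factory=dict)
    arterial_mask: object | None = None        # boolean array
    permeability_k: object | None = None       # per-pixel leakage constant, 1/s
    pi_spots: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    pi_true_mask: dict[str, object] = field(default_factory=dict)
    # MRI
    lesion_mask: object | None = None
    lesion_volume_mm3: float | None = None
    # histology
    injured_total: float | None = None
    injured_per_slice: list[int] = field(default_factory=list)

    @property
    def sds(self) -> list[TrueEvent]:
        return [e for e in self.events if e.kind == "sd"]

    @property
    def seizures(self) -> list[TrueEvent]:
        return [e for e in self.events if e.kind == "seizure"]

    def to_json(self, path: str | Path) -> None:
        """Serialize the scalar/event part of the log (arrays are dropped)."""
        d = asdict(self)
        for key in ("arterial_mask", "permeability_k", "lesion_mask", "pi_true_mask"):
            d.pop(key, None)
        Path(path).write_text(json.dumps(d, indent=2, default=str))
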