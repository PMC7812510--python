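"""Scenario configuration shared by all four synthetic-data generators."""

from __future__ import annotations

from dataclasses import dataclass, field

from .calibration import CalibrationTable, Group, default_calibration


@dataclass(frozen=True)
class ScenarioConfig:
    """One monitored animal: group, timeline and seed.

    The timeline is anchored at recording start.  Photothrombosis (PT, the
    Rose Bengal injection marker) occurs ``pre_pt_min`` minutes in; topical
    4-AP starts ``fourap_delay_min`` minutes after PT in the 4-AP arms (after
    recording start in the no-PT control).  Identical ``(config, seed)``
    reproduce bit-identical outputs.
    """

    group: Group
    seed: int
    pre_pt_min: float = 30.0
    post_pt_min: float = 240.0
    fourap_delay_min: float = 70.0
    sampling_hz: float = 200.0
    inter_electrode_delay_s: float = 20.0
    calibration: CalibrationTable | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.group, Group):
            object.__setattr__(self, "group", Group(self.group))  # raises on unknown group
        if self.post_pt_min <= 0 or self.pre_pt_min < 0:
            raise ValueError("recording duration must be positive")
        if self.sampling_hz < 100:
            raise ValueError("sampling rate must be >= 100 Hz")
        if self.group.has_4ap and not (0 < self.fourap_delay_min < self.post_pt_min):
            raise ValueError("4-AP start must fall inside the post-PT window")
        if self.calibration is None:
            object.__setattr__(self, "calibration", default_calibration(self.group))
        elif self.calibration.group is not self.group:
            raise ValueError("calibration table group mismatch")

    @property
    def duration_min(self) -> float:
        return self.pre_pt_min + self.post_pt_min

    @property
    def pt_time_s(self) -> float | None:
        """Rose Bengal injection / PT induction time, s (None without PT)."""
        return self.pre_pt_min * 60.0 if self.group.has_pt else None

    @property
    def fourap_time_s(self) -> float | None:
        if not self.group.has_4ap:
            return None
        anchor = self.pre_pt_min if self.group.has_pt else 0.0
        return (anchor + self.fourap_delay_min) * 60.0

    def draw(self, name: str) -> float:
        return self.calibration.draw(name, self.seed)
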