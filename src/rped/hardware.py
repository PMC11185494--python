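"""Stimulator-chip power and latency arithmetic.

The stimulator drives each active electrode at a fixed supply voltage
and stimulation current, so power scales linearly with the number of
driven pixels; latency scales with the number of per-pixel neighbor
comparisons.  Defaults describe a subretinal chip at 5 V supply, 100 uA
stimulation current, 2 us per single-pixel edge decision and 25 scan
clusters.  All power is reported in mW, all time in ms, unrounded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "ChipSpec",
    "activated_pixel_power",
    "processing_power",
    "frame_processing_time",
    "temporal_budget_check",
]


@dataclass(frozen=True)
class ChipSpec:
    """Electrical and timing constants of the stimulator chip.

    ``pixel_pitch_um`` is informational metadata (electrode geometry);
    it enters no computation.
    """

    supply_voltage: float = 5.0          # V
    stimulation_current: float = 100e-6  # A
    comparison_time: float = 2e-6        # s per single-pixel edge decision
    n_clusters: int = 25
    total_pixels: int = 2025
    pixel_pitch_um: tuple[float, float, float] = (80.0, 84.0, 10.0)  # w, h, gap

    def __post_init__(self) -> None:
        if min(self.supply_voltage, self.stimulation_current, self.comparison_time) <= 0:
            raise ValueError("electrical/timing values must be positive")
        if self.n_clusters < 1 or self.total_pixels < 1:
            raise ValueError("counts must be >= 1")

    @classmethod
    def from_file(cls, path) -> "ChipSpec":
        """Load from a plain-text ``key = value`` config; missing keys
        keep their defaults, unknown keys are rejected."""
        kwargs = {}
        numeric = {
            "supply_voltage": float,
            "stimulation_current": float,
            "comparison_time": float,
            "n_clusters": int,
            "total_pixels": int,
        }
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in numeric:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            kwargs[key] = numeric[key](value.strip())
        return cls(**kwargs)


def activated_pixel_power(n_active: int, spec: ChipSpec | None = None) -> float:
    """Power to drive the final activation map, in mW: n * V * I."""
    if n_active < 0:
        raise ValueError("n_active must be >= 0")
    spec = spec or ChipSpec()
    return n_active * spec.supply_voltage * spec.stimulation_current * 1e3


def processing_power(
    pixels_per_decision: int,
    n_clusters: int | None = None,
    spec: ChipSpec | None = None,
) -> float:
    """Power of the concurrent edge-decision stage, in mW.

    Each of the ``n_clusters`` blocks drives one decision neighborhood at
    a time: ``pixels_per_decision`` = center + compared neighbors (3 for
    the two-neighbor rule, 5 for the conventional four-neighbor rule).
    A cluster count of 0 is allowed and yields 0 (no concurrent blocks).
    """
    if pixels_per_decision < 1:
        raise ValueError("pixels_per_decision must be >= 1")
    spec = spec or ChipSpec()
    if n_clusters is None:
        n_clusters = spec.n_clusters
    if n_clusters < 0:
        raise ValueError("n_clusters must be >= 0")
    return pixels_per_decision * n_clusters * spec.supply_voltage * spec.stimulation_current * 1e3


def frame_processing_time(
    total_pixels: int,
    n_neighbors: int,
    spec: ChipSpec | None = None,
    parallel: bool = False,
) -> float:
    """Time to edge-assess a whole frame, in ms.

    Serial model by default: every pixel spends ``n_neighbors``
    comparison slots (4 us per pixel for the two-neighbor rule at the
    default 2 us per comparison).  ``parallel=True`` divides by the
    cluster count, modeling fully concurrent cluster scans.
    """
    if total_pixels < 0 or n_neighbors < 0:
        raise ValueError("counts must be >= 0")
    spec = spec or ChipSpec()
    t = total_pixels * n_neighbors * spec.comparison_time * 1e3
    if parallel:
        t /= spec.n_clusters
    return t


def temporal_budget_check(frame_time_ms: float, refresh_rate_hz: float) -> bool:
    """Does a frame fit in the retinal temporal-resolution budget?

    Retinal cells follow stimulation at roughly 10-25 Hz (40-100 ms per
    frame); a frame passes if it completes within one refresh period.
    """
    if refresh_rate_hz <= 0:
        raise ValueError("refresh_rate_hz must be positive")
    return frame_time_ms <= 1000.0 / refresh_rate_hz
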