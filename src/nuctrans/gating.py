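"""Event gating and apoptosis quadrant classification.

Gating keeps only events that look like single, live, nucleated cells:
brightfield area within bounds and aspect ratio high enough (singlet),
viability-dye intensity low (live), and DNA-stain total high enough
(nucleated). Criteria are evaluated in that order and the first failure is
logged per rejected event. Gate bounds are inclusive.

Quadrant classification bins events by annexin-V and viability-dye
intensity with strict-greater-than positivity on each axis, yielding the
four standard cell-death categories (live, early apoptotic, late
apoptotic/double-positive, and dye-only dead).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .synthetic import CellEvent, SyntheticPopulationSpec

_FEATURES = (
    "brightfield_area",
    "aspect_ratio",
    "livedead_intensity",
    "nuclear_stain_total",
)


@dataclass(frozen=True)
class GateConfig:
    """Thresholds for the singlet/live/nucleated gate.

    Defaults are calibrated to the synthetic generator's default geometry
    (cell radius 20 px, nucleus radius 10 px, 64x64 images, stain intensity
    100, background 5): area within [0.7, 1.4] x pi r_cell^2, aspect ratio
    at least 0.7, viability dye at most 150, and DNA-stain total at least
    28000 (background sum plus a quarter of the nominal nucleus signal).
    Real acquisitions need instrument-session-specific values; use
    ``gate_config_for`` to derive them from a population spec.
    """

    area_min: float = 880.0
    area_max: float = 1760.0
    aspect_ratio_min: float = 0.7
    livedead_max: float = 150.0
    nuclear_stain_min: float = 28_000.0

    def __post_init__(self) -> None:
        if self.area_min > self.area_max:
            raise ValueError("area_min must not exceed area_max")
        if not 0 < self.aspect_ratio_min <= 1:
            raise ValueError("aspect_ratio_min must lie in (0, 1]")

    @classmethod
    def unbounded(cls) -> "GateConfig":
        """A gate that keeps everything (identity gate)."""
        return cls(
            area_min=0.0,
            area_max=math.inf,
            aspect_ratio_min=1e-12,
            livedead_max=math.inf,
            nuclear_stain_min=0.0,
        )


def gate_config_for(spec: SyntheticPopulationSpec) -> GateConfig:
    """Derive gate thresholds matched to a synthetic population spec."""
    singlet_area = math.pi * spec.cell_radius_px**2
    n_pixels = spec.image_shape[0] * spec.image_shape[1]
    nucleus_px = math.pi * spec.nucleus_radius_px**2
    background_total = spec.background_level * n_pixels
    return GateConfig(
        area_min=0.7 * singlet_area,
        area_max=1.4 * singlet_area,
        aspect_ratio_min=0.7,
        livedead_max=150.0,
        nuclear_stain_min=background_total
        + 0.25 * spec.nuclear_stain_intensity * nucleus_px,
    )


def _first_failure(event: CellEvent, config: GateConfig) -> Optional[str]:
    for name in _FEATURES:
        value = getattr(event, name, None)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return "missing_feature"
    if not config.area_min <= event.brightfield_area <= config.area_max:
        return "area_out_of_range"
    if event.aspect_ratio < config.aspect_ratio_min:
        return "low_aspect_ratio"
    if event.livedead_intensity > config.livedead_max:
        return "high_livedead"
    if event.nuclear_stain_total < config.nuclear_stain_min:
        return "low_nuclear_stain"
    return None


def gate_events(
    events: Sequence[CellEvent], config: GateConfig
) -> tuple[list[CellEvent], list[tuple[str, str]]]:
    """Split events into kept cells and a per-event rejection log.

    Returns ``(kept, rejection_log)`` where the log holds
    ``(event_id, reason)`` pairs naming the first failed criterion, in the
    order singlet (area, then aspect ratio) -> live -> nucleated.
    """
    kept: list[CellEvent] = []
    log: list[tuple[str, str]] = []
    for event in events:
        reason = _first_failure(event, config)
        if reason is None:
            kept.append(event)
        else:
            log.append((event.event_id, reason))
    return kept, log


@dataclass(frozen=True)
class QuadrantCounts:
    """Counts and percentages of the four annexin-V / viability quadrants."""

    annexin_pos_ld_neg: int  # early apoptotic
    annexin_pos_ld_pos: int  # late apoptotic / double positive
    annexin_neg_ld_pos: int  # dye-only dead
    annexin_neg_ld_neg: int  # live

    @property
    def total(self) -> int:
        return (
            self.annexin_pos_ld_neg
            + self.annexin_pos_ld_pos
            + self.annexin_neg_ld_pos
            + self.annexin_neg_ld_neg
        )

    @property
    def percentages(self) -> Optional[dict[str, float]]:
        """Quadrant percentages, or None for an empty input."""
        if self.total == 0:
            return None
        return {
            name: 100.0 * getattr(self, name) / self.total
            for name in (
                "annexin_pos_ld_neg",
                "annexin_pos_ld_pos",
                "annexin_neg_ld_pos",
                "annexin_neg_ld_neg",
            )
        }


def classify_quadrants(
    annexin_intensity: Iterable[float],
    livedead_intensity: Iterable[float],
    annexin_threshold: float,
    livedead_threshold: float,
) -> QuadrantCounts:
    """Assign each event to exactly one quadrant.

    Positivity on each axis is strict (intensity > threshold), so an event
    exactly at a threshold is negative for that marker.
    """
    annexin = np.asarray(list(annexin_intensity), dtype=float)
    livedead = np.asarray(list(livedead_intensity), dtype=float)
    if annexin.shape != livedead.shape:
        raise ValueError("annexin and livedead intensity vectors differ in length")
    if not (math.isfinite(annexin_threshold) and math.isfinite(livedead_threshold)):
        raise ValueError("quadrant thresholds must be finite")
    a_pos = annexin > annexin_threshold
    l_pos = livedead > livedead_threshold
    return QuadrantCounts(
        annexin_pos_ld_neg=int(np.sum(a_pos & ~l_pos)),
        annexin_pos_ld_pos=int(np.sum(a_pos & l_pos)),
        annexin_neg_ld_pos=int(np.sum(~a_pos & l_pos)),
        annexin_neg_ld_neg=int(np.sum(~a_pos & ~l_pos)),
    )
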