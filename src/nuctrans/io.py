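"""Dataset and configuration I/O.

Events are stored as one multi-page TIFF per cell (page order nuclear,
reporter; each page's description carries the channel name) next to a
comma-delimited companion table ``events.csv`` holding the scalar gating
features and, for synthetic data, the ground truth. The run configuration
is a single YAML document that round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .gating import GateConfig
from .masking import MaskConfig
from .population import PopulationSummary, RdResult
from .scoring import R_MAX_DEFAULT, SimilarityResult
from .synthetic import (
    NUCLEAR_CHANNEL,
    REPORTER_CHANNEL,
    CellEvent,
    EventTruth,
    SyntheticPopulationSpec,
)

logger = logging.getLogger("nuctrans")

EVENT_TABLE = "events.csv"
IMAGE_DIR = "images"

_TABLE_COLUMNS = [
    "event_id",
    "group_label",
    "brightfield_area",
    "aspect_ratio",
    "livedead_intensity",
    "nuclear_stain_total",
    "truth_nuclear_fraction",
    "truth_gate_category",
]

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration of an end-to-end run."""

    nuclear_channel: str = NUCLEAR_CHANNEL
    reporter_channel: str = REPORTER_CHANNEL
    gate: GateConfig = field(default_factory=GateConfig)
    mask: MaskConfig = field(default_factory=MaskConfig)
    background_percentile: Optional[float] = None
    r_max: float = R_MAX_DEFAULT
    control_label: str = "control"
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "nuclear_channel": self.nuclear_channel,
            "reporter_channel": self.reporter_channel,
            "gate": dataclasses.asdict(self.gate),
            "mask": dataclasses.asdict(self.mask),
            "background_percentile": self.background_percentile,
            "r_max": self.r_max,
            "control_label": self.control_label,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        gate = GateConfig(**data.pop("gate", {}))
        mask = MaskConfig(**data.pop("mask", {}))
        return cls(gate=gate, mask=mask, **data)

    def to_yaml(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def write_event_dataset(events: Sequence[CellEvent], out_dir: Path | str) -> Path:
    """Write events as multi-page TIFFs plus the companion event table."""
    out_dir = Path(out_dir)
    image_dir = out_dir / IMAGE_DIR
    image_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for event in events:
        path = image_dir / f"{event.event_id}.tif"
        with tifffile.TiffWriter(path) as writer:
            for channel in (NUCLEAR_CHANNEL, REPORTER_CHANNEL):
                writer.write(
                    event.channel_images[channel].astype(np.float32),
                    description=channel,
                    contiguous=False,
                )
        truth = event.truth
        rows.append(
            {
                "event_id": event.event_id,
                "group_label": event.group_label,
                "brightfield_area": event.brightfield_area,
                "aspect_ratio": event.aspect_ratio,
                "livedead_intensity": event.livedead_intensity,
                "nuclear_stain_total": event.nuclear_stain_total,
                "truth_nuclear_fraction": truth.nuclear_fraction if truth else math.nan,
                "truth_gate_category": truth.gate_category if truth else "",
            }
        )
    table = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    table.to_csv(out_dir / EVENT_TABLE, index=False, float_format=_FLOAT_FMT)
    return out_dir


def read_event_dataset(
    path: Path | str,
    nuclear_channel: str = NUCLEAR_CHANNEL,
    reporter_channel: str = REPORTER_CHANNEL,
) -> list[CellEvent]:
    """Load a dataset written by :func:`write_event_dataset`.

    Channel pages are bound by their TIFF page description; extra pages are
    ignored with a logged note, and a table row without an image file is a
    hard error naming the event.
    """
    path = Path(path)
    table_path = path / EVENT_TABLE
    if not table_path.exists():
        raise FileNotFoundError(f"no event table at {table_path}")
    table = pd.read_csv(table_path)
    missing = set(_TABLE_COLUMNS[:6]) - set(table.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")

    events: list[CellEvent] = []
    for row in table.itertuples(index=False):
        image_path = path / IMAGE_DIR / f"{row.event_id}.tif"
        if not image_path.exists():
            raise FileNotFoundError(
                f"event {row.event_id!r} listed in {EVENT_TABLE} has no image "
                f"file at {image_path}"
            )
        channels: dict[str, np.ndarray] = {}
        with tifffile.TiffFile(image_path) as tif:
            for i, page in enumerate(tif.pages):
                name = (page.description or "").strip() or f"page{i}"
                if name in (nuclear_channel, reporter_channel):
                    channels[name] = page.asarray().astype(float)
                else:
                    logger.info(
                        "event %s: ignoring extra channel page %r", row.event_id, name
                    )
        for needed in (nuclear_channel, reporter_channel):
            if needed not in channels:
                raise ValueError(
                    f"event {row.event_id!r} image lacks channel {needed!r}"
                )
        shapes = {img.shape for img in channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"event {row.event_id!r} channel shapes differ")

        truth = None
        if "truth_gate_category" in table.columns and isinstance(
            row.truth_gate_category, str
        ) and row.truth_gate_category:
            truth = EventTruth(
                nuclear_fraction=float(row.truth_nuclear_fraction),
                gate_category=row.truth_gate_category,
                nucleus_mask=None,
            )
        events.append(
            CellEvent(
                event_id=str(row.event_id),
                channel_images=channels,
                brightfield_area=float(row.brightfield_area),
                aspect_ratio=float(row.aspect_ratio),
                livedead_intensity=float(row.livedead_intensity),
                nuclear_stain_total=float(row.nuclear_stain_total),
                group_label=str(row.group_label),
                truth=truth,
            )
        )
    return events


def scores_to_frame(scores: Sequence[SimilarityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": [s.event_id for s in scores],
            "group_label": [s.group_label for s in scores],
            "mask_px": [s.mask_px for s in scores],
            "pearson_r": [s.pearson_r for s in scores],
            "ss": [s.ss for s in scores],
            "valid": [s.valid for s in scores],
            "invalid_reason": [s.invalid_reason or "" for s in scores],
        }
    )


def summaries_to_frame(summaries: Sequence[PopulationSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": [s.group_label for s in summaries],
            "n_valid": [s.n_valid for s in summaries],
            "mean_ss": [s.mean_ss for s in summaries],
            "sd_ss": [s.sd_ss for s in summaries],
            "flagged": [s.flagged for s in summaries],
        }
    )


def rd_to_frame(panel: Sequence[RdResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "test": [r.test_label for r in panel],
            "control": [r.control_label for r in panel],
            "rd": [r.rd for r in panel],
            "n_test": [r.n_test for r in panel],
            "n_control": [r.n_control for r in panel],
        }
    )


def write_table(frame: pd.DataFrame, path: Path | str) -> Path:
    """Write a comma-delimited table with stable float formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def population_specs_from_yaml(path: Path | str) -> list[SyntheticPopulationSpec]:
    """Read simulation population specs from a YAML document.

    The document is either a list of spec mappings or a mapping with a
    ``populations`` key holding that list.
    """
    data = yaml.safe_load(Path(path).read_text())
    if isinstance(data, dict):
        data = data.get("populations", [])
    if not isinstance(data, list):
        raise ValueError("simulation config must be a list of population specs")
    specs = []
    for entry in data:
        if "image_shape" in entry:
            entry = {**entry, "image_shape": tuple(entry["image_shape"])}
        specs.append(SyntheticPopulationSpec(**entry))
    return specs
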