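"""Synthetic imaging-flow-cytometry events with known ground truth.

Each simulated event is a single cell rendered as two concentric disks on a
small pixel grid: a nucleus (DNA-stain channel) inside a larger cell body.
The translocation reporter deposits a controllable fraction of its total
intensity uniformly over the nucleus disk and the remainder uniformly over
the cytoplasmic annulus, emulating a transcription factor partitioned
between nucleus and cytoplasm. Scalar gating features (brightfield area,
aspect ratio, viability-dye intensity, DNA-stain total) are planted per
event so that gate categories — singlet/live/nucleated versus doublet,
dead, or anucleate — are recoverable downstream.

All generators are pure functions of their spec and seed: the same spec
regenerates byte-identical events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

NUCLEAR_CHANNEL = "nuclear"
REPORTER_CHANNEL = "reporter"

GATE_CATEGORIES = ("singlet_live_nucleated", "doublet", "dead", "anucleate")


@dataclass(frozen=True)
class SyntheticPopulationSpec:
    """Full parameterization of one simulated cell population.

    Parameters
    ----------
    n_events
        Number of cells to generate.
    image_shape
        Pixel grid (rows, cols) of every channel image.
    cell_radius_px, nucleus_radius_px
        Radii of the cell body and nucleus disks; the nucleus must fit
        strictly inside the cell, and the cell inside the image.
    nuclear_fraction_mean, nuclear_fraction_sd
        Location and scale of the per-event nuclear fraction of the
        reporter, drawn from a normal distribution clipped to [0, 1].
    reporter_total_intensity
        Total reporter intensity per cell (arbitrary units) split between
        nucleus and cytoplasm before background and noise.
    nuclear_stain_intensity
        Per-pixel DNA-stain intensity inside the nucleus disk.
    background_level, noise_sd
        Additive background and Gaussian noise standard deviation applied
        to every channel (noise clipped at zero). ``noise_model`` may be
        set to ``"poisson"`` to draw each pixel from a Poisson law with the
        noise-free image as its mean instead.
    crosstalk
        Fraction of the nuclear-stain image bled into the reporter channel
        (models drug autofluorescence contaminating the reporter; off by
        default).
    planted_gate_category
        Which gate category the scalar features emulate.
    """

    n_events: int
    image_shape: tuple[int, int] = (64, 64)
    cell_radius_px: float = 20.0
    nucleus_radius_px: float = 10.0
    nuclear_fraction_mean: float = 0.2
    nuclear_fraction_sd: float = 0.1
    reporter_total_intensity: float = 50_000.0
    nuclear_stain_intensity: float = 100.0
    background_level: float = 5.0
    noise_sd: float = 2.0
    noise_model: str = "gaussian"
    crosstalk: float = 0.0
    planted_gate_category: str = "singlet_live_nucleated"
    group_label: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be non-negative")
        if not (0 < self.nucleus_radius_px < self.cell_radius_px):
            raise ValueError("require 0 < nucleus_radius_px < cell_radius_px")
        if not self.cell_radius_px < min(self.image_shape) / 2:
            raise ValueError("cell_radius_px must be < min(image_shape)/2")
        if not 0.0 <= self.nuclear_fraction_mean <= 1.0:
            raise ValueError("nuclear_fraction_mean must lie in [0, 1]")
        if self.nuclear_fraction_sd < 0:
            raise ValueError("nuclear_fraction_sd must be non-negative")
        if self.noise_sd < 0 or self.background_level < 0:
            raise ValueError("noise_sd and background_level must be non-negative")
        if self.reporter_total_intensity <= 0 or self.nuclear_stain_intensity <= 0:
            raise ValueError("intensities must be positive")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.planted_gate_category not in GATE_CATEGORIES:
            raise ValueError(
                f"planted_gate_category must be one of {GATE_CATEGORIES}"
            )


@dataclass(frozen=True)
class EventTruth:
    """Ground-truth record attached to synthetic events only."""

    nuclear_fraction: float
    gate_category: str
    nucleus_mask: Optional[np.ndarray]  # boolean grid; None for anucleate


@dataclass
class CellEvent:
    """One imaged cell: channel images plus scalar gating features."""

    event_id: str
    channel_images: Mapping[str, np.ndarray]
    brightfield_area: float
    aspect_ratio: float
    livedead_intensity: float
    nuclear_stain_total: float
    group_label: str = ""
    truth: Optional[EventTruth] = None

    def __post_init__(self) -> None:
        shapes = {img.shape for img in self.channel_images.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel images of {self.event_id} differ in shape")


def disk_mask(
    shape: tuple[int, int], center: tuple[float, float], radius: float
) -> np.ndarray:
    """Rasterize a disk by pixel-center membership.

    A pixel belongs to the disk iff its center (integer row/col coordinate)
    lies within ``radius`` of ``center``. This convention defines the
    ground-truth nucleus masks.
    """
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


_SUPERSAMPLE = 4


def disk_coverage(
    shape: tuple[int, int], center: tuple[float, float], radius: float
) -> np.ndarray:
    """Fraction of each pixel's area covered by the disk.

    Intensities are rendered coverage-weighted — a detector integrates
    photons over the whole pixel, so pixels straddling the disk edge carry
    intermediate values in every channel. Coverage is estimated by 4x4
    supersampling of each pixel.
    """
    s = _SUPERSAMPLE
    n_rows, n_cols = shape
    # sub-pixel centers: pixel i spans [i - 0.5, i + 0.5)
    sub = (np.arange(s) + 0.5) / s - 0.5
    rr = (np.arange(n_rows)[:, None] + sub[None, :]).ravel()
    cc = (np.arange(n_cols)[:, None] + sub[None, :]).ravel()
    inside = (
        (rr[:, None] - center[0]) ** 2 + (cc[None, :] - center[1]) ** 2
    ) <= radius**2
    return inside.reshape(n_rows, s, n_cols, s).mean(axis=(1, 3))


def _apply_noise(
    image: np.ndarray, spec: SyntheticPopulationSpec, rng: np.random.Generator
) -> np.ndarray:
    if spec.noise_model == "poisson":
        return rng.poisson(image).astype(float)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
        np.clip(image, 0.0, None, out=image)
    return image


def _planted_features(
    spec: SyntheticPopulationSpec, rng: np.random.Generator
) -> tuple[float, float, float]:
    """Draw (brightfield_area, aspect_ratio, livedead_intensity).

    Ranges are chosen so that, with the calibrated default gate thresholds,
    singlet/live/nucleated events always pass the area, aspect-ratio and
    viability criteria, doublets fail on area, and dead events fail on the
    viability dye.
    """
    singlet_area = math.pi * spec.cell_radius_px**2
    cat = spec.planted_gate_category
    if cat == "doublet":
        area = singlet_area * rng.uniform(1.8, 2.2)
        aspect = rng.uniform(0.35, 0.55)
    else:
        area = singlet_area * rng.uniform(0.9, 1.1)
        aspect = rng.uniform(0.85, 1.0)
    livedead = rng.uniform(500.0, 1000.0) if cat == "dead" else rng.uniform(10.0, 50.0)
    return area, aspect, livedead


def generate_cell_event(
    spec: SyntheticPopulationSpec,
    nuclear_fraction: float,
    rng: np.random.Generator,
    event_id: str = "event-0",
) -> CellEvent:
    """Render one synthetic cell with the given reporter nuclear fraction.

    The reporter channel receives ``nuclear_fraction`` of the total reporter
    intensity spread uniformly over the nucleus disk and the remainder over
    the cytoplasmic annulus; the nuclear channel is the nucleus disk at the
    stain intensity. Disks are rendered coverage-weighted (pixels straddling
    an edge carry partial intensity), so the deposited totals are exact.
    Background and noise are then added to both channels. For anucleate
    events the nucleus disk is absent: the nuclear channel is background
    only and the reporter spreads over the whole cell disk.
    """
    if not 0.0 <= nuclear_fraction <= 1.0:
        raise ValueError(f"nuclear_fraction {nuclear_fraction} outside [0, 1]")

    shape = spec.image_shape
    geom_center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    margin = min(shape) / 2 - spec.cell_radius_px
    max_jitter = int(min(2, max(0, math.floor(margin) - 1)))
    jitter = rng.integers(-max_jitter, max_jitter + 1, size=2) if max_jitter else (0, 0)
    center = (geom_center[0] + jitter[0], geom_center[1] + jitter[1])

    cell_cov = disk_coverage(shape, center, spec.cell_radius_px)
    nucleus_cov = disk_coverage(shape, center, spec.nucleus_radius_px)
    annulus_cov = cell_cov - nucleus_cov
    nucleus_truth = disk_mask(shape, center, spec.nucleus_radius_px)

    anucleate = spec.planted_gate_category == "anucleate"
    nuclear = np.zeros(shape, dtype=float)
    if anucleate:
        reporter = spec.reporter_total_intensity * cell_cov / cell_cov.sum()
        truth_fraction = 0.0
    else:
        reporter = (
            nuclear_fraction
            * spec.reporter_total_intensity
            * nucleus_cov
            / nucleus_cov.sum()
            + (1.0 - nuclear_fraction)
            * spec.reporter_total_intensity
            * annulus_cov
            / annulus_cov.sum()
        )
        nuclear = spec.nuclear_stain_intensity * nucleus_cov
        truth_fraction = nuclear_fraction

    if spec.crosstalk:
        reporter = reporter + spec.crosstalk * nuclear

    nuclear = _apply_noise(nuclear + spec.background_level, spec, rng)
    reporter = _apply_noise(reporter + spec.background_level, spec, rng)

    area, aspect, livedead = _planted_features(spec, rng)

    return CellEvent(
        event_id=event_id,
        channel_images={NUCLEAR_CHANNEL: nuclear, REPORTER_CHANNEL: reporter},
        brightfield_area=area,
        aspect_ratio=aspect,
        livedead_intensity=livedead,
        nuclear_stain_total=float(nuclear.sum()),
        group_label=spec.group_label,
        truth=EventTruth(
            nuclear_fraction=truth_fraction,
            gate_category=spec.planted_gate_category,
            nucleus_mask=None if anucleate else nucleus_truth,
        ),
    )


def generate_population(spec: SyntheticPopulationSpec) -> list[CellEvent]:
    """Generate ``spec.n_events`` events with clipped-normal nuclear fractions."""
    rng = np.random.default_rng(spec.seed)
    fractions = np.clip(
        rng.normal(spec.nuclear_fraction_mean, spec.nuclear_fraction_sd, spec.n_events),
        0.0,
        1.0,
    )
    return [
        generate_cell_event(
            spec, float(f), rng, event_id=f"{spec.group_label}-{i:05d}"
        )
        for i, f in enumerate(fractions)
    ]


def generate_ss_samples(
    mu: float, sigma: float, n: int, seed: int
) -> np.ndarray:
    """Draw similarity-score values directly from Normal(mu, sigma).

    Statistic-level generator for exercising population summaries and the
    discriminant ratio without rendering images.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return np.random.default_rng(seed).normal(mu, sigma, n)


def mixed_population(
    counts: Mapping[str, int],
    base_spec: SyntheticPopulationSpec,
) -> list[CellEvent]:
    """Concatenate populations of several planted gate categories.

    ``counts`` maps gate category -> n_events; each category reuses
    ``base_spec`` with its own derived seed so the mixture is reproducible.
    """
    events: list[CellEvent] = []
    for offset, (category, n) in enumerate(counts.items()):
        sub = replace(
            base_spec,
            n_events=n,
            planted_gate_category=category,
            group_label=f"{base_spec.group_label}-{category}",
            seed=base_spec.seed + offset,
        )
        events.extend(generate_population(sub))
    return events
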