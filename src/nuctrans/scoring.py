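"""Per-cell similarity score between reporter and nuclear-stain images.

The similarity score (SS) is a log-transformed Pearson correlation computed
strictly inside the nuclear mask:

    SS = ln((1 + r') / (1 - r')),   r' = clamp(r, -r_max, +r_max)

with r the sample Pearson correlation between the two channel images over
the masked pixels and r_max = 1 - 1e-6 so that perfectly correlated inputs
stay finite. The transform is twice the inverse hyperbolic tangent of r:
odd, strictly increasing, zero at r = 0, and unbounded as |r| -> 1. A high
SS means the reporter's spatial distribution matches the DNA stain
(nuclear localization); a low or negative SS means a predominantly
cytoplasmic distribution.

Degenerate cells — a mask below the size floor, or a channel that is
constant within the mask — yield an invalid result carrying the reason
rather than a number, and are excluded from population statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .masking import MaskConfig, NuclearMask, compute_nuclear_mask
from .synthetic import CellEvent, NUCLEAR_CHANNEL, REPORTER_CHANNEL

R_MAX_DEFAULT = 1.0 - 1e-6

MASK_TOO_SMALL = "mask_too_small"
ZERO_VARIANCE = "zero_variance"


@dataclass(frozen=True)
class SimilarityResult:
    event_id: str
    pearson_r: float  # NaN when invalid
    ss: float  # NaN when invalid
    mask_px: int
    valid: bool
    invalid_reason: Optional[str] = None
    group_label: str = ""


def pearson_within_mask(
    image_a: np.ndarray,
    image_b: np.ndarray,
    mask: Union[NuclearMask, np.ndarray],
) -> tuple[Optional[float], Optional[str]]:
    """Sample Pearson correlation over exactly the masked pixels.

    Returns ``(r, None)`` on success or ``(None, reason)`` when the mask is
    invalid/too small or either channel is constant within it.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if isinstance(mask, NuclearMask):
        if not mask.valid:
            return None, MASK_TOO_SMALL
        pixels = mask.pixels
    else:
        pixels = np.asarray(mask, dtype=bool)
    if a.shape != b.shape or a.shape != pixels.shape:
        raise ValueError("images and mask must share one shape")
    if pixels.sum() < 2:
        return None, MASK_TOO_SMALL

    va = a[pixels]
    vb = b[pixels]
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        return None, ZERO_VARIANCE
    r = float(np.corrcoef(va, vb)[0, 1])
    return min(1.0, max(-1.0, r)), None


def similarity_score(r: float, r_max: float = R_MAX_DEFAULT) -> float:
    """Log-transform a Pearson correlation into a similarity score."""
    if not math.isfinite(r):
        raise ValueError("r must be finite")
    r = min(r_max, max(-r_max, r))
    return math.log((1.0 + r) / (1.0 - r))


def _subtract_background(image: np.ndarray, percentile: float) -> np.ndarray:
    level = np.percentile(image, percentile)
    return np.clip(image - level, 0.0, None)


def score_event(
    event: CellEvent,
    mask_config: Optional[MaskConfig] = None,
    nuclear_channel: str = NUCLEAR_CHANNEL,
    reporter_channel: str = REPORTER_CHANNEL,
    r_max: float = R_MAX_DEFAULT,
    background_percentile: Optional[float] = None,
) -> SimilarityResult:
    """Mask the nuclear channel, correlate, and log-transform for one cell.

    ``background_percentile``, when set, subtracts that per-image intensity
    percentile from both channels (clipped at zero) before correlating;
    default is no subtraction.
    """
    mask_config = mask_config or MaskConfig()
    for name in (nuclear_channel, reporter_channel):
        if name not in event.channel_images:
            raise KeyError(f"event {event.event_id} has no channel {name!r}")
    nuclear = np.asarray(event.channel_images[nuclear_channel], dtype=float)
    reporter = np.asarray(event.channel_images[reporter_channel], dtype=float)

    mask = compute_nuclear_mask(nuclear, mask_config)
    if background_percentile is not None:
        nuclear = _subtract_background(nuclear, background_percentile)
        reporter = _subtract_background(reporter, background_percentile)

    r, reason = pearson_within_mask(reporter, nuclear, mask)
    if reason is not None:
        return SimilarityResult(
            event_id=event.event_id,
            pearson_r=math.nan,
            ss=math.nan,
            mask_px=mask.pixel_count,
            valid=False,
            invalid_reason=reason,
            group_label=event.group_label,
        )
    return SimilarityResult(
        event_id=event.event_id,
        pearson_r=r,
        ss=similarity_score(r, r_max=r_max),
        mask_px=mask.pixel_count,
        valid=True,
        group_label=event.group_label,
    )


def score_events(
    events: Sequence[CellEvent],
    mask_config: Optional[MaskConfig] = None,
    **kwargs,
) -> list[SimilarityResult]:
    """Score a sequence of events with shared settings."""
    return [score_event(e, mask_config=mask_config, **kwargs) for e in events]
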