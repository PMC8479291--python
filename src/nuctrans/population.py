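"""Population-level similarity-score statistics and the discriminant ratio.

The shift in the SS distribution between a treated and a control cell
population is quantified with the Fisher's discriminant ratio

    Rd = (mean SS_test - mean SS_control) / (sd SS_test + sd SS_control)

using sample (n-1) standard deviations. Rd is kept signed: positive values
mean the test population's scores moved up (toward nuclear localization)
relative to the control. When both standard deviations are zero the ratio
degenerates: equal means give Rd = 0, differing means are flagged as
infinite separation (Rd = +/-inf).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np

from .scoring import SimilarityResult

ScoreInput = Union[Sequence[SimilarityResult], Sequence[float], np.ndarray]


@dataclass(frozen=True)
class PopulationSummary:
    """Mean and spread of valid similarity scores for one group."""

    group_label: str
    n_valid: int
    mean_ss: float  # NaN when flagged
    sd_ss: float  # NaN when flagged

    @property
    def flagged(self) -> bool:
        """True when fewer than two valid scores: sd (hence Rd) undefined."""
        return self.n_valid < 2


@dataclass(frozen=True)
class RdResult:
    test_label: str
    control_label: str
    rd: float  # may be +/-inf for zero-spread populations with unequal means
    n_test: int
    n_control: int


def _valid_ss(scores: ScoreInput) -> np.ndarray:
    if len(scores) and isinstance(scores[0], SimilarityResult):
        values = np.array([s.ss for s in scores if s.valid], dtype=float)
    else:
        values = np.asarray(scores, dtype=float)
    return values[np.isfinite(values)]


def summarize_population(scores: ScoreInput, group_label: str) -> PopulationSummary:
    """Sample mean and (n-1) standard deviation of the valid scores.

    Accepts either SimilarityResult records (invalid ones are dropped) or a
    plain array of SS values (non-finite entries dropped).
    """
    values = _valid_ss(scores)
    n = len(values)
    if n < 2:
        mean = float(values.mean()) if n == 1 else math.nan
        return PopulationSummary(group_label, n, mean, math.nan)
    return PopulationSummary(
        group_label, n, float(values.mean()), float(values.std(ddof=1))
    )


def fisher_rd(test: PopulationSummary, control: PopulationSummary) -> RdResult:
    """Discriminant ratio of a test population against a control."""
    if test.flagged or control.flagged:
        raise ValueError(
            "both populations need >= 2 valid scores for a discriminant ratio"
        )
    sd_sum = test.sd_ss + control.sd_ss
    diff = test.mean_ss - control.mean_ss
    if sd_sum == 0:
        rd = 0.0 if diff == 0 else math.copysign(math.inf, diff)
    else:
        rd = diff / sd_sum
    return RdResult(
        test_label=test.group_label,
        control_label=control.group_label,
        rd=rd,
        n_test=test.n_valid,
        n_control=control.n_valid,
    )


def rd_panel(
    scores_by_group: Mapping[str, ScoreInput], control_label: str
) -> list[RdResult]:
    """One Rd per non-control group versus the shared control, input order."""
    if control_label not in scores_by_group:
        raise KeyError(f"control group {control_label!r} not present")
    control = summarize_population(scores_by_group[control_label], control_label)
    panel: list[RdResult] = []
    for label, scores in scores_by_group.items():
        if label == control_label:
            continue
        panel.append(fisher_rd(summarize_population(scores, label), control))
    return panel


def ss_histogram(
    scores: ScoreInput, bins: int = 50, range_: tuple[float, float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Binned counts of valid SS values for distribution plots/exports."""
    values = _valid_ss(scores)
    return np.histogram(values, bins=bins, range=range_)
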