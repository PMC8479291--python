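"""Companion assay computations: ddCT relative expression and
relative-proliferation normalization.

ddCT: per sample, dCT = mean(target CT) - mean(reference CT) over technical
replicates; ddCT = dCT - dCT_calibrator; fold change = 2^-ddCT. The default
calibrator is the mean dCT across all samples, so fold changes are relative
to the cohort average; a named sample may be used instead for the
conventional calibrator-sample form.

Relative proliferation rescales a treated-culture cell count so that the
pre-treatment count maps to 0% and the untreated end-point count to 100%;
values below 0% indicate net cell loss relative to baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CtRecord:
    """Cycle thresholds for one sample: target and reference gene replicates."""

    sample_id: str
    group_label: str
    target_ct_replicates: Sequence[float]
    reference_ct_replicates: Sequence[float]

    def __post_init__(self) -> None:
        for name, reps in (
            ("target", self.target_ct_replicates),
            ("reference", self.reference_ct_replicates),
        ):
            if len(reps) == 0:
                raise ValueError(f"{name} replicates empty for {self.sample_id}")
            if any(ct <= 0 for ct in reps):
                raise ValueError(f"{name} CT values must be positive")


@dataclass(frozen=True)
class RelativeExpression:
    sample_id: str
    group_label: str
    delta_ct: float
    delta_delta_ct: float
    fold_change: float  # 2 ** -delta_delta_ct


MEAN_OF_ALL = "mean_of_all"


def ddct_relative_expression(
    records: Sequence[CtRecord], calibrator: str = MEAN_OF_ALL
) -> list[RelativeExpression]:
    """Relative expression by the ddCT method.

    ``calibrator`` is either ``"mean_of_all"`` (cohort-average dCT, the
    default) or the sample_id of a calibrator sample.
    """
    if not records:
        raise ValueError("no CT records provided")
    delta_cts = {
        rec.sample_id: float(np.mean(rec.target_ct_replicates))
        - float(np.mean(rec.reference_ct_replicates))
        for rec in records
    }
    if calibrator == MEAN_OF_ALL:
        baseline = float(np.mean(list(delta_cts.values())))
    else:
        if calibrator not in delta_cts:
            raise KeyError(f"calibrator sample {calibrator!r} not found")
        baseline = delta_cts[calibrator]
    out = []
    for rec in records:
        ddct = delta_cts[rec.sample_id] - baseline
        out.append(
            RelativeExpression(
                sample_id=rec.sample_id,
                group_label=rec.group_label,
                delta_ct=delta_cts[rec.sample_id],
                delta_delta_ct=ddct,
                fold_change=2.0 ** (-ddct),
            )
        )
    return out


def records_from_table(
    table: pd.DataFrame, target_gene: str, reference_gene: str
) -> list[CtRecord]:
    """Build CtRecords from a long table (sample_id, group, gene, ct)."""
    required = {"sample_id", "group", "gene", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"CT table missing columns: {sorted(missing)}")
    records = []
    for sample_id, sub in table.groupby("sample_id", sort=False):
        target = sub.loc[sub["gene"] == target_gene, "ct"]
        reference = sub.loc[sub["gene"] == reference_gene, "ct"]
        if target.empty or reference.empty:
            raise ValueError(
                f"sample {sample_id!r} lacks CT values for "
                f"{target_gene!r} or {reference_gene!r}"
            )
        records.append(
            CtRecord(
                sample_id=str(sample_id),
                group_label=str(sub["group"].iloc[0]),
                target_ct_replicates=tuple(target.astype(float)),
                reference_ct_replicates=tuple(reference.astype(float)),
            )
        )
    return records


def expression_table(results: Sequence[RelativeExpression]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "group": [r.group_label for r in results],
            "delta_ct": [r.delta_ct for r in results],
            "delta_delta_ct": [r.delta_delta_ct for r in results],
            "fold_change": [r.fold_change for r in results],
        }
    )


def relative_proliferation(
    count_pre: float, count_untreated: float, count_treated: Union[float, np.ndarray]
) -> Union[float, np.ndarray]:
    """Percent proliferation with pre-treatment = 0% and untreated = 100%."""
    if count_pre < 0:
        raise ValueError("count_pre must be non-negative")
    if count_untreated <= count_pre:
        raise ValueError(
            "count_untreated must exceed count_pre (otherwise the 0-100% "
            "scale is undefined)"
        )
    result = 100.0 * (np.asarray(count_treated, dtype=float) - count_pre) / (
        count_untreated - count_pre
    )
    return float(result) if np.isscalar(count_treated) else result
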