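"""Pre-post behavioral change scores and the median-split group labels.

For each subject the change score is simply ``month6 - baseline`` (min/day for
sitting time ``st``, steps/day for step count ``ns``). The cohort is then split
at the median into *low*- and *high*-change groups, where "high change" means
greater **improvement**: for sitting time an improvement is a decrease
(``improvement_sign = -1``), for step counts an increase
(``improvement_sign = +1``). Ties at the median are resolved deterministically
(ascending subject id) so any even cohort splits exactly in half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .timeseries_io import CohortManifest

#: Default improvement direction per measure: sitting down is good, steps up is good.
IMPROVEMENT_SIGNS = {"st": -1, "ns": +1}


@dataclass(frozen=True)
class BehaviorRecord:
    """One subject's baseline / 6-month / change values for one measure."""

    subject_id: str
    measure: str  # "st" or "ns"
    baseline: float
    month6: float
    change: float

    def __post_init__(self) -> None:
        if self.measure not in ("st", "ns"):
            raise ValidationError(f"measure must be 'st' or 'ns', got {self.measure!r}")
        if not (math.isfinite(self.baseline) and math.isfinite(self.month6)):
            raise ValidationError(f"non-finite behavioral value for {self.subject_id!r}")


@dataclass(frozen=True)
class GroupAssignment:
    """Low/high-change labels from the median split of improvement scores."""

    measure: str
    labels: dict[str, str]  # subject_id -> "low" | "high"
    median_value: float  # median of the raw change scores
    improvement_sign: int

    @property
    def low_ids(self) -> list[str]:
        return sorted(s for s, g in self.labels.items() if g == "low")

    @property
    def high_ids(self) -> list[str]:
        return sorted(s for s, g in self.labels.items() if g == "high")


def compute_change(baseline: float, month6: float) -> float:
    """Return the pre-post change ``month6 - baseline``."""
    if not (math.isfinite(baseline) and math.isfinite(month6)):
        raise ValidationError("baseline and month6 must both be finite")
    return month6 - baseline


def behavior_records(manifest: CohortManifest, measure: str) -> list[BehaviorRecord]:
    """Build per-subject :class:`BehaviorRecord` rows for one measure."""
    if measure not in ("st", "ns"):
        raise ValidationError(f"measure must be 'st' or 'ns', got {measure!r}")
    out = []
    for _, row in manifest.records.iterrows():
        base = float(row[f"{measure}_baseline"])
        after = float(row[f"{measure}_6mo"])
        out.append(
            BehaviorRecord(
                subject_id=str(row["subject_id"]),
                measure=measure,
                baseline=base,
                month6=after,
                change=compute_change(base, after),
            )
        )
    return out


def median_split_groups(
    records: list[BehaviorRecord], improvement_sign: int | None = None
) -> GroupAssignment:
    """Split a cohort at the median improvement score into low/high groups.

    Subjects are ranked by ``s_i = improvement_sign * change_i``; scores
    strictly above the cohort median are "high" (more improvement), strictly
    below are "low". Subjects exactly at the median start in "low" and are
    moved to "high" in ascending subject-id order until the split is balanced
    (exactly for even cohorts, within one subject for odd).
    """
    if len(records) < 2:
        raise ConfigurationError("median split needs at least 2 records")
    measures = {r.measure for r in records}
    if len(measures) != 1:
        raise ValidationError(f"records mix measures: {sorted(measures)}")
    measure = measures.pop()
    if improvement_sign is None:
        improvement_sign = IMPROVEMENT_SIGNS[measure]
    if improvement_sign not in (+1, -1):
        raise ConfigurationError(f"improvement_sign must be +1 or -1, got {improvement_sign}")

    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate subject_ids in records")
    changes = np.array([r.change for r in records], dtype=float)
    scores = improvement_sign * changes
    med = float(np.median(scores))

    labels = {}
    ties = []
    for r, s in zip(records, scores):
        if s > med:
            labels[r.subject_id] = "high"
        elif s < med:
            labels[r.subject_id] = "low"
        else:
            labels[r.subject_id] = "low"
            ties.append(r.subject_id)

    def imbalance() -> int:
        n_low = sum(1 for g in labels.values() if g == "low")
        return n_low - (len(labels) - n_low)

    target = 0 if len(records) % 2 == 0 else 1
    for sid in sorted(ties):
        if imbalance() <= target:
            break
        labels[sid] = "high"

    return GroupAssignment(
        measure=measure,
        labels=labels,
        median_value=float(np.median(changes)),
        improvement_sign=improvement_sign,
    )


def groups_table(records: list[BehaviorRecord], groups: GroupAssignment) -> pd.DataFrame:
    """Tabulate subject_id, measure, change, group (the groups TSV payload)."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "measure": [r.measure for r in records],
            "change": [r.change for r in records],
            "group": [groups.labels[r.subject_id] for r in records],
        }
    )
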