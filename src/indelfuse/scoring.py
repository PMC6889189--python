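"""Precision/recall/F-score and the grouping operator over call sets.

The analysis throughout this package stratifies detection results by up to
four attributes — variation type (ST), variation size (SS), repeat class
(RT), and detecting software (DS) — via the composable grouping operator
``G(F, S)``.  Each stratum gets a :class:`PerformanceRecord` computed from
one-to-one TP/FP/FN labeling:

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F-score   = 2 * precision * recall / (precision + recall)

with the 0/0 cases defined as 0.  Fractions are kept in [0, 1] internally and
converted to percentages (2 decimals, half-up) only at the reporting
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .matching import LabelResult, MergedCall

ATTRIBUTES = ("ST", "SS", "RT", "DS")


class GroupKey(NamedTuple):
    """A stratum of the grouping operator; unused attributes stay None."""

    st: str | None = None
    ss: int | None = None
    rt: str | None = None
    ds: str | None = None


def _attr_of(item, name: str):
    if name == "ST":
        return item.vtype
    if name == "SS":
        return item.size
    if name == "RT":
        return item.repeat_class
    if name == "DS":
        if isinstance(item, MergedCall):
            return "+".join(item.callers)
        return item.caller
    raise ConfigError(f"unknown grouping attribute {name!r}")


def key_of(item, attributes: Sequence[str]) -> GroupKey:
    values = {a.lower(): _attr_of(item, a) for a in attributes}
    return GroupKey(**values)


def group(items: Iterable, attributes: Sequence[str]) -> dict[GroupKey, list]:
    """Partition *items* by the chosen attributes (the G(F, S) operator).

    The result is a partition — every item lands in exactly one group — and
    is insensitive to the order in which attributes are listed.
    """
    if not attributes:
        raise ConfigError("at least one grouping attribute is required")
    if len(set(attributes)) != len(attributes):
        raise ConfigError("duplicate grouping attribute")
    for a in attributes:
        if a not in ATTRIBUTES:
            raise ConfigError(f"unknown grouping attribute {a!r}")
    out: dict[GroupKey, list] = {}
    for item in items:
        out.setdefault(key_of(item, attributes), []).append(item)
    return out


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall, on whatever common scale.

    Accepts fractions or percentages (the formula is scale-invariant) and
    defines the 0/0 limit as 0.
    """
    if precision < 0 or recall < 0:
        raise ValueError("precision and recall must be >= 0")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class PerformanceRecord:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f(self) -> float:
        return f_score(self.precision, self.recall)

    def __add__(self, other: "PerformanceRecord") -> "PerformanceRecord":
        return PerformanceRecord(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn
        )


def as_percent(fraction: float, decimals: int = 2) -> float:
    """Report-boundary conversion: fraction -> percentage, half-up rounding."""
    q = Decimal(10) ** -decimals
    return float(
        (Decimal(repr(fraction)) * 100).quantize(q, rounding=ROUND_HALF_UP)
    )


def performance_table(
    result: LabelResult,
    attributes: Sequence[str],
) -> dict[GroupKey, PerformanceRecord]:
    """Per-group TP/FP/FN records from a labeling, plus the overall record.

    False negatives are attributed to the group of the missed truth variant;
    the overall record (key with all attributes None) is the per-group sum.
    """
    counts: dict[GroupKey, list[int]] = {}
    for call, lab in result.labeled:
        key = key_of(call, attributes)
        c = counts.setdefault(key, [0, 0, 0])
        c[0 if lab == "TP" else 1] += 1
    for t in result.unmatched_truth:
        key = key_of(t, attributes)
        counts.setdefault(key, [0, 0, 0])[2] += 1
    table = {k: PerformanceRecord(*v) for k, v in counts.items()}
    overall = PerformanceRecord(0, 0, 0)
    for rec in table.values():
        overall = overall + rec
    table[GroupKey()] = overall
    return table


def dispersion(
    records: Sequence[PerformanceRecord] | Sequence[float], metric: str | None = None
) -> float:
    """Population standard deviation of a metric across groups.

    *records* may be PerformanceRecords (then *metric* names 'precision',
    'recall' or 'f') or raw values.
    """
    if len(records) == 0:
        raise ValueError("dispersion needs at least one record")
    if metric is not None:
        values = [getattr(r, metric) for r in records]
    else:
        values = list(records)  # type: ignore[arg-type]
    return float(np.std(np.asarray(values, dtype=float)))


def report_frame(
    tables: Mapping[str, Mapping[GroupKey, PerformanceRecord]],
    baseline: str | None = None,
) -> pd.DataFrame:
    """Tabulate per-tool overall performance with a Diff-vs-baseline column.

    Percentages are printed to 2 decimals (half-up); Diff is tool minus
    baseline on the rounded values, mirroring how such tables are usually
    typeset.
    """
    rows = []
    base = tables.get(baseline) if baseline else None
    base_rec = base.get(GroupKey()) if base else None
    for tool in tables:
        rec = tables[tool][GroupKey()]
        row = {
            "tool": tool,
            "precision_pct": as_percent(rec.precision),
            "recall_pct": as_percent(rec.recall),
            "f_score_pct": as_percent(rec.f),
        }
        if base_rec is not None:
            row["precision_diff"] = round(
                row["precision_pct"] - as_percent(base_rec.precision), 2
            )
            row["recall_diff"] = round(
                row["recall_pct"] - as_percent(base_rec.recall), 2
            )
            row["f_score_diff"] = round(
                row["f_score_pct"] - as_percent(base_rec.f), 2
            )
        rows.append(row)
    return pd.DataFrame(rows)


def category_summary(counts: Mapping[str, int]) -> pd.DataFrame:
    """Tally marker counts by annotation category with a total row."""
    if any(v < 0 for v in counts.values()):
        raise ValueError("category counts must be >= 0")
    rows = [{"position": k, "number": int(v)} for k, v in counts.items()]
    rows.append({"position": "total", "number": int(sum(counts.values()))})
    return pd.DataFrame(rows)
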