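"""BF-M: per-stratum selection of the best caller-pair intersection.

Intersecting two callers' results usually raises precision but the gain is
uneven: for some (type, size, repeat-class) strata a given pair is excellent
and for others it is useless.  BF-M therefore learns, for every
(ST, SS, RT) group on training data with known truth, which of the
C(k, 2) pairwise intersections maximizes the F-score, and at apply time
assembles the output as the union over groups of the winning pair's
intersection restricted to that group.

Only pairwise intersections are candidate rules; ties break
lexicographically by caller-pair name so learning is deterministic.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .callset_io import InDelCall
from .errors import ConfigError, InputError, TrainingError
from .matching import (
    LabelResult,
    MatchCriterion,
    MergedCall,
    intersect_callsets,
    label_against_truth,
)
from .scoring import GroupKey, PerformanceRecord, group, performance_table

logger = logging.getLogger(__name__)

RULE_ATTRIBUTES = ("ST", "SS", "RT")


@dataclass
class BfmModel:
    """Learned optimization rules: (ST, SS, RT) group -> best caller pair."""

    rules: dict[GroupKey, tuple[str, str]] = field(default_factory=dict)
    training_scores: dict[GroupKey, dict[tuple[str, str], PerformanceRecord]] = field(
        default_factory=dict
    )

    def training_record(self, key: GroupKey) -> PerformanceRecord:
        return self.training_scores[key][self.rules[key]]

    def to_frame(self):
        rows = []
        for key, pair in sorted(self.rules.items()):
            rec = self.training_scores[key][pair]
            rows.append(
                {
                    "ST": key.st,
                    "SS": key.ss,
                    "RT": key.rt,
                    "caller_pair": "+".join(pair),
                    "train_precision": rec.precision,
                    "train_recall": rec.recall,
                    "train_F": rec.f,
                    "tp": rec.tp,
                    "fp": rec.fp,
                    "fn": rec.fn,
                }
            )
        import pandas as pd

        return pd.DataFrame(rows)

    def save(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str) -> "BfmModel":
        import pandas as pd

        frame = pd.read_csv(path, sep="\t")
        model = cls()
        for _, row in frame.iterrows():
            key = GroupKey(st=row["ST"], ss=int(row["SS"]), rt=row["RT"])
            pair = tuple(row["caller_pair"].split("+"))
            model.rules[key] = pair  # type: ignore[assignment]
            model.training_scores.setdefault(key, {})[pair] = PerformanceRecord(
                int(row["tp"]), int(row["fp"]), int(row["fn"])
            )
        return model


def _pair_tables(
    callsets: Mapping[str, Sequence[InDelCall]],
    truth_calls: Sequence[InDelCall],
    criterion: MatchCriterion,
) -> dict[tuple[str, str], dict[GroupKey, PerformanceRecord]]:
    tables = {}
    for a, b in itertools.combinations(sorted(callsets), 2):
        common = intersect_callsets(callsets[a], callsets[b], criterion)
        labeled = label_against_truth(common, truth_calls, criterion)
        tables[(a, b)] = performance_table(labeled, RULE_ATTRIBUTES)
    return tables


def learn_rules(
    callsets: Mapping[str, Sequence[InDelCall]],
    truth_calls: Sequence[InDelCall],
    criterion: MatchCriterion,
) -> BfmModel:
    """Learn the per-group best-pair rules from training data.

    For every caller pair the common part (IR) is computed, labeled against
    truth, and stratified by (ST, SS, RT); per stratum the pair with the
    highest F-score becomes the rule.  Groups that appear only as missed
    truth (no pair detected anything) still get a rule — the argmax over
    all-zero scores, resolved lexicographically — so their zero score is
    recorded rather than silently dropped.
    """
    if len(callsets) < 2:
        raise ConfigError("BF-M needs at least two callers")
    if not truth_calls:
        raise TrainingError("BF-M training needs a non-empty truth set")
    tables = _pair_tables(callsets, truth_calls, criterion)

    keys: set[GroupKey] = set()
    for table in tables.values():
        keys.update(k for k in table if k != GroupKey())

    model = BfmModel()
    for key in sorted(keys):
        scored = {
            pair: table.get(key, PerformanceRecord(0, 0, 0))
            for pair, table in tables.items()
        }
        best_f = max(rec.f for rec in scored.values())
        # lexicographically smallest pair wins exact F ties (determinism)
        best = min(p for p in scored if scored[p].f == best_f)
        model.rules[key] = best
        model.training_scores[key] = scored
    return model


def apply_rules(
    model: BfmModel,
    callsets: Mapping[str, Sequence[InDelCall]],
    criterion: MatchCriterion,
) -> tuple[list[MergedCall], int]:
    """Screen new call sets with the learned rules.

    Every caller pair named by any rule is intersected once; each merged call
    is routed by its (ST, SS, RT) group and kept only when the group's rule
    selected that pair.  Calls whose group has no rule are dropped; the count
    of dropped calls is returned (and logged) alongside the kept calls.
    """
    needed_pairs = sorted(set(model.rules.values()))
    for pair in needed_pairs:
        for name in pair:
            if name not in callsets:
                raise InputError(f"caller {name!r} required by a rule is missing")
    kept: list[MergedCall] = []
    dropped = 0
    for pair in needed_pairs:
        common = intersect_callsets(
            callsets[pair[0]], callsets[pair[1]], criterion
        )
        for key, members in group(common, RULE_ATTRIBUTES).items():
            if model.rules.get(key) == pair:
                kept.extend(members)
    # count calls from pairs' intersections whose group is unknown to the model
    all_keys = set(model.rules)
    for pair in needed_pairs:
        common = intersect_callsets(
            callsets[pair[0]], callsets[pair[1]], criterion
        )
        for key, members in group(common, RULE_ATTRIBUTES).items():
            if key not in all_keys:
                dropped += len(members)
    if dropped:
        logger.info("BF-M dropped %d calls in groups without a learned rule", dropped)
    kept.sort(key=lambda m: (m.chrom, m.pos))
    return kept, dropped


def evaluate_bfm(
    model: BfmModel,
    callsets: Mapping[str, Sequence[InDelCall]],
    truth_calls: Sequence[InDelCall],
    criterion: MatchCriterion,
) -> tuple[dict[GroupKey, PerformanceRecord], LabelResult]:
    """Apply the rules and score the screened set against truth."""
    screened, _ = apply_rules(model, callsets, criterion)
    labeled = label_against_truth(screened, truth_calls, criterion)
    return performance_table(labeled, RULE_ATTRIBUTES), labeled
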