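"""Decide when two InDel reports describe the same event, and match call sets.

Different callers report the same InDel at slightly different coordinates
whenever the surrounding sequence is self-similar: deleting one AT from
ATATAT can legitimately be reported at any of three positions.  The
consistency criterion therefore compares the coordinate deviation
``D = |P1 - P2|`` against a repeat-aware tolerance: zero (configurable)
outside repeats, and the length of the containing repeat region inside them —
any placement within the region is the same event, provided type and size
agree exactly.

Matching is one-to-one in coordinate order with nearest-position preference,
augmented to a maximum-cardinality matching: within a repeat region every
same-type same-size pair is mutually consistent, so nearest-first assignment
is already optimal there, but mixed repeat/non-repeat neighbourhoods can
strand a partner unless earlier assignments are allowed to shift.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .callset_io import InDelCall
from .errors import CoordinateError
from .varsim import TruthVariant


@dataclass(frozen=True)
class MatchCriterion:
    """Repeat-aware positional tolerance for call consistency.

    ``nonrepeat_tolerance`` bounds D when both calls lie outside annotated
    repeats (default 0: left-normalized reports of one event coincide
    exactly).  Inside repeats the bound is the containing region's length
    (``repeat_tolerance_mode="region-length"``) or a fixed constant.
    """

    nonrepeat_tolerance: int = 0
    repeat_tolerance_mode: str = "region-length"
    fixed_repeat_tolerance: int = 0

    def __post_init__(self) -> None:
        if self.nonrepeat_tolerance < 0 or self.fixed_repeat_tolerance < 0:
            raise ValueError("tolerances must be >= 0")
        if self.repeat_tolerance_mode not in {"region-length", "fixed"}:
            raise ValueError(
                "repeat_tolerance_mode must be 'region-length' or 'fixed'"
            )

    def tolerance(self, a: InDelCall, b: InDelCall) -> int:
        if a.repeat_class == "NonRepeat" and b.repeat_class == "NonRepeat":
            return self.nonrepeat_tolerance
        if self.repeat_tolerance_mode == "fixed":
            return self.fixed_repeat_tolerance
        return max(a.region_length, b.region_length)


def coordinate_deviation(p1: int, p2: int, chrom1: str = "", chrom2: str = "") -> int:
    """The coordinate deviation D = |P1 - P2| between two reports."""
    if chrom1 != chrom2:
        raise CoordinateError(
            f"coordinate deviation undefined across chromosomes "
            f"({chrom1!r} vs {chrom2!r})"
        )
    return abs(p1 - p2)


def is_consistent(a: InDelCall, b: InDelCall, criterion: MatchCriterion) -> bool:
    """True when *a* and *b* describe the same InDel event.

    Requires the same chromosome, the same variation type, the same size, and
    coordinate deviation within the repeat-aware tolerance.  Symmetric, and
    reflexive on any call.
    """
    if a.chrom != b.chrom or a.vtype != b.vtype or a.size != b.size:
        return False
    return abs(a.pos - b.pos) <= criterion.tolerance(a, b)


@dataclass(frozen=True)
class MergedCall:
    """A candidate InDel supported by one or more callers.

    ``reads_by_caller`` keeps each detector's supporting-read count; the
    summed count feeds the classifier's reads feature.  Grouping attributes
    are inherited from the representative (first-matched) call.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    vtype: str
    size: int
    repeat_class: str
    region_length: int
    reads_by_caller: tuple[tuple[str, int], ...]

    @property
    def callers(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.reads_by_caller)

    @property
    def reads(self) -> int:
        """Summed supporting reads across all detecting callers."""
        return sum(r for _, r in self.reads_by_caller)

    def as_call(self, caller: str | None = None) -> InDelCall:
        return InDelCall(
            caller=caller or "+".join(self.callers),
            chrom=self.chrom,
            pos=self.pos,
            ref_allele=self.ref_allele,
            alt_allele=self.alt_allele,
            vtype=self.vtype,
            size=self.size,
            reads=self.reads,
            repeat_class=self.repeat_class,
            region_length=self.region_length,
        )


def _as_merged(call: InDelCall) -> MergedCall:
    return MergedCall(
        chrom=call.chrom,
        pos=call.pos,
        ref_allele=call.ref_allele,
        alt_allele=call.alt_allele,
        vtype=call.vtype,
        size=call.size,
        repeat_class=call.repeat_class,
        region_length=call.region_length,
        reads_by_caller=((call.caller, call.reads),),
    )


def _max_tolerance(criterion: MatchCriterion, calls: Iterable[InDelCall]) -> int:
    if criterion.repeat_tolerance_mode == "fixed":
        rep = criterion.fixed_repeat_tolerance
    else:
        rep = max((c.region_length for c in calls), default=0)
    return max(criterion.nonrepeat_tolerance, rep)


def _greedy_match(
    left: Sequence[InDelCall],
    right: Sequence[InDelCall],
    criterion: MatchCriterion,
) -> list[tuple[int, int]]:
    """Maximum one-to-one matching of *left* onto *right*.

    Left calls are processed in (chrom, pos) order; each tries its consistent
    right partners nearest-first (position ties toward the smaller position)
    and may displace an earlier assignment along an augmenting path, so the
    result is a maximum-cardinality matching — pure nearest-first greedy can
    strand a partner when tolerances differ across a repeat boundary.
    Deterministic given the orderings.  Returns (left_index, right_index)
    pairs.
    """
    order_l = sorted(range(len(left)), key=lambda i: (left[i].chrom, left[i].pos))
    order_r = sorted(range(len(right)), key=lambda j: (right[j].chrom, right[j].pos))
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for j in order_r:
        pos_list, idx_list = by_chrom.setdefault(right[j].chrom, ([], []))
        pos_list.append(right[j].pos)
        idx_list.append(j)

    window = _max_tolerance(criterion, list(left) + list(right))

    def neighbors(i: int) -> list[int]:
        a = left[i]
        entry = by_chrom.get(a.chrom)
        if entry is None:
            return []
        pos_list, idx_list = entry
        lo = bisect.bisect_left(pos_list, a.pos - window)
        hi = bisect.bisect_right(pos_list, a.pos + window)
        found = [
            (abs(a.pos - right[idx_list[k]].pos), right[idx_list[k]].pos, idx_list[k])
            for k in range(lo, hi)
            if is_consistent(a, right[idx_list[k]], criterion)
        ]
        return [j for _, _, j in sorted(found)]

    match_r: dict[int, int] = {}  # right index -> left index

    def try_assign(i: int, visited: set[int]) -> bool:
        for j in neighbors(i):
            if j in visited:
                continue
            visited.add(j)
            if j not in match_r or try_assign(match_r[j], visited):
                match_r[j] = i
                return True
        return False

    for i in order_l:
        try_assign(i, set())
    return sorted((i, j) for j, i in match_r.items())


def intersect_callsets(
    a: Sequence[InDelCall],
    b: Sequence[InDelCall],
    criterion: MatchCriterion,
) -> list[MergedCall]:
    """The common part (IR) of two callers' detection results.

    Consistent pairs are merged one-to-one; each merged call records both
    source callers and sums their supporting reads.  At most
    ``min(|a|, |b|)`` calls are returned.
    """
    pairs = _greedy_match(a, b, criterion)
    out = []
    for i, j in pairs:
        left, right = a[i], b[j]
        out.append(
            replace(
                _as_merged(left),
                reads_by_caller=(
                    (left.caller, left.reads),
                    (right.caller, right.reads),
                ),
            )
        )
    out.sort(key=lambda m: (m.chrom, m.pos))
    return out


def union_callsets(
    callsets: dict[str, Sequence[InDelCall]],
    criterion: MatchCriterion,
) -> list[MergedCall]:
    """Merge several callers' results into one multi-caller candidate set.

    Callers are folded in sorted-name order; each new caller's calls either
    join an existing consistent candidate (one-to-one, greedy) or open a new
    one.  Candidates keep per-caller read counts for the classifier.
    """
    merged: list[MergedCall] = []
    for name in sorted(callsets):
        calls = list(callsets[name])
        reps = [m.as_call() for m in merged]
        pairs = _greedy_match(calls, reps, criterion)
        matched_new = {i for i, _ in pairs}
        for i, j in pairs:
            merged[j] = replace(
                merged[j],
                reads_by_caller=merged[j].reads_by_caller
                + ((calls[i].caller, calls[i].reads),),
            )
        for i, call in enumerate(calls):
            if i not in matched_new:
                merged.append(_as_merged(call))
    merged.sort(key=lambda m: (m.chrom, m.pos))
    return merged


def truth_to_calls(
    truth: Iterable[TruthVariant],
    annotation=None,
    caller: str = "truth",
    reference=None,
) -> list[InDelCall]:
    """Project the 1–50 bp INS/DEL truth records into annotated pseudo-calls.

    Truth positions follow the same anchor-base convention as VCF records
    (position of the base before the event).  Pass the *reference* (chrom →
    sequence) whenever the call sets being compared were left-normalized on
    ingestion, so both sides use the same canonical representation.
    """
    from .callset_io import left_normalize

    calls = []
    for v in truth:
        if not v.is_indel_marker:
            continue
        pos = v.pos - 1  # anchor-base position
        ref_allele, alt_allele = v.ref_allele, v.alt_allele
        if reference is not None and v.chrom in reference:
            anchor = v.anchor or reference[v.chrom][pos - 1]
            pos, ref_allele, alt_allele = left_normalize(
                reference[v.chrom], pos, anchor + v.ref_allele, anchor + v.alt_allele
            )
        calls.append(
            InDelCall(
                caller=caller,
                chrom=v.chrom,
                pos=pos,
                ref_allele=ref_allele,
                alt_allele=alt_allele,
                vtype=v.vtype,
                size=v.size,
                reads=0,
            )
        )
    if annotation is not None:
        from .callset_io import annotate_repeat_class

        calls = annotate_repeat_class(calls, annotation)
    calls.sort(key=lambda c: (c.chrom, c.pos))
    return calls


@dataclass
class LabelResult:
    """Calls labeled against truth: TP/FP per call plus the unmatched truths."""

    labeled: list[tuple[object, str]]  # (call, "TP"|"FP")
    unmatched_truth: list[InDelCall]

    @property
    def tp(self) -> int:
        return sum(1 for _, lab in self.labeled if lab == "TP")

    @property
    def fp(self) -> int:
        return sum(1 for _, lab in self.labeled if lab == "FP")

    @property
    def fn(self) -> int:
        return len(self.unmatched_truth)


def label_against_truth(
    calls: Sequence[InDelCall] | Sequence[MergedCall],
    truth_calls: Sequence[InDelCall],
    criterion: MatchCriterion,
) -> LabelResult:
    """Label candidate calls TP/FP against an annotated truth-call list.

    One-to-one: each truth matches at most one call.  Counts conserve —
    TP + FN = |truth| and TP + FP = |calls|.
    """
    plain = [
        c.as_call() if isinstance(c, MergedCall) else c for c in calls
    ]
    pairs = _greedy_match(plain, truth_calls, criterion)
    matched_calls = {i for i, _ in pairs}
    matched_truth = {j for _, j in pairs}
    labeled = [
        (calls[i], "TP" if i in matched_calls else "FP")
        for i in range(len(calls))
    ]
    unmatched = [
        truth_calls[j] for j in range(len(truth_calls)) if j not in matched_truth
    ]
    return LabelResult(labeled=labeled, unmatched_truth=unmatched)
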