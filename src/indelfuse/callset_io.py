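"""Read per-caller VCFs, extract 1–50 bp InDels, annotate repeat context.

Every candidate call carries the four grouping attributes used throughout the
package: variation type (ST: INS or DEL), variation size (SS: 1–50 bp), the
repeat class of the surrounding region (RT), and the detecting software (DS).
Supporting-read counts come from a per-caller dialect table because callers
disagree about which depth field describes the evidence for an InDel.

Internally all coordinates are the 1-based VCF record positions; interval
arithmetic against the repeat annotation converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pysam
from intervaltree import IntervalTree

from .errors import ConfigError, ParseError

#: The repeat-class vocabulary: transposable-element classes (LINE, LTR, TIR,
#: Helitron), tandem/low-complexity sequence, and everything else.
REPEAT_CLASSES = (
    "LINE",
    "LTR",
    "TIR",
    "Helitron",
    "SimpleRepeat",
    "LowComplexity",
    "NonRepeat",
)

#: Common annotation spellings mapped onto the fixed vocabulary.  Users can
#: extend this (e.g. RepeatMasker family names) via the ``aliases`` argument.
DEFAULT_ALIASES: dict[str, str] = {
    "SSR": "SimpleRepeat",
    "Simple_repeat": "SimpleRepeat",
    "simple repeat": "SimpleRepeat",
    "Low_complexity": "LowComplexity",
    "low complexity": "LowComplexity",
    "LC": "LowComplexity",
    "Ht": "Helitron",
    "RC/Helitron": "Helitron",
    "DNA/TIR": "TIR",
    "Nor": "NonRepeat",
}

MAX_INDEL_SIZE = 50


@dataclass(frozen=True)
class InDelCall:
    """One caller's candidate InDel (1–50 bp) with its grouping attributes."""

    caller: str
    chrom: str
    pos: int  # 1-based VCF record position (anchor base)
    ref_allele: str
    alt_allele: str
    vtype: str  # "INS" | "DEL"
    size: int
    reads: int = 0
    repeat_class: str = "NonRepeat"
    region_length: int = 0  # bp length of the containing repeat region, 0 outside

    def __post_init__(self) -> None:
        if self.vtype not in {"INS", "DEL"}:
            raise ConfigError(f"InDel type must be INS or DEL, got {self.vtype!r}")
        if self.repeat_class not in REPEAT_CLASSES:
            raise ConfigError(f"unknown repeat class {self.repeat_class!r}")


#: Ordered per-caller lookup of the supporting-read field: each entry is
#: (source, key) with source in {"format", "info"}.  The first present field
#: wins; calls with none get 0 reads.
DialectSpec = Sequence[tuple[str, str]]

DEFAULT_DIALECTS: dict[str, DialectSpec] = {
    "generic": (("format", "AD"), ("format", "DP"), ("info", "DP")),
    "samtools": (("info", "DP4"), ("info", "DP"), ("format", "DP")),
    "gatk": (("format", "AD"), ("format", "DP"), ("info", "DP")),
    "varscan": (("format", "AD"), ("format", "DP"), ("info", "DP")),
    "pindel": (("format", "AD"), ("info", "DP")),
    "soapindel": (("info", "DP"), ("format", "DP")),
}


def _reads_from_record(rec: pysam.VariantRecord, dialect: DialectSpec) -> int:
    for source, key in dialect:
        try:
            if source == "info":
                val = rec.info.get(key)
            else:
                sample = rec.samples[0] if len(rec.samples) else None
                val = sample.get(key) if sample is not None else None
        except (KeyError, IndexError):
            val = None
        if val is None:
            continue
        if isinstance(val, (tuple, list)):
            if key == "AD" and len(val) > 1:  # allele depths: take the alt depth
                val = val[1]
            elif key == "DP4":  # samtools ref-fwd/ref-rev/alt-fwd/alt-rev
                val = sum(v or 0 for v in val[2:])
            else:
                val = sum(v or 0 for v in val)
        if val is None:
            continue
        return max(int(val), 0)
    return 0


def classify_alleles(ref: str, alt: str) -> tuple[str, int] | None:
    """Return (vtype, size) for an InDel allele pair, None for anything else."""
    if alt is None or alt.startswith("<") or "." in (ref, alt):
        return None
    diff = len(alt) - len(ref)
    if diff == 0:
        return None  # SNP or MNP
    return ("INS", diff) if diff > 0 else ("DEL", -diff)


def read_caller_vcf(
    path: str,
    caller_id: str,
    reference: Mapping[str, str] | None = None,
    dialects: Mapping[str, DialectSpec] | None = None,
) -> list[InDelCall]:
    """Extract 1–50 bp InDels from one caller's VCF.

    SNPs, symbolic records and InDels larger than 50 bp are dropped.  When a
    *reference* (chrom → sequence) is supplied, every call is left-normalized
    before being returned so that coordinate deviations between callers
    reflect genuine disagreement rather than representation choices.
    """
    table = dict(DEFAULT_DIALECTS)
    if dialects:
        table.update(dialects)
    dialect = table.get(caller_id, table["generic"])

    out: list[InDelCall] = []
    with pysam.VariantFile(path) as vcf:
        for i, rec in enumerate(vcf, start=1):
            try:
                if rec.alts is None:
                    continue
                for alt in rec.alts:
                    kind = classify_alleles(rec.ref, alt)
                    if kind is None:
                        continue
                    vtype, size = kind
                    if size > MAX_INDEL_SIZE:
                        continue
                    pos, ref, alt_n = rec.pos, rec.ref, alt
                    if reference is not None and rec.chrom in reference:
                        pos, ref, alt_n = left_normalize(
                            reference[rec.chrom], rec.pos, rec.ref, alt
                        )
                    out.append(
                        InDelCall(
                            caller=caller_id,
                            chrom=rec.chrom,
                            pos=pos,
                            ref_allele=ref,
                            alt_allele=alt_n,
                            vtype=vtype,
                            size=size,
                            reads=_reads_from_record(rec, dialect),
                        )
                    )
            except (ValueError, TypeError) as exc:
                raise ParseError(f"{path}: malformed record #{i}: {exc}") from exc
    out.sort(key=lambda c: (c.chrom, c.pos))
    return out


def left_normalize(
    seq: str, pos: int, ref: str, alt: str
) -> tuple[int, str, str]:
    """Shift an indel to its smallest representation at the leftmost position.

    Standard VCF normalization: repeatedly trim a shared trailing base
    (extending left with the preceding reference base when an allele would
    empty), then trim shared leading bases.  *pos* is 1-based; *seq* is the
    full chromosome sequence.
    """
    ref, alt = ref.upper(), alt.upper()
    while True:
        if len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1] and (
            len(ref) > 1 or len(alt) > 1
        ):
            ref, alt = ref[:-1], alt[:-1]
            if ref and alt:
                continue
        if (not ref or not alt) and pos > 1:
            base = seq[pos - 2].upper()
            ref, alt = base + ref, base + alt
            pos -= 1
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass
class RepeatAnnotation:
    """Per-chromosome repeat intervals with class labels.

    Intervals are half-open ``[start, end)`` in 0-based coordinates.  Lookup
    returns the class of the smallest containing interval (nested annotations
    resolve to the most specific one) and the containing region's length,
    which doubles as the repeat-aware matching tolerance.
    """

    trees: dict[str, IntervalTree] = field(default_factory=dict)

    @classmethod
    def from_intervals(
        cls,
        intervals: Iterable[tuple[str, int, int, str]],
        aliases: Mapping[str, str] | None = None,
    ) -> "RepeatAnnotation":
        """Build from (chrom, start0, end0, class) tuples."""
        alias = dict(DEFAULT_ALIASES)
        if aliases:
            alias.update(aliases)
        trees: dict[str, IntervalTree] = {}
        for chrom, start, end, label in intervals:
            cls_label = alias.get(label, label)
            if cls_label not in REPEAT_CLASSES:
                raise ConfigError(
                    f"unknown repeat class {label!r} (no alias maps it)"
                )
            if end <= start:
                raise ConfigError(f"empty interval {chrom}:{start}-{end}")
            trees.setdefault(chrom, IntervalTree()).addi(start, end, cls_label)
        return cls(trees)

    @classmethod
    def from_bed(
        cls, path: str, aliases: Mapping[str, str] | None = None
    ) -> "RepeatAnnotation":
        """Read a BED file with the repeat class in column 4."""
        intervals: list[tuple[str, int, int, str]] = []
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ParseError(f"{path}:{i}: need 4 BED columns")
                intervals.append(
                    (parts[0], int(parts[1]), int(parts[2]), parts[3])
                )
        return cls.from_intervals(intervals, aliases=aliases)

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.trees):
                for iv in sorted(self.trees[chrom]):
                    fh.write(f"{chrom}\t{iv.begin}\t{iv.end}\t{iv.data}\n")

    def lookup(self, chrom: str, pos: int) -> tuple[str, int]:
        """Class and region length at 1-based position *pos*.

        Overlap ties break toward the smallest interval; equal spans break
        lexicographically by class for determinism.
        """
        tree = self.trees.get(chrom)
        if tree is None:
            return "NonRepeat", 0
        hits = tree[pos - 1]
        if not hits:
            return "NonRepeat", 0
        best = min(hits, key=lambda iv: (iv.end - iv.begin, iv.data))
        return best.data, best.end - best.begin

    def intervals_of_class(self, label: str) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self.trees):
            for iv in sorted(self.trees[chrom]):
                if iv.data == label:
                    out.append((chrom, iv.begin, iv.end))
        return out


def annotate_repeat_class(
    calls: Iterable[InDelCall], annotation: RepeatAnnotation
) -> list[InDelCall]:
    """Assign every call the repeat class (and region length) at its position."""
    out = []
    for call in calls:
        cls_label, length = annotation.lookup(call.chrom, call.pos)
        out.append(replace(call, repeat_class=cls_label, region_length=length))
    return out
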