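"""Plant known variations into a reference genome and emit a truth set.

The simulator takes a reference FASTA and a :class:`SimulationPlan` describing
how many variations of each class to plant — per-base SNPs, short InDels
(1–50 bp, the marker class), larger insertions/deletions (51–500 bp), and
duplications, inversions and translocations (100–500 bp) — and produces the
mutated genome together with a machine-readable truth VCF.  Placement is
uniform over eligible positions: variants never land on runs of N, footprints
never overlap, and a minimum 1 bp gap separates adjacent footprints.  A fixed
seed makes the whole procedure bit-reproducible.

Coordinates are 1-based throughout this module, matching VCF.  A variant's
``pos`` is the first affected reference base; alleles are stored anchor-free
(a deletion's ``ref_allele`` is exactly the deleted bases) and the VCF
anchor-base convention is applied only at the file boundary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .errors import CapacityError, ConfigError, CoordinateError, OverlapError

NUCLEOTIDES = "ACGT"

#: Variation classes with a fixed planted count (everything except SNPs).
SV_TYPES = ("DUP", "INV", "TRA")

_DEFAULT_SIZE_RANGES: dict[str, tuple[int, int]] = {
    "INDEL": (1, 50),
    "SV": (51, 500),
    "DUP": (100, 500),
    "INV": (100, 500),
    "TRA": (100, 500),
}


@dataclass(frozen=True)
class SimulationPlan:
    """How many variations of each class to plant, and their size ranges.

    Defaults reproduce the soybean-scale simulation design: SNPs at one per
    kilobase, 2,792,000 short InDels (1–50 bp), 20,000 large
    insertions/deletions (51–500 bp), and 1,000 each of duplications,
    inversions and translocations (100–500 bp).  Desk-scale runs pass much
    smaller counts; the ratios are what matter.
    """

    snp_rate: float = 1.0 / 1000
    indel_count: int = 2_792_000
    sv_del_ins_count: int = 20_000
    duplication_count: int = 1_000
    inversion_count: int = 1_000
    translocation_count: int = 1_000
    size_ranges: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_SIZE_RANGES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.indel_count,
            self.sv_del_ins_count,
            self.duplication_count,
            self.inversion_count,
            self.translocation_count,
        )
        if any(c < 0 for c in counts) or not 0.0 <= self.snp_rate <= 1.0:
            raise ConfigError("plan counts must be >= 0 and snp_rate in [0, 1]")
        for key, (lo, hi) in self.size_ranges.items():
            if key not in _DEFAULT_SIZE_RANGES:
                raise ConfigError(f"unknown size-range key {key!r}")
            if lo < 1 or hi < lo:
                raise ConfigError(f"size range for {key} must satisfy 1 <= min <= max")


@dataclass(frozen=True, order=True)
class TruthVariant:
    """One planted variation.

    ``pos`` is the 1-based first affected base.  ``ref_allele``/``alt_allele``
    are anchor-free: a size-2 deletion has ``ref_allele`` of length 2 and an
    empty ``alt_allele``; an insertion the reverse.  ``anchor`` is the
    reference base immediately before ``pos``, captured at sampling time so
    VCF emission needs no reference handle.  DUP/INV/TRA are symbolic
    (``ref_allele`` holds the first segment base only); a translocation also
    records where the excised segment re-inserts.
    """

    chrom: str
    pos: int
    vtype: str
    size: int
    ref_allele: str
    alt_allele: str
    anchor: str = ""
    dest_chrom: str = ""
    dest_pos: int = 0

    def __post_init__(self) -> None:
        if self.vtype not in {"SNP", "INS", "DEL", "DUP", "INV", "TRA"}:
            raise ConfigError(f"unknown variation type {self.vtype!r}")
        if self.pos < 1:
            raise CoordinateError(f"position must be >= 1, got {self.pos}")

    @property
    def footprint(self) -> tuple[int, int]:
        """Half-open 1-based reference interval consumed by this variant."""
        if self.vtype in {"DEL", "DUP", "INV", "TRA"}:
            return (self.pos, self.pos + self.size)
        return (self.pos, self.pos + 1)  # SNP, INS

    @property
    def is_indel_marker(self) -> bool:
        return self.vtype in {"INS", "DEL"} and 1 <= self.size <= 50


def _seq_of(reference: Mapping[str, object], chrom: str) -> str | None:
    val = reference[chrom]
    if isinstance(val, int):
        return None
    return str(val).upper()


def _len_of(reference: Mapping[str, object], chrom: str) -> int:
    val = reference[chrom]
    return val if isinstance(val, int) else len(val)


class _Occupancy:
    """Sorted footprint bookkeeping with a 1 bp separating gap."""

    def __init__(self) -> None:
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}

    def is_free(self, chrom: str, start: int, end: int) -> bool:
        import bisect

        starts = self._starts.get(chrom)
        if not starts:
            return True
        ends = self._ends[chrom]
        # enforce gap: forbid [start-1, end+1) touching any occupied interval
        i = bisect.bisect_left(starts, end + 1)
        if i > 0 and ends[i - 1] + 1 > start:
            return False
        return True

    def add(self, chrom: str, start: int, end: int) -> None:
        import bisect

        starts = self._starts.setdefault(chrom, [])
        ends = self._ends.setdefault(chrom, [])
        i = bisect.bisect_left(starts, start)
        starts.insert(i, start)
        ends.insert(i, end)


def _eligible(seq: str | None, start: int, end: int, chrom_len: int) -> bool:
    """A footprint is eligible when inside the chromosome, after base 1
    (room for a VCF anchor), and free of N."""
    if start < 2 or end > chrom_len + 1:
        return False
    if seq is not None and "N" in seq[start - 1 : end - 1]:
        return False
    return True


def sample_plan(
    reference: Mapping[str, object], plan: SimulationPlan
) -> list[TruthVariant]:
    """Draw a truth set of planted variations according to *plan*.

    *reference* maps chromosome name to either its sequence (preferred — lets
    the sampler capture true alleles and avoid N runs) or its length.  Returns
    variants sorted by (chrom, pos) with pairwise non-overlapping footprints;
    per-type counts match the plan exactly.  Raises :class:`CapacityError`
    when the plan cannot be placed.
    """
    if not reference:
        raise CapacityError("reference is empty")
    rng = np.random.default_rng(plan.seed)
    chroms = sorted(reference)
    lengths = np.array([_len_of(reference, c) for c in chroms], dtype=float)
    genome_len = int(lengths.sum())

    def _mean(key: str) -> float:
        lo, hi = plan.size_ranges[key]
        return (lo + hi) / 2.0

    # expected footprint: deletions consume their size, insertions one base;
    # +2 per variant covers the separating gaps.  Placement still raises if
    # rejection sampling exhausts a locally infeasible genome.
    footprint_budget = (
        plan.indel_count * (0.5 * _mean("INDEL") + 0.5 + 2)
        + plan.sv_del_ins_count * (0.5 * _mean("SV") + 0.5 + 2)
        + plan.duplication_count * (_mean("DUP") + 2)
        + plan.inversion_count * (_mean("INV") + 2)
        + plan.translocation_count * (_mean("TRA") + 4)
    )
    if footprint_budget > genome_len:
        raise CapacityError(
            f"plan needs up to {footprint_budget} bp of footprint but the "
            f"genome has only {genome_len} bp"
        )

    occ = _Occupancy()
    seqs = {c: _seq_of(reference, c) for c in chroms}
    weights = lengths / lengths.sum()
    out: list[TruthVariant] = []

    def place(size: int, span: int) -> tuple[str, int]:
        """Find a free, eligible (chrom, pos) for a footprint of *span* bp."""
        for _ in range(10_000):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            clen = _len_of(reference, chrom)
            if clen < span + 2:
                continue
            pos = int(rng.integers(2, clen - span + 2))
            if _eligible(seqs[chrom], pos, pos + span, clen) and occ.is_free(
                chrom, pos, pos + span
            ):
                occ.add(chrom, pos, pos + span)
                return chrom, pos
        raise CapacityError(f"could not place a {size} bp footprint after 10000 tries")

    def ref_bases(chrom: str, pos: int, n: int) -> str:
        seq = seqs[chrom]
        if seq is None:
            return "." * n
        return seq[pos - 1 : pos - 1 + n]

    def anchor_base(chrom: str, pos: int) -> str:
        seq = seqs[chrom]
        return "" if seq is None else seq[pos - 2]

    def rand_seq(n: int) -> str:
        return "".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, size=n))

    # SNPs: Bernoulli per base at snp_rate (binomial count per chromosome).
    if plan.snp_rate > 0:
        for chrom in chroms:
            clen = _len_of(reference, chrom)
            n_snp = int(rng.binomial(max(clen - 1, 0), plan.snp_rate))
            for _ in range(n_snp):
                try:
                    c, pos = place(1, 1)
                except CapacityError:
                    break  # SNPs are rate-driven; density, not count, is the contract
                ref = ref_bases(c, pos, 1)
                choices = [b for b in NUCLEOTIDES if b != ref]
                alt = choices[int(rng.integers(0, len(choices)))] if ref != "." else "."
                out.append(TruthVariant(c, pos, "SNP", 1, ref, alt))

    def plant_ins_del(count: int, size_range: tuple[int, int]) -> None:
        lo, hi = size_range
        for _ in range(count):
            size = int(rng.integers(lo, hi + 1))
            if rng.random() < 0.5:  # deletion
                chrom, pos = place(size, size)
                out.append(
                    TruthVariant(
                        chrom, pos, "DEL", size,
                        ref_bases(chrom, pos, size), "",
                        anchor=anchor_base(chrom, pos),
                    )
                )
            else:  # insertion
                chrom, pos = place(size, 1)
                out.append(
                    TruthVariant(
                        chrom, pos, "INS", size,
                        "", rand_seq(size),
                        anchor=anchor_base(chrom, pos),
                    )
                )

    plant_ins_del(plan.indel_count, plan.size_ranges["INDEL"])
    plant_ins_del(plan.sv_del_ins_count, plan.size_ranges["SV"])

    for vtype, count in (
        ("DUP", plan.duplication_count),
        ("INV", plan.inversion_count),
        ("TRA", plan.translocation_count),
    ):
        lo, hi = plan.size_ranges[vtype]
        for _ in range(count):
            size = int(rng.integers(lo, hi + 1))
            chrom, pos = place(size, size)
            kwargs: dict[str, object] = {}
            if vtype == "TRA":
                dchrom, dpos = place(1, 1)
                kwargs = {"dest_chrom": dchrom, "dest_pos": dpos}
            out.append(
                TruthVariant(
                    chrom, pos, vtype, size,
                    ref_bases(chrom, pos, 1), f"<{vtype}>",
                    **kwargs,  # type: ignore[arg-type]
                )
            )

    out.sort(key=lambda v: (v.chrom, v.pos))
    return out


def apply_variants(
    reference: Mapping[str, str], truth: Sequence[TruthVariant]
) -> dict[str, str]:
    """Rewrite each chromosome with the planted variations applied.

    Variants must be non-overlapping; they are applied left-to-right with the
    cumulative coordinate shift implied by earlier edits.  Returns the mutated
    genome as a plain dict of sequences.  The mutated total length equals the
    original plus net inserted minus deleted bases (translocations are
    length-neutral genome-wide).
    """
    per_chrom: dict[str, list[tuple[int, int, str]]] = {c: [] for c in reference}
    # (start, end, replacement) edits in 1-based half-open reference coords
    for v in sorted(truth, key=lambda v: (v.chrom, v.pos)):
        if v.chrom not in per_chrom:
            raise CoordinateError(f"unknown chromosome {v.chrom!r}")
        clen = len(reference[v.chrom])
        start, end = v.footprint
        if end > clen + 1:
            raise CoordinateError(
                f"{v.vtype} at {v.chrom}:{v.pos} (size {v.size}) exceeds "
                f"chromosome length {clen}"
            )
        seq = reference[v.chrom]
        segment = seq[start - 1 : end - 1]
        if v.vtype == "SNP":
            per_chrom[v.chrom].append((start, end, v.alt_allele))
        elif v.vtype == "DEL":
            per_chrom[v.chrom].append((start, end, ""))
        elif v.vtype == "INS":
            # inserted bases appear immediately before the affected position
            per_chrom[v.chrom].append((start, start, v.alt_allele))
        elif v.vtype == "DUP":
            per_chrom[v.chrom].append((end, end, segment))  # tandem copy
        elif v.vtype == "INV":
            per_chrom[v.chrom].append((start, end, _revcomp(segment)))
        elif v.vtype == "TRA":
            per_chrom[v.chrom].append((start, end, ""))
            per_chrom.setdefault(v.dest_chrom, []).append(
                (v.dest_pos, v.dest_pos, segment)
            )

    mutated: dict[str, str] = {}
    for chrom, seq in reference.items():
        edits = sorted(per_chrom.get(chrom, ()))
        pieces: list[str] = []
        cursor = 1
        for start, end, repl in edits:
            if start < cursor:
                raise OverlapError(
                    f"overlapping edits on {chrom} near position {start}"
                )
            pieces.append(seq[cursor - 1 : start - 1])
            pieces.append(repl)
            cursor = end
        pieces.append(seq[cursor - 1 :])
        mutated[chrom] = "".join(pieces)
    return mutated


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# truth VCF I/O

_SYMBOLIC = {"DUP", "INV", "TRA"}


def _truth_header(contigs: Iterable[tuple[str, int]]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##source=indelfuse-varsim')
    header.add_line(
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Variation type">'
    )
    header.add_line(
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End of the footprint">'
    )
    header.add_line(
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Variation size in bp">'
    )
    header.add_line(
        '##INFO=<ID=CHR2,Number=1,Type=String,Description="Translocation target chromosome">'
    )
    header.add_line(
        '##INFO=<ID=POS2,Number=1,Type=Integer,Description="Translocation target position">'
    )
    for name, length in contigs:
        header.contigs.add(name, length=length)
    return header


def write_truth(
    truth: Sequence[TruthVariant],
    path: str,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write the truth set as a VCF 4.x file.

    SNP/INS/DEL records use explicit alleles with the anchor-base convention;
    DUP/INV/TRA use a symbolic ALT plus INFO END/SVTYPE (and CHR2/POS2 for
    translocations).  ``read_truth(write_truth(x)) == x``.
    """
    if contigs is None:
        contigs = {}
        for v in truth:
            end = v.footprint[1] - 1
            contigs[v.chrom] = max(contigs.get(v.chrom, 0), end)
            if v.dest_chrom:
                contigs[v.dest_chrom] = max(
                    contigs.get(v.dest_chrom, 0), v.dest_pos
                )
    header = _truth_header(sorted(contigs.items()))
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for v in sorted(truth, key=lambda v: (v.chrom, v.pos)):
            rec = vcf.new_record()
            rec.chrom = v.chrom
            rec.info["SVTYPE"] = v.vtype
            rec.info["SVLEN"] = v.size
            if v.vtype == "SNP":
                rec.start = v.pos - 1  # pysam start is 0-based
                rec.alleles = (v.ref_allele, v.alt_allele)
            elif v.vtype in _SYMBOLIC:
                rec.start = v.pos - 1
                rec.alleles = (v.ref_allele or "N", f"<{v.vtype}>")
                rec.stop = v.pos + v.size - 1
                if v.vtype == "TRA":
                    rec.info["CHR2"] = v.dest_chrom
                    rec.info["POS2"] = v.dest_pos
            else:  # INS/DEL: anchor base precedes the event
                anchor = v.anchor or "N"
                rec.start = v.pos - 2
                if v.vtype == "DEL":
                    rec.alleles = (anchor + v.ref_allele, anchor)
                else:
                    rec.alleles = (anchor, anchor + v.alt_allele)
            vcf.write(rec)


def read_truth(path: str) -> list[TruthVariant]:
    """Read a truth VCF written by :func:`write_truth`."""
    out: list[TruthVariant] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            vtype = rec.info["SVTYPE"]
            size = int(rec.info["SVLEN"])
            if vtype == "SNP":
                out.append(
                    TruthVariant(
                        rec.chrom, rec.pos, "SNP", 1, rec.ref, rec.alts[0]
                    )
                )
            elif vtype in _SYMBOLIC:
                kwargs: dict[str, object] = {}
                if vtype == "TRA":
                    kwargs = {
                        "dest_chrom": rec.info["CHR2"],
                        "dest_pos": int(rec.info["POS2"]),
                    }
                out.append(
                    TruthVariant(
                        rec.chrom, rec.pos, vtype, size,
                        rec.ref, f"<{vtype}>",
                        anchor="", **kwargs,  # type: ignore[arg-type]
                    )
                )
            else:
                anchor = rec.ref[0]
                if vtype == "DEL":
                    ref, alt = rec.ref[1:], ""
                else:
                    ref, alt = "", rec.alts[0][1:]
                out.append(
                    TruthVariant(
                        rec.chrom, rec.pos + 1, vtype, size, ref, alt,
                        anchor=anchor,
                    )
                )
    out.sort(key=lambda v: (v.chrom, v.pos))
    return out


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 70) -> None:
    """Write sequences as FASTA with fixed line width."""
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def variant_counts(truth: Iterable[TruthVariant]) -> dict[str, int]:
    """Per-type tally of a truth set (conservation check helper)."""
    counts: dict[str, int] = {}
    for v in truth:
        counts[v.vtype] = counts.get(v.vtype, 0) + 1
    return counts
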