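"""Synthetic multi-caller call sets with controlled error profiles.

Real callers differ strongly — and stratum by stratum — in how many true
InDels they recover and how many spurious ones they report, and they disagree
about coordinates inside repeats.  This module emulates exactly those
features: a :class:`CallerProfile` fixes per-(type, size, repeat-class)
recall and false-discovery rate, a supporting-read distribution per label
class, and a coordinate-jitter bound inside repeat regions.  Generated call
sets plug directly into the matching/scoring/BF-M/SVM-M machinery, so the
integrators are testable end-to-end without running any real caller.

Named fixture scenarios plant known structure:

- ``dominant-pair``       one caller pair is best in every stratum;
- ``group-dependent-best``  deletions and insertions have different best pairs;
- ``separable-reads``     true and false candidates are separable on reads;
- ``jittered-repeats``    heavy coordinate jitter inside repeat regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .callset_io import InDelCall, RepeatAnnotation, annotate_repeat_class
from .errors import ConfigError
from .matching import MatchCriterion, truth_to_calls
from .varsim import (
    NUCLEOTIDES,
    SimulationPlan,
    TruthVariant,
    sample_plan,
    write_fasta,
    write_truth,
)

#: Read-count distribution: ("nbinom", mean) or ("uniform", lo, hi).
ReadDist = tuple


@dataclass(frozen=True)
class OverrideRule:
    """Recall/FDR override for strata matching the given attribute filters."""

    st: str | None = None
    ss: int | None = None
    rt: str | None = None
    recall: float = 0.0
    fdr: float = 0.0

    def matches(self, st: str, ss: int, rt: str) -> bool:
        return (
            (self.st is None or self.st == st)
            and (self.ss is None or self.ss == ss)
            and (self.rt is None or self.rt == rt)
        )


@dataclass(frozen=True)
class CallerProfile:
    """One synthetic caller's error profile.

    ``recall`` and ``fdr`` are the per-stratum defaults; ``overrides`` are
    checked first (first match wins).  ``jitter`` bounds the uniform
    coordinate offset applied inside repeat regions (further capped at the
    region length, so jittered calls always stay consistent with their source
    truth under the default region-length criterion).
    """

    caller: str
    recall: float = 0.8
    fdr: float = 0.1
    overrides: tuple[OverrideRule, ...] = ()
    tp_reads: ReadDist = ("nbinom", 20.0)
    fp_reads: ReadDist = ("nbinom", 6.0)
    jitter: int = 0

    def __post_init__(self) -> None:
        for r, f in [(self.recall, self.fdr)] + [
            (o.recall, o.fdr) for o in self.overrides
        ]:
            if not (0.0 <= r <= 1.0 and 0.0 <= f <= 1.0):
                raise ConfigError("recall and fdr must lie in [0, 1]")
            if f == 1.0 and r > 0.0:
                raise ConfigError(
                    "fdr = 1 with positive recall is infeasible (no finite "
                    "number of false positives yields that rate)"
                )
        if self.jitter < 0:
            raise ConfigError("jitter must be >= 0")

    def rates_for(self, st: str, ss: int, rt: str) -> tuple[float, float]:
        for rule in self.overrides:
            if rule.matches(st, ss, rt):
                return rule.recall, rule.fdr
        return self.recall, self.fdr


def _draw_reads(rng: np.random.Generator, dist: ReadDist, n: int) -> np.ndarray:
    kind = dist[0]
    if kind == "nbinom":
        mean = float(dist[1])
        if mean <= 0:
            return np.zeros(n, dtype=int)
        shape = 4.0  # over-dispersed relative to Poisson, like real depth
        p = shape / (shape + mean)
        return rng.negative_binomial(shape, p, size=n).astype(int) + 1
    if kind == "uniform":
        lo, hi = int(dist[1]), int(dist[2])
        return rng.integers(lo, hi + 1, size=n)
    raise ConfigError(f"unknown read distribution {kind!r}")


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, size=n))


def _free_intervals_by_class(
    annotation: RepeatAnnotation, truth_calls: Sequence[InDelCall]
) -> dict[str, list[tuple[str, int, int]]]:
    """Repeat intervals that contain no truth call (safe hosts for FPs)."""
    occupied: set[tuple[str, int, int]] = set()
    for call in truth_calls:
        tree = annotation.trees.get(call.chrom)
        if tree is None:
            continue
        for iv in tree[call.pos - 1]:
            occupied.add((call.chrom, iv.begin, iv.end))
    free: dict[str, list[tuple[str, int, int]]] = {}
    for chrom in sorted(annotation.trees):
        for iv in sorted(annotation.trees[chrom]):
            if (chrom, iv.begin, iv.end) not in occupied:
                free.setdefault(iv.data, []).append((chrom, iv.begin, iv.end))
    return free


def simulate_callset(
    truth: Sequence[TruthVariant],
    profile: CallerProfile,
    annotation: RepeatAnnotation,
    seed: int,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[InDelCall]:
    """Emit one synthetic caller's candidate InDels for a truth set.

    Each 1–50 bp truth InDel in stratum g is detected with probability
    ``recall(g)``; detected calls inside repeats are jittered uniformly
    within ``min(jitter, region length)``.  False positives are then added
    per stratum so the realized false-discovery rate matches ``fdr(g)``
    (count = round(TP * fdr / (1 - fdr))), placed in truth-free regions of
    the stratum's repeat class.  Reads are drawn from the profile's
    per-label distribution.  Fully seed-reproducible.
    """
    rng = np.random.default_rng(seed)
    truth_calls = truth_to_calls(truth, annotation)
    out: list[InDelCall] = []
    tp_by_group: dict[tuple[str, int, str], int] = {}

    for tc in truth_calls:
        recall, _ = profile.rates_for(tc.vtype, tc.size, tc.repeat_class)
        if rng.random() >= recall:
            continue
        pos = tc.pos
        if tc.repeat_class != "NonRepeat" and profile.jitter > 0:
            j = min(profile.jitter, tc.region_length)
            pos = max(2, pos + int(rng.integers(-j, j + 1)))
        reads = int(_draw_reads(rng, profile.tp_reads, 1)[0])
        out.append(
            InDelCall(
                caller=profile.caller,
                chrom=tc.chrom,
                pos=pos,
                ref_allele=tc.ref_allele,
                alt_allele=tc.alt_allele,
                vtype=tc.vtype,
                size=tc.size,
                reads=reads,
            )
        )
        key = (tc.vtype, tc.size, tc.repeat_class)
        tp_by_group[key] = tp_by_group.get(key, 0) + 1

    # false positives per stratum, hosted away from every truth footprint
    free = _free_intervals_by_class(annotation, truth_calls)
    truth_pos = {(tc.chrom, tc.pos) for tc in truth_calls}
    if chrom_lengths is None:
        chrom_lengths = {}
        for tc in truth_calls:
            chrom_lengths.setdefault(tc.chrom, 0)
            chrom_lengths[tc.chrom] = max(chrom_lengths[tc.chrom], tc.pos + 100)
    chroms = sorted(chrom_lengths)

    for (st, ss, rt), tp_count in sorted(tp_by_group.items()):
        _, fdr = profile.rates_for(st, ss, rt)
        if fdr <= 0 or tp_count == 0:
            continue
        n_fp = int(round(tp_count * fdr / (1.0 - fdr)))
        hosts = free.get(rt, []) if rt != "NonRepeat" else None
        if rt != "NonRepeat" and not hosts:
            continue  # no truth-free region of this class to contaminate
        made = 0
        attempts = 0
        while made < n_fp and attempts < 50 * n_fp + 100:
            attempts += 1
            if hosts is not None:
                chrom, begin, end = hosts[int(rng.integers(0, len(hosts)))]
                pos = int(rng.integers(begin + 1, end + 1))
            else:
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                pos = int(rng.integers(2, max(chrom_lengths[chrom] - 60, 3)))
                cls_here, _ = annotation.lookup(chrom, pos)
                if cls_here != "NonRepeat":
                    continue
                if any((chrom, pos + d) in truth_pos for d in (-1, 0, 1)):
                    continue
            seq = _rand_seq(rng, ss)
            reads = int(_draw_reads(rng, profile.fp_reads, 1)[0])
            out.append(
                InDelCall(
                    caller=profile.caller,
                    chrom=chrom,
                    pos=pos,
                    ref_allele=seq if st == "DEL" else "",
                    alt_allele="" if st == "DEL" else seq,
                    vtype=st,
                    size=ss,
                    reads=reads,
                )
            )
            made += 1

    out = annotate_repeat_class(out, annotation)
    out.sort(key=lambda c: (c.chrom, c.pos))
    return out


# ---------------------------------------------------------------------------
# fixture scenarios


@dataclass
class Fixture:
    """A deterministic end-to-end bundle: genome, truth, annotation, callsets."""

    scenario: str
    reference: dict[str, str]
    truth: list[TruthVariant]
    annotation: RepeatAnnotation
    callsets: dict[str, list[InDelCall]]
    criterion: MatchCriterion = field(default_factory=MatchCriterion)
    planted: dict = field(default_factory=dict)

    def write(self, outdir: str) -> dict[str, str]:
        """Emit FASTA, truth VCF, repeat BED and per-caller VCFs under *outdir*."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "reference": os.path.join(outdir, "reference.fa"),
            "truth": os.path.join(outdir, "truth.vcf"),
            "repeats": os.path.join(outdir, "repeats.bed"),
        }
        write_fasta(self.reference, paths["reference"])
        contigs = {c: len(s) for c, s in self.reference.items()}
        write_truth(self.truth, paths["truth"], contigs=contigs)
        self.annotation.to_bed(paths["repeats"])
        for caller, calls in self.callsets.items():
            path = os.path.join(outdir, f"{caller}.vcf")
            write_calls_vcf(calls, path, self.reference)
            paths[f"calls:{caller}"] = path
        return paths


def write_calls_vcf(
    calls: Sequence[InDelCall], path: str, reference: Mapping[str, str]
) -> None:
    """Write a caller's calls as a well-formed VCF against *reference*.

    Call positions are anchor-base positions; REF bases are taken from the
    reference so records are valid even for fabricated false positives.
    Supporting reads go to INFO/DP.
    """
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##source=indelfuse-synthdata')
    header.add_line(
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Supporting reads">'
    )
    for chrom in sorted(reference):
        header.contigs.add(chrom, length=len(reference[chrom]))
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for call in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            seq = reference[call.chrom]
            anchor = seq[call.pos - 1]
            rec = vcf.new_record()
            rec.chrom = call.chrom
            rec.start = call.pos - 1
            if call.vtype == "DEL":
                deleted = seq[call.pos : call.pos + call.size]
                if len(deleted) < call.size:  # truncated at chromosome end
                    deleted = (deleted + "ACGT" * call.size)[: call.size]
                rec.alleles = (anchor + deleted, anchor)
            else:
                # alleles may be anchor-free (synthetic) or VCF-style (ingested)
                ins = call.alt_allele
                if len(ins) == call.size + 1:
                    ins = ins[1:]
                elif len(ins) != call.size:
                    ins = "A" * call.size
                rec.alleles = (anchor, anchor + ins)
            rec.info["DP"] = call.reads
            vcf.write(rec)


def _random_genome(rng: np.random.Generator, lengths: Mapping[str, int]) -> dict[str, str]:
    return {
        chrom: "".join(
            NUCLEOTIDES[i] for i in rng.integers(0, 4, size=length)
        )
        for chrom, length in lengths.items()
    }


def _tile_repeats(
    rng: np.random.Generator,
    lengths: Mapping[str, int],
    classes: Sequence[str],
    coverage: float = 0.35,
    span_range: tuple[int, int] = (24, 90),
) -> RepeatAnnotation:
    """Scatter non-overlapping repeat intervals over ~*coverage* of the genome."""
    intervals: list[tuple[str, int, int, str]] = []
    for chrom in sorted(lengths):
        pos = int(rng.integers(0, 200))
        i = 0
        length = lengths[chrom]
        while pos < length - span_range[1] - 10:
            span = int(rng.integers(*span_range))
            label = classes[i % len(classes)]
            intervals.append((chrom, pos, pos + span, label))
            # spacing tuned so repeat bases ≈ coverage fraction of the genome
            gap = int(span * (1.0 - coverage) / coverage)
            pos += span + max(gap, 12) + int(rng.integers(0, 30))
            i += 1
    return RepeatAnnotation.from_intervals(intervals)


SCENARIOS = (
    "dominant-pair",
    "group-dependent-best",
    "separable-reads",
    "jittered-repeats",
)


def make_fixture(
    scenario: str,
    seed: int,
    n_indels: int = 3000,
    genome_length: int = 600_000,
) -> Fixture:
    """Build a named deterministic scenario bundle.

    All scenarios share a random two-chromosome genome, a scattered repeat
    annotation over three classes, and a truth set of ``n_indels`` short
    InDels; they differ only in the synthetic callers' profiles.
    """
    if scenario not in SCENARIOS:
        raise ConfigError(
            f"unknown scenario {scenario!r}; choose one of {SCENARIOS}"
        )
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=8)
    lengths = {"chr1": genome_length * 2 // 3, "chr2": genome_length // 3}
    reference = _random_genome(np.random.default_rng(int(sub[0])), lengths)
    if scenario == "separable-reads":
        # reads alone must carry the planted rule: an empty annotation rules
        # out label noise from position ambiguity inside repeat regions
        annotation = RepeatAnnotation()
    else:
        annotation = _tile_repeats(
            np.random.default_rng(int(sub[1])),
            lengths,
            classes=("SimpleRepeat", "LTR", "TIR"),
        )
    size_range = (1, 2) if scenario in ("dominant-pair", "group-dependent-best") else (1, 10)
    plan = SimulationPlan(
        snp_rate=0.0,
        indel_count=n_indels,
        sv_del_ins_count=0,
        duplication_count=0,
        inversion_count=0,
        translocation_count=0,
        size_ranges={**dict.fromkeys(("SV", "DUP", "INV", "TRA"), (51, 500)),
                     "INDEL": size_range},
        seed=int(sub[2]),
    )
    truth = sample_plan(reference, plan)

    planted: dict = {}
    if scenario == "dominant-pair":
        profiles = [
            CallerProfile("alpha", recall=0.90, fdr=0.10),
            CallerProfile("beta", recall=0.85, fdr=0.12),
            CallerProfile("gamma", recall=0.25, fdr=0.30),
        ]
        planted["best_pair"] = ("alpha", "beta")
    elif scenario == "group-dependent-best":
        profiles = [
            CallerProfile(
                "alpha", recall=0.9, fdr=0.1,
                overrides=(OverrideRule(st="INS", recall=0.2, fdr=0.1),),
            ),
            CallerProfile("beta", recall=0.7, fdr=0.1),
            CallerProfile(
                "gamma", recall=0.9, fdr=0.1,
                overrides=(OverrideRule(st="DEL", recall=0.2, fdr=0.1),),
            ),
        ]
        planted["best_pair_by_type"] = {
            "DEL": ("alpha", "beta"),
            "INS": ("beta", "gamma"),
        }
    elif scenario == "separable-reads":
        profiles = [
            CallerProfile(
                name, recall=0.8, fdr=0.2,
                tp_reads=("uniform", 10, 50), fp_reads=("uniform", 0, 2),
            )
            for name in ("alpha", "beta", "gamma")
        ]
        # any candidate is TP iff its summed reads reach 10: a single
        # detector contributes >= 10 for a true call, while even three
        # callers' false reads sum to at most 6
        planted["reads_threshold"] = 10
    else:  # jittered-repeats
        profiles = [
            CallerProfile(name, recall=0.85, fdr=0.1, jitter=10_000)
            for name in ("alpha", "beta", "gamma")
        ]
        planted["jitter"] = "region-length"

    callsets = {
        p.caller: simulate_callset(
            truth, p, annotation, seed=int(sub[3 + i]), chrom_lengths=lengths
        )
        for i, p in enumerate(profiles)
    }
    return Fixture(
        scenario=scenario,
        reference=reference,
        truth=truth,
        annotation=annotation,
        callsets=callsets,
        planted=planted,
    )
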