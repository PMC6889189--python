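"""Published reference performance figures used for arithmetic cross-checks.

These are the reported precision/recall/F percentages of five InDel callers
and the two integrators (BF-M, SVM-M) from the original full-scale soybean
simulation (2,792,000 planted 1–50 bp InDels), plus the annotation-category
tally of the 21,452 selected marker loci.  They serve as fixed inputs for
consistency checks of the scoring arithmetic — recomputing F from each
(precision, recall) pair, recomputing the Diff-vs-BF-M columns, and summing
the marker categories — not as outputs of this package.
"""

from __future__ import annotations

from .scoring import f_score

#: (tool, precision %, recall %, F-score %) per InDel stratum.  The BF-M row
#: is the Diff baseline of its block; the insertions block has no BF-M row.
REPORTED_PERFORMANCE: dict[str, list[tuple[str, float, float, float]]] = {
    "indels": [
        ("BF-M", 99.32, 65.20, 78.72),
        ("SVM-M", 95.75, 84.56, 89.81),
        ("GATK", 99.49, 25.50, 40.59),
        ("Pindel", 94.69, 41.36, 57.57),
        ("Samtools", 97.46, 65.71, 78.49),
        ("SOAPIndel", 97.25, 74.74, 84.52),
        ("Varscan", 98.59, 64.66, 78.10),
    ],
    "deletions": [
        ("BF-M", 99.21, 66.34, 79.51),
        ("SVM-M", 95.85, 84.84, 90.01),
        ("GATK", 99.40, 26.03, 41.26),
        ("Pindel", 89.89, 39.06, 54.45),
        ("Samtools", 97.78, 66.32, 79.03),
        ("SOAPIndel", 96.86, 75.43, 84.81),
        ("Varscan", 98.55, 65.17, 78.46),
    ],
    "insertions": [
        ("SVM-M", 95.66, 84.29, 89.62),
        ("GATK", 99.59, 24.96, 39.92),
        ("Pindel", 99.45, 43.66, 60.68),
        ("Samtools", 97.14, 65.09, 77.95),
        ("SOAPIndel", 97.64, 74.05, 84.23),
        ("Varscan", 98.64, 64.15, 77.74),
    ],
}

#: Annotation-category counts of the selected marker loci; reported total 21,452.
REPORTED_MARKER_CATEGORIES: dict[str, int] = {
    "intergenic": 12266,
    "promoter": 2379,
    "downstream": 1852,
    "UTR3": 540,
    "UTR5": 571,
    "exonic": 517,
    "intronic": 3309,
    "splicing": 18,
}

REPORTED_MARKER_TOTAL = 21452


def recomputed_f(block: str) -> list[tuple[str, float, float]]:
    """(tool, reported F, F recomputed from the reported P and R) per row."""
    return [
        (tool, f, f_score(p, r))
        for tool, p, r, f in REPORTED_PERFORMANCE[block]
    ]


def max_f_discrepancy() -> float:
    """Largest |reported F - recomputed F| over every reported row."""
    return max(
        abs(f_reported - f_calc)
        for block in REPORTED_PERFORMANCE
        for _, f_reported, f_calc in recomputed_f(block)
    )
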