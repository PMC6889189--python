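# Methods

## The problem and the two integrators

Given a reference genome, per-caller candidate InDel sets (VCF), a
repeat-region annotation (BED with class labels) and a truth set, the
package evaluates and integrates callers over the four attributes that
drive their error profiles: variation type (ST ∈ {INS, DEL}), variation
size (SS, 1–50 bp), repeat class of the containing region (RT ∈ {LINE,
LTR, TIR, Helitron, SimpleRepeat, LowComplexity, NonRepeat}) and detecting
software (DS). The grouping operator `G(F, S)` partitions a call set S by
attribute F and composes, e.g. `G(RT, G(SS, G(ST, S)))`.

**BF-M** learns, for every (ST, SS, RT) stratum on truth-labeled training
data, which pairwise caller intersection maximizes F = 2PR/(P+R), and at
apply time outputs the union over strata of the winning pair's
intersection restricted to that stratum. Only pairs are candidate rules;
exact F ties break to the lexicographically smallest pair so learning is
deterministic. Strata never seen in training are dropped at apply time
(conservative, precision-preserving) and counted in the log.

**SVM-M** featurizes every multi-caller candidate as: one 0/1 indicator
per caller (DS), type as 0/1 (DEL/INS), size in bp, a one-hot over the
seven repeat classes, and supporting reads (the single detector's count,
or the sum over detectors). A C-SVC with RBF kernel exp(−γ‖u−v‖²) is
trained on TP/FP labels obtained by matching candidates against truth;
(C, γ) come from stratified k-fold cross-validated grid search and the
best point is refit on the full training subset. Features are min-max
scaled to [0, 1] with parameters fitted on training data only (inside each
CV fold as well, so no validation leakage); the scaling is stored in the
model. Training is capped (default 100,000 candidates) by label-stratified
subsampling with largest-remainder apportionment.

Encodings for the five attributes are a design choice of this package:
indicator/one-hot for the categorical attributes keeps the RBF distance
meaningful, and the caller-set encoding (rather than a single "best
caller" code) is consistent with the summed-reads rule.

## Matching: when do two reports describe one event?

Coordinate deviation D = |P1 − P2|. Two calls are consistent iff same
chromosome, same type, same size, and D within tolerance. The tolerance is
0 between calls that both lie outside annotated repeats — after
left-normalization two representations of one event coincide exactly — and
the length of the containing repeat region otherwise (the larger region
when the two calls' regions differ). Region length, not repeat-unit
length, is used because in an ATATAT run any of the three placements of an
AT deletion must match, which requires tolerance up to the region span;
both the non-repeat tolerance and a fixed repeat tolerance are
configurable.

Every ingested call is left-normalized (shifted to the smallest position
with an identical haplotype) when a reference is available, and
`truth_to_calls` applies the same normalization, so both sides of any
comparison use one canonical representation.

Call-set intersection, union-merging and truth labeling all use one-to-one
matching. Left calls are processed in coordinate order, each trying its
consistent partners nearest-first; assignments may be displaced along
augmenting paths (Kuhn's algorithm), so the result is a maximum-cardinality
matching. Within one repeat region all same-type same-size calls are
mutually consistent and nearest-first assignment is already optimal; the
augmentation matters only in mixed repeat/non-repeat neighbourhoods, where
pure greedy can strand a partner. The procedure is deterministic: left
order, nearest-first partner order and smaller-position tie-breaks fix the
outcome. Labeling conserves counts (TP + FP = |calls|, TP + FN = |truth|),
and each truth variant matches at most one call.

## Scoring

precision = TP/(TP+FP), recall = TP/(TP+FN), F their harmonic mean, all
with 0/0 defined as 0 (an empty-success stratum scores 0 on all three).
Internals are fractions in [0, 1]; percentages appear only at the
reporting boundary, rounded half-up to 2 decimals. False negatives are
attributed to the stratum of the missed truth variant, so per-stratum
TP/FP/FN sum exactly to the overall record. Dispersion across strata is
the population standard deviation (the choice between population and
sample SD is not determined by the quantities being summarized; population
SD is used throughout).

## The variation simulator

`varsim` plants SNPs (Bernoulli per base at `snp_rate`, default 1/1000),
short InDels (fixed count, default 2,792,000, sizes 1–50 bp), large
insertions/deletions (default 20,000, 51–500 bp) and duplications,
inversions and translocations (default 1,000 each, 100–500 bp) — the
full-scale soybean design; desk-scale runs shrink the counts, not the
ratios. Placement is uniform over eligible positions: no N runs, no
footprint overlap, ≥1 bp gap, nothing at position 1 (room for a VCF
anchor). Insertions draw uniform-random alleles; duplications copy the
segment in tandem; inversions reverse-complement in place; a translocation
is a deletion at the source plus re-insertion at a sampled target,
recorded as a single truth record. Truth variants store anchor-free
alleles plus the sampled anchor base; VCF emission applies the anchor-base
convention (INS/DEL) or symbolic ALT + INFO END/SVTYPE (+CHR2/POS2 for
translocations) and round-trips exactly. The capacity pre-check uses
expected (not worst-case) footprints; genuinely infeasible plans fail at
placement with a capacity error.

## The synthetic caller generator

`synthdata` emulates the features of real caller output that matter to the
integrators, and only those: per-stratum recall and false-discovery rate
(defaults with first-match override rules), a supporting-read distribution
per label class (negative binomial with shape 4 — over-dispersed like real
depth — or uniform bounds for exactly separable scenarios), and uniform
coordinate jitter inside repeat regions capped at the region length, so a
jittered call always stays consistent with its source truth under the
default criterion. False positives are added per stratum at
round(TP·fdr/(1−fdr)) and hosted in truth-free regions of the stratum's
repeat class (or at unoccupied non-repeat positions), which keeps the
realized FDR close to the profile. What it does **not** emulate: read-level
error processes, alignment artefacts, caller-specific biases correlated
across tools, genotype errors. Passing tests therefore demonstrate the
correctness and discriminative behaviour of the integration machinery
under controlled error structure, not performance on real sequencing data.

Named scenarios plant known structure: `dominant-pair` (one pair best
everywhere: alpha 90%/10%, beta 85%/12%, gamma 25%/30% recall/FDR),
`group-dependent-best` (a deletion specialist, a generalist and an
insertion specialist, so deletions and insertions have different best
pairs), `separable-reads` (TP reads uniform 10–50 per caller, FP reads
0–2, so even three callers' false reads sum below one true detector's
minimum — candidates are exactly separable on summed reads; this scenario
uses an empty repeat annotation so the labels carry no position-ambiguity
noise and follow the planted rule exactly), and `jittered-repeats`
(jitter bound far above every region length, i.e. effectively
region-length jitter). Rule-learning scenarios restrict sizes to 1–2 bp
and three repeat classes so each of the ~16 strata holds enough calls
(roughly a hundred or more) for the per-stratum argmax to be deterministic at the planted
separation; read-separability scenarios use sizes 1–10 bp.

## Problem sizes and numerical choices

The test suite and the acceptance script run the scenarios at 600–5,000
planted InDels on 0.3–1.5 Mb two-chromosome genomes: large enough that
binomial noise sits well inside the 3σ bands the checks assert (e.g.
profile recovery at 5,000 truths has σ ≈ 0.006 per axis), small enough
that rule learning takes under a second and a full default grid search
(C ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³, powers-of-four steps, 5 folds) takes seconds.
All randomness flows from explicit seeds through `numpy.random.default_rng`;
fixtures, simulators and training are bit-reproducible, and grid search
uses a seeded stratified k-fold (folds reduced automatically when a class
has fewer members than folds).

Supporting-read extraction from caller VCFs is dialect-driven (per-caller
ordered field lists over FORMAT/INFO: alt allele depth where available,
else site depth, else 0) because callers do not agree on which field
carries the evidence count; the table is user-extensible. Repeat
annotation lookups resolve nested intervals to the smallest containing
interval (most specific class), with lexicographic tie-breaks on equal
spans.

## Known limitations

- The consistency criterion is positional (type, size, deviation); it is
  not a haplotype-aware comparison and will not reconcile complex
  representations that normalization cannot align.
- BF-M considers only caller pairs (not triples or singletons) as rules,
  and drops strata unseen in training.
- The full-scale published comparison figures are used only for arithmetic
  consistency checks; reproducing them would require the original
  reference genome, read simulation, alignment and the five external
  callers, all outside this package's scope.
- Synthetic false positives are sampled independently per caller;
  correlated FP structure between tools (shared alignment artefacts) is
  not modeled, which flatters intersection precision relative to real
  data.
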