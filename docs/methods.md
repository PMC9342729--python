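# Methods

This note documents the models, algorithms and numerical choices behind
`plastocomp`, what the synthetic-data generator does and does not
emulate, and the limitations a user should know about.

## Coordinate model

All internal coordinates are 0-based, half-open; GenBank input/output
converts to and from the 1-based inclusive convention at the boundary,
and reports (inversion calls, repeat tables) print 1-based inclusive
coordinates. Circular genomes are stored linearized at the deposited
origin; origin-spanning features are handled by modular slicing rather
than sequence rotation, so coordinates stay comparable with the deposited
record. Ambiguity codes beyond N are mapped to N on ingest (with a
warning) because all downstream counters assume a closed five-letter
alphabet; N columns are excluded from GC, codon, repeat and distance
computations.

## Quadripartite detection

The IR pair is defined as the longest pair of disjoint, exactly
matching, inextensible inverted segments. Matching is exact by design:
plastome IR copies are homogenized by copy-correction, and the problem of
finding *near*-identical IRs (with substitutions between the copies) is
deliberately out of scope. Detection seeds 32-mer matches between the
genome and its reverse complement and extends them along their diagonal,
deduplicating seeds per diagonal, so the cost is one extension per
distinct match run. The longer of the two single-copy intervals between
the IR copies is named LSC (a naming convention, not an inference), IRb
is the copy clockwise of the LSC, and the four junctions JLB/JSB/JSA/JLA
are the positions between the last base of one region and the first base
of the next — this pins down every junction-distance and split-length
number to an unambiguous convention. Sequences with no inverted pair of
at least `min_ir_len` (default 1,000 bp; plastome IRs are kb-scale, and
the threshold keeps chance palindromes out) raise a "no quadripartite
structure" error rather than returning a degenerate partition.

## Genome summary statistics

GC content is 100·(G+C)/(A+C+G+T) to 2 decimals (half-up), N excluded
from numerator and denominator. Because the IRs duplicate genes, gene
counting supports two policies: `unique` (default) counts each gene name
once regardless of IR duplication and also emits a per-name multiplicity
column; `all_copies` counts every annotated copy. Published plastome
gene inventories typically de-duplicate, but the reader can always
reconstruct either number, which makes the ambiguity harmless. Codon
usage (genetic code 11) defaults to counting every annotated CDS copy and
is switchable to unique; CDS lengths not divisible by three lose their
trailing partial codon with a log entry, and internal stop codons are
counted as stops and logged, never fatal — annotation noise should not
abort a survey. Splicing classification calls a multi-exon gene *cis*
when its transcript-ordered exons run monotonically along the genome on
one strand, and *trans* otherwise (mixed strands or out-of-order exons,
the plastid rps12 geometry); intron count is parts − 1.

## Repeat surveys

**Microsatellites.** A hit is a maximal run of a primitive 1–6 bp motif
meeting the per-unit-size minimum repeat counts (defaults
1→10, 2→6, 3→5, 4→5, 5→5, 6→5). Runs are maximal in the periodicity
sense (the position before the run does not continue the period; partial
trailing copies are not counted), motifs must be primitive (not
themselves a repetition), and a shorter-unit call whose interval lies
inside a longer-unit call is suppressed. The canonical class label is
the lexicographically smallest rotation of the motif and of its reverse
complement, joined smallest-first (A/T, AT/AT, AGG/CCT …). Compound or
interrupted-repeat merging is off: each run is reported separately.

**Tandem repeats.** The tandem detector is an intentionally simplified
stand-in for the classic stochastic-model finders, whose scoring
internals are not reproducible from their parameter strings. For every
candidate period d (1 … 500) the sequence is compared with itself
shifted by d; long match runs seed tracts which are extended across
isolated mismatch columns (a neighbouring run is absorbed only if it is
at least max(3, 2·gap) long and overall mismatch density stays ≤ 20 %),
snapped to whole copies, and scored against the majority-rule consensus
at +2 per match, −7 per mismatch (minimum score 50). Copies are compared
to the consensus positionally — no intra-copy indels — and reported
identity is the mean pairwise identity among full copies. The default
report keeps tracts with unit ≥ 30 bp and identity ≥ 90 %. Consequences:
tandems whose copies differ by indels are fragmented or missed, and tract
boundaries can shift by a few bases when flanking background happens to
continue the period; counts from this detector are therefore not
comparable with other tools' counts.

**Dispersed repeats.** The target quantity is every maximal repeated
pair (forward or palindromic orientation) of length ≥ `min_len` (30)
with ≤ `max_hamming` (3) mismatches. A *maximal window* is a paired span
that cannot be extended at either end without exceeding the budget or
leaving the sequence; the reported hit is the window's match-trimmed
core (terminal mismatch columns removed), deduplicated. Trimming is
essential for interpretable output: without it, a planted repeat in
random background is reported as h+1 overlapping windows, each padded
with chance-matched columns that soak up unused mismatch budget.
Detection is exact, not heuristic: any qualifying hit contains an exact
match of length ≥ ceil((min_len − h)/(h + 1)) = 7, which is the seed
size, so seeding cannot miss a hit; seeds are extended on their
(anti)diagonal with local mismatch scans, and per-diagonal exact-run
bookkeeping keeps long repeats from being re-extended thousands of
times. By default the scan masks IRb, because the IR pair itself is a
~38 kb palindromic repeat that would otherwise dominate every survey;
hits with a copy entirely inside the mask are suppressed, and the IRa
twin of any real IRb-internal repeat still reports.

## Synteny and inversion calling

Whole-genome comparison is anchor-based: 21-mers (k configurable, ≥ 15)
that are unique in both genomes — counting a k-mer and its reverse
complement as one class — become anchors with a same/inverted
orientation. Reference IRs are masked during anchoring because they are
near-identical across related plastomes and would make anchors ambiguous.
Anchors sorted by reference position are chained greedily into
orientation-consistent collinear blocks (query coordinate must move in
the direction the orientation dictates; neither genome may jump more
than `max_gap`, default 5 kb); blocks under `min_block` (1 kb) are
discarded, and an inverted block whose surviving neighbours are
same-orientation is called an inversion. Anchor resolution leaves the
endpoints uncertain by roughly the flanking-repeat length plus k, since
repeated sequence near breakpoints cannot anchor, so calls are *snapped*:
the windows (default ±500 bp) around both endpoints are searched for the
longest maximal palindromic pair with one copy near each endpoint, and
the endpoints move to the repeat copies' inner edges. After snapping the
5' copy ends exactly where the inversion starts and the 3' copy starts
exactly where it ends — the contiguous coordinate signature expected of
a repeat-mediated inversion, and the property the closed-loop tests
assert exactly. When no qualifying pair exists the call is left
unsnapped with its anchor-resolution endpoints. Homology of a repeat
unit in another genome is assessed by best local alignment on both
strands (match +1, mismatch −2, gap open −5, extend −2, score
threshold 20) via Biopython's PairwiseAligner.

## Hypervariable spacer scan

Spacers are gaps between genomically adjacent gene features, walked in
circular order (trans-spliced genes contribute their contiguous exon
blocks separately, so a distant exon does not swallow the loci between).
Filters, in order: zero-length gaps; loci spanning any of the four
junctions; loci intersecting a caller-supplied exclusion set (use this
for a known rearrangement: distances across an inversion would mix
orientation artefacts into the divergence signal); IR-duplicate loci
(IRb copy dropped, IRa twin kept). Locus names concatenate the flanking
gene labels with anticodon suffixes intact (e.g. `trnL-UAG-ccsA`).

Each locus is aligned across genomes: two sequences get an optimal
global affine-gap alignment (match +1, mismatch −1, open 10, extend 2 —
the classic clustalw-style DNA penalties on a unit match scale) via
Biopython; more sequences are aligned progressively along an
average-linkage guide tree built from 4-mer count distances, with
profile–profile Gotoh dynamic programming (expected match/mismatch score
between column base-frequency profiles; gap fractions score zero). The
DP keeps two score rows and full int8 traceback pointers, so memory is
O(L) floats plus 3·L² bytes, which keeps multi-kb spacers affordable.
Input residues are never altered — columns only gain gaps — and that
invariant is tested.

Pairwise distances use the Kimura two-parameter model with pairwise
deletion (columns with a gap or N in either row are excluded per pair):
P and Q are the transition and transversion proportions over the
compared sites and d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q), reported per
100 sites to match the scale of classic `distmat` output. When a log
argument is ≤ 0 the pair is flagged saturated instead of producing a
number. Per-locus summaries report both the maximum and the mean
pairwise distance; ranking uses the maximum by default (a published
single-value-per-region figure is usually the extreme pair; reporting
both makes the choice transparent), and the report keeps the top 5 loci
at or above a threshold of 5 per 100 sites, both configurable.

## Diagnostic marker sites

A site is an alignment column whose residue pattern separates at least
one taxon pair after collapsing individuals to taxa; columns where
individuals of one taxon disagree are skipped with a log entry, because
a diagnostic marker must be fixed within taxon, not probabilistic. Gap
columns are indel sites, treated as a fifth character state per column;
adjacent-gap merging is available but off by default (column-wise is the
conservative, testable choice when no merging rule is given). The
minimal discriminating set is computed greedily (largest uncovered gain
first) and, whenever the site list has ≤ 20 entries, verified against
exhaustive search over all smaller subsets; pairs no site separates are
reported as uncovered and `fully_discriminating` is false.

## Synthetic data: what it emulates, and what it does not

The generator builds LSC + IRb + SSC + IRa with IRa the exact reverse
complement of IRb, i.i.d. background at a configurable GC fraction
(default 0.38, typical of plastomes), an auto-scaled gene set (CDS with
real start/stop structure and no internal stops, tRNA names with
anticodon suffixes, IR-duplicated rRNA/tRNA genes, cis multi-exon genes
on both strands, one trans-spliced three-exon gene), and planted repeats.
Defaults follow the scale of a real ~170 kb plastome: LSC 86 kb, SSC
8 kb, IR 38 kb, 30 microsatellites (19 mono-, 8 di-, 3 trinucleotide),
two tandem arrays, two dispersed pairs, and optionally a 20 kb LSC
inversion flanked by a 164 bp palindromic pair. Tests use a `scaled()`
variant (LSC 12 kb, SSC 3 kb, IR 4 kb) with the same structure; the
acceptance script runs the full-scale study.

Two constructions make closed-loop testing exact rather than
statistical. First, chance microsatellites are removed by rejection:
gene sequences are drawn SSR-free, and background that happens to
contain a qualifying run is locally resampled until the SSR scan reports
exactly the planted set (the IRa mirror is kept in sync). Second,
planted repeat pairs and IR boundaries are *sealed*: the h+1 alignment
columns immediately outside each planted copy are forced to mismatch
(and the base adjacent to each junction is forced not to extend the IR),
so every maximal window trims back to exactly the planted coordinates.
Planted mismatches inside a pair are spread so that no mismatch-free
fragment reaches reporting length on its own. Without sealing, chance
matches just outside a planted repeat would make recovered lengths
overshoot by a few bases — real genomes behave like the unsealed case,
which is why detector *correctness* is established separately against
brute-force oracles on unsealed random sequence.

Divergence follows a K80 (two-parameter) substitution process on a star
topology: each derived genome sits one branch (default 0.015
substitutions/site, κ = α/β = 2) from the ancestor, per-site outcomes
are drawn from the exact K80 transition probabilities (multiple hits
included), and per-locus rate multipliers emulate hypervariable spacers
(the full-study default plants five loci at 10.0, 4.6, 2.9, 2.0 and 1.8
times background, giving expected maximum pairwise distances of about
30, 14, 9, 6 and 5.4 per 100 sites — distinctly above a ~3 background).
Indels (length 1–4, rate 5×10⁻⁴/site) fall only in intergenic
single-copy sequence so annotations lift exactly; the IR copies receive
identical substitutions (IRb is mutated, IRa rebuilt as its reverse
complement), emulating plastome copy-correction — without this, derived
genomes would lose their detectable quadripartite structure, which real
plastomes do not. Expected distances are recorded as truth alongside
realized transition/transversion counts, supporting both statistical and
exact assertions.

What the generator does **not** emulate: real base composition structure
(codon bias, strand asymmetry, GC gradients), selection (all sites drawn
i.i.d. and mutated independently), IR boundary expansion/contraction
between genomes, tRNA/rRNA secondary structure, annotation errors, or
sequencing artefacts. Passing closed-loop tests therefore demonstrates
that the detectors recover what they define, at realistic scales and
divergences — not that they are robust to every artefact of real
GenBank records.

## Problem sizes used in validation

The test suite runs closed-loop recovery on 20 seeded replicates each
for IR boundaries/SSRs/dispersed repeats and for inversion endpoints and
flank lengths at the 23 kb test scale; oracle equivalence on 100 seeded
sequences (SSR at 400 bp, dispersed at 300–700 bp against a full
diagonal scanner, with the scanner itself validated against a
definitional micro-oracle on ~70 bp strings); K2p recovery at true
distances 5, 10 and 20 per 100 sites over 50 loci × 500 bp (mean within
3 standard errors); hypervariable ranking on 100 seeded replicates of a
13 kb four-genome study with one 10× locus (≥ 95 must rank it first);
and marker minimal sets against the exhaustive optimum on 100 seeded
site tables. The acceptance script runs the 170 kb study once per seed.

## Known limitations

* IR detection requires exact copy identity; genomes whose IRs have
  diverged between copies will under-segment.
* The quadripartite detector works on the linearized deposited sequence;
  an IR pair straddling the deposited origin would be missed.
* The tandem detector is indel-free and not comparable with
  stochastic-model tools (by design; see above).
* The progressive aligner has no iterative refinement; column homology
  degrades at high divergence, where K2p saturation flags appear first.
* Inversion calling assumes a single co-linear backbone; nested or
  overlapping rearrangements are out of scope, as are translocations and
  duplications.
* Greedy chaining (not full longest-chain DP) is used for synteny
  blocks; with the unique-anchor construction and `min_block` filter the
  difference only matters for genomes far more rearranged than the
  single-inversion case this package targets.
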