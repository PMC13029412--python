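# Methods

This note documents the models, conventions and numerical choices behind
fam111kit, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Curation

Keyword filtering drops a record when its lower-cased description contains
any exclusion keyword as a substring (default set: *synthetic,
hypothetical, partial, low quality, predicted*); the organism field is not
searched. Dereplication is greedy within each taxonomic class: records are
visited longest-first (ties by id) and join the first cluster whose founder
they match above the identity threshold (default 0.97), so the longest
isoform represents each cluster and clustering never crosses class
boundaries. Sequence identity is defined on the optimal global alignment as
identical residue pairs divided by aligned residue pairs, excluding gap
columns — a denominator that is robust when lengths differ. Composition
percentages are rounded to integers.

## Alignment

Pairwise alignment is global affine-gap alignment under BLOSUM62 with gap
open −11 and extend −1, where "open" is the score of the first gap position
and terminal gaps are penalized like internal ones. The implementation
delegates to Biopython's `PairwiseAligner`; the test suite checks its
optima against an exhaustive enumeration oracle on short sequences.
Determinism comes from taking the aligner's first reported optimal
alignment.

The multiple alignment is one progressive pass, deliberately without
iterative refinement: a UPGMA guide tree is built from (1 − identity)
distances, and at each internal node the two child profiles are aligned by
dynamic programming. The column-pair score is the arithmetic mean of all
residue-pair substitution scores between the two columns, with a gap
scoring 0 against anything; gap penalties in profile space reuse the
−11/−1 affine parameters. The DP is vectorized row-wise (the
horizontal-gap state is a running maximum, computed by prefix-max), with
traceback tie-breaking preferring match, then gap-in-second-profile, then
gap-in-first — making the output deterministic. Row order follows the
guide-tree leaf order, and de-gapping any row reproduces the input sequence
byte-for-byte.

## Conservation scoring and motif calling

Each column is scored on the 0–11 scale classical for alignment
annotation: 11 when all non-gap residues are identical, otherwise the
number of ten binary physicochemical properties (hydrophobic, polar, small,
proline, tiny, aliphatic, aromatic, positive, negative, charged — the
canonical conservation-analysis assignments, replaceable via
`PropertyTable`) that are uniformly present or uniformly absent across the
column's residues. Columns with more than 10% gaps score 0, consistent with
the 90% frequency rule below; modal frequencies are computed over all rows,
gaps included in the denominator, so a "90%-conserved" position must be
present in 90% of sequences.

Motif anchors come in two kinds. A *literal* anchor needs score ≥ 10 and
modal frequency ≥ 90% — the published selection rule. A *pair* anchor
(rendered `[A/B]`) needs the top two residues to jointly cover ≥ 90% of the
column and to share at least `pair_min_score` of the ten properties. The
default is 8, not 10: requiring perfect property agreement would leave only
three residue pairs ({I,L}, {W,Y}, {A,G}) eligible and would reject the
two-way alternatives that actually occur in the FAM111A motifs (L/V share
9 properties; A/T, L/F, F/L share 8). At 8, every pair in the seven
reference motifs qualifies except G/E (4 shared properties), which no
property-based rule can admit. All thresholds are configurable.

Motifs are maximal anchor runs: anchors separated by at most 3 wildcard
columns chain together; a chain is emitted when it has ≥ 3 anchors and a
length of 5–12 columns, and longer chains are split greedily at anchor
boundaries. These shape limits are reverse-engineered from the seven
reference patterns (one has three consecutive wildcards; the shortest has
length 5) and are exposed as `MotifShape`. Pattern scanning reports every
window whose violations (wildcards never violate) do not exceed the
mismatch budget, sorted by (mismatches, start). The default scanning budget
in the pipeline is 1 mismatch, because the published motif placements on
the human sequence are not all exact (the motif-3 instance starts on Ile380
where the pattern wants L/V).

## Phylogeny

UPGMA in its classic arithmetic-mean form: merge the closest pair, place
the merged node at half the merge distance, and average distances to other
clusters weighted by cluster size. Ties in merge order are broken on the
lexicographically smallest pair of cluster minimum-member labels, and
children are stored in canonical order (smallest descendant label first),
so the tree and its Newick serialization are independent of input order.
Trees are ultrametric by construction; branch lengths are derived as height
differences. Monophyly reports find, per class, the smallest clade
containing all of the class's leaves and check it contains no other
class's leaf. No bootstrap support is computed.

## Variant annotation

Coordinates are 1-based closed intervals throughout, matching protein-level
variant notation. The variant grammar covers missense, deletion (`del`),
frameshift (`fs`), synonymous (`K586K`), bare positions (`D439`, kept as
position-only rather than rejected), and multi-allelic forms
(`S541[Y/P]`, `V357[I/fs]`) which expand to one record per alternative. The
domain map ships PIP 16–28, UBL2/DBD 176–282 and SPD 332–600 plus point
annotations (catalytic triad, oxyanion hole, cleavage site, S1 pocket);
UBL1/UBL2 boundaries are never published precisely and are left to the
caller. Annotation computes containing domains, containing motif calls, an
S1-pocket flag and the distance to the nearest triad residue, and reports
discordances between computed domains and the table's printed region
labels informationally — e.g. the table assigns F231A to "PIP" although
position 231 lies outside 16–28; the table is never silently corrected.

Mutation blocks default to labels mode (one block per printed block label),
which reproduces the two known blocks. Density mode (windows of width 60
holding ≥ 5 variant sites, overlapping windows merged) is exploratory: a
plain positional clustering cannot reproduce the printed block boundaries,
because the largest within-block position gap exceeds the between-block
gap.

## The bundled reference sequence

Live database access is out of scope, so the package bundles a *synthetic
surrogate* of human FAM111A (so labeled in its filename and FASTA header),
constructed by `scripts/make_reference_fixture.py`: a 611-residue sequence
carrying every published residue annotation at its published coordinate —
all 34 variant reference residues, the catalytic triad H385/D439/S541, the
oxyanion hole G539/S541, the cleavage site F334/G335, the 14 S1-pocket
residues, a PIP-box-shaped segment at 16–28, and plausible instances of the
seven motifs at placements consistent with the variant table's motif
labels — with seeded-random residues elsewhere. Verification and annotation
behave on it exactly as they would on the real record at the annotated
positions; any analysis sensitive to the unannotated filler (e.g. scanning
for novel motifs) reflects the surrogate, not human FAM111A.

## The synthetic-family generator

`FamilySpec` defaults describe the study conditions for all recovery tests:
40 taxa in four classes (21/11/7/1, i.e. 52/28/18/2% — mammal, fish,
reptile, cnidarian proportions typical of such datasets), an ultrametric
tree of height 1 with one subtree per class (class monophyly holds by
construction; a `scramble_classes` mode provides the negative control),
root length 360, and the seven reference motifs planted in a conserved core
spanning the middle ~55% of the sequence.

Substitutions follow a uniform replacement model (no empirical matrix —
sufficient for threshold-based recovery tests and simpler to reason about)
at 1.5 expected substitutions per site per unit height. That rate is chosen
so the variable regions are genuinely variable under the anchor rule: at
substantially lower rates most leaves retain the root residue and free
columns frequently classify as anchors, contradicting the planted truth
labels; at 1.5 the planted anchors are exactly the anchor-classified
columns. Planted literal columns never substitute freely — at most 10% of
taxa may deviate, and only within the residue's physicochemical equivalence
class (G↔A, I↔L, W↔Y), so the column keeps score ≥ 10 at ≥ 90% modal
frequency. Planted pair columns alternate only between their two residues.
Pattern pairs whose residues share fewer than 8 properties (G/E) are
planted as their first residue, since "alternating between incompatible
residues" would contradict the conservation the motif is supposed to
exhibit.

Indels occur only outside motif columns (rate 0.02 events per site per unit
height, geometric lengths with mean 3), and long indels (20–60 residues,
8% of events) are confined outside the conserved core — mirroring a family
whose long alignment gaps sit in the terminal regions. The truth object
carries the generating tree, the true alignment (maintained exactly through
indel bookkeeping: de-gapping row *i* always equals sequence *i*), and
per-taxon motif spans.

What passing recovery tests show: that the pipeline recovers planted,
threshold-satisfying motifs from clade-structured families with indel-free
conserved cores. What they do not show: performance on real families with
empirical substitution processes, rate heterogeneity across sites and
lineages, motif gain/loss, or alignment-ambiguous cores.

## Problem sizes and numerics

Recovery statistics use the 40-taxon default family across ten seeds
(17–26); pairwise-alignment optimality is enumerated exhaustively for
sequences up to length 8; UPGMA is cross-checked against an independent
average-linkage implementation on random matrices and verified ultrametric
to 1e-9. Profile-DP traceback uses a relative tolerance of 1e-6 when
re-deriving the predecessor state from stored layer values. Degenerate
inputs are defined throughout: empty FASTA files parse to empty lists,
empty variant tables to empty record lists, all-gap columns score 0 and are
flagged, and an empty motif list is a valid calling result.

## Known limitations

- The published 1858 → 85 sequence reduction is database-version-dependent
  and is not reproduced; curation is tested on synthetic families and small
  fixtures instead.
- The progressive MSA is a single pass without refinement and does not aim
  to match any external aligner's output byte-for-byte.
- Density-mode block detection with default parameters need not reproduce
  label-mode blocks (see above); its output is reported, not asserted.
- The conservation model is property-based only; no entropy, rate or
  position-specific scoring-matrix methods are provided.
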