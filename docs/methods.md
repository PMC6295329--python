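# Methods

## Scope and data model

`mitocr` characterizes the *structure* of mitochondrial genomes: gene-order
rearrangement class, control-region (CR) domain architecture, repeated
sequence content, and simple composition/divergence statistics. It does not
annotate genes de novo (annotations are authoritative input, read from
GenBank flat files), build alignments, fold RNA secondary structure, or
infer trees.

Coordinates are 0-based half-open on the linearized heavy strand
everywhere inside the package; GenBank input (1-based inclusive) and GFF3
output (1-based inclusive) are converted at the boundary. A feature that
spans the circular origin is kept as one interval whose end exceeds the
genome length and is read modulo the length; rotation
(`MitoGenome.rotated`) re-normalizes such intervals. This single-interval
convention was chosen over splitting wrapped features into two parts
because it sorts, rotates and round-trips without special cases.

Gene names are normalized into a controlled vocabulary (13 protein genes,
`rrnS`/`rrnL`, 22 tRNAs with tRNA-Leu/tRNA-Ser disambiguated by codon
class, `OL`, `CR`) by case- and punctuation-insensitive alias lookup. The
alias table ships as `vocabulary.tsv` and can be extended per call; a bare
`tRNA-Leu`/`tRNA-Ser` without codon-class evidence maps to `unknown`
rather than being guessed.

## Gene-order classification

The canonical (Type I) template is the standard vertebrate order of 39
tokens (37 genes + O_L + CR) beginning at tRNA-Phe, with nine genes on the
light strand (tRNA-Gln, -Ala, -Asn, -Cys, -Tyr, tRNA-Ser(UCN), *ND6*,
tRNA-Glu, tRNA-Pro). Each rearrangement type is an event signature
against this template:

| type | event |
|------|-------|
| I    | none (circularly equal to the template) |
| II   | one extra tRNA-Gln and one extra *ND4*, each removable in place |
| III  | >1 O_L token, all between tRNA-Asn and tRNA-Cys |
| IV   | same content, tRNA-Glu immediately 5′ of tRNA-Pro |
| V    | tRNA-Glu absent, everything else canonical |
| VI   | one contiguous duplicated block intersecting the *ND4*…tRNA-Ile span |

Every signature test is evaluated on the circular order (rotation cannot
change the call), and each requires the *rest* of the order to match the
template exactly, so compound rearrangements fall through to `novel` with
the raw content difference instead of being silently matched — the types
are treated as single event classes. Where the published record is
internally inconsistent about which species carries the translocation
versus the deletion of tRNA-Glu, the classifier encodes the events
(translocation = IV, deletion = V) and leaves species assignment to input
data. The exact extent of the Type VI duplicated block is ambiguous in the
literature; any contiguous duplicated block whose span intersects
[*ND4* … tRNA-Ile] is accepted and the observed endpoints are recorded.
Pseudogenized duplicate copies count as copies whenever they are annotated
with a vocabulary label, because the typing is order/content-based.

GeneOrder canonicalization picks, among rotations starting at tRNA-Phe,
the lexicographically smallest — deterministic even when a duplication has
produced two tRNA-Phe copies.

## Control-region partition

The CR is the heavy-strand span strictly between end(tRNA-Pro) and
start(tRNA-Phe), wrap-aware. Motifs are found by an IUPAC-aware Hamming
scan: a window position matches when the sequence base lies in the pattern
code's set; `N` in the sequence never matches and must spend mismatch
budget. Default budgets are TAS 0, CSB-F 3, CSB-1 3, CSB-2 2, CSB-3 2 —
looser for CSB-1 because it is the most variable of the three CSB blocks —
and all are configurable. Ties among equal-mismatch hits go to the
leftmost hit.

The published partition rule for the three domains is not recoverable, so
the package states its own and treats the exact tiling as the invariant
instead of reproducing published boundary positions: ETAS = [0, e) with e
the 3′ end of the last TAS-bearing tandem array (fallbacks: last TAS hit in
the 5′ half, then a configurable default fraction of the CR, 1/3); CSB =
[c, CR length) with c the start of the best CSB-1 hit (fewest mismatches,
then leftmost; CSB-2 as fallback); CCR the remainder. A partition with an
empty domain or e ≥ c is a hard error, never silently adjusted. Per-domain
A+T% is reported alongside.

## Tandem-repeat detection

The detector is a seed-and-extend scheme (the published analyses used a
standard tandem-repeat finder with default parameters; only unit length
and copy number feed the downstream interpretation, and those two
statistics are robust to the detector):

1. **Seeding.** Exact k-mer (k = 8) recurrences give candidate (position,
   period) pairs for periods in [min_unit, max_unit].
2. **Extension.** From each seed, copies are stepped in both directions;
   each neighbouring copy is re-located by infix (edlib HW) alignment of
   the current copy within a ± period/8 window, so indel drift and an
   imprecise seeded period self-correct. A step must reach identity
   ≥ `min_identity` (default 0.7), where identity = 1 − edit distance /
   max(length) — edit distance, not Hamming, because real VNTR copies
   differ in length.
3. **Refinement.** The positional match profile M[x] = (s[x] == s[x+p]) is
   dense (≈ 1 − 2·divergence) inside an array and at the random
   base-coincidence level outside, independent of phase. When the profile
   near the candidate shows a single dense run, its extent fixes the array
   start and the copy count exactly; a split profile marks an indel and the
   alignment-stepping estimate stands. After refinement, flanking copies
   that an indel pushed outside the run are re-attached by re-stepping with
   a threshold midway between the detection floor and the core copies'
   identity — genuine copies clear it, absorbed flank sequence does not.
4. **Filtering and merging.** A candidate any of whose copies is internally
   periodic (positional identity at a smaller shift ≥ `min_identity`) is a
   multiple of that period and is dropped — the smaller period is seeded
   independently. Overlapping survivors are merged, ranked by the identity
   each adjacency carries above a random-DNA baseline (`min_identity` −
   0.1) times the unit length; this keeps a rival that absorbs flank
   sequence or sits at a shifted phase from outranking the clean array on
   sheer length. Remaining ties go to the smaller unit, then leftmost.

Unit decomposition cuts a long unit into consecutive base-length sub-units
plus a remainder (concatenation always reconstructs the unit exactly);
sub-units whose best identity to their siblings or a reference falls below
0.65 — clearly of the family but diverged — are flagged "box-like".
Microsatellite runs are maximal perfect repeats (default motifs TA and CA,
minimum 4 copies). The stem scanner reports every (arm, loop) placement
whose arms reverse-complement-match at ≥ 0.8, a deliberate substitute for
free-energy folding: it asks only whether hairpin-capable inverted repeats
exist, not which structure is thermodynamically optimal.

The identity metric behind published "similarity" percentages for the box
family is not defined in the record (alignment method and gap treatment
unknown); the package reports its edit-distance identity and does not
claim to reproduce those exact percentages.

## Composition and distances

Skews are computed on the heavy strand as given: AT-skew = (A−T)/(A+T),
GC-skew = (G−C)/(G+C); ambiguity codes count toward length but are
excluded from skews, and a skew with a zero denominator is undefined
rather than zero. Reverse-complementing a sequence negates both skews
exactly (property-tested). Cohort tables report mean, sample SD (n−1) and
SE = SD/√n; whether a published "±" is SD or SE is often unstated, so both
are exposed — across the five-genome cohort the printed ±0.61 matches the
SE (SD is 1.36), which is why SE is the default display.

p-distance is mismatches over comparable sites; sites with a gap or N in
either row (pairwise deletion, default) or in any row (complete deletion)
are excluded, and a pair with zero comparable sites is undefined (NaN).
Group summaries average the unordered within-group pairs; the SE is a
seeded site bootstrap (default 500 replicates) because the published ±SE
method is unstated. Singleton groups are reported as undefined, matching
the convention of dashing out single-member groups.

## Synthetic data

The generator is the package's study-condition definition, not a tuning
dial. Defaults: a 16,800 bp circular genome (a *target minimum* — spacer
pads up to it, and duplication-carrying arrangements come out longer, as
real ones do) on the Type I layout; realistic gene spans (*ND5* longest at
1,700 bp, *ATPase8* shortest at 165 bp; tRNAs 60–72 bp); base composition
(A, T, G, C) = (0.305, 0.218, 0.155, 0.322), near the genus average, drawn
by exact-count shuffling so realized composition tracks the target within
a percentage point. The CR recipe mirrors a peguensis-like 1,653 bp CR:
a 75-bp unit × 6 copies at 5% per-copy substitution divergence (TAS
protected), with a 0.1 per-copy chance of one 1–3 bp indel so the
edit-distance identity metric is exercised; 496 bp ETAS (array + pad);
312 bp CCR with one CSB-F instantiation centred; 845 bp CSB segment with
CSB-1 at the domain start (so the partition anchor is exact), then (TA)₆,
CSB-2, CSB-3, (CA)₇ at evenly spaced offsets, G-breaks preventing
microsatellite runs from extending into filler. Degenerate motif
instantiations are seeded draws from each code's set. Everything planted
is recorded in a TruthRecord that matches the emitted annotation exactly,
and identical spec + seed gives byte-identical GenBank output.

What the generator does **not** emulate: codon structure, transcription
signals, realistic tRNA secondary structure, phylogenetically correlated
divergence, heteroplasmy, and sequencing error. Passing tests therefore
demonstrate that the algorithms invert the generative model they specify —
rearrangement events, planted arrays, motif placements — not that real
annotations are error-free.

## Numerical and testing choices

Problem sizes in the test and acceptance suites (200 planted arrays with
units 25/75/225 bp and 2–8 copies; 100 classifier instances per type; 1000
scanner oracle cases; 300-site alignments) were chosen as the smallest
sizes at which the binomial noise of the measured rates is well inside the
asserted margins. Oracles are independent by construction: exhaustive
IUPAC expansion for the scanner, quadratic Levenshtein DP for identity,
positional recount for p-distance, direct base-pairing enumeration for
stems.

Known limitations: copy-number recovery degrades near the 10% per-copy
divergence boundary for short (25 bp) units, where a single adjacency can
drop below the 0.7 identity floor by chance; two-copy arrays occasionally
yield no exact 8-mer seed at high divergence and are missed entirely (the
≥95% recovery margin budgets for both); and the CR partition reproduces
published domain *sums*, not published boundary positions, since the
boundary rule is the package's own.
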