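# Methods

This note documents the conventions, parameters and design choices behind
`srnalocus`, and what the synthetic-data tests do and do not demonstrate.

## Coordinate frame and attribution conventions

All public coordinates are 1-based inclusive on the single reference locus.
One convention drives every layer: an siRNA is located by its **5′ end** —
`start` for a sense alignment, `end` (the rightmost matched base) for an
antisense alignment. Position tracks, feature confinement, phase registration
and occupancy all use this rule; using a single convention everywhere removes
an entire class of off-by-one disagreements between layers, and it is the
convention under which phased trains (defined by Dicer's 21-nt processivity
from a fixed cut) are arithmetic progressions of 5′ ends.

Feature annotations (TSV `name  start  end`, or GFF3 with the seqid matching
the FASTA id) must be non-overlapping and sorted. Ambiguity codes in the
reference are rejected rather than wildcarded: mapping is perfect-match, and
an IUPAC wildcard would silently change read counts.

## Trimming

The insert is the prefix before the leftmost exact occurrence of the full 3′
adapter; failing that, an exact adapter prefix of ≥ `min_overlap` (default 7)
bases anchored at the read's 3′ end. Inserts outside 15–45 nt are rejected
with reason `length`; reads without a detectable adapter are rejected with
reason `no_adapter` rather than passed through, since for short-cycle
small-RNA runs an adapterless read implies an insert longer than the read.
No quality filtering or mismatch-tolerant trimming is done — downstream
perfect-match mapping already discards erroneous reads. A pre-trimmed mode
applies only the length window. The accounting identity
`accepted + rejected = input` is asserted in tests.

## Mapping and the multimap policy

Mapping is exact substring search of each species against the locus and of
its reverse complement against the locus (placements reported on both
strands, all occurrences). Correctness is pinned to a brute-force oracle that
compares every substring and reverse-complemented substring of a random 2-kb
locus.

A locus-confined reference is effectively single-copy, but multi-mapping is
still possible in principle, so it is an explicit policy rather than a silent
choice: `all` (default) attributes the full count at every placement for
per-position layers while counting each read once in library totals;
`fractional` spreads count/m; `unique` drops multi-mappers. Under `all`, a
species placing on both strands is counted once in totals, on the strand of
its first (sense-first, leftmost) placement — a deterministic tie-break for a
case that is vanishingly rare on realistic loci but must not break the
`sense + antisense = total` identity.

## Profiles

- **Size distribution**: stranded histogram over 18–25 nt plus an
  out-of-range bin, computed with the same per-placement weights as the
  position tracks, so the cross-layer identity (track sum = histogram cell)
  holds exactly.
- **Boundary distances**: for each (strand, length) class, the distance from
  the downstream feature's first base to the boundary-proximal (leftmost)
  matched base of the nearest alignment *fully contained* in that feature;
  0 means flush, absent classes are reported as undefined. For antisense
  siRNAs the leftmost base is the 3′ end, which is how antisense ends are
  naturally annotated next to an upstream boundary. The rule is echoed in
  the report header because other measures (nearest end vs 5′ end) are
  conceivable; this is the simplest one consistent with per-class
  annotations of boundary proximity.
- **Allele classification**: each species is perfect-match tested against
  both whole allele references (both strands) and classed
  common / specific_a / specific_b / unplaced. Testing whole sequences
  rather than a lifted diagnostic window handles indels between alleles with
  no coordinate arithmetic.

## Commonality

"More than five reads" is interpreted strictly (count ≥ 6); the threshold is
a parameter. Ranks are average-tied (scipy `rankdata`); Spearman's r_s is
computed on species passing the threshold in **both** samples, re-ranked
within that common set (the common-set size is what the per-pair n refers
to). The alternative — restricting each sample's global ranks to the common
set — is available as `mode="global"` since the choice is not forced by the
analysis definition; the two agree when the common set is rank-dense at the
top. With ties, r_s equals the Pearson correlation of tied-averaged rank
vectors, which the tests assert against scipy as an independent oracle.
Top-N membership ties are broken lexicographically so reports are
deterministic; this affects reporting only, never r_s. Significance is exact
(full permutation enumeration) for n ≤ 8 and a t approximation with n − 2 df
otherwise; p values are reported but nothing downstream depends on them.

## Phasing

Phase registers: sense `p = ((coord − 1) mod 21) + 1`, antisense
`p = ((L − coord) mod 21) + 1` — phase 1 anchored at the first (sense) and
last (antisense) reference base, registers advancing in each strand's 5′→3′
direction. For each strand the 21 registers partition [1, L] (tested
exhaustively). The unit length is a parameter (22-nt phasing can be
explored) but 21 is the default because unit length = siRNA length for
DCL4 products.

Occupancy is presence/absence: a cycle position is occupied when ≥ 1 read
(`min_depth` knob) of a 21-nt species has its 5′ end exactly there. Phased
regions are maximal runs of ≥ 3 (`min_units`) consecutive occupied cycle
positions; span = 21 × n_units. A region's 5′ end is its first unit's 5′
coordinate; its 3′ end is the last unit's terminal base. Reports carry both
strand-relative and absolute (left/right) coordinates because antisense
regions run right-to-left.

Phasing scores use the log-odds form
`score = ln[(1 + 10·P/(1+U))^(k−2)]` with a k ≥ 3 gate, over windows of 9
consecutive cycles (window length and constants are parameters): P is the
in-phase read total, U the out-of-phase total within the window's nt
footprint, k the number of occupied in-phase cycles. The window slides one
cycle at a time and each cycle position receives the best score among the
windows covering it — with a one-sided window, positions near a region's 3′
end would otherwise score zero purely by window placement.

End conservation between samples is exact-coordinate identity of region 5′
ends (and separately 3′ ends) on the same strand. The default tolerance is
0 because ends offset by one nucleotide belong to *neighboring registers*
and are a distinct phenomenon, not a fuzzy match; a tolerance knob exists
for exploration.

## Synthetic libraries

The generator emulates the structure the analysis assumes, with defaults
chosen as a realistic silenced-locus library:

| parameter | default | rationale |
|---|---|---|
| locus | 2 080 nt; upstream/exon1/intron/exon2/downstream = 200/180/300/1200/200 | gene-scale locus with a long second exon |
| size mixture | 21: 0.70, 22: 0.20, 24: 0.06, 23: 0.04 | 21 ≫ 22 > 24 > 23 ordering of a DCL4-dominated library |
| antisense fraction | 0.70 | antisense excess of roughly 7:3 seen in silenced-tissue libraries |
| confinement | exon2 | production confined to the exon where degradation initiates; a leaky mode plants elsewhere for negative controls |
| hot spots | 12 positions, log-abundance N(3.5, 1.0²), Poisson-realized | a few extra-abundant species dominating the rank list (heavy-tailed law) |
| background | 150 species at mean depth 2 | sparse low-count species |
| phased trains | explicit (strand, first unit, n_units, depth); deterministic depth | planted units must be occupied with certainty for exact-recovery tests |
| adapter / read length | `TCGTATGCCGTCTTCTGCTTG`, 36 nt | Genome-Analyzer-era small-RNA chemistry |
| paired coupling | shared σ = 1.4, noise σ = 0.4, log-mean 2.5 | implied log-abundance correlation ≈ 0.92, giving realized rank correlations in the 0.7–0.85 range typical of mechanistically related libraries |

Counts follow a log-normal abundance law with Poisson realization (the
simplest law reproducing heavy-tailed hot spots); a deterministic law
(rounded expectation, min 1) exists for tests that need exact expectations,
e.g. that zero coupling noise yields r_s = 1. Species are drawn with a
uniqueness check (resampled if the drawn substring multi-maps on the locus)
so ground truth reconciles exactly with pipeline accounting under every
multimap policy. Paired ground truth records the *achieved* Spearman
correlation of the realized counts — pooled over strands on all common
species, and per strand on the above-threshold common set, the latter being
definitionally identical to what the pipeline estimates.

What passing these tests shows: the pipeline recovers exactly what was
planted (counts, positions, strand/size proportions, phased regions, rank
correlation) under the generative model. What it does not show: robustness
to real-library artifacts the generator deliberately omits — ligation bias,
realistic error/quality profiles, miRNA/degradation contaminants, multi-copy
references — so agreement on synthetic data is a correctness statement, not
a benchmark of biological recall.

## Problem sizes and determinism

Tests and the acceptance script run on 2-kb loci with hundreds of species
and up to ~10⁴ reads — large enough for the binomial/Poisson tolerances used
(3 sd bands; ±0.1 on rank correlations over 20 seeds) and small enough to
run in seconds. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical (seed, design) inputs produce
byte-identical FASTQ, tables and reports (timestamps are excluded from
hashed report content).

## Known limitations

Single-record references only; no spliced-coordinate projection (mapping is
to the genomic locus); no normalisation across library sizes (ranks are
scale-free; raw counts are reported); exact-match only, so SNPs between the
sequenced material and the reference shift reads into the unmapped tally
rather than being placed.
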