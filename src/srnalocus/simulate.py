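"""Synthetic small-RNA library generator with full ground-truth bookkeeping.

The generator emulates the statistical structure of deep-sequenced siRNA
libraries from a single silenced locus: reads of 15-45 nt dominated by the
21-nt class with 22-nt second (default mixture 21:0.70, 22:0.20, 24:0.06,
23:0.04), an antisense excess (default antisense fraction 0.70, matching
the roughly 7:3 antisense:sense read split seen in silenced petal tissue),
production confined to exon 2 with a handful of log-normally abundant hot
spots, phased 21-nt unit trains in chosen registers, and a uniform
background of low-count species.  Paired designs couple two samples through
a shared log-abundance term plus independent per-sample noise, producing a
tunable between-sample rank correlation; the *achieved* correlation on the
realized counts is recorded so tests compare against what was actually
generated, not what was targeted.

Reads are emitted as insert + 3' adapter truncated to the read length, so
the full trimming path is exercised.  Sequencing error is off by default
(perfect-match mapping would silently drop erroneous reads); an error-rate
knob exists to exercise unmapped accounting.  Everything is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import stats

from .mapping import ANTISENSE, SENSE, map_species, reverse_complement
from .phasing import DEFAULT_UNIT, PhasedRegion, phase_of
from .reads import RawRead
from .reference import Feature, ReferenceLocus

__all__ = [
    "DEFAULT_FEATURE_LENGTHS",
    "DEFAULT_SIZE_MIXTURE",
    "DEFAULT_ADAPTER",
    "PhasedTrainSpec",
    "PairedCoupling",
    "SyntheticDesign",
    "SpeciesTruth",
    "GroundTruth",
    "PairedGroundTruth",
    "generate_locus",
    "simulate_library",
    "simulate_paired",
    "write_fastq",
    "write_fasta",
]

#: (five_prime_upstream, exon1, intron, exon2, three_prime_downstream) lengths.
DEFAULT_FEATURE_LENGTHS = (200, 180, 300, 1200, 200)
FEATURE_NAMES = (
    "five_prime_upstream",
    "exon1",
    "intron",
    "exon2",
    "three_prime_downstream",
)
#: 21 >> 22 > 24 > 23, the size-class ordering of a DCL4-dominated library.
DEFAULT_SIZE_MIXTURE: dict[int, float] = {21: 0.70, 22: 0.20, 24: 0.06, 23: 0.04}
#: Genome-Analyzer-era small-RNA 3' adapter.
DEFAULT_ADAPTER = "TCGTATGCCGTCTTCTGCTTG"


@dataclass(frozen=True)
class PhasedTrainSpec:
    """A planted run of consecutive occupied 21-nt phase units.

    ``first_unit_coord`` is the 5'-end coordinate of the strand-wise first
    unit (rightmost for antisense); every unit carries ``depth`` reads.
    """

    strand: str
    first_unit_coord: int
    n_units: int
    depth: int = 10
    unit: int = DEFAULT_UNIT

    def unit_coords(self) -> list[int]:
        step = self.unit if self.strand == SENSE else -self.unit
        return [self.first_unit_coord + i * step for i in range(self.n_units)]

    def expected_region(self, L: int) -> PhasedRegion:
        coords = self.unit_coords()
        return PhasedRegion(
            strand=self.strand,
            phase=phase_of(self.first_unit_coord, self.strand, L, self.unit),
            first_unit_coord=coords[0],
            last_unit_coord=coords[-1],
            n_units=self.n_units,
            unit=self.unit,
        )


@dataclass(frozen=True)
class PairedCoupling:
    """Shared-signal model for a two-sample design: per-species expected
    log-abundance = mu + shared N(0, shared_sigma) + sample N(0, noise_sigma).
    The implied correlation of expected log-abundances is
    shared_sigma^2 / (shared_sigma^2 + noise_sigma^2)."""

    shared_sigma: float = 1.4
    noise_sigma: float = 0.4
    log_mu: float = 2.5


@dataclass(frozen=True)
class SyntheticDesign:
    """Study conditions for one synthetic library.

    Defaults emulate a silenced-locus library: everything planted inside
    exon 2, heavy-tailed hot spots, 21-dominant size mixture, antisense
    excess, a few phased trains, sparse background.
    """

    seed: int = 7
    feature_lengths: tuple[int, ...] = DEFAULT_FEATURE_LENGTHS
    size_mixture: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_MIXTURE)
    )
    antisense_fraction: float = 0.70
    n_hotspots: int = 12
    hotspot_log_mu: float = 3.5
    hotspot_log_sigma: float = 1.0
    n_background_species: int = 150
    background_depth: float = 2.0
    phased_trains: tuple[PhasedTrainSpec, ...] = ()
    confine_feature: str | None = "exon2"  # None = anywhere on the locus
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 36
    error_rate: float = 0.0
    count_law: str = "poisson"  # "poisson" | "deterministic"

    def __post_init__(self) -> None:
        total = sum(self.size_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"size mixture proportions sum to {total}, not 1")
        if not (0.0 <= self.antisense_fraction <= 1.0):
            raise ValueError("antisense_fraction must be in [0, 1]")
        if self.count_law not in ("poisson", "deterministic"):
            raise ValueError(f"unknown count law {self.count_law!r}")


@dataclass(frozen=True)
class SpeciesTruth:
    """Ground truth for one planted species."""

    sequence: str
    strand: str
    five_prime_coord: int
    length: int
    count: int
    origin: str  # hotspot | train | background


@dataclass
class GroundTruth:
    """Everything the generator planted, reconciling exactly with the reads."""

    sample_id: str
    species: list[SpeciesTruth]
    planted_regions: list[PhasedRegion]
    total_reads: int

    def class_total(self, length: int | None = None, strand: str | None = None) -> int:
        return sum(
            sp.count
            for sp in self.species
            if (length is None or sp.length == length)
            and (strand is None or sp.strand == strand)
        )

    def position_totals(self, length: int, strand: str) -> dict[int, int]:
        out: dict[int, int] = {}
        for sp in self.species:
            if sp.length == length and sp.strand == strand:
                out[sp.five_prime_coord] = out.get(sp.five_prime_coord, 0) + sp.count
        return out


@dataclass
class PairedGroundTruth:
    """Realized coupling between the two samples.

    ``achieved_rs_all`` pools both strands over species present in both
    samples; ``achieved_rs`` is per strand over species above the read
    threshold in both samples (the same set the rank-correlation analysis
    uses), so pipeline estimates are compared against what was actually
    generated.
    """

    truth_a: GroundTruth
    truth_b: GroundTruth
    achieved_rs_all: float
    achieved_rs: dict[str, float | None]
    n_common: int
    n_common_above_threshold: dict[str, int]


def generate_locus(
    seed: int, feature_lengths: tuple[int, ...] = DEFAULT_FEATURE_LENGTHS
) -> ReferenceLocus:
    """Random ACGT locus with the canonical five-feature annotation laid
    end-to-end in order; deterministic given the seed."""
    if any(n < 1 for n in feature_lengths):
        raise ValueError("feature lengths must be >= 1")
    if len(feature_lengths) != len(FEATURE_NAMES):
        raise ValueError(f"expected {len(FEATURE_NAMES)} feature lengths")
    rng = np.random.default_rng(seed)
    L = int(sum(feature_lengths))
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=L)])
    features = []
    pos = 1
    for name, n in zip(FEATURE_NAMES, feature_lengths):
        features.append(Feature(pos, pos + n - 1, name))
        pos += n
    return ReferenceLocus(id=f"synthetic_locus_seed{seed}", sequence=seq, features=tuple(features))


def _species_sequence(locus: ReferenceLocus, strand: str, five_prime: int, length: int) -> str:
    if strand == SENSE:
        start, end = five_prime, five_prime + length - 1
    else:
        start, end = five_prime - length + 1, five_prime
    segment = locus.slice(start, end)
    return segment if strand == SENSE else reverse_complement(segment)


def _planting_window(locus: ReferenceLocus, design: SyntheticDesign) -> tuple[int, int]:
    if design.confine_feature is None:
        return 1, locus.length
    feat = locus.feature(design.confine_feature)
    return feat.start, feat.end


def _draw_position(
    rng: np.random.Generator,
    locus: ReferenceLocus,
    design: SyntheticDesign,
    strand: str,
    length: int,
) -> int:
    """5'-end coordinate such that the alignment fits in the planting window;
    retries until the drawn species sequence maps uniquely on the locus, so
    ground truth reconciles under every multimap policy."""
    lo, hi = _planting_window(locus, design)
    for _ in range(50):
        if strand == SENSE:
            five = int(rng.integers(lo, hi - length + 2))
        else:
            five = int(rng.integers(lo + length - 1, hi + 1))
        seq = _species_sequence(locus, strand, five, length)
        if len(map_species(seq, locus)) == 1:
            return five
    raise RuntimeError("could not place a uniquely-mapping species in 50 draws")


def _realize_count(rng: np.random.Generator, expected: float, law: str) -> int:
    if law == "poisson":
        return int(rng.poisson(expected))
    return max(1, int(round(expected)))


def _draw_length(rng: np.random.Generator, mixture: dict[int, float]) -> int:
    lengths = sorted(mixture)
    probs = np.array([mixture[n] for n in lengths])
    return int(rng.choice(lengths, p=probs / probs.sum()))


def _draw_strand(rng: np.random.Generator, antisense_fraction: float) -> str:
    return ANTISENSE if rng.random() < antisense_fraction else SENSE


def _build_species(
    design: SyntheticDesign, locus: ReferenceLocus, rng: np.random.Generator
) -> list[SpeciesTruth]:
    planted: dict[str, SpeciesTruth] = {}

    def add(sp: SpeciesTruth) -> None:
        prev = planted.get(sp.sequence)
        if prev is not None:  # same placement drawn twice: merge counts
            sp = replace(prev, count=prev.count + sp.count)
        planted[sp.sequence] = sp

    # phased trains: deterministic per-unit depth so occupancy is certain
    for train in design.phased_trains:
        for coord in train.unit_coords():
            seq = _species_sequence(locus, train.strand, coord, train.unit)
            add(SpeciesTruth(seq, train.strand, coord, train.unit, train.depth, "train"))

    # hot spots: few positions with heavy-tailed (log-normal) abundance
    for _ in range(design.n_hotspots):
        length = _draw_length(rng, design.size_mixture)
        strand = _draw_strand(rng, design.antisense_fraction)
        coord = _draw_position(rng, locus, design, strand, length)
        expected = float(
            np.exp(rng.normal(design.hotspot_log_mu, design.hotspot_log_sigma))
        )
        count = _realize_count(rng, expected, design.count_law)
        if count > 0:
            seq = _species_sequence(locus, strand, coord, length)
            add(SpeciesTruth(seq, strand, coord, length, count, "hotspot"))

    # uniform background of sparse species
    for _ in range(design.n_background_species):
        length = _draw_length(rng, design.size_mixture)
        strand = _draw_strand(rng, design.antisense_fraction)
        coord = _draw_position(rng, locus, design, strand, length)
        count = _realize_count(rng, design.background_depth, design.count_law)
        if count > 0:
            seq = _species_sequence(locus, strand, coord, length)
            add(SpeciesTruth(seq, strand, coord, length, count, "background"))

    return sorted(planted.values(), key=lambda sp: sp.sequence)


def _emit_reads(
    species: list[SpeciesTruth],
    design: SyntheticDesign,
    rng: np.random.Generator,
    sample_id: str,
) -> list[RawRead]:
    reads: list[RawRead] = []
    bases = np.array(list("ACGT"))
    for i, sp in enumerate(species):
        raw = (sp.sequence + design.adapter)[: design.read_length]
        for j in range(sp.count):
            seq = raw
            if design.error_rate > 0 and rng.random() < design.error_rate:
                pos = int(rng.integers(0, len(sp.sequence)))
                alt = str(rng.choice(bases[bases != seq[pos]]))
                seq = seq[:pos] + alt + seq[pos + 1 :]
            reads.append(
                RawRead(f"{sample_id}_sp{i}_r{j}", seq, "I" * len(raw))
            )
    order = rng.permutation(len(reads))
    return [reads[int(idx)] for idx in order]


def simulate_library(
    design: SyntheticDesign,
    locus: ReferenceLocus,
    sample_id: str = "synthetic",
) -> tuple[list[RawRead], GroundTruth]:
    """Generate one library and its ground truth.  Byte-reproducible given
    (design, locus)."""
    rng = np.random.default_rng(design.seed)
    species = _build_species(design, locus, rng)
    regions = [t.expected_region(locus.length) for t in design.phased_trains]
    reads = _emit_reads(species, design, rng, sample_id)
    truth = GroundTruth(
        sample_id=sample_id,
        species=species,
        planted_regions=regions,
        total_reads=sum(sp.count for sp in species),
    )
    return reads, truth


def simulate_paired(
    design: SyntheticDesign,
    locus: ReferenceLocus,
    coupling: PairedCoupling = PairedCoupling(),
    n_shared_species: int = 200,
    sample_ids: tuple[str, str] = ("sample_a", "sample_b"),
    min_reads_exclusive: int = 5,
) -> tuple[list[RawRead], list[RawRead], PairedGroundTruth]:
    """Generate two libraries over a shared 21-nt species universe with
    coupled abundances, plus any phased trains of the design (planted in
    both samples at their stated depth).

    Per-species expected abundance in each sample is exp(shared + noise)
    with shared ~ N(log_mu, shared_sigma) drawn once and noise drawn per
    sample; counts are then realized by the design's count law.  The
    achieved Spearman correlation of the realized counts (on species present
    in both samples, and separately on species above the read threshold in
    both) is recorded in the returned ground truth.
    """
    rng = np.random.default_rng(design.seed)
    # shared species universe of 21-nt positions
    universe: list[tuple[str, int]] = []
    seen: set[tuple[str, int]] = set()
    while len(universe) < n_shared_species:
        strand = _draw_strand(rng, design.antisense_fraction)
        coord = _draw_position(rng, locus, design, strand, 21)
        if (strand, coord) not in seen:
            seen.add((strand, coord))
            universe.append((strand, coord))
    shared = rng.normal(coupling.log_mu, coupling.shared_sigma, size=len(universe))

    per_sample_species: list[list[SpeciesTruth]] = []
    for _sample in sample_ids:
        noise = rng.normal(0.0, coupling.noise_sigma, size=len(universe))
        expected = np.exp(shared + noise)
        species: dict[str, SpeciesTruth] = {}
        for (strand, coord), mu in zip(universe, expected):
            count = _realize_count(rng, float(mu), design.count_law)
            if count > 0:
                seq = _species_sequence(locus, strand, coord, 21)
                species[seq] = SpeciesTruth(seq, strand, coord, 21, count, "coupled")
        for train in design.phased_trains:
            for coord in train.unit_coords():
                seq = _species_sequence(locus, train.strand, coord, train.unit)
                prev = species.get(seq)
                count = train.depth + (prev.count if prev else 0)
                species[seq] = SpeciesTruth(
                    seq, train.strand, coord, train.unit, count, "train"
                )
        per_sample_species.append(sorted(species.values(), key=lambda sp: sp.sequence))

    counts_a = {sp.sequence: sp.count for sp in per_sample_species[0]}
    counts_b = {sp.sequence: sp.count for sp in per_sample_species[1]}
    strand_of = {sp.sequence: sp.strand for sp in per_sample_species[0]}
    common = sorted(set(counts_a) & set(counts_b))
    x = np.array([counts_a[s] for s in common], dtype=float)
    y = np.array([counts_b[s] for s in common], dtype=float)
    rs_all = float(stats.spearmanr(x, y).statistic) if len(common) >= 3 else float("nan")
    achieved_rs: dict[str, float | None] = {}
    n_above: dict[str, int] = {}
    for strand in (SENSE, ANTISENSE):
        above = [
            s
            for s in common
            if strand_of[s] == strand
            and counts_a[s] > min_reads_exclusive
            and counts_b[s] > min_reads_exclusive
        ]
        n_above[strand] = len(above)
        if len(above) >= 3:
            xa = np.array([counts_a[s] for s in above], dtype=float)
            ya = np.array([counts_b[s] for s in above], dtype=float)
            achieved_rs[strand] = float(stats.spearmanr(xa, ya).statistic)
        else:
            achieved_rs[strand] = None

    regions = [t.expected_region(locus.length) for t in design.phased_trains]
    truths = []
    reads_out = []
    for sample_id, species in zip(sample_ids, per_sample_species):
        reads = _emit_reads(species, design, rng, sample_id)
        truths.append(
            GroundTruth(
                sample_id=sample_id,
                species=species,
                planted_regions=regions,
                total_reads=sum(sp.count for sp in species),
            )
        )
        reads_out.append(reads)

    paired = PairedGroundTruth(
        truth_a=truths[0],
        truth_b=truths[1],
        achieved_rs_all=rs_all,
        achieved_rs=achieved_rs,
        n_common=len(common),
        n_common_above_threshold=n_above,
    )
    return reads_out[0], reads_out[1], paired


def write_fastq(reads: list[RawRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = read.qualities or "I" * len(read.sequence)
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")


def write_fasta(reads: list[RawRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f">{read.id}\n{read.sequence}\n")
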