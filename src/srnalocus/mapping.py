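"""Perfect-match placement of siRNA species on the reference locus.

Every species is searched as an exact substring of the locus (sense strand)
and of its reverse complement (antisense strand); all placements on both
strands are reported.  An antisense alignment covering reference bases
``[start, end]`` has the siRNA's 5' end at ``end`` (the rightmost matched
base) - this single convention drives all position tracks, boundary
distances and phase registration downstream.

Multi-mapping species (rare on an effectively single-copy locus) are handled
by an explicit policy:

``all`` (default)
    full count at every placement for per-position attribution, but each
    read counted once in library-level totals;
``fractional``
    count / m at each of the m placements everywhere;
``unique``
    only uniquely-placed species contribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .reads import SiRNASpecies, SpeciesTable
from .reference import ReferenceLocus

__all__ = [
    "SENSE",
    "ANTISENSE",
    "STRANDS",
    "MULTIMAP_POLICIES",
    "Alignment",
    "MappedSet",
    "reverse_complement",
    "map_species",
    "map_table",
    "strand_read_totals",
    "alignment_weight",
    "five_prime_coord",
    "write_mapped_tsv",
    "write_sam",
]

SENSE = "sense"
ANTISENSE = "antisense"
STRANDS = (SENSE, ANTISENSE)
MULTIMAP_POLICIES = ("all", "fractional", "unique")

_STRAND_ORDER = {SENSE: 0, ANTISENSE: 1}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Alignment:
    """One perfect-match placement of a species on the locus.

    ``start``/``end`` are 1-based inclusive reference coordinates of the
    matched segment regardless of strand; ``n_placements`` is the species'
    total number of placements (both strands), used by multimap policies.
    """

    sequence: str
    strand: str
    start: int
    end: int
    count: int
    n_placements: int = 1

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def five_prime(self) -> int:
        """Reference coordinate of the siRNA's 5' end."""
        return self.start if self.strand == SENSE else self.end

    @property
    def three_prime(self) -> int:
        """Reference coordinate of the siRNA's 3' end."""
        return self.end if self.strand == SENSE else self.start


def five_prime_coord(alignment: Alignment) -> int:
    return alignment.five_prime


@dataclass
class MappedSet:
    """All placements of a species table on a locus, plus unmapped tallies."""

    sample_id: str
    locus_id: str
    locus_length: int
    alignments: list[Alignment] = field(default_factory=list)
    unmapped_species: int = 0
    unmapped_reads: int = 0
    multimap_policy: str = "all"

    def iter_class(self, length: int | None = None, strand: str | None = None):
        for aln in self.alignments:
            if length is not None and aln.length != length:
                continue
            if strand is not None and aln.strand != strand:
                continue
            yield aln

    def species_counts(
        self, length: int | None = None, strand: str | None = None
    ) -> dict[str, int]:
        """Per-species read counts for a (length, strand) class, each species
        counted once however many placements it has in the class."""
        out: dict[str, int] = {}
        for aln in self.iter_class(length, strand):
            out[aln.sequence] = aln.count
        return out

    @property
    def mapped_species(self) -> int:
        return len({aln.sequence for aln in self.alignments})


def alignment_weight(alignment: Alignment, policy: str) -> float:
    """Per-placement read weight under a multimap policy (for position-level
    attribution: tracks, size histograms, feature confinement)."""
    if policy == "all":
        return float(alignment.count)
    if policy == "fractional":
        return alignment.count / alignment.n_placements
    if policy == "unique":
        return float(alignment.count) if alignment.n_placements == 1 else 0.0
    raise ValueError(f"unknown multimap policy {policy!r}")


def map_species(species: SiRNASpecies | str, locus: ReferenceLocus) -> list[Alignment]:
    """All perfect-match placements of one species on both strands, sorted by
    (strand, start); empty list if the species does not map."""
    if isinstance(species, str):
        species = SiRNASpecies(species, 1)
    seq = species.sequence
    n = len(seq)
    placements: list[tuple[str, int]] = []
    for strand, query in ((SENSE, seq), (ANTISENSE, reverse_complement(seq))):
        pos = locus.sequence.find(query)
        while pos >= 0:
            placements.append((strand, pos + 1))
            pos = locus.sequence.find(query, pos + 1)
    placements.sort(key=lambda p: (_STRAND_ORDER[p[0]], p[1]))
    m = len(placements)
    return [
        Alignment(seq, strand, start, start + n - 1, species.count, m)
        for strand, start in placements
    ]


def map_table(
    table: SpeciesTable, locus: ReferenceLocus, multimap_policy: str = "all"
) -> MappedSet:
    """Map every species of a table; aggregates placements and unmapped
    tallies into a :class:`MappedSet`."""
    if multimap_policy not in MULTIMAP_POLICIES:
        raise ValueError(f"unknown multimap policy {multimap_policy!r}")
    mapped = MappedSet(
        sample_id=table.sample_id,
        locus_id=locus.id,
        locus_length=locus.length,
        multimap_policy=multimap_policy,
    )
    for species in table.species:
        placements = map_species(species, locus)
        if placements:
            mapped.alignments.extend(placements)
        else:
            mapped.unmapped_species += 1
            mapped.unmapped_reads += species.count
    return mapped


def strand_read_totals(mapped: MappedSet) -> tuple[float, float, float]:
    """Library-level (sense, antisense, total) mapped-read accounting.

    Under the ``all`` policy each read is counted once: a species is
    attributed to the strand of its first placement in (sense-first,
    leftmost) order.  Under ``fractional`` placements contribute count/m;
    under ``unique`` only single-placement species count.
    """
    policy = mapped.multimap_policy
    totals = {SENSE: 0.0, ANTISENSE: 0.0}
    if policy == "all":
        first: dict[str, Alignment] = {}
        for aln in mapped.alignments:
            prev = first.get(aln.sequence)
            key = (_STRAND_ORDER[aln.strand], aln.start)
            if prev is None or key < (_STRAND_ORDER[prev.strand], prev.start):
                first[aln.sequence] = aln
        for aln in first.values():
            totals[aln.strand] += aln.count
    else:
        for aln in mapped.alignments:
            totals[aln.strand] += alignment_weight(aln, policy)
    sense, anti = totals[SENSE], totals[ANTISENSE]
    return sense, anti, sense + anti


def write_mapped_tsv(mapped: MappedSet, path: str | Path) -> None:
    """Serialize as TSV (deterministic: placement order then sequence)."""
    rows = sorted(
        mapped.alignments,
        key=lambda a: (_STRAND_ORDER[a.strand], a.start, a.sequence),
    )
    with open(path, "w") as fh:
        fh.write("sequence\tstrand\tstart\tend\tlength\tcount\tn_placements\n")
        for a in rows:
            fh.write(
                f"{a.sequence}\t{a.strand}\t{a.start}\t{a.end}\t{a.length}\t"
                f"{a.count}\t{a.n_placements}\n"
            )


def write_sam(mapped: MappedSet, path: str | Path) -> None:
    """Optional SAM export against the single-record reference (flag 0/16,
    POS = start, exact-match CIGAR); one line per placement."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": mapped.locus_id, "LN": mapped.locus_length}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, aln in enumerate(mapped.alignments):
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = f"{mapped.sample_id}_sp{i}"
            seg.flag = 0 if aln.strand == SENSE else 16
            seg.reference_id = 0
            seg.reference_start = aln.start - 1
            seg.mapping_quality = 255
            seg.cigarstring = f"{aln.length}M"
            seg.query_sequence = (
                aln.sequence if aln.strand == SENSE else reverse_complement(aln.sequence)
            )
            seg.set_tag("NH", aln.n_placements)
            seg.set_tag("RC", aln.count)
            out.write(seg)
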