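"""Descriptive profiling of a mapped siRNA library.

Four layers, all driven by the single 5'-end attribution convention of the
mapper (sense 5' end = ``start``, antisense 5' end = ``end``):

* strand-resolved size distributions over a tabulated length range (default
  18-25 nt) with an out-of-range bin so grand totals reconcile;
* per-position read tracks per (length class, strand), indexed by the 5'-end
  coordinate;
* feature confinement (which annotated feature each alignment's 5' end
  falls in);
* distances from a feature boundary (e.g. intron / exon 2) to the nearest
  siRNA of each (strand, length) class fully contained in the downstream
  feature;
* allele-discriminating classification of species against a pair of
  diverged references (e.g. endogene vs transgene).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mapping import (
    ANTISENSE,
    SENSE,
    STRANDS,
    Alignment,
    MappedSet,
    alignment_weight,
    map_species,
)
from .reads import SpeciesTable
from .reference import AllelePair, ReferenceLocus, boundary_coordinate, feature_of

__all__ = [
    "SizeDistribution",
    "PositionTrack",
    "BoundaryReport",
    "AlleleClassification",
    "size_distribution",
    "position_track",
    "feature_confinement",
    "boundary_distances",
    "classify_alleles",
    "write_position_track_bedgraph",
]

DEFAULT_SIZE_RANGE = (18, 25)
OTHER_BIN = "other"

#: Rule used for boundary distances, echoed in report headers.
BOUNDARY_RULE = (
    "distance = (leftmost matched base of the nearest alignment fully inside "
    "the downstream feature) - (first base of the downstream feature); 0 = flush"
)


@dataclass
class SizeDistribution:
    """Stranded length histogram of mapped reads (weights per the multimap
    policy of the source MappedSet)."""

    sample_id: str
    size_range: tuple[int, int]
    counts: dict[tuple[int, str], float]
    other: dict[str, float]

    def get(self, length: int, strand: str) -> float:
        return self.counts.get((length, strand), 0.0)

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.size_range
        rows = [
            {
                "length": n,
                **{s: self.get(n, s) for s in STRANDS},
            }
            for n in range(lo, hi + 1)
        ]
        rows.append({"length": OTHER_BIN, **{s: self.other.get(s, 0.0) for s in STRANDS}})
        return pd.DataFrame(rows)


@dataclass
class PositionTrack:
    """Per-position read counts of one (length, strand) class, indexed by
    5'-end reference coordinate (vector index i = coordinate i + 1)."""

    sample_id: str
    length: int
    strand: str
    counts: np.ndarray  # float vector of locus length

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def at(self, coordinate: int) -> float:
        return float(self.counts[coordinate - 1])


@dataclass
class BoundaryReport:
    """Nearest-siRNA distances from a feature boundary, per (strand, length).

    ``distances[(strand, length)]`` is an int >= 0 or ``None`` when no
    alignment of that class lies fully inside the downstream feature.
    """

    sample_id: str
    boundary: tuple[str, str]
    boundary_coordinate: int
    rule: str
    distances: dict[tuple[str, int], int | None]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"strand": s, "length": n, "distance_nt": d}
            for (s, n), d in sorted(self.distances.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class AlleleClassification:
    """Partition of species by perfect-match status against two alleles."""

    label_a: str
    label_b: str
    classes: dict[str, str]  # sequence -> common | specific_a | specific_b | unplaced
    read_counts: dict[str, int] = field(default_factory=dict)

    def n_in_class(self, cls: str) -> int:
        return sum(1 for c in self.classes.values() if c == cls)

    def reads_in_class(self, cls: str) -> int:
        return sum(
            self.read_counts.get(seq, 0)
            for seq, c in self.classes.items()
            if c == cls
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sequence": seq, "count": self.read_counts.get(seq, 0), "class": cls}
            for seq, cls in sorted(self.classes.items())
        ]
        return pd.DataFrame(rows)


def size_distribution(
    mapped: MappedSet, size_range: tuple[int, int] = DEFAULT_SIZE_RANGE
) -> SizeDistribution:
    """Stranded histogram of mapped read lengths over ``size_range`` plus an
    out-of-range bin; per-placement weights follow the multimap policy, so it
    sums cell-by-cell to the position tracks."""
    lo, hi = size_range
    counts: dict[tuple[int, str], float] = {}
    other = {s: 0.0 for s in STRANDS}
    for aln in mapped.alignments:
        w = alignment_weight(aln, mapped.multimap_policy)
        if lo <= aln.length <= hi:
            key = (aln.length, aln.strand)
            counts[key] = counts.get(key, 0.0) + w
        else:
            other[aln.strand] += w
    return SizeDistribution(mapped.sample_id, size_range, counts, other)


def position_track(mapped: MappedSet, length: int, strand: str) -> PositionTrack:
    """Read counts attributed at each alignment's 5'-end coordinate for one
    (length, strand) class."""
    vec = np.zeros(mapped.locus_length, dtype=float)
    for aln in mapped.iter_class(length, strand):
        vec[aln.five_prime - 1] += alignment_weight(aln, mapped.multimap_policy)
    return PositionTrack(mapped.sample_id, length, strand, vec)


def feature_confinement(
    mapped: MappedSet, locus: ReferenceLocus
) -> pd.DataFrame:
    """Read counts and fractions per annotated feature (5'-end rule: each
    alignment belongs to the feature containing its 5' end)."""
    totals: dict[str, float] = {f.name: 0.0 for f in locus.features}
    totals["unannotated"] = 0.0
    for aln in mapped.alignments:
        name = feature_of(locus, aln.five_prime)
        totals[name] = totals.get(name, 0.0) + alignment_weight(
            aln, mapped.multimap_policy
        )
    grand = sum(totals.values())
    rows = [
        {
            "feature": name,
            "reads": reads,
            "fraction": reads / grand if grand > 0 else float("nan"),
        }
        for name, reads in totals.items()
    ]
    return pd.DataFrame(rows)


def boundary_distances(
    mapped: MappedSet,
    locus: ReferenceLocus,
    boundary: tuple[str, str] = ("intron", "exon2"),
    lengths: tuple[int, ...] = (21, 22),
) -> BoundaryReport:
    """Distance from a feature boundary to the nearest qualifying siRNA of
    each (strand, length) class.

    Qualifying alignments lie fully inside the downstream feature; the
    distance is measured to the alignment's boundary-proximal (leftmost)
    matched base, which for antisense siRNAs is their 3' end - matching how
    antisense ends are annotated next to an upstream boundary.
    """
    coord = boundary_coordinate(locus, *boundary)
    down = locus.feature(boundary[1])
    distances: dict[tuple[str, int], int | None] = {}
    for strand in STRANDS:
        for n in lengths:
            best: int | None = None
            for aln in mapped.iter_class(n, strand):
                if aln.start >= down.start and aln.end <= down.end:
                    d = aln.start - coord
                    if best is None or d < best:
                        best = d
            distances[(strand, n)] = best
    return BoundaryReport(mapped.sample_id, boundary, coord, BOUNDARY_RULE, distances)


def classify_alleles(table: SpeciesTable, pair: AllelePair) -> AlleleClassification:
    """Classify each species by perfect-match status (both strands) against
    the two alleles: ``common`` (matches both), ``specific_a`` /
    ``specific_b`` (matches exactly one), ``unplaced`` (matches neither).
    The full species sequence is tested against each whole reference, so
    indels between alleles need no coordinate lifting."""
    classes: dict[str, str] = {}
    read_counts: dict[str, int] = {}
    for sp in table.species:
        in_a = bool(map_species(sp, pair.reference_a))
        in_b = bool(map_species(sp, pair.reference_b))
        if in_a and in_b:
            cls = "common"
        elif in_a:
            cls = "specific_a"
        elif in_b:
            cls = "specific_b"
        else:
            cls = "unplaced"
        classes[sp.sequence] = cls
        read_counts[sp.sequence] = sp.count
    return AlleleClassification(pair.label_a, pair.label_b, classes, read_counts)


def write_position_track_bedgraph(track: PositionTrack, locus_id: str, path: str | Path) -> None:
    """Write the nonzero entries of a track as bedGraph-like TSV
    (locus id, start-1, start, count)."""
    with open(path, "w") as fh:
        fh.write(f"# sample={track.sample_id} length={track.length} strand={track.strand}\n")
        for i in np.nonzero(track.counts)[0]:
            coord = int(i) + 1
            fh.write(f"{locus_id}\t{coord - 1}\t{coord}\t{track.counts[i]:g}\n")
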