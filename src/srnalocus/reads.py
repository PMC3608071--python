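"""Read ingestion, 3' adapter trimming, and collapse to unique siRNA species.

The trimming rule is deliberately simple and reproducible: the insert is the
prefix of the read before the leftmost exact match of the full adapter; if the
full adapter is absent, an exact adapter *prefix* of at least ``min_overlap``
bases anchored at the read's 3' end is accepted.  Reads with no detectable
adapter are discarded (for short-cycle small-RNA runs an adapterless read
implies an insert longer than the read, outside the retained length window
anyway).  Inserts are then filtered to the 15-45 nt window and collapsed into
unique species with aggregated read counts.

No quality filtering or mismatch-tolerant trimming is performed: downstream
mapping is perfect-match, which already drops erroneous reads.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "RawRead",
    "SiRNASpecies",
    "SpeciesTable",
    "TrimResult",
    "read_reads",
    "trim_adapter",
    "trim_and_filter",
    "length_filter",
    "collapse",
    "write_species_table",
    "read_species_table",
]

MIN_INSERT_LEN = 15
MAX_INSERT_LEN = 45
DEFAULT_MIN_OVERLAP = 7


@dataclass(frozen=True)
class RawRead:
    id: str
    sequence: str
    qualities: str | None = None  # Phred+33 string; retained but unused


@dataclass(frozen=True)
class SiRNASpecies:
    """A unique small-RNA sequence (as sequenced, 5'->3') with its read count."""

    sequence: str
    count: int


@dataclass
class SpeciesTable:
    """Collapsed species of one library, ordered by count desc then sequence."""

    sample_id: str
    species: list[SiRNASpecies] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return sum(sp.count for sp in self.species)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def counts(self) -> dict[str, int]:
        return {sp.sequence: sp.count for sp in self.species}


@dataclass(frozen=True)
class TrimResult:
    """Outcome of adapter trimming: either an insert or a rejection reason."""

    sequence: str | None
    reason: str | None = None  # None | "length" | "no_adapter"

    @property
    def accepted(self) -> bool:
        return self.sequence is not None


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_reads(path: str | Path, format: str | None = None) -> Iterator[RawRead]:
    """Stream reads from a FASTA or FASTQ file (optionally gzipped).

    ``format`` is ``"fastq"`` or ``"fasta"``; when ``None`` it is inferred
    from the file extension.  Malformed records raise ``ValueError`` carrying
    the index of the offending record.
    """
    path = Path(path)
    if format is None:
        stem = path.name[: -len(".gz")] if path.suffix == ".gz" else path.name
        ext = Path(stem).suffix.lower()
        format = "fastq" if ext in (".fastq", ".fq") else "fasta"
    if format not in ("fastq", "fasta"):
        raise ValueError(f"unknown read format {format!r}")

    index = 0
    with _open_maybe_gzip(path) as fh:
        try:
            if format == "fastq":
                for title, seq, qual in FastqGeneralIterator(fh):
                    index += 1
                    yield RawRead(title.split()[0], seq.upper(), qual)
            else:
                for title, seq in SimpleFastaParser(fh):
                    index += 1
                    yield RawRead(title.split()[0], seq.upper())
        except ValueError as exc:
            raise ValueError(f"{path}: malformed record after record {index}: {exc}") from exc


def trim_adapter(
    read: RawRead | str,
    adapter: str,
    min_len: int = MIN_INSERT_LEN,
    max_len: int = MAX_INSERT_LEN,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> TrimResult:
    """Trim the 3' adapter from a read and apply the insert length window.

    Returns a :class:`TrimResult` whose ``sequence`` is the insert when
    accepted, else ``None`` with ``reason`` set to ``"no_adapter"`` (adapter
    not found) or ``"length"`` (insert outside ``[min_len, max_len]``).
    """
    if not adapter:
        raise ValueError("adapter sequence must be non-empty")
    seq = read.sequence if isinstance(read, RawRead) else read
    seq = seq.upper()
    adapter = adapter.upper()

    pos = seq.find(adapter)
    if pos < 0:
        # fall back: adapter prefix of >= min_overlap nt flush with the 3' end
        max_prefix = min(len(adapter) - 1, len(seq))
        for k in range(max_prefix, min_overlap - 1, -1):
            if seq.endswith(adapter[:k]):
                pos = len(seq) - k
                break
        else:
            return TrimResult(None, "no_adapter")
    insert = seq[:pos]
    if not (min_len <= len(insert) <= max_len):
        return TrimResult(None, "length")
    return TrimResult(insert)


def length_filter(
    sequences: Iterable[str],
    min_len: int = MIN_INSERT_LEN,
    max_len: int = MAX_INSERT_LEN,
) -> tuple[list[str], int]:
    """Apply only the length window (pre-trimmed inputs).  Returns the kept
    sequences and the number rejected."""
    kept, rejected = [], 0
    for seq in sequences:
        if min_len <= len(seq) <= max_len:
            kept.append(seq.upper())
        else:
            rejected += 1
    return kept, rejected


def trim_and_filter(
    reads: Iterable[RawRead],
    adapter: str,
    min_len: int = MIN_INSERT_LEN,
    max_len: int = MAX_INSERT_LEN,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[list[str], Counter]:
    """Trim a read stream; returns accepted inserts and a tally of rejection
    reasons.  ``accepted + sum(rejections) == number of input reads``."""
    accepted: list[str] = []
    rejections: Counter = Counter()
    for read in reads:
        result = trim_adapter(read, adapter, min_len, max_len, min_overlap)
        if result.accepted:
            accepted.append(result.sequence)
        else:
            rejections[result.reason] += 1
    return accepted, rejections


def collapse(sequences: Iterable[str], sample_id: str) -> SpeciesTable:
    """Collapse trimmed inserts into unique species with read counts.

    Ordering is deterministic: count descending, then lexicographic, so any
    permutation of the input stream yields an identical table.
    """
    tally = Counter(seq.upper() for seq in sequences)
    species = [
        SiRNASpecies(seq, n)
        for seq, n in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return SpeciesTable(sample_id=sample_id, species=species)


def write_species_table(table: SpeciesTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tcount\n")
        for sp in table.species:
            fh.write(f"{sp.sequence}\t{sp.count}\n")


def read_species_table(path: str | Path, sample_id: str) -> SpeciesTable:
    species = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sequence"):
            raise ValueError(f"{path}: expected 'sequence\\tcount' header")
        for line in fh:
            seq, count = line.rstrip("\n").split("\t")
            species.append(SiRNASpecies(seq, int(count)))
    species.sort(key=lambda sp: (-sp.count, sp.sequence))
    return SpeciesTable(sample_id=sample_id, species=species)
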