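"""Reference locus model: a single annotated gene region and its coordinate frame.

All coordinates at the public interface are 1-based inclusive, matching the
convention of figure annotations on single-locus references.  The locus is a
plain nucleotide sequence over {A, C, G, T} with an ordered, non-overlapping
set of named feature intervals (typically ``five_prime_upstream``, ``exon1``,
``intron``, ``exon2``, ``three_prime_downstream``).  Ambiguity codes are
rejected outright: downstream mapping is perfect-match only and IUPAC
wildcards would silently change read counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "CANONICAL_FEATURE_NAMES",
    "Feature",
    "ReferenceLocus",
    "AllelePair",
    "ReferenceError",
    "load_reference",
    "write_reference",
    "feature_of",
    "boundary_coordinate",
]

#: Feature names used by the default annotation of a silenced-gene locus.
#: Free-form labels are also accepted; these are only the canonical set.
CANONICAL_FEATURE_NAMES = (
    "five_prime_upstream",
    "exon1",
    "intron",
    "exon2",
    "three_prime_downstream",
)

_VALID_BASES = frozenset("ACGT")

#: Default mapping from GFF3 ``type`` column values to feature labels.
DEFAULT_GFF3_TYPE_MAP: Mapping[str, str] = {
    "five_prime_UTR": "five_prime_upstream",
    "exon": "exon",
    "intron": "intron",
    "three_prime_UTR": "three_prime_downstream",
}


class ReferenceError(ValueError):
    """Raised for malformed reference sequences or annotations."""


@dataclass(frozen=True, order=True)
class Feature:
    """A named interval on the locus, 1-based inclusive."""

    start: int
    end: int
    name: str = field(compare=False)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ReferenceError(
                f"feature {self.name!r}: invalid interval [{self.start}, {self.end}]"
            )

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class ReferenceLocus:
    """A validated single-record reference with its feature annotation.

    Parameters
    ----------
    id
        Accession or identifier of the sequence record.
    sequence
        Uppercase nucleotide sequence over {A, C, G, T}.
    features
        Non-overlapping, coordinate-sorted features tiling a subset of
        ``[1, L]``, with unique names.
    """

    id: str
    sequence: str
    features: tuple[Feature, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ReferenceError(f"reference {self.id!r}: empty sequence")
        bad = next(
            (i for i, b in enumerate(self.sequence) if b not in _VALID_BASES), None
        )
        if bad is not None:
            raise ReferenceError(
                f"reference {self.id!r}: non-ACGT character "
                f"{self.sequence[bad]!r} at position {bad + 1}"
            )
        L = len(self.sequence)
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ReferenceError(f"reference {self.id!r}: duplicate feature names")
        prev: Feature | None = None
        for feat in self.features:
            if feat.end > L:
                raise ReferenceError(
                    f"feature {feat.name!r}: end {feat.end} exceeds locus length {L}"
                )
            if prev is not None:
                if feat.start <= prev.end:
                    raise ReferenceError(
                        f"features {prev.name!r} and {feat.name!r} overlap or are "
                        f"unsorted ([{prev.start},{prev.end}] vs "
                        f"[{feat.start},{feat.end}])"
                    )
            prev = feat

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> Feature:
        for feat in self.features:
            if feat.name == name:
                return feat
        raise KeyError(f"no feature named {name!r} on reference {self.id!r}")

    def slice(self, start: int, end: int) -> str:
        """Subsequence by 1-based inclusive coordinates."""
        if not (1 <= start <= end <= self.length):
            raise ReferenceError(f"slice [{start}, {end}] outside [1, {self.length}]")
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class AllelePair:
    """Two alleles of the same gene (e.g. endogene and transgene) whose
    sequence divergence makes some siRNA species allele-diagnostic."""

    reference_a: ReferenceLocus
    reference_b: ReferenceLocus
    label_a: str = "allele_a"
    label_b: str = "allele_b"

    def __post_init__(self) -> None:
        if self.reference_a.sequence == self.reference_b.sequence:
            raise ReferenceError(
                "allele pair sequences are identical; no diagnostic positions"
            )


def _parse_tsv_annotation(path: Path) -> list[Feature]:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ReferenceError(
                    f"{path}:{lineno}: expected 3 columns (name, start, end)"
                )
            name, start, end = parts[0], parts[1], parts[2]
            try:
                feats.append(Feature(int(start), int(end), name))
            except ValueError as exc:
                raise ReferenceError(f"{path}:{lineno}: {exc}") from exc
    return feats


def _parse_gff3_annotation(
    path: Path, seqid: str, type_map: Mapping[str, str] | None
) -> list[Feature]:
    type_map = dict(DEFAULT_GFF3_TYPE_MAP if type_map is None else type_map)
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ReferenceError(f"{path}:{lineno}: expected 9 GFF3 columns")
            rec_seqid, _source, ftype, start, end, _score, _strand, _phase, attrs = cols
            if rec_seqid != seqid:
                raise ReferenceError(
                    f"{path}:{lineno}: seqid {rec_seqid!r} does not match "
                    f"reference id {seqid!r}"
                )
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            name = attr_map.get("Name") or type_map.get(ftype, ftype)
            feats.append(Feature(int(start), int(end), name))
    return feats


def load_reference(
    fasta_path: str | Path,
    annotation_path: str | Path | None = None,
    dialect: str = "auto",
    gff3_type_map: Mapping[str, str] | None = None,
) -> ReferenceLocus:
    """Load and validate a single-record FASTA plus its feature annotation.

    ``dialect`` is ``"tsv"`` (3 columns: name, start, end), ``"gff3"``, or
    ``"auto"`` (by file extension).  The sequence is uppercased; ambiguity
    codes raise :class:`ReferenceError` naming the offending position.
    """
    fasta_path = Path(fasta_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ReferenceError(
            f"{fasta_path}: expected exactly one record, found {len(records)}"
        )
    rec = records[0]
    seq = str(rec.seq).upper()

    features: list[Feature] = []
    if annotation_path is not None:
        annotation_path = Path(annotation_path)
        if dialect == "auto":
            dialect = "gff3" if annotation_path.suffix.lower() in (".gff", ".gff3") else "tsv"
        if dialect == "tsv":
            features = _parse_tsv_annotation(annotation_path)
        elif dialect == "gff3":
            features = _parse_gff3_annotation(annotation_path, rec.id, gff3_type_map)
        else:
            raise ReferenceError(f"unknown annotation dialect {dialect!r}")
        features.sort()

    return ReferenceLocus(id=rec.id, sequence=seq, features=tuple(features))


def write_reference(
    locus: ReferenceLocus, fasta_path: str | Path, annotation_path: str | Path
) -> None:
    """Write a locus back out as FASTA + 3-column TSV (round-trips with
    :func:`load_reference`)."""
    with open(fasta_path, "w") as fh:
        fh.write(f">{locus.id}\n")
        for i in range(0, locus.length, 70):
            fh.write(locus.sequence[i : i + 70] + "\n")
    with open(annotation_path, "w") as fh:
        fh.write("# name\tstart\tend\n")
        for feat in locus.features:
            fh.write(f"{feat.name}\t{feat.start}\t{feat.end}\n")


def feature_of(locus: ReferenceLocus, position: int) -> str:
    """Name of the feature containing ``position`` (1-based), or
    ``"unannotated"`` for in-range positions outside every feature."""
    if not (1 <= position <= locus.length):
        raise ReferenceError(
            f"position {position} outside [1, {locus.length}] on {locus.id!r}"
        )
    for feat in locus.features:
        if position in feat:
            return feat.name
        if position < feat.start:
            break
    return "unannotated"


def boundary_coordinate(
    locus: ReferenceLocus, upstream_feature: str, downstream_feature: str
) -> int:
    """1-based coordinate of the first base of ``downstream_feature``,
    provided the two features are strictly adjacent."""
    up = locus.feature(upstream_feature)
    down = locus.feature(downstream_feature)
    if up.end + 1 != down.start:
        raise ReferenceError(
            f"features {upstream_feature!r} (ends {up.end}) and "
            f"{downstream_feature!r} (starts {down.start}) are not adjacent"
        )
    return down.start
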