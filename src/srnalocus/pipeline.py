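"""End-to-end orchestration: trim -> map -> profile -> compare -> phasing.

A run is described by a single YAML/TOML-style mapping (see
:class:`RunConfig`); ``run`` composes the library stages in order and writes
a machine-readable report bundle of TSV tables plus a JSON summary, each
stamped with the config hash so identical configs provably produce identical
tables.  Optional stages (allele classification without a second reference,
pairwise comparison without pairs) are skipped with a logged warning;
missing required inputs abort.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import commonality, phasing, profiling
from .mapping import MULTIMAP_POLICIES, STRANDS, MappedSet, map_table, strand_read_totals, write_mapped_tsv
from .reads import collapse, length_filter, read_reads, trim_and_filter, write_species_table
from .reference import AllelePair, ReferenceLocus, load_reference

__all__ = ["ConfigError", "SampleConfig", "RunConfig", "validate_config", "run", "ReportBundle"]

logger = logging.getLogger("srnalocus")

_RUN_KEYS = {
    "samples",
    "reference",
    "allele_b",
    "pairs",
    "adapter",
    "pre_trimmed",
    "min_len",
    "max_len",
    "min_overlap",
    "min_reads_exclusive",
    "min_units",
    "size_range",
    "n_phases",
    "window_cycles",
    "multimap_policy",
    "boundary",
    "outdir",
    "seed",
    "log_level",
}
_SAMPLE_KEYS = {"id", "reads", "format"}
_REFERENCE_KEYS = {"fasta", "annotation", "dialect"}


class ConfigError(ValueError):
    """Raised with the collected list of configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass(frozen=True)
class SampleConfig:
    id: str
    reads: str
    format: str | None = None


@dataclass(frozen=True)
class RunConfig:
    samples: tuple[SampleConfig, ...]
    reference_fasta: str
    reference_annotation: str | None = None
    reference_dialect: str = "auto"
    allele_b_fasta: str | None = None
    allele_b_label: str = "allele_b"
    pairs: tuple[tuple[str, str], ...] = ()
    adapter: str | None = None
    pre_trimmed: bool = False
    min_len: int = 15
    max_len: int = 45
    min_overlap: int = 7
    min_reads_exclusive: int = 5
    min_units: int = 3
    size_range: tuple[int, int] = (18, 25)
    n_phases: int = 21
    window_cycles: int = 9
    multimap_policy: str = "all"
    boundary: tuple[str, str] = ("intron", "exon2")
    outdir: str = "srnalocus_out"
    seed: int = 0
    log_level: str = "INFO"

    def canonical(self) -> dict:
        d = dataclasses.asdict(self)
        d["samples"] = [dataclasses.asdict(s) for s in self.samples]
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(source: str | Path | dict) -> RunConfig:
    """Normalize a YAML file or mapping into a :class:`RunConfig`, rejecting
    unknown keys, bad types and missing required fields; all problems are
    collected into one :class:`ConfigError`."""
    if not isinstance(source, dict):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    if not isinstance(source, dict):
        raise ConfigError(["config root must be a mapping"])
    errors: list[str] = []
    for key in source:
        if key not in _RUN_KEYS:
            errors.append(f"unknown key {key!r}")

    samples: list[SampleConfig] = []
    for i, entry in enumerate(source.get("samples", []) or []):
        unknown = set(entry) - _SAMPLE_KEYS
        if unknown:
            errors.append(f"samples[{i}]: unknown keys {sorted(unknown)}")
        if "id" not in entry or "reads" not in entry:
            errors.append(f"samples[{i}]: requires 'id' and 'reads'")
            continue
        samples.append(
            SampleConfig(str(entry["id"]), str(entry["reads"]), entry.get("format"))
        )
    if not samples:
        errors.append("at least one sample is required")

    ref = source.get("reference") or {}
    unknown = set(ref) - _REFERENCE_KEYS
    if unknown:
        errors.append(f"reference: unknown keys {sorted(unknown)}")
    if "fasta" not in ref:
        errors.append("reference.fasta is required")

    kwargs: dict = {}
    for key, cast in (
        ("min_len", int),
        ("max_len", int),
        ("min_overlap", int),
        ("min_reads_exclusive", int),
        ("min_units", int),
        ("n_phases", int),
        ("window_cycles", int),
        ("seed", int),
    ):
        if key in source:
            try:
                value = cast(source[key])
            except (TypeError, ValueError):
                errors.append(f"{key}: expected an integer")
                continue
            if key != "seed" and value <= 0:
                errors.append(f"{key}: must be positive, got {value}")
            kwargs[key] = value
    if "size_range" in source:
        sr = source["size_range"]
        if not (isinstance(sr, (list, tuple)) and len(sr) == 2):
            errors.append("size_range: expected [lo, hi]")
        else:
            kwargs["size_range"] = (int(sr[0]), int(sr[1]))
    if "multimap_policy" in source:
        if source["multimap_policy"] not in MULTIMAP_POLICIES:
            errors.append(
                f"multimap_policy: expected one of {MULTIMAP_POLICIES}"
            )
        else:
            kwargs["multimap_policy"] = source["multimap_policy"]
    if "boundary" in source:
        b = source["boundary"]
        if not (isinstance(b, (list, tuple)) and len(b) == 2):
            errors.append("boundary: expected [upstream, downstream]")
        else:
            kwargs["boundary"] = (str(b[0]), str(b[1]))
    if "pairs" in source:
        pairs = []
        for i, pair in enumerate(source["pairs"] or []):
            if not (isinstance(pair, (list, tuple)) and len(pair) == 2):
                errors.append(f"pairs[{i}]: expected [sample_a, sample_b]")
            else:
                pairs.append((str(pair[0]), str(pair[1])))
        kwargs["pairs"] = tuple(pairs)
    if "pre_trimmed" in source:
        kwargs["pre_trimmed"] = bool(source["pre_trimmed"])
    if "adapter" in source and source["adapter"] is not None:
        kwargs["adapter"] = str(source["adapter"])
    allele = source.get("allele_b")
    if allele:
        if "fasta" not in allele:
            errors.append("allele_b.fasta is required when allele_b is given")
        else:
            kwargs["allele_b_fasta"] = str(allele["fasta"])
            kwargs["allele_b_label"] = str(allele.get("label", "allele_b"))
    for key in ("outdir", "log_level"):
        if key in source:
            kwargs[key] = str(source[key])

    if not kwargs.get("pre_trimmed", False) and "adapter" not in kwargs:
        errors.append("adapter is required unless pre_trimmed is true")

    if errors:
        raise ConfigError(errors)

    return RunConfig(
        samples=tuple(samples),
        reference_fasta=str(ref["fasta"]),
        reference_annotation=ref.get("annotation"),
        reference_dialect=ref.get("dialect", "auto"),
        **kwargs,
    )


@dataclass
class SampleReport:
    sample_id: str
    accounting: dict
    mapped: MappedSet
    size_distribution: pd.DataFrame
    feature_confinement: pd.DataFrame
    boundary: pd.DataFrame | None
    alleles: pd.DataFrame | None


@dataclass
class PairReport:
    sample_a: str
    sample_b: str
    commonality: dict[str, pd.DataFrame]  # per strand
    phase_summaries: dict[str, pd.DataFrame]  # per sample
    end_conservation: pd.DataFrame


@dataclass
class ReportBundle:
    config: RunConfig
    locus: ReferenceLocus
    sample_reports: dict[str, SampleReport]
    pair_reports: list[PairReport]

    @property
    def config_hash(self) -> str:
        return self.config.config_hash


def _process_sample(config: RunConfig, sample: SampleConfig, locus: ReferenceLocus) -> SampleReport:
    reads = read_reads(sample.reads, sample.format)
    if config.pre_trimmed:
        inserts, n_rejected = length_filter(
            (r.sequence for r in reads), config.min_len, config.max_len
        )
        rejections = {"length": n_rejected}
    else:
        inserts, counter = trim_and_filter(
            reads, config.adapter, config.min_len, config.max_len, config.min_overlap
        )
        rejections = dict(counter)
    table = collapse(inserts, sample.id)
    mapped = map_table(table, locus, config.multimap_policy)
    sense, anti, total = strand_read_totals(mapped)
    accounting = {
        "input_reads": len(inserts) + sum(rejections.values()),
        "accepted_reads": len(inserts),
        "rejected": rejections,
        "n_species": table.n_species,
        "mapped_reads_sense": sense,
        "mapped_reads_antisense": anti,
        "mapped_reads_total": total,
        "unmapped_species": mapped.unmapped_species,
        "unmapped_reads": mapped.unmapped_reads,
    }
    logger.info(
        "sample %s: input=%d accepted=%d rejected=%s mapped=%g unmapped=%d",
        sample.id,
        accounting["input_reads"],
        accounting["accepted_reads"],
        rejections,
        total,
        mapped.unmapped_reads,
    )

    size_df = profiling.size_distribution(mapped, config.size_range).to_frame()
    confinement = profiling.feature_confinement(mapped, locus)
    boundary_df = None
    feature_names = {f.name for f in locus.features}
    if set(config.boundary) <= feature_names:
        boundary_df = profiling.boundary_distances(mapped, locus, config.boundary).to_frame()
    else:
        logger.warning(
            "sample %s: boundary features %s absent from annotation; skipping",
            sample.id,
            config.boundary,
        )

    alleles_df = None
    if config.allele_b_fasta:
        ref_b = load_reference(config.allele_b_fasta)
        pair = AllelePair(locus, ref_b, locus.id, config.allele_b_label)
        alleles_df = profiling.classify_alleles(table, pair).to_frame()

    return SampleReport(
        sample_id=sample.id,
        accounting=accounting,
        mapped=mapped,
        size_distribution=size_df,
        feature_confinement=confinement,
        boundary=boundary_df,
        alleles=alleles_df,
    )


def _process_pair(config: RunConfig, rep_a: SampleReport, rep_b: SampleReport) -> PairReport:
    commonality_frames = {}
    for strand in STRANDS:
        try:
            report = commonality.compare_samples(
                rep_a.mapped,
                rep_b.mapped,
                length=21,
                strand=strand,
                min_reads_exclusive=config.min_reads_exclusive,
            )
            commonality_frames[strand] = report.to_frame()
        except ValueError as exc:
            logger.warning(
                "pair %s/%s strand %s: commonality skipped (%s)",
                rep_a.sample_id,
                rep_b.sample_id,
                strand,
                exc,
            )
    regions = {}
    summaries = {}
    for rep in (rep_a, rep_b):
        regs = []
        for strand in STRANDS:
            regs.extend(
                phasing.call_phased_regions(
                    rep.mapped, strand, config.min_units, unit=config.n_phases
                )
            )
        regions[rep.sample_id] = regs
        summaries[rep.sample_id] = phasing.phase_summary(regs, unit=config.n_phases)
    conservation = phasing.end_conservation(
        regions[rep_a.sample_id], regions[rep_b.sample_id]
    )
    rows = [
        {
            "strand": strand,
            "n_regions_b": conservation.n_regions_b[strand],
            "conserved_five_prime": conservation.conserved_five_prime[strand],
            "conserved_three_prime": conservation.conserved_three_prime[strand],
        }
        for strand in STRANDS
    ]
    return PairReport(
        sample_a=rep_a.sample_id,
        sample_b=rep_b.sample_id,
        commonality=commonality_frames,
        phase_summaries=summaries,
        end_conservation=pd.DataFrame(rows),
    )


def _write_bundle(bundle: ReportBundle) -> None:
    outdir = Path(bundle.config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = bundle.config_hash
    header = f"# config_hash={chash}\n"

    def dump(df: pd.DataFrame, path: Path) -> None:
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)

    summary: dict = {"config_hash": chash, "samples": {}, "pairs": []}
    for sid, rep in bundle.sample_reports.items():
        sdir = outdir / sid
        sdir.mkdir(exist_ok=True)
        dump(rep.size_distribution, sdir / "size_distribution.tsv")
        dump(rep.feature_confinement, sdir / "feature_confinement.tsv")
        if rep.boundary is not None:
            with open(sdir / "boundary_distances.tsv", "w") as fh:
                fh.write(header)
                fh.write(f"# rule: {profiling.BOUNDARY_RULE}\n")
                rep.boundary.to_csv(fh, sep="\t", index=False)
        if rep.alleles is not None:
            dump(rep.alleles, sdir / "allele_classification.tsv")
        write_mapped_tsv(rep.mapped, sdir / "alignments.tsv")
        for length in (21, 22, 23, 24):
            for strand in STRANDS:
                track = profiling.position_track(rep.mapped, length, strand)
                if track.total > 0:
                    profiling.write_position_track_bedgraph(
                        track, bundle.locus.id, sdir / f"track_{length}nt_{strand}.tsv"
                    )
        summary["samples"][sid] = rep.accounting
    for pair in bundle.pair_reports:
        pdir = outdir / f"{pair.sample_a}_vs_{pair.sample_b}"
        pdir.mkdir(exist_ok=True)
        for strand, df in pair.commonality.items():
            dump(df, pdir / f"commonality_{strand}.tsv")
        for sid, df in pair.phase_summaries.items():
            dump(df, pdir / f"phase_summary_{sid}.tsv")
        dump(pair.end_conservation, pdir / "end_conservation.tsv")
        summary["pairs"].append(
            {"sample_a": pair.sample_a, "sample_b": pair.sample_b}
        )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


def run(config: RunConfig, write: bool = True) -> ReportBundle:
    """Execute the full pipeline under one config; returns the in-memory
    bundle and (by default) writes the TSV/JSON report tree to
    ``config.outdir``."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    locus = load_reference(
        config.reference_fasta, config.reference_annotation, config.reference_dialect
    )
    sample_reports = {
        s.id: _process_sample(config, s, locus) for s in config.samples
    }
    pair_reports = []
    for id_a, id_b in config.pairs:
        if id_a not in sample_reports or id_b not in sample_reports:
            raise ConfigError([f"pair ({id_a}, {id_b}) references unknown sample ids"])
        pair_reports.append(
            _process_pair(config, sample_reports[id_a], sample_reports[id_b])
        )
    bundle = ReportBundle(config, locus, sample_reports, pair_reports)
    if write:
        _write_bundle(bundle)
    return bundle
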