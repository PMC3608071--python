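"""Cross-sample commonality of siRNA species abundances.

Given two mapped libraries, the analysis (for one length class and strand,
typically 21-nt) is:

1. per-species read counts, species with more than ``min_reads_exclusive``
   reads retained (">5 reads" means strictly greater, i.e. count >= 6);
2. abundance ranking, most abundant = rank 1, average ranks for ties;
3. coverage: value A = total reads of the class, value B = reads belonging
   to above-threshold species, coverage = B / A;
4. top-N overlap: how many of sample A's N most abundant species appear in
   sample B, and within B's top how-many;
5. Spearman rank correlation r_s over the species passing the threshold in
   BOTH samples (re-ranked within that common set by default; restricting
   each sample's global ranks to the common set is available as a mode).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mapping import MappedSet

__all__ = [
    "DEFAULT_MIN_READS_EXCLUSIVE",
    "RankedSpecies",
    "TopNOverlap",
    "CommonalityReport",
    "InsufficientCommonSpeciesError",
    "rank_species",
    "coverage_fraction",
    "coverage_ratio",
    "top_n_overlap",
    "spearman_rank_correlation",
    "spearman_p_value",
    "compare_samples",
]

DEFAULT_MIN_READS_EXCLUSIVE = 5


class InsufficientCommonSpeciesError(ValueError):
    """Raised when fewer than 3 species are common to both samples."""


@dataclass(frozen=True)
class RankedSpecies:
    sequence: str
    strand: str
    count: int
    rank: float  # 1 = most abundant; average ranks for ties


@dataclass
class TopNOverlap:
    """For each of sample A's top-n species: its ordinal position in B.

    ``k`` is the deepest ordinal position in B among the found species, i.e.
    "m of n found within B's top k".  Ordinal positions break count ties
    lexicographically for determinism.
    """

    n: int
    m_found: int
    k: int | None
    entries: list[dict] = field(default_factory=list)


@dataclass
class CommonalityReport:
    sample_a: str
    sample_b: str
    length: int
    strand: str
    min_reads_exclusive: int
    value_a: dict[str, int]  # per sample: total reads of the class
    value_b: dict[str, int]  # per sample: reads in above-threshold species
    coverage: dict[str, float | None]
    n_species: dict[str, int]
    n_above_threshold: dict[str, int]
    n_common_above_threshold: int
    spearman_rs: float | None
    spearman_p: float | None
    top_n: TopNOverlap | None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sample in (self.sample_a, self.sample_b):
            rows.append(
                {
                    "sample": sample,
                    "length": self.length,
                    "strand": self.strand,
                    "value_a": self.value_a[sample],
                    "value_b": self.value_b[sample],
                    "coverage": self.coverage[sample],
                    "n_species": self.n_species[sample],
                    "n_above_threshold": self.n_above_threshold[sample],
                    "n_common_above_threshold": self.n_common_above_threshold,
                    "spearman_rs": self.spearman_rs,
                    "spearman_p": self.spearman_p,
                }
            )
        return pd.DataFrame(rows)


def _ranked(counts: dict[str, int], strand: str) -> list[RankedSpecies]:
    if not counts:
        return []
    seqs = sorted(counts)
    values = np.array([counts[s] for s in seqs], dtype=float)
    ranks = stats.rankdata(-values, method="average")
    ranked = [
        RankedSpecies(seq, strand, int(counts[seq]), float(r))
        for seq, r in zip(seqs, ranks)
    ]
    ranked.sort(key=lambda rs: (rs.rank, rs.sequence))
    return ranked


def rank_species(
    mapped: MappedSet,
    length: int = 21,
    strand: str = "sense",
    min_reads_exclusive: int = DEFAULT_MIN_READS_EXCLUSIVE,
) -> list[RankedSpecies]:
    """Abundance-ranked species of one (length, strand) class with count
    strictly greater than ``min_reads_exclusive`` (pass 0 for the full
    unfiltered list).  Ties receive average ranks."""
    counts = mapped.species_counts(length, strand)
    kept = {s: c for s, c in counts.items() if c > min_reads_exclusive}
    return _ranked(kept, strand)


def coverage_ratio(value_a: int | float, value_b: int | float) -> float:
    """value B / value A rounded to 3 decimals (the scale used in reports)."""
    if value_a <= 0:
        raise ZeroDivisionError("value A must be positive")
    return round(value_b / value_a, 3)


def coverage_fraction(
    mapped: MappedSet,
    length: int = 21,
    strand: str = "sense",
    min_reads_exclusive: int = DEFAULT_MIN_READS_EXCLUSIVE,
) -> tuple[int, int, float | None]:
    """(value A, value B, B / A) for one (length, strand) class: total class
    reads vs reads in species above the threshold.  Ratio is ``None`` when
    the class is empty."""
    counts = mapped.species_counts(length, strand)
    value_a = sum(counts.values())
    value_b = sum(c for c in counts.values() if c > min_reads_exclusive)
    ratio = coverage_ratio(value_a, value_b) if value_a > 0 else None
    return value_a, value_b, ratio


def _ordinal_positions(ranked: list[RankedSpecies]) -> dict[str, int]:
    ordered = sorted(ranked, key=lambda rs: (-rs.count, rs.sequence))
    return {rs.sequence: i + 1 for i, rs in enumerate(ordered)}


def top_n_overlap(
    ranked_a: list[RankedSpecies],
    ranked_b: list[RankedSpecies],
    n: int = 20,
) -> TopNOverlap:
    """How many of A's n most abundant species occur in B, and how deep in
    B's ranking they reach."""
    if not ranked_a or not ranked_b:
        raise ValueError("both rankings must be nonempty")
    if n > len(ranked_a):
        n = len(ranked_a)
    pos_a = _ordinal_positions(ranked_a)
    pos_b = _ordinal_positions(ranked_b)
    top_a = sorted(pos_a, key=pos_a.get)[:n]
    entries = []
    found_positions = []
    for seq in top_a:
        in_b = pos_b.get(seq)
        entries.append({"sequence": seq, "position_a": pos_a[seq], "position_b": in_b})
        if in_b is not None:
            found_positions.append(in_b)
    k = max(found_positions) if found_positions else None
    return TopNOverlap(n=n, m_found=len(found_positions), k=k, entries=entries)


def spearman_rank_correlation(
    ranked_a: list[RankedSpecies],
    ranked_b: list[RankedSpecies],
    common_only: bool = True,
    mode: str = "rerank",
) -> tuple[float, int]:
    """Spearman r_s between two samples' species abundances.

    ``mode="rerank"`` (default): species above threshold in both samples are
    re-ranked within the common set and r_s computed on those ranks.
    ``mode="global"``: each sample's global (threshold-filtered) ranks are
    restricted to the common set and correlated as-is.
    Raises :class:`InsufficientCommonSpeciesError` below 3 common species.
    """
    a = {rs.sequence: rs for rs in ranked_a}
    b = {rs.sequence: rs for rs in ranked_b}
    common = sorted(set(a) & set(b)) if common_only else sorted(set(a) | set(b))
    n = len(common)
    if n < 3:
        raise InsufficientCommonSpeciesError(
            f"insufficient common species ({n} < 3)"
        )
    if mode == "rerank":
        x = np.array([a[s].count for s in common], dtype=float)
        y = np.array([b[s].count for s in common], dtype=float)
        rs = float(stats.spearmanr(x, y).statistic)
    elif mode == "global":
        x = np.array([a[s].rank for s in common])
        y = np.array([b[s].rank for s in common])
        rs = float(stats.pearsonr(x, y).statistic)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return rs, n


def spearman_p_value(rs: float, n: int) -> float:
    """Two-sided p for r_s: exact permutation enumeration for n <= 8, else
    the t approximation with n - 2 degrees of freedom."""
    if n < 3:
        raise ValueError("need n >= 3")
    if n <= 8:
        base = np.arange(1, n + 1, dtype=float)
        obs = abs(rs)
        hits = total = 0
        for perm in itertools.permutations(base):
            r = float(stats.pearsonr(base, np.array(perm)).statistic)
            total += 1
            if abs(r) >= obs - 1e-12:
                hits += 1
        return hits / total
    t = rs * math.sqrt((n - 2) / max(1e-12, 1.0 - rs * rs))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def compare_samples(
    mapped_a: MappedSet,
    mapped_b: MappedSet,
    length: int = 21,
    strand: str = "sense",
    min_reads_exclusive: int = DEFAULT_MIN_READS_EXCLUSIVE,
    n_top: int = 20,
    mode: str = "rerank",
) -> CommonalityReport:
    """Full pairwise commonality report for one (length, strand) class."""
    reports: dict[str, dict] = {}
    ranked: dict[str, list[RankedSpecies]] = {}
    for mapped in (mapped_a, mapped_b):
        counts = mapped.species_counts(length, strand)
        va = sum(counts.values())
        vb = sum(c for c in counts.values() if c > min_reads_exclusive)
        ranked[mapped.sample_id] = rank_species(
            mapped, length, strand, min_reads_exclusive
        )
        reports[mapped.sample_id] = {
            "value_a": va,
            "value_b": vb,
            "coverage": coverage_ratio(va, vb) if va > 0 else None,
            "n_species": len(counts),
            "n_above_threshold": sum(1 for c in counts.values() if c > min_reads_exclusive),
        }
    ra, rb = ranked[mapped_a.sample_id], ranked[mapped_b.sample_id]
    try:
        rs, n_common = spearman_rank_correlation(ra, rb, mode=mode)
        p = spearman_p_value(rs, n_common)
    except InsufficientCommonSpeciesError:
        rs, p = None, None
        n_common = len({x.sequence for x in ra} & {x.sequence for x in rb})
    top = top_n_overlap(ra, rb, n_top) if ra and rb else None
    return CommonalityReport(
        sample_a=mapped_a.sample_id,
        sample_b=mapped_b.sample_id,
        length=length,
        strand=strand,
        min_reads_exclusive=min_reads_exclusive,
        value_a={s: reports[s]["value_a"] for s in reports},
        value_b={s: reports[s]["value_b"] for s in reports},
        coverage={s: reports[s]["coverage"] for s in reports},
        n_species={s: reports[s]["n_species"] for s in reports},
        n_above_threshold={s: reports[s]["n_above_threshold"] for s in reports},
        n_common_above_threshold=n_common,
        spearman_rs=rs,
        spearman_p=p,
        top_n=top,
    )
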