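"""Phased-siRNA detection in 21 registers on both strands.

A 21-nt siRNA population processed by successive Dicer cuts from a fixed
entry point leaves 5' ends at 21-nt intervals.  Each strand of the locus is
therefore partitioned into 21 phase registers: phase 1 is anchored at the
first reference base for the sense strand and at the last reference base for
the antisense strand, and a register's *cycle positions* are the arithmetic
progression of 5'-end coordinates with step 21 (ascending for sense,
descending for antisense, i.e. in the strand's own 5'->3' order).

A cycle position is *occupied* when at least one read of a 21-nt siRNA has
its 5' end exactly there.  A *phased region* is a maximal run of >= 3
consecutive occupied cycle positions in one register; its span is
21 x n_units nt.  Phasing scores over a sliding window of 9 cycles follow
the log-odds form of Howell et al. (2007):

    score = ln[(1 + 10 * P / (1 + U)) ** (k - 2)]   for k >= 3, else 0

with P the in-phase read total, U the out-of-phase read total within the
window footprint, and k the number of occupied in-phase cycle positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mapping import ANTISENSE, SENSE, STRANDS, MappedSet

__all__ = [
    "DEFAULT_UNIT",
    "DEFAULT_MIN_UNITS",
    "DEFAULT_WINDOW_CYCLES",
    "PhasedRegion",
    "PhasingScoreTrack",
    "EndConservationReport",
    "phase_of",
    "cycle_positions",
    "five_prime_read_counts",
    "occupancy",
    "call_phased_regions",
    "phasing_score",
    "end_conservation",
    "phase_summary",
]

DEFAULT_UNIT = 21
DEFAULT_MIN_UNITS = 3
DEFAULT_WINDOW_CYCLES = 9
DEFAULT_SCORE_FACTOR = 10.0


def phase_of(coord: int, strand: str, L: int, unit: int = DEFAULT_UNIT) -> int:
    """Phase register (1..unit) of a 5'-end coordinate.

    Sense: phase 1 anchored at coordinate 1.  Antisense: phase 1 anchored at
    coordinate L (registers advance in the strand's 5'->3' direction).
    """
    if not (1 <= coord <= L):
        raise ValueError(f"coordinate {coord} outside [1, {L}]")
    if strand == SENSE:
        return (coord - 1) % unit + 1
    if strand == ANTISENSE:
        return (L - coord) % unit + 1
    raise ValueError(f"unknown strand {strand!r}")


def cycle_positions(
    strand: str, phase: int, L: int, unit: int = DEFAULT_UNIT
) -> list[int]:
    """5'-end coordinates of one register in cycle order (sense ascending
    from the 5' anchor; antisense descending from coordinate L)."""
    if not (1 <= phase <= unit):
        raise ValueError(f"phase {phase} outside [1, {unit}]")
    if strand == SENSE:
        return list(range(phase, L + 1, unit))
    if strand == ANTISENSE:
        return list(range(L - phase + 1, 0, -unit))
    raise ValueError(f"unknown strand {strand!r}")


@dataclass(frozen=True)
class PhasedRegion:
    """Maximal run of consecutive occupied cycle positions in one register.

    ``first_unit_coord`` / ``last_unit_coord`` are the 5'-end coordinates of
    the strand-wise first (most 5') and last (most 3') occupied units; for
    antisense regions the first unit is therefore the *rightmost*.
    """

    strand: str
    phase: int
    first_unit_coord: int
    last_unit_coord: int
    n_units: int
    unit: int = DEFAULT_UNIT

    @property
    def span(self) -> int:
        """Nucleotide span covered by the region: unit x n_units."""
        return self.unit * self.n_units

    @property
    def five_prime_coord(self) -> int:
        return self.first_unit_coord

    @property
    def three_prime_coord(self) -> int:
        """Terminal base of the last unit (strand-wise 3' extremity)."""
        if self.strand == SENSE:
            return self.last_unit_coord + self.unit - 1
        return self.last_unit_coord - self.unit + 1

    @property
    def left(self) -> int:
        """Leftmost absolute coordinate covered."""
        return self.first_unit_coord if self.strand == SENSE else self.three_prime_coord

    @property
    def right(self) -> int:
        """Rightmost absolute coordinate covered."""
        return self.three_prime_coord if self.strand == SENSE else self.first_unit_coord


@dataclass
class PhasingScoreTrack:
    """Scores assigned to cycle positions, one value per reference
    coordinate (each coordinate belongs to exactly one register)."""

    sample_id: str
    strand: str
    window_cycles: int
    unit: int
    scores: np.ndarray  # length L; score of the window anchored at each coord

    def at(self, coordinate: int) -> float:
        return float(self.scores[coordinate - 1])


@dataclass
class EndConservationReport:
    """How many of sample B's phased regions have a 5' (resp. 3') end at the
    exact coordinate of some same-strand region end in sample A."""

    n_regions_b: dict[str, int]
    conserved_five_prime: dict[str, int]
    conserved_three_prime: dict[str, int]
    matched_five_prime: dict[str, list[int]] = field(default_factory=dict)
    matched_three_prime: dict[str, list[int]] = field(default_factory=dict)


def five_prime_read_counts(
    mapped: MappedSet, strand: str, length: int = DEFAULT_UNIT
) -> dict[int, float]:
    """Total reads whose 5' end sits at each coordinate, for one
    (length, strand) class.  Presence/absence logic only needs > 0, so the
    full per-placement count is used."""
    out: dict[int, float] = {}
    for aln in mapped.iter_class(length, strand):
        out[aln.five_prime] = out.get(aln.five_prime, 0.0) + aln.count
    return out


def occupancy(
    mapped: MappedSet,
    strand: str,
    phase: int,
    length: int = DEFAULT_UNIT,
    unit: int = DEFAULT_UNIT,
    min_depth: float = 1,
) -> list[tuple[int, float]]:
    """Occupied cycle positions of one register, in cycle order, with read
    counts.  A position is occupied when reads with a 5' end exactly there
    total at least ``min_depth`` (default 1 read: presence/absence)."""
    depth = five_prime_read_counts(mapped, strand, length)
    return [
        (c, depth[c])
        for c in cycle_positions(strand, phase, mapped.locus_length, unit)
        if depth.get(c, 0.0) >= min_depth
    ]


def call_phased_regions(
    mapped: MappedSet,
    strand: str,
    min_units: int = DEFAULT_MIN_UNITS,
    length: int = DEFAULT_UNIT,
    unit: int = DEFAULT_UNIT,
    min_depth: float = 1,
) -> list[PhasedRegion]:
    """Maximal runs of >= ``min_units`` consecutive occupied cycle positions,
    over all registers of one strand, sorted by (phase, first unit)."""
    depth = five_prime_read_counts(mapped, strand, length)
    regions: list[PhasedRegion] = []
    for phase in range(1, unit + 1):
        cycles = cycle_positions(strand, phase, mapped.locus_length, unit)
        run: list[int] = []
        for coord in cycles + [None]:  # sentinel flushes the last run
            if coord is not None and depth.get(coord, 0.0) >= min_depth:
                run.append(coord)
                continue
            if len(run) >= min_units:
                regions.append(
                    PhasedRegion(
                        strand=strand,
                        phase=phase,
                        first_unit_coord=run[0],
                        last_unit_coord=run[-1],
                        n_units=len(run),
                        unit=unit,
                    )
                )
            run = []
    regions.sort(key=lambda r: (r.phase, r.first_unit_coord))
    return regions


def window_score(P: float, U: float, k: int, factor: float = DEFAULT_SCORE_FACTOR) -> float:
    """Score of a single window: ln[(1 + factor*P/(1+U))^(k-2)] for k >= 3,
    else 0.  P/U are in-phase/out-of-phase read totals, k the number of
    occupied in-phase cycle positions."""
    if k < 3:
        return 0.0
    return (k - 2) * math.log(1.0 + factor * P / (1.0 + U))


def phasing_score(
    mapped: MappedSet,
    strand: str,
    window_cycles: int = DEFAULT_WINDOW_CYCLES,
    length: int = DEFAULT_UNIT,
    unit: int = DEFAULT_UNIT,
    factor: float = DEFAULT_SCORE_FACTOR,
) -> PhasingScoreTrack:
    """Sliding-window phasing scores for one strand.

    For each register, a window of ``window_cycles`` consecutive cycles
    slides one cycle at a time; its footprint is the ``window_cycles x
    unit`` nt it covers.  Within the footprint, P sums reads at in-phase
    cycle positions, U sums reads at every other position, and k counts
    occupied in-phase cycles; the window's score is
    ln[(1 + factor * P / (1 + U)) ** (k - 2)] when k >= 3, else 0.  Each
    cycle position is assigned the best score among the windows covering
    it, so every position of a clean phased run scores positive.
    """
    L = mapped.locus_length
    depth = five_prime_read_counts(mapped, strand, length)
    dense = np.zeros(L, dtype=float)
    for coord, v in depth.items():
        dense[coord - 1] = v
    cum = np.concatenate([[0.0], np.cumsum(dense)])  # cum[i] = sum of coords 1..i

    def range_total(lo: int, hi: int) -> float:
        return float(cum[hi] - cum[lo - 1])

    scores = np.zeros(L, dtype=float)
    w = window_cycles
    for phase in range(1, unit + 1):
        cycles = cycle_positions(strand, phase, L, unit)
        m = len(cycles)
        if m == 0:
            continue
        vals = np.array([depth.get(c, 0.0) for c in cycles])
        occ = vals > 0
        for i in range(m):
            j = min(m, i + w)  # window cycles i..j-1
            c_first, c_last = cycles[i], cycles[j - 1]
            lo, hi = (c_first, min(L, c_last + unit - 1)) if strand == SENSE else (
                max(1, c_last - unit + 1),
                c_first,
            )
            P = float(vals[i:j].sum())
            k = int(occ[i:j].sum())
            U = range_total(lo, hi) - P
            s = window_score(P, U, k, factor)
            if s > 0.0:
                for c in cycles[i:j]:
                    if s > scores[c - 1]:
                        scores[c - 1] = s
    return PhasingScoreTrack(mapped.sample_id, strand, window_cycles, unit, scores)


def end_conservation(
    regions_a: list[PhasedRegion],
    regions_b: list[PhasedRegion],
    tolerance: int = 0,
) -> EndConservationReport:
    """Count sample B regions whose 5' end (resp. 3' end) coincides with a
    same-strand region end in sample A.

    Matching is exact-coordinate by default (``tolerance=0``): ends of
    regions in neighboring phases offset by a single nucleotide are distinct.
    """
    report = EndConservationReport({}, {}, {}, {}, {})
    for strand in STRANDS:
        a5 = {r.five_prime_coord for r in regions_a if r.strand == strand}
        a3 = {r.three_prime_coord for r in regions_a if r.strand == strand}
        b = [r for r in regions_b if r.strand == strand]

        def hit(coord: int, pool: set[int]) -> bool:
            if tolerance == 0:
                return coord in pool
            return any(abs(coord - c) <= tolerance for c in pool)

        m5 = sorted({r.five_prime_coord for r in b if hit(r.five_prime_coord, a5)})
        m3 = sorted({r.three_prime_coord for r in b if hit(r.three_prime_coord, a3)})
        report.n_regions_b[strand] = len(b)
        report.conserved_five_prime[strand] = sum(
            1 for r in b if hit(r.five_prime_coord, a5)
        )
        report.conserved_three_prime[strand] = sum(
            1 for r in b if hit(r.three_prime_coord, a3)
        )
        report.matched_five_prime[strand] = m5
        report.matched_three_prime[strand] = m3
    return report


def phase_summary(
    regions: list[PhasedRegion],
    unit: int = DEFAULT_UNIT,
    strands: tuple[str, ...] = STRANDS,
) -> pd.DataFrame:
    """Per-(strand, phase) totals: region count, total and maximum contiguous
    units, and extreme 5'/3' coordinates.  Phases with no regions appear as
    zero rows so absent registers are visible."""
    rows = []
    for strand in strands:
        for phase in range(1, unit + 1):
            sub = [r for r in regions if r.strand == strand and r.phase == phase]
            if sub:
                five = [r.five_prime_coord for r in sub]
                three = [r.three_prime_coord for r in sub]
                extreme5 = min(five) if strand == SENSE else max(five)
                extreme3 = max(three) if strand == SENSE else min(three)
                rows.append(
                    {
                        "strand": strand,
                        "phase": phase,
                        "n_regions": len(sub),
                        "total_units": sum(r.n_units for r in sub),
                        "max_units": max(r.n_units for r in sub),
                        "extreme_five_prime": extreme5,
                        "extreme_three_prime": extreme3,
                    }
                )
            else:
                rows.append(
                    {
                        "strand": strand,
                        "phase": phase,
                        "n_regions": 0,
                        "total_units": 0,
                        "max_units": 0,
                        "extreme_five_prime": pd.NA,
                        "extreme_three_prime": pd.NA,
                    }
                )
    return pd.DataFrame(rows)
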