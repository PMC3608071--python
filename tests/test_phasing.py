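"""Phase registers, phased-region calling, phasing scores and end
conservation."""

import math

import numpy as np
import pytest

from srnalocus.mapping import ANTISENSE, SENSE, map_table, reverse_complement
from srnalocus.phasing import (
    PhasedRegion,
    call_phased_regions,
    cycle_positions,
    end_conservation,
    occupancy,
    phase_of,
    phase_summary,
    phasing_score,
    window_score,
)
from srnalocus.reads import SiRNASpecies, SpeciesTable
from srnalocus.reference import ReferenceLocus

from conftest import random_sequence

L = 2000


@pytest.fixture
def locus():
    return ReferenceLocus("ph", random_sequence(np.random.default_rng(67), L))


def _mapped(locus, placements):
    """(strand, five_prime_coord, length, count) placements -> MappedSet."""
    counts = {}
    for strand, five, length, count in placements:
        if strand == SENSE:
            start, end = five, five + length - 1
        else:
            start, end = five - length + 1, five
        seq = locus.slice(start, end)
        if strand == ANTISENSE:
            seq = reverse_complement(seq)
        counts[seq] = counts.get(seq, 0) + count
    table = SpeciesTable("s", [SiRNASpecies(s, c) for s, c in sorted(counts.items())])
    return map_table(table, locus)


class TestPhaseOf:
    def test_sense_anchor_at_first_base(self):
        assert phase_of(1, SENSE, L) == 1
        assert phase_of(22, SENSE, L) == 1
        assert phase_of(2, SENSE, L) == 2

    def test_antisense_anchor_at_last_base(self):
        assert phase_of(L, ANTISENSE, L) == 1
        assert phase_of(L - 21, ANTISENSE, L) == 1
        assert phase_of(L - 1, ANTISENSE, L) == 2

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            phase_of(0, SENSE, L)
        with pytest.raises(ValueError):
            phase_of(L + 1, SENSE, L)

    @pytest.mark.parametrize("strand", [SENSE, ANTISENSE])
    def test_registers_partition_the_locus(self, strand):
        """The 21 registers' cycle positions are disjoint and cover 1..L."""
        small_L = 500
        seen = {}
        for phase in range(1, 22):
            for coord in cycle_positions(strand, phase, small_L):
                assert coord not in seen
                seen[coord] = phase
        assert set(seen) == set(range(1, small_L + 1))
        for coord, phase in seen.items():
            assert phase_of(coord, strand, small_L) == phase

    def test_exactly_21_distinct_registers(self):
        for strand in (SENSE, ANTISENSE):
            phases = {phase_of(c, strand, L) for c in range(1, L + 1)}
            assert phases == set(range(1, 22))


class TestOccupancy:
    def test_single_alignment_occupies_its_cycle(self, locus):
        mapped = _mapped(locus, [(SENSE, 43, 21, 1)])
        assert phase_of(43, SENSE, L) == 1
        assert occupancy(mapped, SENSE, 1) == [(43, 1)]
        assert occupancy(mapped, SENSE, 2) == []

    def test_non_21mers_do_not_count(self, locus):
        mapped = _mapped(locus, [(SENSE, 43, 22, 5)])
        assert occupancy(mapped, SENSE, 1) == []

    def test_min_depth_gate(self, locus):
        mapped = _mapped(locus, [(SENSE, 43, 21, 1), (SENSE, 64, 21, 3)])
        assert [c for c, _ in occupancy(mapped, SENSE, 1, min_depth=2)] == [64]


class TestCallPhasedRegions:
    def test_nineteen_units_span_399(self, locus):
        first = 100
        units = [(SENSE, first + 21 * i, 21, 10) for i in range(19)]
        regions = call_phased_regions(_mapped(locus, units), SENSE)
        assert len(regions) == 1
        region = regions[0]
        assert region.n_units == 19
        assert region.span == 399
        assert region.first_unit_coord == first
        assert region.last_unit_coord == first + 21 * 18

    def test_two_units_not_a_region(self, locus):
        units = [(SENSE, 100, 21, 10), (SENSE, 121, 21, 10)]
        assert call_phased_regions(_mapped(locus, units), SENSE) == []

    def test_gap_splits_maximal_runs(self, locus):
        coords = [100 + 21 * i for i in (0, 1, 2, 3, 5, 6, 7, 8)]  # cycle 4 empty
        units = [(SENSE, c, 21, 2) for c in coords]
        regions = call_phased_regions(_mapped(locus, units), SENSE)
        assert [r.n_units for r in regions] == [4, 4]
        assert regions[0].last_unit_coord + 42 == regions[1].first_unit_coord

    def test_antisense_region_orientation(self, locus):
        first = 1500  # antisense: units descend
        units = [(ANTISENSE, first - 21 * i, 21, 3) for i in range(5)]
        regions = call_phased_regions(_mapped(locus, units), ANTISENSE)
        assert len(regions) == 1
        region = regions[0]
        assert region.first_unit_coord == 1500
        assert region.last_unit_coord == 1500 - 21 * 4
        assert region.five_prime_coord == 1500
        assert region.three_prime_coord == 1500 - 21 * 4 - 20
        assert region.left < region.right == 1500

    def test_regions_in_same_phase_are_separated(self, locus):
        """Maximality: no two reported regions in one phase are adjacent."""
        rng = np.random.default_rng(71)
        coords = sorted(rng.choice(range(40), size=25, replace=False))
        units = [(SENSE, 100 + 21 * int(c), 21, 1) for c in coords]
        regions = call_phased_regions(_mapped(locus, units), SENSE)
        by_phase = {}
        for r in regions:
            by_phase.setdefault(r.phase, []).append(r)
        for regs in by_phase.values():
            regs.sort(key=lambda r: r.first_unit_coord)
            for a, b in zip(regs, regs[1:]):
                assert b.first_unit_coord - a.last_unit_coord >= 2 * 21


class TestPhasingScore:
    def test_direct_formula(self):
        assert window_score(30, 2, 5) == pytest.approx(3 * math.log(101))

    def test_empty_window_zero(self):
        assert window_score(0, 0, 0) == 0.0

    def test_two_occupied_cycles_zero(self):
        assert window_score(50, 0, 2) == 0.0

    def test_clean_train_scores_positive_everywhere_inside(self, locus):
        first = 300
        units = [(SENSE, first + 21 * i, 21, 10) for i in range(12)]
        mapped = _mapped(locus, units)
        track = phasing_score(mapped, SENSE)
        for i in range(12):
            assert track.at(first + 21 * i) > 0.0

    def test_no_reads_no_score(self, locus):
        track = phasing_score(_mapped(locus, []), SENSE)
        assert track.scores.sum() == 0.0

    def test_out_of_phase_reads_damp_score(self, locus):
        units = [(SENSE, 300 + 21 * i, 21, 10) for i in range(6)]
        clean = phasing_score(_mapped(locus, units), SENSE)
        noisy = phasing_score(
            _mapped(locus, units + [(SENSE, 310 + 21 * i, 21, 10) for i in range(6)]),
            SENSE,
        )
        assert noisy.at(300) < clean.at(300)


class TestEndConservation:
    def _regions(self, specs):
        return [
            PhasedRegion(strand, phase, first, last, n)
            for strand, phase, first, last, n in specs
        ]

    def test_identical_regions_all_conserved(self):
        regs = self._regions([(SENSE, 3, 100, 184, 5), (ANTISENSE, 7, 900, 816, 5)])
        report = end_conservation(regs, regs)
        assert report.conserved_five_prime[SENSE] == 1
        assert report.conserved_three_prime[SENSE] == 1
        assert report.conserved_five_prime[ANTISENSE] == 1

    def test_disjoint_regions_none_conserved(self):
        a = self._regions([(SENSE, 3, 100, 184, 5)])
        b = self._regions([(SENSE, 5, 500, 584, 5)])
        report = end_conservation(a, b)
        assert report.conserved_five_prime[SENSE] == 0
        assert report.conserved_three_prime[SENSE] == 0

    def test_one_nucleotide_offset_neighboring_phase_not_conserved(self):
        """Ends in neighboring registers offset by a single nucleotide are
        distinct under the exact-coordinate rule."""
        a = self._regions([(SENSE, 3, 100, 184, 5)])
        b = self._regions([(SENSE, 4, 101, 185, 5)])
        report = end_conservation(a, b)
        assert report.conserved_five_prime[SENSE] == 0
        assert report.conserved_three_prime[SENSE] == 0
        relaxed = end_conservation(a, b, tolerance=1)
        assert relaxed.conserved_five_prime[SENSE] == 1


class TestPhaseSummary:
    def test_empty_regions_gives_zero_rows_for_all_registers(self):
        frame = phase_summary([])
        assert len(frame) == 42  # 21 registers x 2 strands
        assert (frame["n_regions"] == 0).all()

    def test_max_units_in_named_phase(self):
        regions = [PhasedRegion(ANTISENSE, 10, 1500, 1122, 19)]
        frame = phase_summary(regions)
        row = frame[(frame["strand"] == ANTISENSE) & (frame["phase"] == 10)].iloc[0]
        assert row["max_units"] == 19 and row["n_regions"] == 1

    def test_matches_brute_force_recount(self, locus):
        rng = np.random.default_rng(73)
        placements = [
            (SENSE, 100 + 21 * int(c), 21, 2)
            for c in sorted(rng.choice(range(60), size=35, replace=False))
        ] + [
            (ANTISENSE, 1800 - 21 * int(c), 21, 2)
            for c in sorted(rng.choice(range(40), size=20, replace=False))
        ]
        mapped = _mapped(locus, placements)
        regions = []
        for strand in (SENSE, ANTISENSE):
            regions.extend(call_phased_regions(mapped, strand))
        frame = phase_summary(regions)
        for _, row in frame.iterrows():
            sub = [
                r
                for r in regions
                if r.strand == row["strand"] and r.phase == row["phase"]
            ]
            assert row["n_regions"] == len(sub)
            assert row["total_units"] == sum(r.n_units for r in sub)
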