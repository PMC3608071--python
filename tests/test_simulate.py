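"""Synthetic-library generator: determinism, reconciliation, and recovery of
planted structure by the pipeline."""

import numpy as np
import pytest

from srnalocus.mapping import ANTISENSE, SENSE, map_table, strand_read_totals
from srnalocus.phasing import call_phased_regions
from srnalocus.profiling import position_track, size_distribution
from srnalocus.reads import collapse, trim_and_filter
from srnalocus.simulate import (
    PairedCoupling,
    PhasedTrainSpec,
    SyntheticDesign,
    generate_locus,
    simulate_library,
    simulate_paired,
    write_fastq,
)


def run_pipeline(reads, design, locus, sample_id="s"):
    inserts, _ = trim_and_filter(reads, design.adapter)
    return map_table(collapse(inserts, sample_id), locus)


class TestGenerateLocus:
    def test_feature_arithmetic(self):
        locus = generate_locus(1, (200, 180, 300, 1200, 200))
        assert locus.length == 2080
        exon2 = locus.feature("exon2")
        assert (exon2.start, exon2.end) == (681, 1880)

    def test_deterministic(self):
        assert generate_locus(5) == generate_locus(5)
        assert generate_locus(5) != generate_locus(6)

    def test_zero_length_feature_rejected(self):
        with pytest.raises(ValueError):
            generate_locus(1, (200, 0, 300, 1200, 200))


class TestSimulateLibrary:
    def test_bit_reproducible(self, tmp_path):
        locus = generate_locus(2)
        design = SyntheticDesign(seed=9)
        reads1, truth1 = simulate_library(design, locus)
        reads2, truth2 = simulate_library(design, locus)
        assert truth1 == truth2
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        write_fastq(reads1, p1)
        write_fastq(reads2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_design_empty_library(self):
        locus = generate_locus(2)
        design = SyntheticDesign(seed=9, n_hotspots=0, n_background_species=0)
        reads, truth = simulate_library(design, locus)
        assert reads == [] and truth.total_reads == 0

    def test_reconciliation_with_pipeline_accounting(self):
        """Noise-free library: pipeline totals equal ground truth exactly."""
        locus = generate_locus(3)
        design = SyntheticDesign(seed=13)
        reads, truth = simulate_library(design, locus)
        mapped = run_pipeline(reads, design, locus)
        sense, anti, total = strand_read_totals(mapped)
        assert total == truth.total_reads
        assert sense == truth.class_total(strand=SENSE)
        assert anti == truth.class_total(strand=ANTISENSE)
        assert mapped.unmapped_reads == 0
        dist = size_distribution(mapped)
        for length in (21, 22, 23, 24):
            for strand in (SENSE, ANTISENSE):
                assert dist.get(length, strand) == truth.class_total(length, strand)

    def test_position_tracks_match_planted_tallies(self):
        locus = generate_locus(4)
        design = SyntheticDesign(seed=17)
        reads, truth = simulate_library(design, locus)
        mapped = run_pipeline(reads, design, locus)
        for strand in (SENSE, ANTISENSE):
            track = position_track(mapped, 21, strand)
            planted = truth.position_totals(21, strand)
            for coord, count in planted.items():
                assert track.at(coord) == count
            assert track.total == sum(planted.values())

    def test_planted_confined_to_exon2(self):
        locus = generate_locus(5)
        design = SyntheticDesign(seed=19)
        _, truth = simulate_library(design, locus)
        exon2 = locus.feature("exon2")
        for sp in truth.species:
            assert exon2.start <= sp.five_prime_coord <= exon2.end

    def test_size_mixture_within_binomial_tolerance(self):
        """Realized class proportions stay within 3 sd of the binomial
        expectation at 10,000 planted draws."""
        locus = generate_locus(6)
        design = SyntheticDesign(
            seed=23,
            n_hotspots=0,
            n_background_species=10000,
            background_depth=1.0,
            count_law="deterministic",
        )
        _, truth = simulate_library(design, locus)
        n = truth.total_reads  # one read per draw under the deterministic law
        for length, p in design.size_mixture.items():
            realized = truth.class_total(length=length)
            sd = (n * p * (1 - p)) ** 0.5
            assert abs(realized - n * p) <= 3 * sd

    def test_strand_fraction_recovered(self):
        locus = generate_locus(7)
        design = SyntheticDesign(
            seed=29,
            n_hotspots=0,
            n_background_species=4000,
            background_depth=1.0,
            count_law="deterministic",
        )
        _, truth = simulate_library(design, locus)
        frac = truth.class_total(strand=ANTISENSE) / truth.total_reads
        assert abs(frac - design.antisense_fraction) < 0.03

    def test_sequencing_error_produces_unmapped_reads(self):
        locus = generate_locus(8)
        design = SyntheticDesign(seed=31, error_rate=0.5, n_background_species=300)
        reads, truth = simulate_library(design, locus)
        mapped = run_pipeline(reads, design, locus)
        _, _, total = strand_read_totals(mapped)
        assert mapped.unmapped_reads > 0
        assert total + mapped.unmapped_reads == truth.total_reads


class TestPlantedRegionRecovery:
    def test_noise_free_recovery_is_exact(self):
        locus = generate_locus(9)
        exon2 = locus.feature("exon2")
        trains = (
            PhasedTrainSpec(SENSE, exon2.start + 4, 6, depth=10),
            PhasedTrainSpec(ANTISENSE, exon2.end - 3, 4, depth=8),
        )
        design = SyntheticDesign(
            seed=37, n_hotspots=0, n_background_species=0, phased_trains=trains
        )
        reads, truth = simulate_library(design, locus)
        mapped = run_pipeline(reads, design, locus)
        called = []
        for strand in (SENSE, ANTISENSE):
            called.extend(call_phased_regions(mapped, strand))
        assert sorted(called, key=lambda r: (r.strand, r.first_unit_coord)) == sorted(
            truth.planted_regions, key=lambda r: (r.strand, r.first_unit_coord)
        )

    def test_recovery_robust_to_low_background(self):
        """Planted trains survive sparse background over 20 seeds; spurious
        regions only arise from sampled in-phase background runs >= 3."""
        locus = generate_locus(10)
        exon2 = locus.feature("exon2")
        train = PhasedTrainSpec(SENSE, exon2.start + 10, 8, depth=20)
        for seed in range(20):
            design = SyntheticDesign(
                seed=100 + seed,
                n_hotspots=0,
                n_background_species=60,
                background_depth=1.0,
                phased_trains=(train,),
            )
            reads, truth = simulate_library(design, locus)
            mapped = run_pipeline(reads, design, locus)
            regions = call_phased_regions(mapped, SENSE)
            planted = truth.planted_regions[0]
            containing = [
                r
                for r in regions
                if r.phase == planted.phase
                and r.first_unit_coord <= planted.first_unit_coord
                and r.last_unit_coord >= planted.last_unit_coord
            ]
            assert len(containing) == 1


class TestSimulatePaired:
    def test_deterministic_counts_same_exposure_rs_one(self):
        locus = generate_locus(11)
        design = SyntheticDesign(seed=41, count_law="deterministic")
        _, _, paired = simulate_paired(
            design, locus, PairedCoupling(noise_sigma=0.0), n_shared_species=100
        )
        assert paired.achieved_rs_all == pytest.approx(1.0)

    def test_independent_abundances_near_zero_rs(self):
        """With no shared term the null correlation stays small on average
        (20 replicates, 200 species)."""
        locus = generate_locus(12)
        values = []
        for seed in range(20):
            design = SyntheticDesign(seed=500 + seed)
            _, _, paired = simulate_paired(
                design,
                locus,
                PairedCoupling(shared_sigma=0.0, noise_sigma=1.2),
                n_shared_species=200,
            )
            values.append(paired.achieved_rs_all)
        assert abs(float(np.mean(values))) < 0.25

    def test_pipeline_rs_tracks_achieved_rs(self):
        """Pipeline-estimated r_s per strand is within 0.1 of the generator's
        achieved r_s for every seed."""
        from srnalocus.commonality import compare_samples

        locus = generate_locus(13)
        for seed in range(20):
            design = SyntheticDesign(seed=900 + seed)
            reads_a, reads_b, paired = simulate_paired(design, locus)
            ma = run_pipeline(reads_a, design, locus, "a")
            mb = run_pipeline(reads_b, design, locus, "b")
            for strand in (SENSE, ANTISENSE):
                achieved = paired.achieved_rs[strand]
                if achieved is None:
                    continue
                report = compare_samples(ma, mb, length=21, strand=strand)
                assert report.spearman_rs == pytest.approx(achieved, abs=0.1)
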