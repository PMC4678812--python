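import numpy as np
import pytest

from sirspread import simdata
from sirspread.sio import ConfigurationError, revcomp_dna, to_rna


class TestSimConfig:
    def test_replicate_floor(self):
        with pytest.raises(ConfigurationError):
            simdata.SimConfig(replicates=1)

    def test_fraction_bounds(self):
        with pytest.raises(ConfigurationError):
            simdata.SimConfig(frac_21=1.2)
        with pytest.raises(ConfigurationError):
            simdata.SimConfig(rdr6_dependence=-0.1)

    def test_sample_names(self):
        config = simdata.SimConfig(replicates=2)
        assert len(config.samples) == 8
        assert "ski2_RDR6_rep1" in config.samples


class TestSimulateReference:
    def test_determinism(self):
        config = simdata.SimConfig(seed=5, n_genes=10, n_target_genes=3)
        ref1, truth1, mir1 = simdata.simulate_reference(config)
        ref2, truth2, mir2 = simdata.simulate_reference(config)
        assert ref1.genome == ref2.genome
        assert mir1 == mir2
        assert simdata.truth_to_frame(truth1).equals(simdata.truth_to_frame(truth2))

    def test_zero_target_genes(self):
        config = simdata.SimConfig(n_target_genes=0, n_genes=8)
        reference, truth, mirnas = simdata.simulate_reference(config)
        assert reference.target_sites == []
        assert truth == []
        assert len(reference.annotation) == 8

    def test_site_is_reverse_complement_of_mirna(self):
        config = simdata.SimConfig(seed=2, n_genes=10, n_target_genes=4)
        reference, _, mirnas = simdata.simulate_reference(config)
        for ts in reference.target_sites:
            gene = reference.annotation[ts.transcript_id]
            genomic = reference.genome[gene.chrom][
                gene.start + ts.start: gene.start + ts.end]
            assert to_rna(revcomp_dna(genomic)) == mirnas[ts.mirna_name]

    def test_capacity_error(self):
        with pytest.raises(ConfigurationError, match="capacity"):
            simdata.simulate_reference(simdata.SimConfig(
                n_genes=200, chromosome_length=5000, n_chromosomes=1))

    def test_planted_loci_inside_genes(self):
        config = simdata.SimConfig(seed=3)
        reference, truth, _ = simdata.simulate_reference(config)
        for locus in truth:
            gene = reference.annotation[locus.gene_id]
            assert gene.start < locus.cleavage < gene.end


class TestSimulateReads:
    def test_library_size_bookkeeping(self, small_sim):
        for sample, reads in small_sim["reads"].items():
            assert small_sim["library_sizes"][sample] == len(reads)

    def test_determinism(self):
        config = simdata.SimConfig(seed=11, n_genes=6, n_target_genes=2,
                                   chromosome_length=20_000)
        reference, truth, _ = simdata.simulate_reference(config)
        r1, l1 = simdata.simulate_reads(reference, truth, config)
        r2, l2 = simdata.simulate_reads(reference, truth, config)
        assert l1 == l2
        assert r1 == r2

    def test_rdr6_dependence_removes_planted_signal(self, small_sim):
        """With rdr6_dependence=1, planted positions in rdr6 samples carry
        only background-level reads."""
        truth = small_sim["truth"]
        config = small_sim["config"]
        halfwidth = config.peak_halfwidth
        for genotype in ("SKI2_rdr6", "ski2_rdr6"):
            reads = [r for s, rs in small_sim["reads"].items()
                     if s.startswith(genotype) for r in rs]
            for locus in truth:
                near = [r for r in reads if r.chrom == locus.chrom
                        and abs(r.five_prime - locus.cleavage) <= halfwidth]
                # background over 2*halfwidth nt of a 1200 nt gene, 2 reps:
                # expectation ~ 2 * bg_mean * (300/1200) = 7.5; gate generously
                assert len(near) <= 40

    def test_5p_direction_reads_left_of_cleavage(self):
        config = simdata.SimConfig(seed=9, n_genes=4, n_target_genes=1,
                                   chromosome_length=20_000, n_chromosomes=1,
                                   directions=("5p",), background_mean=0.0,
                                   transitive_mean=200.0)
        reference, truth, _ = simdata.simulate_reference(config)
        reads, _ = simdata.simulate_reads(reference, truth, config)
        locus = truth[0]
        planted = [r for r in reads["ski2_RDR6_rep1"]]
        assert len(planted) > 50
        assert all(r.five_prime < locus.cleavage for r in planted)

    def test_3p_direction_reads_right_of_cleavage(self):
        config = simdata.SimConfig(seed=9, n_genes=4, n_target_genes=1,
                                   chromosome_length=20_000, n_chromosomes=1,
                                   directions=("3p",), background_mean=0.0,
                                   transitive_mean=200.0)
        reference, truth, _ = simdata.simulate_reference(config)
        reads, _ = simdata.simulate_reads(reference, truth, config)
        locus = truth[0]
        assert all(r.five_prime >= locus.cleavage
                   for r in reads["ski2_RDR6_rep1"])

    def test_21mer_fraction(self):
        config = simdata.SimConfig(seed=13, n_genes=4, n_target_genes=1,
                                   chromosome_length=40_000, n_chromosomes=1,
                                   background_mean=0.0, transitive_mean=10_000.0,
                                   dispersion=0.0, frac_21=0.8)
        reference, truth, _ = simdata.simulate_reference(config)
        reads, _ = simdata.simulate_reads(reference, truth, config)
        planted = reads["ski2_RDR6_rep1"]
        assert len(planted) >= 9000
        frac = np.mean([r.length == 21 for r in planted])
        assert abs(frac - 0.8) <= 0.02  # ~5 binomial SEs at n=10000

    def test_read_sizes_within_range(self, small_sim):
        config = small_sim["config"]
        for reads in small_sim["reads"].values():
            for r in reads:
                assert config.size_min <= r.length <= config.size_max

    def test_fold_change_between_genotypes(self, small_sim):
        """Planted loci carry ~fold_change more reads in ski2_RDR6 than WT."""
        truth = small_sim["truth"]
        hw = small_sim["config"].peak_halfwidth

        def near_count(genotype):
            reads = [r for s, rs in small_sim["reads"].items()
                     if s.startswith(genotype) for r in rs]
            return sum(1 for r in reads for locus in truth
                       if r.chrom == locus.chrom
                       and abs(r.five_prime - locus.cleavage) <= hw)

        mutant = near_count("ski2_RDR6")
        wild = near_count("SKI2_RDR6")
        assert mutant > 4 * max(wild, 1)


class TestTruthTable:
    def test_frame_columns(self, small_sim):
        df = simdata.truth_to_frame(small_sim["truth"])
        assert {"gene_id", "chrom", "cleavage", "direction",
                "mean_ski2_RDR6"}.issubset(df.columns)

    def test_expected_means_follow_config(self, small_sim):
        config = small_sim["config"]
        locus = small_sim["truth"][0]
        assert locus.expected_means["ski2_RDR6"] == config.transitive_mean
        assert locus.expected_means["SKI2_RDR6"] == pytest.approx(
            config.transitive_mean / config.fold_change)
        assert locus.expected_means["ski2_rdr6"] == 0.0


class TestSimulateRaceClones:
    def test_empty_fragment_rejected(self):
        with pytest.raises(ConfigurationError):
            simdata.simulate_race_clones("", 10, {"": 1.0})

    def test_all_untailed(self):
        clones, truth = simdata.simulate_race_clones("ACG" * 20, 15, {"": 1.0})
        assert all(t == "" for t in truth)
        assert all(seq == "ACG".replace("T", "U") * 20 for seq in clones.values())

    def test_determinism(self):
        spectrum = {"": 0.5, "U": 0.3, "AA": 0.2}
        c1, t1 = simdata.simulate_race_clones("ACGU" * 10, 30, spectrum, seed=8)
        c2, t2 = simdata.simulate_race_clones("ACGU" * 10, 30, spectrum, seed=8)
        assert c1 == c2 and t1 == t2

    def test_trim_bounds(self):
        with pytest.raises(ConfigurationError):
            simdata.simulate_race_clones("ACGU", 5, {"": 1.0}, trim_dist={10: 1.0})
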