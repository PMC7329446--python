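"""Simulator: determinism, truth conservation, statistical calibration."""

import numpy as np
import pytest

from stratascan import sim
from stratascan.sim import (
    ConfigError,
    GametologDepths,
    SimulationConfig,
    simulate_alignments,
    simulate_cds_pairs,
    simulate_gametologs,
    simulate_genome,
    simulate_profiles,
)


class TestConfigValidation:
    def test_nonpositive_length_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(scaffold_length=0)

    def test_proportions_bounded(self):
        with pytest.raises(ConfigError):
            SimulationConfig(heterozygosity=1.5)

    def test_stratum_divergence_ordering(self):
        with pytest.raises(ConfigError):
            SimulationConfig(stratum1_zw_divergence=0.001, stratum2_zw_divergence=0.002)

    def test_depths_positive(self):
        with pytest.raises(ConfigError):
            SimulationConfig(female_depth=0)


class TestGenome:
    def test_no_w_when_configured_zero(self):
        cfg = SimulationConfig(n_autosomal_scaffolds=2, scaffold_length=20_000,
                               n_w_specific=0, n_par=0, n_stratum1=0, n_stratum2=0)
        genome = simulate_genome(cfg)
        assert all(s.label != sim.W_SPECIFIC for s in genome.scaffolds)

    def test_truth_partition(self, small_genome, small_config):
        table = small_genome.truth_table()
        assert len(table) == len(small_genome.scaffolds)
        assert table["scaffold"].is_unique
        counts = table["label"].value_counts()
        assert counts[sim.AUTOSOME] == small_config.n_autosomal_scaffolds
        assert counts[sim.W_SPECIFIC] == small_config.n_w_specific

    def test_fasta_byte_identical_across_runs(self, small_config, tmp_path):
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        simulate_genome(small_config).write_fasta(p1)
        simulate_genome(small_config).write_fasta(p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert p1.read_bytes().startswith(b">aut01\n")

    def test_heterozygosity_calibrated(self):
        """Observed autosomal heterozygous-site fraction within 3 binomial
        SDs of the configured rate on a 1-Mb scaffold."""
        cfg = SimulationConfig(n_autosomal_scaffolds=1, scaffold_length=1_000_000,
                               n_par=0, n_stratum1=0, n_stratum2=0, n_w_specific=0,
                               seed=3)
        genome = simulate_genome(cfg)
        p = 0.005
        n = cfg.scaffold_length
        observed = len(genome.female_variants["aut01"]) / n
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(observed - p) < 3 * sd

    def test_repeat_enrichment_on_w(self, small_genome):
        w = [small_genome.repeat_fraction(s.name) for s in small_genome.scaffolds
             if s.label == sim.W_SPECIFIC]
        auto = [small_genome.repeat_fraction(s.name) for s in small_genome.scaffolds
                if s.label == sim.AUTOSOME]
        assert min(w) > np.mean(auto)

    def test_repeat_intervals_within_bounds(self, small_genome):
        for s in small_genome.scaffolds:
            iv = small_genome.repeat_intervals[s.name]
            if len(iv):
                assert iv.min() >= 0 and iv.max() <= s.length
                assert (iv[:, 1] > iv[:, 0]).all()

    def test_alternate_sequence_differs_at_divergence_rate(self, small_genome):
        name = "str1_1"
        backbone = small_genome.backbone_sequence(name)
        alt = small_genome.alternate_sequence(name)
        frac = (backbone != alt).mean()
        expected = 0.005 + 0.012
        sd = np.sqrt(expected * (1 - expected) / len(backbone))
        assert abs(frac - expected) < 4 * sd


class TestProfiles:
    def test_male_depth_zero_on_w_scaffold(self, small_genome):
        profiles = simulate_profiles(small_genome)
        sv = profiles.scaffold_sites("w1", "male")
        assert sv.depth.sum() == 0

    def test_female_half_depth_on_stratum1(self, small_genome, small_config):
        profiles = simulate_profiles(small_genome)
        sv = profiles.scaffold_sites("str1_1", "female")
        mean = small_config.female_depth / 2
        sd = np.sqrt(mean / len(sv.depth))
        assert abs(sv.depth.mean() - mean) < 3 * sd

    def test_homozygous_site_single_base(self, small_genome):
        profiles = simulate_profiles(small_genome)
        counts = profiles.counts_matrix("aut01", "female")
        hom = np.setdiff1d(np.arange(200), small_genome.female_variants["aut01"])
        rows = counts[hom]
        covered = rows[rows.sum(axis=1) > 0]
        assert ((covered > 0).sum(axis=1) == 1).all()

    def test_heterozygous_split_preserves_depth(self, small_genome):
        profiles = simulate_profiles(small_genome)
        sv = profiles.scaffold_sites("aut01", "female")
        counts = profiles.counts_matrix("aut01", "female")
        np.testing.assert_array_equal(counts.sum(axis=1), sv.depth)

    def test_deterministic_re_access(self, small_genome):
        profiles = simulate_profiles(small_genome)
        a = profiles.scaffold_sites("aut02", "male")
        b = profiles.scaffold_sites("aut02", "male")
        np.testing.assert_array_equal(a.depth, b.depth)
        np.testing.assert_array_equal(a.allele1, b.allele1)

    def test_profile_tsv_roundtrip(self, tmp_path):
        cfg = SimulationConfig(n_autosomal_scaffolds=1, scaffold_length=2_000,
                               n_par=0, n_stratum1=0, n_stratum2=0, n_w_specific=0,
                               female_depth=10, male_depth=10, seed=5)
        genome = simulate_genome(cfg)
        profiles = simulate_profiles(genome)
        path = tmp_path / "f.pro"
        profiles.write_tsv("female", path)
        from stratascan import winstats
        loaded = winstats.load_profile_counts(path, genome.scaffold_lengths)
        np.testing.assert_array_equal(loaded["aut01"],
                                      profiles.counts_matrix("aut01", "female"))


class TestGametologs:
    def test_stratum1_w_most_divergent(self):
        groups = simulate_gametologs(None, {"STRATUM1": 5}, seed=2, n_codons=400)
        for grp in groups:
            w = grp.sequences[grp.w_label]
            z_label = "female_h2" if grp.w_label == "female_h1" else "female_h1"
            z = grp.sequences[z_label]
            m = grp.sequences["male_h1"]
            ident = lambda a, b: np.mean([x == y for x, y in zip(a, b)])
            assert ident(w, z) < ident(z, m)

    def test_zero_branch_lengths_identical_sequences(self):
        depths = GametologDepths(0, 0, 0, 0, 0, 0, 0)
        groups = simulate_gametologs(None, {"STRATUM2": 2}, depths, seed=1, n_codons=50)
        for grp in groups:
            assert len(set(grp.sequences.values())) == 1

    def test_inconsistent_ordering_rejected(self):
        with pytest.raises(ConfigError):
            GametologDepths(outgroup=0.01, congener1=0.05)

    def test_group_invariants(self):
        groups = simulate_gametologs(None, {"STRATUM1": 2, "AUTOSOME": 2}, seed=6)
        for grp in groups:
            lengths = {len(s) for s in grp.sequences.values()}
            assert len(lengths) == 1 and next(iter(lengths)) % 3 == 0
            assert len(grp.sequences) == 7

    def test_cds_pairs_pass_qc_and_hit_divergence(self):
        from stratascan import dnds
        pairs = simulate_cds_pairs(20, 0.01, n_codons=500, seed=4)
        diffs = []
        for _, h1, h2 in pairs:
            assert dnds.qc_cds(h1).passed and dnds.qc_cds(h2).passed
            diffs.append(np.mean([a != b for a, b in zip(h1, h2)]))
        assert np.mean(diffs) == pytest.approx(0.01, rel=0.2)


class TestAlignmentSim:
    def test_planted_duplicate_record(self, small_genome):
        alns = simulate_alignments(small_genome, n_duplicates=1,
                                   duplicate_identity=0.95, duplicate_overlap=1.0)
        assert len(alns.self_records) == 1
        rec = alns.self_records[0]
        assert rec.identity == pytest.approx(0.95, abs=1e-3)
        assert rec.target == alns.duplicate_truth[rec.query]

    def test_reverse_strand_records(self, small_genome):
        ref_map = {"aut01": ("chrX", 0, "-")}
        alns = simulate_alignments(small_genome, ref_map, n_duplicates=0)
        assert alns.reference_records
        assert all(r.strand == "-" for r in alns.reference_records)

    def test_overlapping_offsets_rejected(self, small_genome):
        ref_map = {"aut01": ("chr1", 0, "+"), "aut02": ("chr1", 1000, "+")}
        with pytest.raises(ConfigError, match="overlapping"):
            simulate_alignments(small_genome, ref_map, n_duplicates=0)

    def test_shuffled_scaffold_majority_elsewhere(self, small_genome):
        alns = simulate_alignments(small_genome, n_duplicates=0,
                                   shuffled_scaffolds=("aut03",))
        recs = [r for r in alns.reference_records if r.query == "aut03"]
        own = sum(r.q_aligned for r in recs if r.target == "chrA02")
        other = sum(r.q_aligned for r in recs if r.target != "chrA02")
        assert other > own > 0
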