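"""Codon-level divergence estimation against independent enumeration oracles."""

import itertools

import numpy as np
import pytest

from stratascan import dnds, sim
from stratascan.dnds import (
    CODONS,
    STOPS,
    CodonAlignment,
    compare_regions,
    filter_ds,
    jc_correction,
    ng86_estimate,
    ng86_sites,
    prepare_pair,
    qc_cds,
    yn00_estimate,
)

import oracles

SENSE_CODONS = [c for c in CODONS if c not in STOPS]


def _aln(seq1: str, seq2: str) -> CodonAlignment:
    return prepare_pair(seq1, seq2)


class TestQcCds:
    @pytest.mark.parametrize("seq,passed,reason", [
        ("ATG" + "AAA" * 39, True, "OK"),                      # exactly 120 nt
        ("ATGAAATAA", False, "TOO_SHORT"),
        ("ATG" + "AAA" * 20 + "TGA" + "AAA" * 20, False, "INTERNAL_STOP"),
        ("ATG" + "AAA" * 39 + "TGA", True, "OK"),              # terminal stop fine
        ("CCC" + "AAA" * 39, False, "NO_START"),
        ("ATG" + "AAA" * 39 + "A", False, "NOT_TRIPLET"),
        ("ATG" + "AAN" * 39, False, "AMBIGUOUS"),
    ])
    def test_rules(self, seq, passed, reason):
        result = qc_cds(seq)
        assert result.passed is passed
        assert result.reason == reason


class TestSiteCounts:
    def test_spot_values(self):
        assert ng86_sites("TTT")[0] == pytest.approx(1 / 3)
        assert ng86_sites("TGG")[0] == 0.0

    def test_all_sense_codons_match_oracle(self):
        for codon in SENSE_CODONS:
            s, n = ng86_sites(codon)
            so, no = oracles.oracle_sites(codon)
            assert s == pytest.approx(so, abs=1e-12), codon
            assert n == pytest.approx(no, abs=1e-12), codon

    def test_stop_codon_rejected(self):
        with pytest.raises(dnds.SequenceError):
            ng86_sites("TGA")


class TestNg86Estimate:
    def test_identical_pair_zero(self):
        est = ng86_estimate(_aln("ATGAAACCC", "ATGAAACCC"))
        assert est.Sd == est.Nd == 0.0
        assert est.dS == est.dN == 0.0

    def test_matches_oracle_on_all_low_difference_codon_pairs(self):
        """Exhaustive pathway-enumeration check for all sense-codon pairs
        with at most two differences (the full 61x61 grid, filtered)."""
        checked = 0
        for c1, c2 in itertools.product(SENSE_CODONS, repeat=2):
            ndiff = sum(a != b for a, b in zip(c1, c2))
            if ndiff > 2:
                continue
            est = ng86_estimate(_aln(c1, c2))
            S, N, Sd, Nd, _, _ = oracles.oracle_ng86(c1, c2)
            assert abs(est.S - S) < 1e-9, (c1, c2)
            assert abs(est.N - N) < 1e-9, (c1, c2)
            assert abs(est.Sd - Sd) < 1e-9, (c1, c2)
            assert abs(est.Nd - Nd) < 1e-9, (c1, c2)
            checked += 1
        assert checked > 2000

    def test_matches_oracle_on_random_sequences(self, rng):
        for _ in range(10):
            idx1 = rng.choice(len(SENSE_CODONS), size=80)
            seq1 = "".join(SENSE_CODONS[i] for i in idx1)
            # mutate a few sites
            seq2 = list(seq1)
            for pos in rng.choice(len(seq2), size=12, replace=False):
                seq2[pos] = "ACGT"[rng.integers(4)]
            seq2 = "".join(seq2)
            try:
                est = ng86_estimate(_aln(seq1, seq2))
            except dnds.SequenceError:
                continue  # mutation created a stop codon; pair not comparable
            S, N, Sd, Nd, dS, dN = oracles.oracle_ng86(
                *_roundtrip(seq1, seq2))
            assert est.Sd == pytest.approx(Sd, abs=1e-9)
            assert est.Nd == pytest.approx(Nd, abs=1e-9)
            assert est.dS == pytest.approx(dS, abs=1e-9)

    def test_symmetry(self, rng):
        pairs = sim.simulate_cds_pairs(5, 0.05, n_codons=100, seed=4)
        for _, h1, h2 in pairs:
            a = ng86_estimate(_aln(h1, h2))
            b = ng86_estimate(_aln(h2, h1))
            assert a.dS == pytest.approx(b.dS, abs=1e-12)
            assert a.dN == pytest.approx(b.dN, abs=1e-12)

    def test_sites_sum_to_three_per_codon(self, rng):
        pairs = sim.simulate_cds_pairs(3, 0.02, n_codons=150, seed=9)
        for _, h1, h2 in pairs:
            est = ng86_estimate(_aln(h1, h2))
            assert est.S + est.N == pytest.approx(3 * est.n_codons, abs=1e-9)

    def test_saturation_flagged_not_raised(self):
        # maximally different codons repeated -> p above the JC domain
        seq1 = "AAA" * 60
        seq2 = "GGG" * 60
        est = ng86_estimate(_aln(seq1, seq2))
        assert est.saturated


def _roundtrip(seq1, seq2):
    """Strip codons the package's aligner-prep would strip, via prepare_pair."""
    aln = prepare_pair(seq1, seq2)
    dec = lambda arr: "".join(CODONS[i] for i in arr)
    return dec(aln.codons1), dec(aln.codons2)


class TestJcCorrection:
    def test_value_at_p_01(self):
        assert jc_correction(0.1) == pytest.approx(0.1073, abs=1e-4)

    def test_saturation(self):
        assert np.isnan(jc_correction(0.75))


class TestYn00:
    def test_identical_pair(self):
        est = yn00_estimate(_aln("ATGAAACCC" * 20, "ATGAAACCC" * 20))
        assert est.dS == est.dN == 0.0
        assert not est.flags

    def test_reduces_to_ng86_sites_at_kappa_one_uniform(self, rng):
        pairs = sim.simulate_cds_pairs(10, 0.03, n_codons=200, seed=21)
        for _, h1, h2 in pairs:
            aln = _aln(h1, h2)
            y = yn00_estimate(aln, fix_kappa=1.0, codon_freqs="uniform")
            g = ng86_estimate(aln)
            assert y.S == pytest.approx(g.S, abs=1e-6)
            assert y.N == pytest.approx(g.N, abs=1e-6)

    def test_symmetric_in_sequences(self):
        pairs = sim.simulate_cds_pairs(5, 0.05, n_codons=120, seed=33)
        for _, h1, h2 in pairs:
            a = yn00_estimate(_aln(h1, h2))
            b = yn00_estimate(_aln(h2, h1))
            assert a.dS == pytest.approx(b.dS, rel=1e-9)
            assert a.dN == pytest.approx(b.dN, rel=1e-9)

    def test_monotone_in_simulated_divergence(self):
        means = []
        for div in (0.005, 0.02, 0.06):
            ests = [yn00_estimate(_aln(h1, h2))
                    for _, h1, h2 in sim.simulate_cds_pairs(15, div, n_codons=400, seed=5)]
            means.append(np.mean([e.dS for e in ests if e.defined]))
        assert means[0] < means[1] < means[2]

    def test_recovers_true_divergence_roughly(self):
        ests = [yn00_estimate(_aln(h1, h2))
                for _, h1, h2 in sim.simulate_cds_pairs(25, 0.01, n_codons=2000, seed=8)]
        mean_ds = np.mean([e.dS for e in ests])
        assert mean_ds == pytest.approx(0.01, rel=0.15)


class TestFilterAndCompare:
    def _est(self, ds, flags=()):
        return dnds.DnDsEstimate(100, 200, ds * 100, 0, ds, 0, ds, 0.0, 2.0,
                                 "NG86", 100, flags)

    def test_filter_ds(self):
        ests = [self._est(0.19), self._est(0.25),
                self._est(float("nan"), ("SATURATED",))]
        kept = filter_ds(ests)
        assert [e.dS for e in kept] == [0.19]

    def test_boundary_kept(self):
        assert filter_ds([self._est(0.2)])  # retained at the cap

    def test_single_gene_region_mean_only(self):
        out = compare_regions({"GENOME": [self._est(0.01), self._est(0.02)],
                               "SDR": [self._est(0.05)]})
        assert out["SDR"]["mean"] == pytest.approx(0.05)
        assert np.isnan(out["SDR"]["p"])

    def test_shifted_region_significant(self):
        genome = [self._est(d) for d in np.linspace(0.001, 0.01, 40)]
        strat = [self._est(d) for d in np.linspace(0.012, 0.03, 25)]
        out = compare_regions({"GENOME": genome, "STRATUM1": strat})
        assert out["STRATUM1"]["p"] < 1e-6

    def test_null_regions_not_significant_on_average(self, rng):
        ps = []
        for s in range(10):
            vals = rng.normal(0.01, 0.002, size=60).clip(min=0)
            genome = [self._est(v) for v in vals[:40]]
            other = [self._est(v) for v in vals[40:]]
            ps.append(compare_regions({"GENOME": genome, "PAR": other})["PAR"]["p"])
        assert 0.15 < np.mean(ps) < 0.85

    def test_missing_baseline_errors(self):
        with pytest.raises(ValueError, match="baseline"):
            compare_regions({"SDR": [self._est(0.05)]})


class TestPreparePair:
    def test_gapped_codon_columns_dropped_pairwise(self):
        aln = prepare_pair("ATGAAA---CCC", "ATGAAATTTCCC")
        assert aln.n_codons == 3

    def test_terminal_stop_stripped(self):
        aln = prepare_pair("ATGAAATAA", "ATGAAATAA")
        assert aln.n_codons == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(dnds.SequenceError):
            prepare_pair("ATGAAA", "ATG")
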