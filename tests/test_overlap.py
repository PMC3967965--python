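"""LD expansion, interval membership, Venn counts and binomial enrichment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirsnp.core import GenomicInterval, MirsnpError
from mirsnp.overlap import (
    LdPair,
    SnpRecord,
    binomial_enrichment,
    expand_ld,
    overlap_venn,
    snps_in_track,
    track_overlap_fraction,
)
from oracles import brute_overlap_flags, exact_binom_upper_tail


class TestExpandLd:
    def test_empty_table_identity(self):
        assert expand_ld({"rsA"}, []) == {"rsA"}

    def test_partner_above_threshold_added(self):
        assert expand_ld({"rsA"}, [LdPair("rsA", "rsB", 0.9)]) == {"rsA", "rsB"}

    def test_threshold_is_strict(self):
        assert expand_ld({"rsA"}, [LdPair("rsA", "rsB", 0.8)], r2_min=0.8) == {"rsA"}

    def test_symmetric(self):
        assert expand_ld({"rsB"}, [LdPair("rsA", "rsB", 0.9)]) == {"rsA", "rsB"}

    def test_single_hop_only(self):
        pairs = [LdPair("rsA", "rsB", 0.9), LdPair("rsB", "rsC", 0.9)]
        assert expand_ld({"rsA"}, pairs) == {"rsA", "rsB"}

    @given(
        snps=st.sets(st.integers(0, 30), min_size=1, max_size=10),
        pairs=st.lists(
            st.tuples(st.integers(0, 30), st.integers(0, 30), st.floats(0, 1)),
            max_size=20,
        ),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_and_idempotent(self, snps, pairs):
        ld = [LdPair(f"rs{a}", f"rs{b}", r) for a, b, r in pairs if a != b]
        base = {f"rs{i}" for i in snps}
        once = expand_ld(base, ld)
        assert once >= base
        assert expand_ld(once, ld) >= once  # monotone under re-application


class TestSnpsInTrack:
    def test_halfopen_boundaries(self):
        track = [GenomicInterval("chr1", 10, 20)]
        inside = SnpRecord("a", "chr1", 10)
        outside = SnpRecord("b", "chr1", 20)
        assert snps_in_track([inside, outside], track) == [True, False]

    def test_empty_track_all_false(self):
        snps = [SnpRecord(f"s{i}", "chr1", i) for i in range(5)]
        assert snps_in_track(snps, []) == [False] * 5

    def test_chromosome_mismatch_is_nonoverlap(self):
        track = [GenomicInterval("chr2", 0, 100)]
        assert snps_in_track([SnpRecord("a", "chr1", 50)], track) == [False]

    def test_matches_brute_force_oracle_at_scale(self):
        """10^4 SNPs x 10^3 intervals against all-pairs membership."""
        rng = np.random.default_rng(17)
        chroms = ["chr1", "chr2"]
        snps = [
            SnpRecord(f"s{i}", chroms[int(rng.integers(2))], int(rng.integers(0, 100_000)))
            for i in range(10_000)
        ]
        ivs = []
        for i in range(1_000):
            start = int(rng.integers(0, 99_900))
            ivs.append(
                GenomicInterval(chroms[int(rng.integers(2))], start, start + int(rng.integers(1, 100)))
            )
        got = snps_in_track(snps, ivs)
        expected = brute_overlap_flags(
            [s.pos for s in snps], [s.chrom for s in snps], [(v.chrom, v.start, v.end) for v in ivs]
        )
        assert got == expected


class TestOverlapVenn:
    def test_disjoint_all_zero(self):
        snps = [SnpRecord("a", "chr1", 5)]
        tf = [GenomicInterval("chr1", 100, 200)]
        mir = [GenomicInterval("chr1", 300, 400)]
        venn = overlap_venn(snps, tf, mir)
        assert (venn.n_in_tf, venn.n_in_mir, venn.n_in_both) == (0, 0, 0)

    def test_five_snp_hand_tally(self):
        """2 TF-only, 1 both, 1 miR-only, 1 neither; marginals include 'both'."""
        tf = [GenomicInterval("chr1", 0, 100)]
        mir = [GenomicInterval("chr1", 50, 150)]
        snps = [
            SnpRecord("tf1", "chr1", 10),
            SnpRecord("tf2", "chr1", 20),
            SnpRecord("both", "chr1", 60),
            SnpRecord("mir", "chr1", 120),
            SnpRecord("none", "chr1", 500),
        ]
        venn = overlap_venn(snps, tf, mir)
        assert (venn.n_snps, venn.n_in_tf, venn.n_in_mir, venn.n_in_both) == (5, 3, 2, 1)
        assert venn.fractions == {"tf": 0.6, "mir": 0.4, "both": 0.2}

    def test_generator_roundtrip(self):
        """Venn fractions recover the generator's configured co-occurrence."""
        from mirsnp.simulate import synth_tracks

        tr = synth_tracks(n_snps=5000, co_occurrence=0.05, p_tf_only=0.15, p_mir_only=0.05, seed=9)
        venn = overlap_venn(list(tr.snps), list(tr.tf_track), list(tr.mir_track))
        se = np.sqrt(0.05 * 0.95 / 5000)
        assert abs(venn.fractions["both"] - 0.05) < 3 * se


class TestBinomialEnrichment:
    def test_zero_hits_p_one(self):
        assert binomial_enrichment(100, 0, 0.3).p_binomial == 1.0

    def test_five_of_five_half(self):
        assert binomial_enrichment(5, 5, 0.5).p_binomial == pytest.approx(0.03125)

    def test_f_one_p_one(self):
        for k in (0, 3, 10):
            assert binomial_enrichment(10, k, 1.0).p_binomial == pytest.approx(1.0)

    @given(
        n=st.integers(1, 500),
        f=st.floats(0.0, 1.0),
        data=st.data(),
    )
    @settings(max_examples=80, deadline=None)
    def test_matches_exact_rational_summation(self, n, f, data):
        k = data.draw(st.integers(0, n))
        got = binomial_enrichment(n, k, f).p_binomial
        exact = exact_binom_upper_tail(n, k, f)
        assert got == pytest.approx(exact, abs=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(MirsnpError):
            binomial_enrichment(5, 6, 0.5)
        with pytest.raises(MirsnpError):
            binomial_enrichment(5, 2, 1.5)


def test_track_overlap_fraction():
    mir = [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 100, 110)]
    tf = [GenomicInterval("chr1", 5, 50)]
    assert track_overlap_fraction(mir, tf) == pytest.approx(0.5)
    assert track_overlap_fraction([], tf) == 0.0
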