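"""Moving-window ensembles, SNP context summaries and probing concordance."""

import pytest
from hypothesis import given, settings, strategies as st

from mirsnp.core import MirsnpError, Transcript, Variant
from mirsnp.ensemble import (
    DEFAULT_SCHEME,
    CleavageRecord,
    WindowScheme,
    enumerate_windows,
    fold_ensemble,
    probing_concordance,
    site_accessibility,
    snp_context_summary,
)
from mirsnp.fixtures import fig5_cleavage_records
from mirsnp.fold import SecondaryStructure, dotbracket_to_pairs, mfe_fold, pair_context


def _centered_toy(n=2000, pos=None):
    pos = pos or n // 2
    seq = "A" * n
    t = Transcript("t", seq)
    return t, Variant("t", pos, "A", "G")


class TestEnumerateWindows:
    def test_default_scheme_yields_90_per_allele(self):
        t, v = _centered_toy()
        windows = enumerate_windows(t, v, DEFAULT_SCHEME)
        assert len(windows) == 90  # 10 + 20 + 20 + 40; both alleles -> 180
        assert DEFAULT_SCHEME.n_windows() == 90

    def test_small_scheme_offsets(self):
        t, v = _centered_toy(400)
        scheme = WindowScheme(sizes=(100,), steps=(25,))
        windows = enumerate_windows(t, v, scheme)
        assert [w.snp_offset for w in windows] == [25, 50, 75, 100]
        for w in windows:
            assert t.seq[w.start - 1 : w.end][w.snp_offset - 1] == t.base(v.pos)
            assert w.end - w.start + 1 == 100

    def test_out_of_bounds_is_error_not_clip(self):
        t = Transcript("t", "A" * 900)
        v = Variant("t", 850, "A", "G")  # 50 nt from the 3' end
        with pytest.raises(MirsnpError, match="outside transcript"):
            enumerate_windows(t, v, DEFAULT_SCHEME)

    def test_step_outside_10_25_rejected(self):
        with pytest.raises(MirsnpError, match="10-25"):
            WindowScheme(sizes=(100,), steps=(50,))

    @given(
        sizes=st.lists(st.integers(30, 200), min_size=1, max_size=4),
        data=st.data(),
    )
    @settings(max_examples=40, deadline=None)
    def test_count_formula(self, sizes, data):
        """Window count is sum of floor(size/step) over the scheme."""
        steps = tuple(data.draw(st.integers(10, 25)) for _ in sizes)
        scheme = WindowScheme(sizes=tuple(sizes), steps=steps)
        t, v = _centered_toy(2 * max(sizes) + 210, pos=max(sizes) + 100)
        windows = enumerate_windows(t, v, scheme)
        assert len(windows) == sum(s // d for s, d in zip(sizes, steps))


SMALL = WindowScheme(sizes=(40, 60), steps=(10, 20), description="test grid")


class TestFoldEnsemble:
    def test_both_alleles_same_coordinates(self, toy):
        t, v, _ = toy
        folded = fold_ensemble(t, v, SMALL)
        ref = [fw.spec for fw in folded if fw.allele == "ref"]
        alt = [fw.spec for fw in folded if fw.allele == "alt"]
        assert ref == alt
        assert len(folded) == 2 * SMALL.n_windows()

    def test_single_window_structures_differ_only_via_snp(self, toy):
        t, v, _ = toy
        scheme = WindowScheme(sizes=(30,), steps=(15,))
        folded = fold_ensemble(t, v, scheme)
        by_allele = {fw.allele: fw for fw in folded if fw.spec.snp_offset == 15}
        sref, salt = by_allele["ref"].structure, by_allele["alt"].structure
        assert sref.seq != salt.seq
        diffs = [k for k, (a, b) in enumerate(zip(sref.seq, salt.seq)) if a != b]
        assert diffs == [14]

    def test_deterministic(self, toy):
        t, v, _ = toy
        a = fold_ensemble(t, v, SMALL)
        b = fold_ensemble(t, v, SMALL)
        assert [fw.structure.pairs for fw in a] == [fw.structure.pairs for fw in b]


class TestSnpContextSummary:
    def test_unstructured_background_all_loop(self):
        t, v = _centered_toy(300)  # poly-A cannot pair at all
        summary = snp_context_summary(fold_ensemble(t, v, SMALL))
        assert summary["ref"].fraction_loop == 1.0
        assert summary["ref"].n_windows == SMALL.n_windows()

    def test_planted_stem_through_snp_all_stem(self):
        """The SNP closes a designed hairpin that fits inside every window
        frame, so the DP must pair it in each of them."""
        # hairpin GGC/AAAA/GCC spans the 10 nt ending at the SNP, which is
        # the minimum shared upstream context of the offsets {10, 20, 30}
        seq = "A" * 50 + "GGC" + "AAAA" + "GCC" + "A" * 50
        pos = 60  # the final C of the 3' strand, paired to the first G
        t = Transcript("t", seq)
        assert t.base(pos) == "C"
        v = Variant("t", pos, "C", "A")
        scheme = WindowScheme(sizes=(30,), steps=(10,))
        folded = fold_ensemble(t, v, scheme)
        ref_summary = snp_context_summary(folded)["ref"]
        assert ref_summary.fraction_loop == 0.0
        assert ref_summary.n_windows == 3

    def test_fractions_match_direct_recount(self, toy):
        t, v, _ = toy
        folded = fold_ensemble(t, v, SMALL)
        summary = snp_context_summary(folded)
        for allele in ("ref", "alt"):
            stems = sum(
                1
                for fw in folded
                if fw.allele == allele
                and pair_context(fw.structure, fw.spec.snp_offset) == "stem"
            )
            assert summary[allele].n_stem == stems

    def test_order_invariance(self, toy):
        t, v, _ = toy
        folded = fold_ensemble(t, v, SMALL)
        forward = snp_context_summary(folded)
        backward = snp_context_summary(list(reversed(folded)))
        assert forward["ref"] == backward["ref"]


class TestSiteAccessibility:
    def test_all_unpaired(self):
        s = SecondaryStructure("A" * 20, frozenset(), 0.0)
        assert site_accessibility(s, 5, 11) == 1.0

    def test_fully_paired_site(self):
        db = "((((((....))))))"
        s = SecondaryStructure("G" * 16, dotbracket_to_pairs(db), 0.0)
        assert site_accessibility(s, 1, 6) == 0.0

    def test_partial(self):
        db = "(((....)))......"
        s = SecondaryStructure("G" * 16, dotbracket_to_pairs(db), 0.0)
        # site 7..13: positions 7 unpaired, 8-10 paired, 11-13 unpaired -> 4/7
        assert site_accessibility(s, 7, 13) == pytest.approx(4 / 7)

    def test_out_of_bounds(self):
        s = SecondaryStructure("A" * 10, frozenset(), 0.0)
        with pytest.raises(MirsnpError):
            site_accessibility(s, 5, 11)


class TestProbingConcordance:
    def test_unpaired_structure_full_concordance(self):
        s = SecondaryStructure("A" * 30, frozenset(), 0.0)
        recs = [CleavageRecord(position=p, reagent="Pb", strength="strong") for p in (3, 9, 20)]
        rep = probing_concordance(s, recs)
        assert rep.fraction == 1.0
        assert rep.n_total == 3

    def test_t1_on_non_g_flagged_invalid(self):
        s = SecondaryStructure("AAAAA", frozenset(), 0.0)
        rep = probing_concordance(s, [CleavageRecord(position=2, reagent="T1", strength="weak")])
        assert rep.n_total == 0
        assert rep.verdicts[0][1] == "invalid_t1"

    def test_position_outside_window_errors(self):
        s = SecondaryStructure("AAAAA", frozenset(), 0.0)
        with pytest.raises(MirsnpError):
            probing_concordance(s, [CleavageRecord(position=99, reagent="Pb", strength="weak")])

    def test_packaged_fixture_hand_tally(self, toy):
        """Counting the packaged cleavage table against a designed structure
        reproduces a hand tally (Pb: unpaired; T1: unpaired G only)."""
        t, v, _ = toy
        records = fig5_cleavage_records()
        c_recs = [r for r in records if r.allele == "C"]
        g_recs = [r for r in records if r.allele == "G"]
        assert len(c_recs) == 6 and len(g_recs) == 8

        # window 1040..1079 of the C allele, everything unpaired: all six Pb
        # records (1058-1063) concordant
        window = t.seq[1039:1079]
        s_open = SecondaryStructure(window, frozenset(), 0.0)
        rep = probing_concordance(s_open, c_recs, window_start=1040)
        assert (rep.n_concordant, rep.n_total) == (6, 6)

        # G allele on the same open window: T1 at 1054 and 1070 hit G
        # residues; T1 at 1058 hits the alt G; all 5 Pb + 3 T1 concordant
        from mirsnp.core import apply_allele

        g_window = apply_allele(t, v, "alt").seq[1039:1079]
        rep_g = probing_concordance(
            SecondaryStructure(g_window, frozenset(), 0.0), g_recs, window_start=1040
        )
        assert (rep_g.n_concordant, rep_g.n_total) == (8, 8)

        # pair positions 1058-1060 (local 19-21) with 1069-1071: those Pb
        # records become discordant on the C allele
        paired = frozenset({(19, 32), (20, 31), (21, 30)})
        rep2 = probing_concordance(
            SecondaryStructure(window, paired, 0.0), c_recs, window_start=1040
        )
        assert (rep2.n_concordant, rep2.n_total) == (3, 6)
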