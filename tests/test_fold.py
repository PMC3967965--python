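"""MFE folding: scorer identities, DP-vs-enumeration equivalence, contexts."""

import random

import pytest

from mirsnp.core import MirsnpError
from mirsnp.fold import (
    InvalidStructureError,
    SecondaryStructure,
    dotbracket_to_pairs,
    energy_of_structure,
    mfe_fold,
    pair_context,
)
from oracles import brute_min_energy, enumerate_structures


class TestScorer:
    def test_empty_structure_is_zero_reference(self, model):
        assert energy_of_structure("ACGUACGUACGU", frozenset(), model) == 0.0

    def test_hand_summed_helix(self, model):
        """Three GC-on-GC stacks plus a hairpin-4 penalty, straight from the table."""
        seq = "GGGGAAAACCCC"
        pairs = {(1, 12), (2, 11), (3, 10), (4, 9)}
        expected = 3 * model.stack_energy("GC", "GC") + model.hairpin(12)[4] / 100.0
        assert energy_of_structure(seq, pairs, model) == pytest.approx(expected)
        assert expected == pytest.approx(3 * -3.26 + 5.60)

    def test_crossing_pairs_rejected(self, model):
        with pytest.raises(InvalidStructureError, match="crossing"):
            energy_of_structure("GGGGGAAAAACCCCCUUUUU", {(1, 12), (5, 17)}, model)

    def test_short_hairpin_rejected(self, model):
        with pytest.raises(InvalidStructureError, match="hairpin"):
            energy_of_structure("GAAC", {(1, 4)}, model)

    def test_noncanonical_pair_rejected(self, model):
        with pytest.raises(InvalidStructureError, match="non-canonical"):
            energy_of_structure("AAAAAA", {(1, 6)}, model)

    def test_clashing_pairs_rejected(self, model):
        with pytest.raises(InvalidStructureError, match="more than one"):
            energy_of_structure("GGAAAACCCC", {(1, 10), (1, 9)}, model)


class TestMfeFold:
    def test_unpairable_sequence_all_dots(self, model):
        s = mfe_fold("AAAAAAAAAA", model)
        assert s.dotbracket == ".........."
        assert s.energy == 0.0

    def test_too_short_for_any_pair(self, model):
        s = mfe_fold("GCGC", model)
        assert s.dotbracket == "...."
        assert s.energy == 0.0

    def test_perfect_hairpin(self, model):
        s = mfe_fold("GGGGAAAACCCC", model)
        assert s.dotbracket == "((((....))))"
        best, _ = brute_min_energy(s.seq, lambda q, p: energy_of_structure(q, p, model))
        assert s.energy == pytest.approx(best)

    def test_deterministic(self, model, toy):
        seq = toy[0].seq[1000:1100]
        assert mfe_fold(seq, model).pairs == mfe_fold(seq, model).pairs

    def test_matches_enumeration_oracle_randomized(self, model):
        """DP energy equals exhaustive-enumeration minimum on short sequences."""
        rng = random.Random(20140327)
        for _ in range(60):
            n = rng.randint(5, 12)
            seq = "".join(rng.choice("ACGU") for _ in range(n))
            best, _ = brute_min_energy(seq, lambda q, p: energy_of_structure(q, p, model))
            got = mfe_fold(seq, model)
            assert got.energy == pytest.approx(best), seq
            # scorer/DP consistency on the returned structure
            assert energy_of_structure(seq, got.pairs, model) == pytest.approx(got.energy)

    def test_matches_oracle_with_constraints(self, model):
        rng = random.Random(1058)
        for _ in range(25):
            n = rng.randint(6, 12)
            seq = "".join(rng.choice("ACGU") for _ in range(n))
            cons = frozenset(rng.sample(range(1, n + 1), k=2))
            best, _ = brute_min_energy(
                seq, lambda q, p: energy_of_structure(q, p, model), constraints=cons
            )
            got = mfe_fold(seq, model, constraints=cons)
            assert got.energy == pytest.approx(best), (seq, cons)
            assert not any(i in cons or j in cons for i, j in got.pairs)

    def test_constraint_monotonicity(self, model):
        """Forcing positions unpaired can never lower the optimum."""
        rng = random.Random(6232)
        for _ in range(20):
            n = rng.randint(10, 40)
            seq = "".join(rng.choice("ACGU") for _ in range(n))
            free = mfe_fold(seq, model).energy
            cons = rng.sample(range(1, n + 1), k=3)
            constrained = mfe_fold(seq, model, constraints=cons).energy
            assert constrained >= free - 1e-9

    def test_multiloop_recovered(self, model):
        """A designed two-hairpin clover folds into a multiloop the scorer re-scores."""
        seq = "GGGGGCCCCAAAAGGGGUUUUCCCCGGGGAAAACCCCGCCCC"
        s = mfe_fold(seq, model)
        assert energy_of_structure(seq, s.pairs, model) == pytest.approx(s.energy)

    def test_invalid_constraint_position(self, model):
        with pytest.raises(MirsnpError):
            mfe_fold("GGGAAACCC", model, constraints=[99])


class TestDotbracket:
    def test_roundtrip(self):
        db = "((..((...))..)).."
        pairs = dotbracket_to_pairs(db)
        s = SecondaryStructure("A" * len(db), pairs, 0.0)
        assert s.dotbracket == db

    def test_unbalanced_rejected(self):
        with pytest.raises(InvalidStructureError):
            dotbracket_to_pairs("(()")


class TestPairContext:
    @pytest.mark.parametrize(
        "db,pos,expected",
        [
            ("((((....))))", 6, "hairpin_loop"),
            ("((((....))))", 2, "stem"),
            ("..((((....))))", 1, "exterior"),
            ("((.((....)).))", 3, "internal_or_bulge"),
            ("((((...))((...))))", 2, "stem"),
        ],
    )
    def test_contexts(self, db, pos, expected):
        s = SecondaryStructure("G" * len(db), dotbracket_to_pairs(db), 0.0)
        assert pair_context(s, pos) == expected

    def test_multiloop_unpaired(self):
        db = "((((...)).((...)).))"
        s = SecondaryStructure("G" * len(db), dotbracket_to_pairs(db), 0.0)
        assert pair_context(s, 10) == "multiloop"

    def test_out_of_range(self):
        s = SecondaryStructure("GGGAAACCC", frozenset(), 0.0)
        with pytest.raises(MirsnpError):
            pair_context(s, 10)


def test_enumeration_oracle_is_nontrivial():
    """Sanity: the oracle enumerates more than the empty structure."""
    structs = enumerate_structures("GGGGAAAACCCC")
    assert frozenset() in structs
    assert any(len(p) >= 4 for p in structs)
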