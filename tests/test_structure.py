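"""Sequence/structure domain model: parsing, pairing rules, stacks."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from stackpath import (
    PairFate,
    RnaSequence,
    SecondaryStructure,
    Stack,
    classify_pair,
    enumerate_stacks,
    pair_allowed,
    parse_structure,
    render_structure,
    stack_relation,
    structure_distance,
)
from stackpath.structure import ParseError, StructureError

from conftest import random_valid_structure


class TestRnaSequence:
    def test_valid_and_length(self):
        x = RnaSequence("gcau")
        assert x.letters == "GCAU"
        assert x.n == 4
        assert x.base(1) == "G" and x.base(4) == "U"

    def test_t_normalized_with_warning(self):
        with pytest.warns(UserWarning, match="normalizing"):
            x = RnaSequence("ACGT")
        assert x.letters == "ACGU"

    @pytest.mark.parametrize("bad", ["", "ACGX", "AC GU"])
    def test_rejects_bad_input(self, bad):
        with pytest.raises(ValueError):
            RnaSequence(bad)


class TestDotBracket:
    def test_parse_gc_helix(self):
        S = parse_structure("((((....))))....")
        assert S.pairs == frozenset({(1, 12), (2, 11), (3, 10), (4, 9)})

    def test_parse_all_dots(self):
        assert parse_structure("." * 16).pairs == frozenset()

    @pytest.mark.parametrize("text", ["(..))", "((..)", "(.x.)"])
    def test_parse_errors_carry_position(self, text):
        with pytest.raises(ParseError) as err:
            parse_structure(text)
        assert err.value.position is not None

    def test_render_au_helix(self):
        S = SecondaryStructure({(5, 16), (6, 15), (7, 14), (8, 13)})
        assert render_structure(S, 16) == "....((((....))))"

    def test_render_empty(self):
        assert render_structure(SecondaryStructure(), 4) == "...."

    def test_render_out_of_range(self):
        with pytest.raises(StructureError):
            render_structure(SecondaryStructure({(1, 20)}), 16)

    @given(st.data())
    def test_parse_render_roundtrip(self, data):
        rng = random.Random(data.draw(st.integers(0, 10**6)))
        n = data.draw(st.integers(8, 60))
        S = random_valid_structure(rng, n)
        assert parse_structure(render_structure(S, n)).pairs == S.pairs


class TestStructureValidation:
    def test_rejects_crossing(self):
        with pytest.raises(StructureError, match="crossing"):
            SecondaryStructure({(2, 11), (5, 16)})

    def test_rejects_shared_position(self):
        with pytest.raises(StructureError, match="reused"):
            SecondaryStructure({(1, 12), (1, 16)})

    def test_rejects_inverted(self):
        with pytest.raises(StructureError):
            SecondaryStructure({(12, 1)})


class TestPairAllowed:
    def test_wobble(self, toy_x):
        assert pair_allowed(toy_x, 1, 16)  # G-U

    def test_loop_too_short(self, toy_x):
        assert not pair_allowed(toy_x, 1, 2)

    def test_canonical_au(self, toy_x):
        assert pair_allowed(toy_x, 5, 16)  # A-U

    def test_noncomplementary(self, toy_x):
        assert not pair_allowed(toy_x, 1, 4)  # G-G


class TestClassifyPair:
    def test_conflict(self):
        S = SecondaryStructure({(1, 12)})
        assert classify_pair(S, (1, 16)) is PairFate.CONFLICT

    def test_clash(self):
        S = SecondaryStructure({(2, 11)})
        assert classify_pair(S, (5, 16)) is PairFate.CLASH

    def test_ok_on_empty(self):
        assert classify_pair(SecondaryStructure(), (5, 16)) is PairFate.OK

    @given(st.integers(0, 10**6))
    def test_ok_iff_full_revalidation_passes(self, seed):
        """classify OK exactly when rebuilding S + pair from scratch succeeds."""
        rng = random.Random(seed)
        n = 30
        S = random_valid_structure(rng, n)
        i = rng.randint(1, n - 1)
        j = rng.randint(i + 1, n)
        fate = classify_pair(S, (i, j))
        if (i, j) in S.pairs:
            # re-adding a present pair conflicts even though the set is unchanged
            assert fate is PairFate.CONFLICT
            return
        try:
            SecondaryStructure(set(S.pairs) | {(i, j)})
            rebuilt_ok = True
        except StructureError:
            rebuilt_ok = False
        assert (fate is PairFate.OK) == rebuilt_ok


class TestStructureDistance:
    def test_toy_distance_is_eight(self, toy_A, toy_B):
        assert structure_distance(toy_A, toy_B) == 8

    def test_identity_and_empty(self, toy_A):
        assert structure_distance(toy_A, toy_A) == 0
        three = SecondaryStructure({(1, 10), (2, 9), (3, 8)})
        assert structure_distance(SecondaryStructure(), three) == 3

    @given(st.integers(0, 10**6))
    def test_metric_properties(self, seed):
        rng = random.Random(seed)
        n = 24
        A, B, C = (random_valid_structure(rng, n, 6) for _ in range(3))
        dAB = structure_distance(A, B)
        assert dAB == structure_distance(B, A)
        assert dAB >= 0
        assert (dAB == 0) == (A.pairs == B.pairs)
        assert dAB <= structure_distance(A, C) + structure_distance(C, B)


def _brute_force_stacks(x: RnaSequence, min_len: int, min_hairpin: int = 3):
    """Independent enumeration: allowability matrix, runs per anti-diagonal."""
    n = x.n
    allowed = {
        (i, j)
        for i in range(1, n + 1)
        for j in range(i + 1, n + 1)
        if pair_allowed(x, i, j, min_hairpin)
    }
    found = set()
    for s in range(3, 2 * n + 1):  # anti-diagonal: i + j = s
        run = []
        for i in range(1, n + 1):
            j = s - i
            if j <= i:
                break
            if (i, j) in allowed:
                run.append((i, j))
            else:
                if len(run) >= min_len:
                    found.add((run[0], len(run)))
                run = []
        if len(run) >= min_len:
            found.add((run[0], len(run)))
    return found


class TestEnumerateStacks:
    def test_toy_contains_gc_au_and_gu_stacks(self, toy_x):
        stacks = enumerate_stacks(toy_x, 4)
        as_sets = [set(st.pairs) for st in stacks]
        assert {(1, 12), (2, 11), (3, 10), (4, 9)} in as_sets
        assert {(5, 16), (6, 15), (7, 14), (8, 13)} in as_sets
        assert {(1, 16), (2, 15), (3, 14), (4, 13)} in as_sets

    def test_unpairable_sequence(self):
        assert enumerate_stacks(RnaSequence("AAAAAAAA")) == ()

    def test_min_len_n_is_empty(self, toy_x):
        assert enumerate_stacks(toy_x, toy_x.n) == ()

    @given(st.integers(0, 500))
    def test_matches_bruteforce_on_random_sequences(self, seed):
        rng = random.Random(seed)
        n = rng.randint(12, 30)
        x = RnaSequence("".join(rng.choice("ACGU") for _ in range(n)))
        got = {(st_.outer, st_.length) for st_ in enumerate_stacks(x, 3)}
        assert got == _brute_force_stacks(x, 3)


class TestStackRelation:
    def test_any_stack_compatible_with_empty(self, toy_x):
        gc = Stack((1, 12), 4)
        assert stack_relation(gc, SecondaryStructure()) == "compatible"

    def test_crossing_stack_incompatible(self, toy_A):
        au = Stack((5, 16), 4)
        assert stack_relation(au, toy_A) == "incompatible"

    def test_subset_stack_compatible(self, toy_A):
        gc = Stack((1, 12), 4)
        assert stack_relation(gc, toy_A) == "compatible"
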