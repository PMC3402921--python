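"""Mutation strategies: reference behaviors and universal contracts."""

import random
from collections import Counter

import pytest
from hypothesis import given
from hypothesis import strategies as st

from stackpath import (
    Action,
    ActionChain,
    MutationContext,
    biased_index_choice,
    feasible_interval,
    m1_move,
    m2_swap,
    m3_insert_pair,
    m4_force_stack,
    m5_convert_stacks,
    simple_pathway,
    validate_chain,
)
from stackpath.mutation import relocate_action
from stackpath.pathway import chain_is_valid
from stackpath.synthetic import RandomInstanceSpec, random_instance, toy_switch

ALL_STRATEGIES = (m1_move, m2_swap, m3_insert_pair, m4_force_stack, m5_convert_stacks)


@pytest.fixture()
def toy_chain(toy_A, toy_B):
    return simple_pathway(toy_A, toy_B, "outermost_first", "innermost_first")


@pytest.fixture()
def toy_ctx(toy_x, toy_A, toy_B):
    return MutationContext.for_instance(toy_x, toy_A, toy_B, seed=7)


def _multiset(chain):
    return Counter(chain.actions)


class TestRelocation:
    def test_move_first_action_after_fourth(self, toy_chain):
        acts = relocate_action(toy_chain.actions, 1, 4)
        expected = toy_chain.actions[1:4] + (toy_chain.actions[0],) + toy_chain.actions[4:]
        assert acts == expected

    def test_adjacent_backward_move_is_identity(self, toy_chain):
        assert relocate_action(toy_chain.actions, 3, 2) == toy_chain.actions

    def test_interval_admits_known_valid_target(self, toy_chain, toy_A, toy_B):
        interval = feasible_interval(toy_A, toy_B, toy_chain.actions, 1)
        assert interval is not None
        l, u = interval
        assert l <= 4 <= u  # relocating the first deletion after a4 is valid
        for t2 in range(l, u + 1):
            if t2 == 1:
                continue
            assert chain_is_valid(
                toy_A, toy_B, relocate_action(toy_chain.actions, 1, t2)
            )

    def test_interval_excludes_known_invalid_target(self, toy_chain, toy_A, toy_B):
        # moving the last addition to the front is invalid (crosses helix A)
        interval = feasible_interval(toy_A, toy_B, toy_chain.actions, 8)
        assert interval is not None
        l, _ = interval
        assert l > 1

    def test_single_action_chain_has_no_targets(self):
        from stackpath import SecondaryStructure

        A = SecondaryStructure()
        B = SecondaryStructure({(1, 8)})
        acts = (Action("add", (1, 8)),)
        assert feasible_interval(A, B, acts, 1) is None


class TestBiasedChoice:
    def test_degenerate_interval(self):
        rng = random.Random(0)
        assert biased_index_choice(5, 5, "front_loaded", rng) == 5

    def test_front_loaded_weights_match_linear_law(self):
        """[1,3] with beta=1 should draw with probabilities (3/6, 2/6, 1/6)."""
        rng = random.Random(123)
        n = 100_000
        counts = Counter(
            biased_index_choice(1, 3, "front_loaded", rng) for _ in range(n)
        )
        for t, p in [(1, 3 / 6), (2, 2 / 6), (3, 1 / 6)]:
            sigma = (n * p * (1 - p)) ** 0.5
            assert abs(counts[t] - n * p) < 3 * sigma

    def test_back_loaded_reverses_preference(self):
        rng = random.Random(5)
        counts = Counter(
            biased_index_choice(1, 4, "back_loaded", rng) for _ in range(20_000)
        )
        assert counts[4] > counts[1]

    def test_exclusion(self):
        rng = random.Random(1)
        draws = {biased_index_choice(1, 3, "back_loaded", rng, exclude=2)
                 for _ in range(200)}
        assert 2 not in draws


class TestReferenceBehaviors:
    def test_m1_produces_relocations(self, toy_chain, toy_ctx):
        q = m1_move(toy_chain, toy_ctx)
        assert q is not None
        assert _multiset(q) == _multiset(toy_chain)
        assert chain_is_valid(q.A, q.B, q.actions)

    def test_m2_swap_of_middle_deletions_is_valid(self, toy_chain, toy_A, toy_B):
        acts = list(toy_chain.actions)
        acts[1], acts[3] = acts[3], acts[1]
        assert chain_is_valid(toy_A, toy_B, acts)

    def test_m2_endpoint_swap_is_invalid(self, toy_chain, toy_A, toy_B):
        acts = list(toy_chain.actions)
        acts[0], acts[7] = acts[7], acts[0]
        assert not chain_is_valid(toy_A, toy_B, acts)

    def test_m3_reference_insertion(self, toy_chain, toy_A, toy_B):
        # add(1,16) after a1 and del(1,16) after a7
        acts = (
            toy_chain.actions[:1]
            + (Action("add", (1, 16)),)
            + toy_chain.actions[1:7]
            + (Action("del", (1, 16)),)
            + toy_chain.actions[7:]
        )
        v = validate_chain(toy_A, toy_B, acts)
        assert v.ok
        assert any((1, 16) in S.pairs for S in v.intermediates)

    def test_m3_nested_triple_builds_temporary_wobble_stack(
        self, toy_chain, toy_A, toy_B
    ):
        """Three nested insertions form the transient GU helix of the toy."""
        acts = list(toy_chain.actions)
        # successively: add(1,16) after a1, add(2,15) after a3', add(3,14) after a5''
        acts = acts[:1] + [Action("add", (1, 16))] + acts[1:7] + [Action("del", (1, 16))] + acts[7:]
        acts = acts[:3] + [Action("add", (2, 15))] + acts[3:7] + [Action("del", (2, 15))] + acts[7:]
        acts = acts[:5] + [Action("add", (3, 14))] + acts[5:7] + [Action("del", (3, 14))] + acts[7:]
        v = validate_chain(toy_A, toy_B, tuple(acts))
        assert v.ok
        assert any(
            {(1, 16), (2, 15), (3, 14)} <= S.pairs for S in v.intermediates
        )

    def test_m3_offspring_of_direct_chain_has_two_indirect_actions(
        self, toy_chain, toy_ctx
    ):
        q = m3_insert_pair(toy_chain, toy_ctx)
        assert q is not None
        assert len(q) == len(toy_chain) + 2
        added = _multiset(q) - _multiset(toy_chain)
        assert sum(added.values()) == 2
        (a1, _), (a2, _) = added.items()
        assert a1.pair == a2.pair and {a1.kind, a2.kind} == {"add", "del"}

    def test_m4_forces_consecutive_stack_formation(self, toy_chain, toy_ctx):
        q = m4_force_stack(toy_chain, toy_ctx)
        assert q is not None
        assert chain_is_valid(q.A, q.B, q.actions)
        # no direct action lost
        assert set(_multiset(toy_chain)) <= set(_multiset(q))

    def test_m5_requires_deletions(self, toy_ctx):
        from stackpath import SecondaryStructure

        A = SecondaryStructure()
        B = SecondaryStructure({(5, 16), (6, 15), (7, 14), (8, 13)})
        chain = simple_pathway(A, B)
        ctx = MutationContext.for_instance(toy_ctx.x, A, B, seed=3)
        assert m5_convert_stacks(chain, ctx) is None

    def test_m5_interleaves_melting_and_formation(self):
        """With partially overlapping helices, some offspring avoids the
        fully unpaired intermediate that the simple pathway passes through."""
        from stackpath import RnaSequence, SecondaryStructure

        # helix A = (1..4, 9..12); helix B = (10..13, 18..21): they share
        # only positions 10-12, so B can start forming before A fully melts
        x = RnaSequence("GGGG" + "AAAA" + "CCCC" + "C" + "AAAA" + "GGGG")
        A = SecondaryStructure({(1, 12), (2, 11), (3, 10), (4, 9)})
        B = SecondaryStructure({(10, 21), (11, 20), (12, 19), (13, 18)})
        chain = simple_pathway(A, B)
        v0 = validate_chain(A, B, chain.actions)
        assert min(len(S.pairs) for S in v0.intermediates) == 0
        found_better = False
        for seed in range(10):
            ctx = MutationContext.for_instance(x, A, B, seed=seed)
            q = m5_convert_stacks(chain, ctx)
            if q is None:
                continue
            v = validate_chain(A, B, q.actions)
            if min(len(S.pairs) for S in v.intermediates) > 0:
                found_better = True
                break
        assert found_better


class TestUniversalContracts:
    @given(st.integers(0, 25))
    def test_offspring_validity_and_multisets(self, seed):
        inst = random_instance(RandomInstanceSpec(n=26, k_stacks=2, seed=seed))
        chain = simple_pathway(inst.A, inst.B)
        ctx = MutationContext.for_instance(
            inst.x, inst.A, inst.B, seed=seed + 1000
        )
        for fn in ALL_STRATEGIES:
            for _ in range(8):
                q = fn(chain, ctx)
                if q is None:
                    continue
                assert chain_is_valid(inst.A, inst.B, q.actions)
                if fn in (m1_move, m2_swap):
                    assert _multiset(q) == _multiset(chain)
                elif fn is m3_insert_pair:
                    assert len(q) == len(chain) + 2
                else:
                    direct = Counter(
                        a for a in chain.actions
                        if a.is_direct(inst.A, inst.B)
                    )
                    assert all(
                        _multiset(q)[a] >= c for a, c in direct.items()
                    )

    def test_deterministic_offspring_stream(self, toy_chain, toy_x, toy_A, toy_B):
        def stream(seed):
            ctx = MutationContext.for_instance(toy_x, toy_A, toy_B, seed=seed)
            out = []
            for fn in ALL_STRATEGIES:
                for _ in range(5):
                    q = fn(toy_chain, ctx)
                    out.append(None if q is None else q.actions)
            return out

        assert stream(99) == stream(99)
        assert stream(99) != stream(100)  # astronomically unlikely to collide

    def test_empty_chain_yields_none(self, toy_x, toy_A):
        chain = ActionChain((), toy_A, toy_A)
        ctx = MutationContext.for_instance(toy_x, toy_A, toy_A, seed=0)
        for fn in ALL_STRATEGIES:
            assert fn(chain, ctx) is None
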