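"""Offspring-generating mutation strategies on action chains.

Five strategies, in three families:

* reordering — M1 relocates one action, M2 swaps two actions;
* indirect detours — M3 inserts a complementary add/del (or del/add)
  pair, letting a pathway transiently use base pairs outside A and B;
* stack moves — M4 forces the formation of a whole compatible helix
  after some step, M5 converts between incompatible helices by
  interleaving the deletions that unblock each added pair.

Every strategy returns either a *valid* chain with the same endpoints
or ``None`` (after ``retry_limit`` failed draws).  The random source in
the context is the only nondeterminism: a fixed seed reproduces the
offspring stream exactly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .structure import (
    PairFate,
    RnaSequence,
    SecondaryStructure,
    Stack,
    classify_pair,
    enumerate_stacks,
    pair_allowed,
    stack_relation,
)
from .pathway import Action, ActionChain, chain_is_valid

__all__ = [
    "MutationContext",
    "feasible_interval",
    "biased_index_choice",
    "m1_move",
    "m2_swap",
    "m3_insert_pair",
    "m4_force_stack",
    "m5_convert_stacks",
    "relocate_action",
]


@dataclass
class MutationContext:
    """Shared state for the mutation operators.

    ``beta`` shapes the biased position choice (weights are linear for
    beta=1); ``retry_limit`` bounds the rejected draws per offspring.
    """

    x: RnaSequence
    A: SecondaryStructure
    B: SecondaryStructure
    stacks: tuple[Stack, ...] = ()
    rng: random.Random = field(default_factory=random.Random)
    retry_limit: int = 50
    beta: float = 1.0
    min_hairpin: int = 3

    @classmethod
    def for_instance(
        cls,
        x: RnaSequence,
        A: SecondaryStructure,
        B: SecondaryStructure,
        seed: int | None = None,
        min_stack_len: int = 4,
        min_hairpin: int = 3,
        retry_limit: int = 50,
        beta: float = 1.0,
    ) -> "MutationContext":
        return cls(
            x=x,
            A=A,
            B=B,
            stacks=enumerate_stacks(x, min_stack_len, min_hairpin),
            rng=random.Random(seed),
            retry_limit=retry_limit,
            beta=beta,
            min_hairpin=min_hairpin,
        )


# ---------------------------------------------------------------------------
# shared machinery
# ---------------------------------------------------------------------------

def relocate_action(
    actions: tuple[Action, ...], t1: int, t2: int
) -> tuple[Action, ...]:
    """Remove action at 1-based position t1 and re-insert it after position t2.

    t2 ranges over 0..m with t2 = 0 meaning "place first"; t2 refers to
    the action originally at that position.
    """
    m = len(actions)
    if not 1 <= t1 <= m:
        raise IndexError(f"t1={t1} out of range 1..{m}")
    if not 0 <= t2 <= m or t2 == t1:
        raise IndexError(f"t2={t2} invalid for t1={t1}, m={m}")
    moved = actions[t1 - 1]
    rest = actions[: t1 - 1] + actions[t1:]
    at = t2 if t2 < t1 else t2 - 1  # index of original a_t2 within rest
    return rest[:at] + (moved,) + rest[at:]


def feasible_interval(
    A: SecondaryStructure,
    B: SecondaryStructure,
    actions: tuple[Action, ...],
    t1: int,
) -> tuple[int, int] | None:
    """Contiguous block [l, u] of valid relocation targets around t1.

    Scans outward from t1 in both directions, stopping at the first
    infeasible position on each side (full chain revalidation decides
    feasibility).  t1 itself is excluded as a target.  A single-action
    chain has no distinct rearrangement and yields ``None``.
    """
    m = len(actions)
    if m < 2:
        return None
    lo = t1
    t2 = t1 - 1
    while t2 >= 0 and chain_is_valid(A, B, relocate_action(actions, t1, t2)):
        lo = t2
        t2 -= 1
    hi = t1
    t2 = t1 + 1
    while t2 <= m and chain_is_valid(A, B, relocate_action(actions, t1, t2)):
        hi = t2
        t2 += 1
    if lo == t1 and hi == t1:
        return None
    return (lo, hi)


def biased_index_choice(
    l: int,
    u: int,
    mode: str,
    rng: random.Random,
    beta: float = 1.0,
    exclude: int | None = None,
) -> int:
    """Draw an index in [l, u] with strictly monotone weights.

    front_loaded: weight(t) = (u - t + 1)**beta (earlier more likely);
    back_loaded:  weight(t) = (t - l + 1)**beta (later more likely).
    """
    if mode not in ("front_loaded", "back_loaded"):
        raise ValueError(f"unknown bias mode {mode!r}")
    candidates = [t for t in range(l, u + 1) if t != exclude]
    if not candidates:
        raise ValueError(f"empty choice interval [{l},{u}] excluding {exclude}")
    if mode == "front_loaded":
        weights = [float(u - t + 1) ** beta for t in candidates]
    else:
        weights = [float(t - l + 1) ** beta for t in candidates]
    return rng.choices(candidates, weights=weights, k=1)[0]


def _replay(
    A: SecondaryStructure, actions: list[Action] | tuple[Action, ...], upto: int
) -> SecondaryStructure | None:
    """Structure after the first ``upto`` actions, or None if invalid."""
    from .pathway import PathwayError, apply_action

    S = A
    try:
        for a in actions[:upto]:
            S = apply_action(S, a)
    except PathwayError:
        return None
    return S


# ---------------------------------------------------------------------------
# M1 / M2 — reordering
# ---------------------------------------------------------------------------

def m1_move(p: ActionChain, ctx: MutationContext) -> ActionChain | None:
    """Relocate one uniformly chosen action within its feasible interval.

    Additions are re-placed front-loaded and deletions back-loaded:
    pairing early and unpairing late keeps intermediates stacked.
    """
    m = len(p)
    if m < 2:
        return None
    for _ in range(ctx.retry_limit):
        t1 = ctx.rng.randint(1, m)
        interval = feasible_interval(p.A, p.B, p.actions, t1)
        if interval is None:
            continue
        l, u = interval
        mode = (
            "front_loaded"
            if p.actions[t1 - 1].kind == "add"
            else "back_loaded"
        )
        t2 = biased_index_choice(l, u, mode, ctx.rng, ctx.beta, exclude=t1)
        return ActionChain(relocate_action(p.actions, t1, t2), p.A, p.B)
    return None


def m2_swap(p: ActionChain, ctx: MutationContext) -> ActionChain | None:
    """Swap two uniformly chosen actions; invalid draws are restarted."""
    m = len(p)
    if m < 2:
        return None
    for _ in range(ctx.retry_limit):
        t1 = ctx.rng.randint(1, m - 1)
        t2 = ctx.rng.randint(t1 + 1, m)
        acts = list(p.actions)
        acts[t1 - 1], acts[t2 - 1] = acts[t2 - 1], acts[t1 - 1]
        if chain_is_valid(p.A, p.B, acts):
            return ActionChain(tuple(acts), p.A, p.B)
    return None


# ---------------------------------------------------------------------------
# M3 — complementary action pair (indirect detours)
# ---------------------------------------------------------------------------

def _complementary_insertion_block(
    A: SecondaryStructure,
    B: SecondaryStructure,
    actions: list[Action] | tuple[Action, ...],
    t1: int,
    first: Action,
    second: Action,
) -> tuple[int, int] | None:
    """Contiguous block of valid positions t2 > t1 for the second action.

    The candidate chain places ``first`` after a_t1 and ``second`` after
    the action originally at t2; scanning starts at t1+1 and the first
    contiguous run of valid placements is returned.
    """
    acts = tuple(actions)
    m = len(acts)
    lo = None
    hi = None
    for t2 in range(t1 + 1, m + 1):
        cand = (
            acts[:t1] + (first,) + acts[t1:t2] + (second,) + acts[t2:]
        )
        if chain_is_valid(A, B, cand):
            if lo is None:
                lo = t2
            hi = t2
        elif lo is not None:
            break
    if lo is None:
        return None
    return (lo, hi)


def m3_insert_pair(
    p: ActionChain, ctx: MutationContext, sign: str | None = None
) -> ActionChain | None:
    """Insert a complementary add/del (or del/add) pair of actions.

    For ``add_then_del`` the pair is drawn uniformly from pairs that
    neither conflict nor clash with the structure after the anchor; for
    ``del_then_add`` from the pairs present there.  The complementary
    action position is drawn back-loaded, so a transient pair lives for
    a while before being undone.
    """
    m = len(p)
    if m == 0:
        return None
    if sign is not None and sign not in ("add_then_del", "del_then_add"):
        raise ValueError(f"unknown sign {sign!r}")
    inter = p.intermediates()
    for _ in range(ctx.retry_limit):
        s = sign or ctx.rng.choice(("add_then_del", "del_then_add"))
        t1 = ctx.rng.randint(1, m)
        S = inter[t1]
        if s == "add_then_del":
            n = ctx.x.n
            candidates = [
                (i, j)
                for i in range(1, n)
                for j in range(i + 1, n + 1)
                if pair_allowed(ctx.x, i, j, ctx.min_hairpin)
                and classify_pair(S, (i, j)) is PairFate.OK
            ]
            if not candidates:
                continue
            pair = candidates[ctx.rng.randrange(len(candidates))]
            first, second = Action("add", pair), Action("del", pair)
        else:
            candidates = sorted(S.pairs)
            if not candidates:
                continue
            pair = candidates[ctx.rng.randrange(len(candidates))]
            first, second = Action("del", pair), Action("add", pair)
        block = _complementary_insertion_block(
            p.A, p.B, p.actions, t1, first, second
        )
        if block is None:
            continue
        t2 = biased_index_choice(*block, "back_loaded", ctx.rng, ctx.beta)
        acts = (
            p.actions[:t1]
            + (first,)
            + p.actions[t1:t2]
            + (second,)
            + p.actions[t2:]
        )
        return ActionChain(acts, p.A, p.B)
    return None


# ---------------------------------------------------------------------------
# M4 / M5 — stack formation and conversion
# ---------------------------------------------------------------------------

def _place_add_after(
    work: list[Action], ctx: MutationContext, pos: int, pair: tuple[int, int]
) -> tuple[list[Action], int] | None:
    """Make ``pair`` form directly after 1-based position ``pos``.

    Relocates an existing later add of the same pair when there is one
    (M1 mechanics); otherwise inserts the addition together with a
    back-loaded complementary deletion (M3 mechanics).  Returns the new
    action list and the position of the placed addition, or None.
    """
    target = Action("add", pair)
    idx = next(
        (k for k in range(pos, len(work)) if work[k] == target), None
    )
    if idx is not None:
        new = work[:pos] + [work[idx]] + work[pos:idx] + work[idx + 1:]
        if chain_is_valid(ctx.A, ctx.B, new):
            return new, pos + 1
        return None
    first, second = target, Action("del", pair)
    block = _complementary_insertion_block(
        ctx.A, ctx.B, work, pos, first, second
    )
    if block is None:
        return None
    t2 = biased_index_choice(*block, "back_loaded", ctx.rng, ctx.beta)
    new = work[:pos] + [first] + work[pos:t2] + [second] + work[t2:]
    if chain_is_valid(ctx.A, ctx.B, new):
        return new, pos + 1
    return None


def _place_del_after(
    work: list[Action], ctx: MutationContext, pos: int, pair: tuple[int, int]
) -> tuple[list[Action], int] | None:
    """Make ``pair`` be deleted directly after position ``pos``.

    Mirror image of :func:`_place_add_after`: relocate a later deletion
    of the pair forward, or insert a deletion plus a back-loaded
    complementary re-addition.
    """
    target = Action("del", pair)
    idx = next(
        (k for k in range(pos, len(work)) if work[k] == target), None
    )
    if idx is not None:
        new = work[:pos] + [work[idx]] + work[pos:idx] + work[idx + 1:]
        if chain_is_valid(ctx.A, ctx.B, new):
            return new, pos + 1
        return None
    first, second = target, Action("add", pair)
    block = _complementary_insertion_block(
        ctx.A, ctx.B, work, pos, first, second
    )
    if block is None:
        return None
    t2 = biased_index_choice(*block, "back_loaded", ctx.rng, ctx.beta)
    new = work[:pos] + [first] + work[pos:t2] + [second] + work[t2:]
    if chain_is_valid(ctx.A, ctx.B, new):
        return new, pos + 1
    return None


def m4_force_stack(p: ActionChain, ctx: MutationContext) -> ActionChain | None:
    """Force a whole compatible helix to form after a random step.

    The missing pairs of the chosen stack are placed consecutively,
    innermost pair first, each via relocation of its existing addition
    or via a transient complementary pair.
    """
    m = len(p)
    if m == 0 or not ctx.stacks:
        return None
    inter = p.intermediates()
    for _ in range(ctx.retry_limit):
        t = ctx.rng.randint(1, m)
        S_t = inter[t]
        cands = [
            st
            for st in ctx.stacks
            if set(st.pairs) - S_t.pairs
            and stack_relation(st, S_t) == "compatible"
        ]
        if not cands:
            continue
        st = cands[ctx.rng.randrange(len(cands))]
        work, pos = list(p.actions), t
        ok = True
        for pair in st.pairs_innermost_first():
            if pair in _replay(p.A, work, pos).pairs:
                continue
            placed = _place_add_after(work, ctx, pos, pair)
            if placed is None:
                ok = False
                break
            work, pos = placed
        if ok and chain_is_valid(p.A, p.B, work):
            return ActionChain(tuple(work), p.A, p.B)
    return None


def _blocking_pairs(
    S: SecondaryStructure, pair: tuple[int, int]
) -> list[tuple[int, int]]:
    """Pairs of S that conflict with or cross ``pair``, innermost first."""
    i, j = pair
    blockers = [
        (ii, jj)
        for ii, jj in S.pairs
        if i in (ii, jj)
        or j in (ii, jj)
        or i < ii < j < jj
        or ii < i < jj < j
    ]
    return sorted(blockers, key=lambda q: (-q[0], q[1]))


def m5_convert_stacks(
    p: ActionChain, ctx: MutationContext
) -> ActionChain | None:
    """Convert to a helix incompatible with the current structure.

    Anchored at a random deletion action; the chosen stack conflicts or
    clashes with the structure there.  Compatible member pairs are
    placed as in M4; for each incompatible member every blocking pair
    is deleted just before the addition (relocating its existing
    deletion or inserting a transient del/add pair), so the old helix
    melts while the new one forms instead of via a fully unpaired
    intermediate.
    """
    m = len(p)
    if m == 0 or not ctx.stacks:
        return None
    del_positions = [
        t for t, a in enumerate(p.actions, start=1) if a.kind == "del"
    ]
    if not del_positions:
        return None
    inter = p.intermediates()
    for _ in range(ctx.retry_limit):
        t = del_positions[ctx.rng.randrange(len(del_positions))]
        S_t = inter[t]
        cands = [
            st
            for st in ctx.stacks
            if stack_relation(st, S_t) == "incompatible"
        ]
        if not cands:
            continue
        st = cands[ctx.rng.randrange(len(cands))]
        work, pos = list(p.actions), t
        ok = True
        for pair in st.pairs_innermost_first():
            S_pos = _replay(p.A, work, pos)
            if S_pos is None:
                ok = False
                break
            if pair in S_pos.pairs:
                continue
            for blocker in _blocking_pairs(S_pos, pair):
                placed = _place_del_after(work, ctx, pos, blocker)
                if placed is None:
                    ok = False
                    break
                work, pos = placed
            if not ok:
                break
            placed = _place_add_after(work, ctx, pos, pair)
            if placed is None:
                ok = False
                break
            work, pos = placed
        if ok and chain_is_valid(p.A, p.B, work):
            return ActionChain(tuple(work), p.A, p.B)
    return None
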