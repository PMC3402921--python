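"""Exact minimum-barrier solver for *direct* pathways.

Direct pathways only ever use base pairs of A and B, so the reachable
state space is the set of valid structures S with S a subset of A u B
and the moves are single pair additions/deletions.  The minimum
achievable barrier over this space is a bottleneck (minimax) path
problem: minimize, over paths from A to B, the maximum node energy.
A lexicographic Dijkstra on the label (bottleneck energy, steps) solves
it exactly; ties beyond that are broken on a canonical state ordering
so the certificate chain is deterministic.

This solves only the direct restriction (the unrestricted problem is
NP-hard); it serves as an upper-bound oracle for the evolutionary
search, whose indirect moves can only match or beat the direct optimum.
"""

from __future__ import annotations

import heapq

from .energy import EnergyModel
from .pathway import Action, ActionChain
from .structure import (
    PairFate,
    RnaSequence,
    SecondaryStructure,
    classify_pair,
)

__all__ = ["exact_direct_barrier", "StateSpaceTooLarge"]


class StateSpaceTooLarge(ValueError):
    """|A u B| exceeds the configured state-space cap."""


def exact_direct_barrier(
    model: EnergyModel,
    x: RnaSequence,
    A: SecondaryStructure,
    B: SecondaryStructure,
    cap: int = 16,
) -> tuple[float, ActionChain]:
    """Minimum-barrier direct pathway from A to B, exactly.

    Returns ``(barrier, chain)`` where the barrier is the bottleneck
    energy minus E(A), the maximum being taken over every structure on
    the path including both endpoints.  Raises
    :class:`StateSpaceTooLarge` when |A u B| > cap (the state space is
    2^|A u B| in the worst case).
    """
    union = sorted(A.pairs | B.pairs)
    if len(union) > cap:
        raise StateSpaceTooLarge(
            f"|A u B| = {len(union)} exceeds cap {cap}"
        )

    energy_memo: dict[frozenset, float] = {}

    def energy(node: frozenset) -> float:
        if node not in energy_memo:
            energy_memo[node] = model.evaluate(x, SecondaryStructure(node))
        return energy_memo[node]

    start = frozenset(A.pairs)
    goal = frozenset(B.pairs)
    e_start = energy(start)
    if start == goal:
        return 0.0, ActionChain((), A, B)

    def node_key(node: frozenset) -> tuple:
        return tuple(sorted(node))

    best: dict[frozenset, tuple[float, int]] = {start: (e_start, 0)}
    parent: dict[frozenset, tuple[frozenset, Action]] = {}
    heap: list[tuple[float, int, tuple, frozenset]] = [
        (e_start, 0, node_key(start), start)
    ]
    while heap:
        bott, steps, _, node = heapq.heappop(heap)
        if (bott, steps) > best.get(node, (float("inf"), 0)):
            continue
        if node == goal:
            break
        S = SecondaryStructure(node)
        for pair in union:
            if pair in node:
                action = Action("del", pair)
                nxt = node - {pair}
            else:
                if classify_pair(S, pair) is not PairFate.OK:
                    continue
                action = Action("add", pair)
                nxt = node | {pair}
            label = (max(bott, energy(nxt)), steps + 1)
            if label < best.get(nxt, (float("inf"), 0)):
                best[nxt] = label
                parent[nxt] = (node, action)
                heapq.heappush(
                    heap, (label[0], label[1], node_key(nxt), nxt)
                )
    if goal not in best:  # pragma: no cover - goal always reachable
        raise RuntimeError("goal unreachable in direct state space")
    actions: list[Action] = []
    node = goal
    while node != start:
        node, action = parent[node]
        actions.append(action)
    chain = ActionChain.checked(A, B, reversed(actions))
    return best[goal][0] - e_start, chain
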