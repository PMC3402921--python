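"""Action-chain representation of refolding pathways.

A pathway from structure A to structure B is encoded as an ordered chain
of elementary actions, each adding or deleting one base pair.  A chain
is *valid* when every action applies cleanly (no position conflict, no
crossing clash) and the final structure equals B.  Chains and pathways
are in bijection: the chain determines every intermediate structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .energy import EnergyModel
from .structure import (
    PairFate,
    RnaSequence,
    SecondaryStructure,
    classify_pair,
    structure_distance,
)

__all__ = [
    "Action",
    "ActionChain",
    "PathwayRecord",
    "PathwayError",
    "ConflictError",
    "ClashError",
    "ChainValidation",
    "apply_action",
    "validate_chain",
    "simple_pathway",
    "energy_profile",
    "fitness_key",
    "compare_fitness",
    "group_stacks",
]

#: Precision (kcal/mol) at which energies enter fitness comparisons,
#: matching the print precision of the evaluator.
FITNESS_DECIMALS = 2


class PathwayError(ValueError):
    pass


class ConflictError(PathwayError):
    """Add on an occupied position, or del of an absent pair."""


class ClashError(PathwayError):
    """Add that would cross an existing pair."""


@dataclass(frozen=True)
class Action:
    """One elementary move: add or delete base pair ``pair``."""

    kind: str  # "add" | "del"
    pair: tuple[int, int]

    def __post_init__(self) -> None:
        if self.kind not in ("add", "del"):
            raise ValueError(f"action kind must be add|del, got {self.kind!r}")
        object.__setattr__(self, "pair", (int(self.pair[0]), int(self.pair[1])))

    def inverse(self) -> "Action":
        return Action("del" if self.kind == "add" else "add", self.pair)

    def is_direct(
        self, A: SecondaryStructure, B: SecondaryStructure
    ) -> bool:
        return self.pair in A.pairs or self.pair in B.pairs

    def __str__(self) -> str:
        return f"{self.kind}({self.pair[0]},{self.pair[1]})"


def apply_action(S: SecondaryStructure, a: Action) -> SecondaryStructure:
    """Apply one action; raises ConflictError/ClashError when improper."""
    if a.kind == "del":
        if a.pair not in S.pairs:
            raise ConflictError(f"{a}: pair not present")
        return S.without_pair(a.pair)
    fate = classify_pair(S, a.pair)
    if fate is PairFate.CONFLICT:
        raise ConflictError(f"{a}: position already paired")
    if fate is PairFate.CLASH:
        raise ClashError(f"{a}: crosses an existing pair")
    return S.with_pair(a.pair)


def chain_is_valid(
    A: SecondaryStructure,
    B: SecondaryStructure,
    actions: Sequence[Action],
) -> bool:
    """Fast validity check: replays without materializing structures."""
    pairs = set(A.pairs)
    paired: dict[int, int] = {}
    for i, j in pairs:
        paired[i] = j
        paired[j] = i
    for a in actions:
        i, j = a.pair
        if a.kind == "del":
            if paired.get(i) != j:
                return False
            pairs.discard((i, j))
            del paired[i], paired[j]
        else:
            if i in paired or j in paired:
                return False
            if any(i < ii < j < jj or ii < i < jj < j for ii, jj in pairs):
                return False
            pairs.add((i, j))
            paired[i] = j
            paired[j] = i
    return pairs == set(B.pairs)


@dataclass(frozen=True)
class ChainValidation:
    """Outcome of replaying an action sequence from A."""

    ok: bool
    intermediates: tuple[SecondaryStructure, ...]
    failed_step: int | None = None  # 1-based index of first offending action
    reason: str | None = None


def validate_chain(
    A: SecondaryStructure,
    B: SecondaryStructure,
    actions: Sequence[Action],
) -> ChainValidation:
    """Replay ``actions`` from A; succeed iff every step applies and ends at B.

    Failures are reported in the return value (first offending step),
    never raised; the inputs are not mutated.
    """
    # fast replay on a partner map; clash via sorted pair scan
    pairs = set(A.pairs)
    paired: dict[int, int] = {}
    for i, j in pairs:
        paired[i] = j
        paired[j] = i
    structures = [A]
    for t, a in enumerate(actions, start=1):
        i, j = a.pair
        if a.kind == "del":
            if paired.get(i) != j:
                return ChainValidation(
                    False, tuple(structures), t, f"{a}: pair not present"
                )
            pairs.discard((i, j))
            del paired[i], paired[j]
        else:
            if i in paired or j in paired:
                return ChainValidation(
                    False, tuple(structures), t, f"{a}: position already paired"
                )
            clash = any(
                i < ii < j < jj or ii < i < jj < j for ii, jj in pairs
            )
            if clash:
                return ChainValidation(
                    False, tuple(structures), t, f"{a}: crosses an existing pair"
                )
            pairs.add((i, j))
            paired[i] = j
            paired[j] = i
        structures.append(SecondaryStructure(pairs))
    if pairs != set(B.pairs):
        return ChainValidation(
            False, tuple(structures), len(actions) or None,
            "final structure differs from B",
        )
    return ChainValidation(True, tuple(structures))


@dataclass(frozen=True)
class ActionChain:
    """A validated action chain transforming endpoint A into endpoint B."""

    actions: tuple[Action, ...]
    A: SecondaryStructure
    B: SecondaryStructure

    @classmethod
    def checked(
        cls,
        A: SecondaryStructure,
        B: SecondaryStructure,
        actions: Iterable[Action],
    ) -> "ActionChain":
        acts = tuple(actions)
        v = validate_chain(A, B, acts)
        if not v.ok:
            raise PathwayError(
                f"invalid action chain at step {v.failed_step}: {v.reason}"
            )
        return cls(acts, A, B)

    def __len__(self) -> int:
        return len(self.actions)

    def intermediates(self) -> tuple[SecondaryStructure, ...]:
        v = validate_chain(self.A, self.B, self.actions)
        if not v.ok:  # pragma: no cover - construction enforces validity
            raise PathwayError(f"corrupt chain: {v.reason}")
        return v.intermediates

    def is_direct(self) -> bool:
        return all(a.is_direct(self.A, self.B) for a in self.actions)


def group_stacks(
    pairs: Iterable[tuple[int, int]]
) -> list[list[tuple[int, int]]]:
    """Group pairs into runs of consecutively nested pairs.

    A run is (i,j), (i+1,j-1), ...; runs are returned 5'->3' by outer
    pair, each ordered outermost-first.
    """
    pset = set(pairs)
    runs: list[list[tuple[int, int]]] = []
    for i, j in sorted(pset):
        if (i - 1, j + 1) in pset:
            continue
        run = [(i, j)]
        while (run[-1][0] + 1, run[-1][1] - 1) in pset:
            run.append((run[-1][0] + 1, run[-1][1] - 1))
        runs.append(run)
    return runs


def simple_pathway(
    A: SecondaryStructure,
    B: SecondaryStructure,
    degrade_dir: str = "outermost_first",
    form_dir: str = "innermost_first",
) -> ActionChain:
    """The stackwise direct pathway: delete all of A-B, then add all of B-A.

    Stacks of A-B are degraded in 5'->3' order of their outer pair, each
    in ``degrade_dir``; stacks of B-A are then formed in 5'->3' order,
    each in ``form_dir``.  Since every remaining or added pair belongs
    to a single valid structure, the chain is always valid, with length
    equal to the base-pair distance between A and B.
    """
    for name, val in (("degrade_dir", degrade_dir), ("form_dir", form_dir)):
        if val not in ("outermost_first", "innermost_first"):
            raise ValueError(f"{name} must be outermost_first|innermost_first")
    actions: list[Action] = []
    for run in group_stacks(A.pairs - B.pairs):
        ordered = run if degrade_dir == "outermost_first" else run[::-1]
        actions.extend(Action("del", p) for p in ordered)
    for run in group_stacks(B.pairs - A.pairs):
        ordered = run if form_dir == "outermost_first" else run[::-1]
        actions.extend(Action("add", p) for p in ordered)
    chain = ActionChain.checked(A, B, actions)
    assert len(chain) == structure_distance(A, B)
    return chain


@dataclass(frozen=True)
class PathwayRecord:
    """A chain together with its energy profile and fitness statistics.

    ``barrier`` is the saddle energy minus E(A), with the saddle taken
    over all structures S_0..S_m inclusive, so barrier >= 0 and
    barrier >= E(B) - E(A) always hold.  ``mean_excess`` averages
    E(S_t) - E(S_0) over t = 1..m and breaks fitness ties.
    """

    chain: ActionChain
    energies: tuple[float, ...]
    saddle_index: int
    barrier: float
    mean_excess: float
    origin: str = "init"
    serial: int = field(default=0, compare=False)

    def fitness_key(self) -> tuple[float, float, int, int]:
        return fitness_key(self)


def energy_profile(
    model: EnergyModel,
    x: RnaSequence,
    chain: ActionChain,
    origin: str = "init",
    serial: int = 0,
) -> PathwayRecord:
    """Evaluate every structure along the chain and derive the fitness stats."""
    energies = tuple(model.evaluate(x, S) for S in chain.intermediates())
    saddle_index = max(range(len(energies)), key=lambda t: (energies[t], -t))
    barrier = energies[saddle_index] - energies[0]
    if len(energies) > 1:
        mean_excess = sum(e - energies[0] for e in energies[1:]) / (
            len(energies) - 1
        )
    else:
        mean_excess = 0.0
    return PathwayRecord(
        chain, energies, saddle_index, barrier, mean_excess, origin, serial
    )


def fitness_key(p: PathwayRecord) -> tuple[float, float, int, int]:
    """Sort key: barrier, then mean excess energy, then chain length.

    Energies are rounded to evaluator print precision (0.01 kcal/mol) so
    tie-breaking is stable; residual ties fall back on creation order.
    """
    return (
        round(p.barrier, FITNESS_DECIMALS),
        round(p.mean_excess, FITNESS_DECIMALS),
        len(p.chain),
        p.serial,
    )


def compare_fitness(p: PathwayRecord, q: PathwayRecord) -> int:
    """-1 if p is fitter, +1 if q is fitter, 0 if indistinguishable."""
    kp, kq = fitness_key(p)[:3], fitness_key(q)[:3]
    if kp < kq:
        return -1
    if kp > kq:
        return 1
    return 0
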