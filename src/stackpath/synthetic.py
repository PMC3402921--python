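"""Synthetic refolding instances for tests and benchmarks.

The generator plants complementary helix arms into a random sequence so
that the stack set is guaranteed to be non-empty, then assembles the
two endpoint structures as unions of mutually compatible stacks drawn
from that set.  Planted helices occupy disjoint sequence positions but
their pair sets may cross, which is exactly what produces instances
where melting one helix while forming another pays off.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .io import Instance
from .structure import (
    RnaSequence,
    SecondaryStructure,
    Stack,
    enumerate_stacks,
    stack_relation,
)

__all__ = [
    "RandomInstanceSpec",
    "random_instance",
    "toy_switch",
    "GenerationError",
]


def toy_switch() -> Instance:
    """The built-in 16-nt toy switch.

    GGGGAAAACCCCUUUU refolds from a four-pair GC helix
    ``((((....))))....`` into a crossing four-pair AU helix
    ``....((((....))))``; the sequence also admits a four-pair GU helix
    joining the 5' Gs to the 3' Us, the natural transient detour.
    """
    from .structure import parse_structure

    return Instance(
        RnaSequence("GGGGAAAACCCCUUUU"),
        parse_structure("((((....))))...."),
        parse_structure("....((((....))))"),
        label="toy-switch",
    )

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


class GenerationError(RuntimeError):
    """Instance generation failed within the retry budget."""


@dataclass(frozen=True)
class RandomInstanceSpec:
    """Parameters of one synthetic instance.

    ``n`` is the sequence length (>= 12), ``k_stacks`` the number of
    stacks per endpoint structure; everything is deterministic under
    ``seed``.
    """

    n: int = 30
    k_stacks: int = 2
    seed: int = 0
    min_stack_len: int = 4
    min_hairpin: int = 3
    max_tries: int = 200

    def __post_init__(self) -> None:
        if self.n < 12:
            raise ValueError("n must be >= 12 to fit one helix plus loop")
        if self.k_stacks < 1:
            raise ValueError("k_stacks must be >= 1")


def _plant_helices(
    rng: random.Random, n: int, count: int, min_hairpin: int
) -> str:
    """Random sequence with ``count`` planted complementary arm pairs."""
    letters = [rng.choice("ACGU") for _ in range(n)]
    free = set(range(n))
    for _ in range(count):
        w = rng.randint(4, 5)
        placed = False
        for _ in range(50):
            i = rng.randint(0, n - 2 * w - min_hairpin - 1)
            j_hi = n - w
            j_lo = i + w + min_hairpin
            if j_lo > j_hi:
                continue
            j = rng.randint(j_lo, j_hi)
            left = set(range(i, i + w))
            right = set(range(j, j + w))
            if not (left | right) <= free:
                continue
            for k in range(w):
                # arm pairing: position i+k pairs with j+w-1-k
                letters[j + w - 1 - k] = _COMPLEMENT[letters[i + k]]
            free -= left | right
            placed = True
            break
        if not placed:
            break
    return "".join(letters)


def _draw_structure(
    rng: random.Random,
    stacks: tuple[Stack, ...],
    k: int,
) -> SecondaryStructure:
    order = list(stacks)
    rng.shuffle(order)
    S = SecondaryStructure()
    taken = 0
    for st in order:
        if taken == k:
            break
        if stack_relation(st, S) == "compatible" and not (
            set(st.pairs) <= S.pairs
        ):
            S = SecondaryStructure(S.pairs | set(st.pairs))
            taken += 1
    return S


def random_instance(spec: RandomInstanceSpec) -> Instance:
    """Generate a synthetic instance (sequence, A, B) per the spec.

    A and B are each unions of up to ``k_stacks`` mutually compatible
    stacks of the generated sequence; the two structures are distinct.
    Raises :class:`GenerationError` after ``max_tries`` failures.
    """
    rng = random.Random(spec.seed)
    for _ in range(spec.max_tries):
        seq = _plant_helices(
            rng, spec.n, spec.k_stacks + 1, spec.min_hairpin
        )
        try:
            x = RnaSequence(seq)
        except ValueError:  # pragma: no cover - generator emits ACGU only
            continue
        stacks = enumerate_stacks(x, spec.min_stack_len, spec.min_hairpin)
        if len(stacks) < 2:
            continue
        A = _draw_structure(rng, stacks, spec.k_stacks)
        if not A.pairs:
            continue
        for _ in range(20):
            B = _draw_structure(rng, stacks, spec.k_stacks)
            if B.pairs and B.pairs != A.pairs:
                return Instance(
                    x, A, B,
                    label=f"synthetic-n{spec.n}-k{spec.k_stacks}-s{spec.seed}",
                )
    raise GenerationError(f"could not generate an instance for {spec}")
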