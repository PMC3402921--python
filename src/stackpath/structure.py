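"""RNA sequence and secondary-structure domain model.

Positions are 1-based throughout the public interface, following the
standard (i, j) convention for base pairs with i < j.  Structures are
pseudoknot-free: the pair set is disjoint (no position paired twice) and
non-crossing (no i < i' < j < j').
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator

__all__ = [
    "RnaSequence",
    "SecondaryStructure",
    "Stack",
    "PairFate",
    "StructureError",
    "ParseError",
    "parse_structure",
    "render_structure",
    "pair_allowed",
    "classify_pair",
    "structure_distance",
    "enumerate_stacks",
    "stack_relation",
    "MIN_HAIRPIN",
]

#: Minimum number of unpaired bases enclosed by a hairpin-closing pair.
MIN_HAIRPIN = 3

#: Admissible pairings: Watson-Crick plus the G-U wobble.
_ALLOWED_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

_ALPHABET = frozenset("ACGU")


class StructureError(ValueError):
    """Raised when a structure violates disjointness/non-crossing rules."""


class ParseError(StructureError):
    """Raised on malformed dot-bracket input; carries the offending position."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class PairFate(Enum):
    """Outcome of testing a base pair against an existing structure."""

    OK = "ok"
    CONFLICT = "conflict"  # i or j already paired
    CLASH = "clash"  # would cross an existing pair (pseudoknot)


class RnaSequence:
    """A validated RNA sequence over {A, C, G, U}.

    ``T`` in the input is normalized to ``U`` with a warning (common in
    FASTA files of DNA origin).  Lowercase input is upcased.
    """

    __slots__ = ("letters",)

    def __init__(self, letters: str):
        s = letters.strip().upper()
        if "T" in s:
            warnings.warn("sequence contains T; normalizing to U", stacklevel=2)
            s = s.replace("T", "U")
        if not s:
            raise ValueError("empty RNA sequence")
        bad = set(s) - _ALPHABET
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)}; expected A/C/G/U")
        self.letters = s

    @property
    def n(self) -> int:
        return len(self.letters)

    def __len__(self) -> int:
        return len(self.letters)

    def base(self, i: int) -> str:
        """Residue at 1-based position i."""
        if not 1 <= i <= len(self.letters):
            raise IndexError(f"position {i} out of range 1..{len(self.letters)}")
        return self.letters[i - 1]

    def __str__(self) -> str:
        return self.letters

    def __repr__(self) -> str:
        return f"RnaSequence({self.letters!r})"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RnaSequence) and self.letters == other.letters

    def __hash__(self) -> int:
        return hash(self.letters)


def _check_pairs(pairs: Iterable[tuple[int, int]]) -> frozenset[tuple[int, int]]:
    pset = frozenset((int(i), int(j)) for i, j in pairs)
    seen: set[int] = set()
    for i, j in pset:
        if not i < j:
            raise StructureError(f"base pair ({i},{j}) must satisfy i < j")
        if i < 1:
            raise StructureError(f"base pair ({i},{j}) has position < 1")
        if i in seen or j in seen:
            raise StructureError(f"position reused by base pair ({i},{j})")
        seen.add(i)
        seen.add(j)
    ordered = sorted(pset)
    for a in range(len(ordered)):
        i, j = ordered[a]
        for b in range(a + 1, len(ordered)):
            ii, jj = ordered[b]
            if ii > j:
                break
            if i < ii < j < jj:
                raise StructureError(
                    f"crossing base pairs ({i},{j}) and ({ii},{jj}) (pseudoknot)"
                )
    return pset


@dataclass(frozen=True)
class SecondaryStructure:
    """An immutable pseudoknot-free set of base pairs.

    Validation (disjointness and non-crossing) happens at construction,
    so any in-hand instance is a legal structure.
    """

    pairs: frozenset[tuple[int, int]]

    def __init__(self, pairs: Iterable[tuple[int, int]] = ()):
        object.__setattr__(self, "pairs", _check_pairs(pairs))

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(sorted(self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        return pair in self.pairs

    def partner_map(self) -> dict[int, int]:
        """Position -> partner-position mapping (both directions)."""
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def max_position(self) -> int:
        return max((j for _, j in self.pairs), default=0)

    def with_pair(self, pair: tuple[int, int]) -> "SecondaryStructure":
        return SecondaryStructure(self.pairs | {tuple(pair)})

    def without_pair(self, pair: tuple[int, int]) -> "SecondaryStructure":
        return SecondaryStructure(self.pairs - {tuple(pair)})

    def to_dotbracket(self, n: int) -> str:
        return render_structure(self, n)

    @classmethod
    def from_dotbracket(cls, text: str) -> "SecondaryStructure":
        return parse_structure(text)


def parse_structure(text: str) -> SecondaryStructure:
    """Parse a dot-bracket string into a structure.

    Only ``.``, ``(`` and ``)`` are accepted; brackets must balance.
    """
    text = text.strip()
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(text, start=1):
        if ch == ".":
            continue
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ParseError(f"unmatched ')' at position {pos}", pos)
            pairs.append((stack.pop(), pos))
        else:
            raise ParseError(f"illegal character {ch!r} at position {pos}", pos)
    if stack:
        raise ParseError(f"unmatched '(' at position {stack[-1]}", stack[-1])
    return SecondaryStructure(pairs)


def render_structure(S: SecondaryStructure, n: int) -> str:
    """Render a structure as a length-n dot-bracket string."""
    if S.max_position() > n:
        raise StructureError(
            f"base pair reaches position {S.max_position()} but n={n}"
        )
    chars = ["."] * n
    for i, j in S.pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


def pair_allowed(
    x: RnaSequence, i: int, j: int, min_hairpin: int = MIN_HAIRPIN
) -> bool:
    """True iff (i, j) is a canonical/wobble pair with a legal hairpin gap.

    Admits A-U, G-C and G-U, and requires at least ``min_hairpin``
    unpaired bases between i and j.
    """
    if not 1 <= i < j <= x.n:
        raise IndexError(f"pair ({i},{j}) out of range for n={x.n}")
    if j - i - 1 < min_hairpin:
        return False
    return (x.base(i), x.base(j)) in _ALLOWED_PAIRS


def classify_pair(S: SecondaryStructure, pair: tuple[int, int]) -> PairFate:
    """Test whether a pair can be added to S.

    ``CONFLICT`` if either endpoint is already paired, ``CLASH`` if some
    existing pair crosses it, ``OK`` otherwise (in which case S + pair is
    again a valid structure).
    """
    i, j = pair
    for ii, jj in S.pairs:
        if i in (ii, jj) or j in (ii, jj):
            return PairFate.CONFLICT
    for ii, jj in S.pairs:
        if i < ii < j < jj or ii < i < jj < j:
            return PairFate.CLASH
    return PairFate.OK


def structure_distance(A: SecondaryStructure, B: SecondaryStructure) -> int:
    """Base-pair distance |A - B| + |B - A| (symmetric difference size)."""
    return len(A.pairs ^ B.pairs)


@dataclass(frozen=True)
class Stack:
    """A helix: ``length`` consecutive nested pairs starting at ``outer``.

    Member pairs are (i, j), (i+1, j-1), ..., (i+length-1, j-length+1).
    """

    outer: tuple[int, int]
    length: int

    @property
    def pairs(self) -> tuple[tuple[int, int], ...]:
        i, j = self.outer
        return tuple((i + k, j - k) for k in range(self.length))

    def pairs_innermost_first(self) -> tuple[tuple[int, int], ...]:
        return tuple(reversed(self.pairs))


def enumerate_stacks(
    x: RnaSequence,
    min_stack_len: int = 4,
    min_hairpin: int = MIN_HAIRPIN,
) -> tuple[Stack, ...]:
    """All maximal runs of >= min_stack_len consecutive allowable pairs.

    Scans every anti-diagonal of the complementarity matrix: a run starts
    at (i, j) when (i-1, j+1) is not allowable, and extends inward while
    successive (i+k, j-k) remain allowable.  Each maximal run is reported
    once; sub-stacks are not enumerated separately.
    """
    if min_stack_len < 1:
        raise ValueError("min_stack_len must be >= 1")
    n = x.n
    found: list[Stack] = []
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            if not pair_allowed(x, i, j, min_hairpin):
                continue
            # start of a maximal run only
            if i > 1 and j < n and pair_allowed(x, i - 1, j + 1, min_hairpin):
                continue
            length = 1
            while (
                i + length < j - length
                and pair_allowed(x, i + length, j - length, min_hairpin)
            ):
                length += 1
            if length >= min_stack_len:
                found.append(Stack((i, j), length))
    return tuple(sorted(found, key=lambda st: st.outer))


def stack_relation(st: Stack, S: SecondaryStructure) -> str:
    """'compatible' if every member pair is in S or addable; else 'incompatible'.

    Pairs are tested innermost-out against S progressively extended with
    the pairs already admitted, so a stack whose members are mutually
    consistent with S in formation order counts as compatible.
    """
    work = S
    for pair in st.pairs_innermost_first():
        if pair in work:
            continue
        if classify_pair(work, pair) is not PairFate.OK:
            return "incompatible"
        work = work.with_pair(pair)
    return "compatible"
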