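"""Free-energy evaluation backends.

Two interchangeable backends implement the same contract
``evaluate(sequence, structure) -> kcal/mol``:

``TurnerModel``
    Adapter to the ViennaRNA nearest-neighbour evaluator.  Defaults to
    the Turner-1999 parameter set with d1-style dangling-end treatment
    (single-base dangles, no coaxial stacking), selectable to
    Turner-2004.  Requires the ``RNA`` Python bindings.

``SimpleNearestNeighborModel``
    A self-contained simplified nearest-neighbour model: a 21-entry
    stacking table (canonical + wobble neighbours, all terms <= 0) plus
    logarithmic loop penalties and an affine multiloop term.  It exists
    so that search and tests run with zero external dependencies; its
    absolute values are NOT calibrated against Turner parameters, but it
    preserves the qualitative landscape (stacking stabilizes, loops
    penalize).

Both backends are pure functions of (sequence, structure): the empty
structure always evaluates to 0.0 kcal/mol.
"""

from __future__ import annotations

import math
from typing import Protocol

from .structure import RnaSequence, SecondaryStructure, render_structure

__all__ = [
    "EnergyModel",
    "TurnerModel",
    "SimpleNearestNeighborModel",
    "BackendUnavailableError",
    "load_energy_backend",
]


class BackendUnavailableError(RuntimeError):
    """The requested external evaluator cannot be loaded."""


class EnergyModel(Protocol):
    name: str
    parameter_set: str
    dangle_mode: str

    def evaluate(self, x: RnaSequence, S: SecondaryStructure) -> float:
        ...


def _check_lengths(x: RnaSequence, S: SecondaryStructure) -> None:
    if S.max_position() > x.n:
        raise ValueError(
            f"structure reaches position {S.max_position()} "
            f"but sequence length is {x.n}"
        )


# ---------------------------------------------------------------------------
# Turner backend (ViennaRNA adapter)
# ---------------------------------------------------------------------------

# ViennaRNA keeps the active parameter set in process-global state; track
# what is currently loaded so fold_compounds are rebuilt on switches.
_LOADED_PARAMS: list[str | None] = [None]


class TurnerModel:
    """Nearest-neighbour Turner energies via the ViennaRNA bindings.

    dangle_mode 'd1' maps to ViennaRNA ``--dangles=1``.
    """

    name = "turner"
    dangle_mode = "d1"

    _PARAM_LOADERS = {
        "turner1999": "params_load_RNA_Turner1999",
        "turner2004": "params_load_RNA_Turner2004",
    }

    def __init__(self, parameter_set: str = "turner1999"):
        if parameter_set not in self._PARAM_LOADERS:
            raise ValueError(
                f"unknown parameter set {parameter_set!r}; "
                f"expected one of {sorted(self._PARAM_LOADERS)}"
            )
        try:
            import RNA  # noqa: F401
        except ImportError as exc:  # pragma: no cover - env-dependent
            raise BackendUnavailableError(
                "the ViennaRNA Python bindings (module 'RNA') are required "
                "for the turner backend; install the viennarna package or "
                "use the 'simple' backend"
            ) from exc
        self._RNA = RNA
        self.parameter_set = parameter_set
        self._fc_cache: dict[str, object] = {}
        self._memo: dict[tuple[str, frozenset], float] = {}

    def _ensure_params(self) -> None:
        if _LOADED_PARAMS[0] != self.parameter_set:
            getattr(self._RNA, self._PARAM_LOADERS[self.parameter_set])()
            _LOADED_PARAMS[0] = self.parameter_set
            self._fc_cache.clear()

    def _fold_compound(self, letters: str):
        self._ensure_params()
        fc = self._fc_cache.get(letters)
        if fc is None:
            md = self._RNA.md()
            md.dangles = 1
            fc = self._RNA.fold_compound(letters, md)
            self._fc_cache[letters] = fc
        return fc

    def evaluate(self, x: RnaSequence, S: SecondaryStructure) -> float:
        _check_lengths(x, S)
        key = (x.letters, S.pairs)
        if key in self._memo:
            return self._memo[key]
        if not S.pairs:
            e = 0.0
        else:
            fc = self._fold_compound(x.letters)
            e = float(fc.eval_structure(render_structure(S, x.n)))
        self._memo[key] = e
        return e


# ---------------------------------------------------------------------------
# Built-in simplified nearest-neighbour model
# ---------------------------------------------------------------------------

# Stacking free energies (kcal/mol) for two adjacent pairs, keyed
# "x_i x_j / x_{i+1} x_{j-1}" with (i,j) the outer and (i+1,j-1) the
# inner pair.  The 36 oriented neighbour combinations collapse to 21
# entries under strand-reversal symmetry; every term is <= 0 so that
# helix extension never destabilizes.
_STACKING_21 = {
    "AU/AU": -0.9,
    "AU/CG": -2.2,
    "AU/GC": -2.1,
    "AU/GU": -0.6,
    "AU/UA": -1.1,
    "AU/UG": -1.4,
    "CG/AU": -2.1,
    "CG/CG": -2.9,
    "CG/GC": -3.4,
    "CG/GU": -1.4,
    "CG/UG": -2.1,
    "GC/AU": -2.2,
    "GC/CG": -3.3,
    "GC/GU": -1.5,
    "GC/UG": -2.5,
    "GU/AU": -1.4,
    "GU/GU": -0.5,
    "GU/UG": -0.6,
    "UA/AU": -1.3,
    "UA/GU": -1.0,
    "UG/GU": -0.3,
}

# Loop penalties a + b*ln(size) (kcal/mol); multiloop is affine.
_HAIRPIN_A, _HAIRPIN_B = 4.5, 1.75  # size measured from 3 upward
_BULGE_A, _BULGE_B = 3.5, 1.75
_INTERNAL_A, _INTERNAL_B = 2.0, 1.75
_MULTI_CLOSE, _MULTI_BRANCH, _MULTI_UNPAIRED = 3.4, 0.4, 0.1


def _canonical_stack_key(outer: tuple[str, str], inner: tuple[str, str]) -> str:
    k1 = f"{outer[0]}{outer[1]}/{inner[0]}{inner[1]}"
    k2 = f"{inner[1]}{inner[0]}/{outer[1]}{outer[0]}"  # read from the other strand
    return min(k1, k2)


def stacking_energy(
    x: RnaSequence, outer: tuple[int, int], inner: tuple[int, int]
) -> float:
    """Tabulated stacking term for inner pair directly inside outer."""
    i, j = outer
    key = _canonical_stack_key(
        (x.base(i), x.base(j)), (x.base(inner[0]), x.base(inner[1]))
    )
    return _STACKING_21[key]


class SimpleNearestNeighborModel:
    """Dependency-free simplified nearest-neighbour energy model.

    Decomposes the structure into the loops closed by each base pair:
    stacked pairs contribute a tabulated stacking term, hairpin /
    bulge / internal loops a logarithmic penalty, multiloops an affine
    penalty.  The exterior loop contributes nothing.
    """

    name = "simple"
    parameter_set = "simple"
    dangle_mode = "none"

    def __init__(self) -> None:
        self._memo: dict[tuple[str, frozenset], float] = {}

    def evaluate(self, x: RnaSequence, S: SecondaryStructure) -> float:
        _check_lengths(x, S)
        key = (x.letters, S.pairs)
        if key in self._memo:
            return self._memo[key]
        total = 0.0
        ordered = sorted(S.pairs)
        for idx, (i, j) in enumerate(ordered):
            children = _direct_children(ordered, idx)
            total += _loop_energy(x, (i, j), children)
        e = round(total, 6)
        self._memo[key] = e
        return e


def _direct_children(
    ordered: list[tuple[int, int]], idx: int
) -> list[tuple[int, int]]:
    """Pairs directly enclosed by ordered[idx] (no intervening pair)."""
    i, j = ordered[idx]
    children: list[tuple[int, int]] = []
    bound = i
    for ii, jj in ordered[idx + 1:]:
        if ii > j:
            break
        if ii > bound and ii > i and jj < j:
            children.append((ii, jj))
            bound = jj
    return children


def _loop_energy(
    x: RnaSequence, closing: tuple[int, int], children: list[tuple[int, int]]
) -> float:
    i, j = closing
    if not children:
        size = j - i - 1
        return _HAIRPIN_A + _HAIRPIN_B * math.log(size / 3.0)
    if len(children) == 1:
        ii, jj = children[0]
        left, right = ii - i - 1, j - jj - 1
        if left == 0 and right == 0:
            return stacking_energy(x, (i, j), (ii, jj))
        size = left + right
        if left == 0 or right == 0:
            return _BULGE_A + _BULGE_B * math.log(size)
        return _INTERNAL_A + _INTERNAL_B * math.log(size / 2.0 + 0.5)
    unpaired = (j - i - 1) - sum(jj - ii + 1 for ii, jj in children)
    return (
        _MULTI_CLOSE
        + _MULTI_BRANCH * (len(children) + 1)
        + _MULTI_UNPAIRED * unpaired
    )


def load_energy_backend(
    name: str, parameter_set: str | None = None
) -> EnergyModel:
    """Construct an energy backend by name ('turner' or 'simple')."""
    if name == "turner":
        return TurnerModel(parameter_set or "turner1999")
    if name == "simple":
        return SimpleNearestNeighborModel()
    raise ValueError(f"unknown energy backend {name!r}; expected turner|simple")
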