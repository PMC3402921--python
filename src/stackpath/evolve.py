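"""Evolutionary search for low-barrier refolding pathways.

Each generation, every pathway in the population spawns offspring
through the five mutation strategies; per-parent the best ``l2``
offspring plus the ``l1`` elites of the old population form the
candidate list, from which the best ``l3`` survive.  The per-strategy
offspring budget adapts to how many of a strategy's offspring made it
into the new population.  Elitism makes the best-so-far barrier
non-increasing across generations.
"""

from __future__ import annotations

from dataclasses import dataclass

from .energy import EnergyModel, load_energy_backend
from .mutation import (
    MutationContext,
    m1_move,
    m2_swap,
    m3_insert_pair,
    m4_force_stack,
    m5_convert_stacks,
)
from .pathway import (
    ActionChain,
    PathwayRecord,
    energy_profile,
    fitness_key,
    simple_pathway,
)
from .structure import RnaSequence, SecondaryStructure

__all__ = [
    "EAConfig",
    "StrategyStats",
    "GenerationStats",
    "EAResult",
    "STRATEGIES",
    "initial_population",
    "allocate_offspring",
    "next_generation",
    "run_ea",
]

STRATEGIES = ("M1", "M2", "M3", "M4", "M5")

_STRATEGY_FN = {
    "M1": m1_move,
    "M2": m2_swap,
    "M3": m3_insert_pair,
    "M4": m4_force_stack,
    "M5": m5_convert_stacks,
}


@dataclass(frozen=True)
class EAConfig:
    """Control parameters of the evolutionary search.

    Defaults follow the reference configuration: at most ``max_gen``
    productive iterations, a plateau window of ``gamma``, ``offspring``
    (L) offspring per parent split across strategies with a floor of
    ``l_min``, ``l1`` elites, ``l2`` offspring kept per parent and a
    population of ``l3``.
    """

    max_gen: int = 10
    gamma: int = 5
    offspring: int = 100
    l_min: int = 3
    l1: int = 10
    l2: int = 5
    l3: int = 100
    seed: int = 0
    energy: str = "simple"
    parameter_set: str = "turner1999"
    min_stack_len: int = 4
    min_hairpin: int = 3
    retry_limit: int = 50
    beta: float = 1.0
    #: stop as soon as the barrier reaches max(0, E(B)-E(A)) + floor_tol;
    #: ``literal_floor`` switches to the looser |E(B)-E(A)| variant.
    floor_tol: float = 1e-6
    literal_floor: bool = False
    #: absolute safety cap on iterations (the loop may run past max_gen
    #: while successive iterations keep improving)
    hard_cap: int = 100

    def __post_init__(self) -> None:
        for name in (
            "max_gen", "gamma", "offspring", "l_min", "l1", "l2", "l3",
            "retry_limit", "hard_cap",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.l2 > self.offspring:
            raise ValueError("l2 (per-parent keep) cannot exceed offspring L")


@dataclass
class StrategyStats:
    """Per-strategy bookkeeping for the adaptive offspring allocation."""

    allocated: dict[str, int]
    selected: dict[str, int]


@dataclass(frozen=True)
class GenerationStats:
    generation: int
    offspring_produced: int
    candidate_count: int
    population_size: int
    opt_barrier: float
    allocated: dict[str, int]
    selected: dict[str, int]


@dataclass(frozen=True)
class EAResult:
    best: PathwayRecord
    trace: tuple[GenerationStats, ...]
    stop_reason: str


def initial_population(
    model: EnergyModel,
    x: RnaSequence,
    A: SecondaryStructure,
    B: SecondaryStructure,
) -> list[PathwayRecord]:
    """The four stackwise simple pathways, evaluated and fitness-sorted.

    Each degrades all stacks of A-B in one direction and then forms all
    stacks of B-A in one direction (2 x 2 direction choices).  For
    A == B the population is the single empty pathway.
    """
    if A.pairs == B.pairs:
        chain = ActionChain((), A, B)
        return [energy_profile(model, x, chain, origin="init", serial=0)]
    records = []
    serial = 0
    for degrade in ("outermost_first", "innermost_first"):
        for form in ("outermost_first", "innermost_first"):
            chain = simple_pathway(A, B, degrade, form)
            records.append(
                energy_profile(model, x, chain, origin="init", serial=serial)
            )
            serial += 1
    records.sort(key=fitness_key)
    return records


def allocate_offspring(
    stats: StrategyStats | None, cfg: EAConfig
) -> dict[str, int]:
    """Per-strategy offspring counts for the next generation.

    With no history (first generation) the budget L is split uniformly.
    Afterwards each strategy receives a share of L proportional to its
    success ratio b_y / l_y of the previous generation, floored at
    ``l_min``; the shares need not sum to exactly L.
    """
    uniform = {y: max(cfg.l_min, round(cfg.offspring / len(STRATEGIES)))
               for y in STRATEGIES}
    if stats is None:
        return uniform
    ratios = {}
    for y in STRATEGIES:
        ly = stats.allocated.get(y, 0)
        by = stats.selected.get(y, 0)
        ratios[y] = (by / ly) if ly > 0 else 0.0
    total = sum(ratios.values())
    if total <= 0:
        return uniform
    return {
        y: max(cfg.l_min, round(ratios[y] / total * cfg.offspring))
        for y in STRATEGIES
    }


def next_generation(
    population: list[PathwayRecord],
    ctx: MutationContext,
    model: EnergyModel,
    cfg: EAConfig,
    allocation: dict[str, int],
    serial_start: int,
) -> tuple[list[PathwayRecord], list[PathwayRecord], PathwayRecord, StrategyStats, int]:
    """One iteration: offspring, candidate list O_k, survivors P_k.

    Returns (O_k, P_k, OPT_k, stats, next_serial).  Offspring counts
    selected into P_k are tallied per strategy for the adaptive
    allocation; duplicate chains in O_k are dropped (best kept).
    """
    serial = serial_start
    candidates: list[PathwayRecord] = []
    produced = 0
    for parent in population:
        brood: list[PathwayRecord] = []
        for strategy in STRATEGIES:
            fn = _STRATEGY_FN[strategy]
            for _ in range(allocation[strategy]):
                child = fn(parent.chain, ctx)
                if child is None:
                    continue
                brood.append(
                    energy_profile(
                        model, ctx.x, child, origin=strategy, serial=serial
                    )
                )
                serial += 1
                produced += 1
        brood.sort(key=fitness_key)
        candidates.extend(brood[: cfg.l2])
    # elitism: the best l1 of the previous population join O_k
    candidates.extend(population[: cfg.l1])
    candidates.sort(key=fitness_key)
    seen: set[tuple] = set()
    o_k: list[PathwayRecord] = []
    for rec in candidates:
        sig = rec.chain.actions
        if sig in seen:
            continue
        seen.add(sig)
        o_k.append(rec)
    opt = o_k[0]
    p_k = o_k[: cfg.l3]
    selected = {y: 0 for y in STRATEGIES}
    for rec in p_k:
        if rec.serial >= serial_start and rec.origin in selected:
            selected[rec.origin] += 1
    stats = StrategyStats(allocated=dict(allocation), selected=selected)
    return o_k, p_k, opt, stats, serial


def _barrier_floor(model: EnergyModel, x, A, B, cfg: EAConfig) -> float:
    ea = model.evaluate(x, A)
    eb = model.evaluate(x, B)
    if cfg.literal_floor:
        return abs(eb - ea)
    return max(0.0, eb - ea)


def run_ea(
    x: RnaSequence,
    A: SecondaryStructure,
    B: SecondaryStructure,
    cfg: EAConfig | None = None,
    model: EnergyModel | None = None,
) -> EAResult:
    """Full evolutionary search from structure A to structure B.

    Stops when the barrier reaches its theoretical floor, when no
    improvement occurred over ``gamma`` consecutive iterations, or when
    ``max_gen`` iterations have passed and the last one brought no
    improvement.  The best chain ever seen is returned together with a
    per-generation trace of the incumbent barrier.
    """
    cfg = cfg or EAConfig()
    if model is None:
        model = load_energy_backend(cfg.energy, cfg.parameter_set)
    if A.max_position() > x.n or B.max_position() > x.n:
        raise ValueError("structure exceeds sequence length")
    ctx = MutationContext.for_instance(
        x, A, B,
        seed=cfg.seed,
        min_stack_len=cfg.min_stack_len,
        min_hairpin=cfg.min_hairpin,
        retry_limit=cfg.retry_limit,
        beta=cfg.beta,
    )
    population = initial_population(model, x, A, B)
    opt_history = [population[0]]
    trace: list[GenerationStats] = []
    serial = len(population)
    if A.pairs == B.pairs:
        return EAResult(population[0], (), "start equals target")

    floor = _barrier_floor(model, x, A, B, cfg)
    if population[0].barrier <= floor + cfg.floor_tol:
        return EAResult(population[0], (), "barrier at theoretical floor")

    stats: StrategyStats | None = None
    stop_reason = "iteration cap reached"
    for k in range(1, cfg.hard_cap + 1):
        allocation = allocate_offspring(stats, cfg)
        serial_before = serial
        o_k, population, opt, stats, serial = next_generation(
            population, ctx, model, cfg, allocation, serial
        )
        opt_history.append(opt)
        trace.append(
            GenerationStats(
                generation=k,
                offspring_produced=serial - serial_before,
                candidate_count=len(o_k),
                population_size=len(population),
                opt_barrier=opt.barrier,
                allocated=stats.allocated,
                selected=stats.selected,
            )
        )
        if opt.barrier <= floor + cfg.floor_tol:
            stop_reason = "barrier at theoretical floor"
            break
        key_now = fitness_key(opt)[:3]
        if k > cfg.gamma and key_now == fitness_key(opt_history[k - cfg.gamma])[:3]:
            stop_reason = f"plateau over {cfg.gamma} iterations"
            break
        if k >= cfg.max_gen and key_now == fitness_key(opt_history[k - 1])[:3]:
            stop_reason = "no improvement after max_gen"
            break
    best = min(opt_history, key=fitness_key)
    return EAResult(best, tuple(trace), stop_reason)
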