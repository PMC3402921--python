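# Methods

## Model and representation

A secondary structure is a set of base pairs (i, j), 1-based, i < j,
that is disjoint (no shared position) and non-crossing (no
i < i′ < j < j′); pseudoknots are excluded throughout. Admissible
pairings are A·U, G·C and the G·U wobble, with at least 3 unpaired
bases enclosed by any pair (the standard minimum hairpin loop; the
threshold is configurable).

A refolding pathway from A to B is encoded as an **action chain**:
an ordered sequence of `add(i,j)` / `del(i,j)` moves such that every
prefix applies cleanly (an addition must neither *conflict* — reuse a
paired position — nor *clash* — cross an existing pair; a deletion
must remove a present pair) and the final structure equals B. Chains
and pathways are in bijection, so the search never revisits the
ambiguity of structure sequences. Validity is always established by
replaying the chain from A; mutation operators never emit a chain that
does not replay.

The quality of a pathway is its **energy barrier**
max_t E(S_t) − E(S₀), with the maximum taken over all structures
*including both endpoints*. The endpoints-inclusive convention
guarantees barrier ≥ 0 and barrier ≥ E(B) − E(A) and matches how
barrier landscapes are usually defined; fitness ties are broken by the
mean energy excess over S₁..Sₘ (S₀ is excluded since its excess is
identically zero), then by chain length (shorter preferred), then by
creation order for full determinism. Energies enter comparisons
rounded to 0.01 kcal/mol — the print precision of the evaluator — so
tie-breaking does not depend on sub-centikcal float noise.

## Energy models

Two interchangeable backends implement
`evaluate(sequence, structure) → kcal/mol`; both are pure functions
and map the empty structure to 0.0.

**Turner adapter.** ViennaRNA's nearest-neighbour evaluator through
its Python bindings, defaulting to the Turner-1999 parameter set with
d1 dangling-end treatment (single-base dangles, no coaxial stacking);
Turner-2004 is selectable. ViennaRNA keeps the active parameter set in
process-global state, so the adapter tracks the loaded set and
rebuilds its fold compounds when two models with different parameters
are interleaved. Evaluations are memoized by (sequence, pair set);
memoization is behaviorally invisible.

**Built-in simplified model.** A self-contained nearest-neighbour
model used so that the search, the exact oracle and the entire test
suite run with zero external dependencies: a 21-entry stacking table
over the six pair types (the 36 oriented neighbour combinations
collapse to 21 under strand-reversal symmetry; every entry ≤ 0, so
helix extension never destabilizes), hairpin/bulge/internal penalties
of the Jacobson–Stockmayer form a + b·ln(size), and an affine
multiloop penalty. The constants live in `energy.py`. The model
preserves the qualitative landscape — stacking stabilizes, loops
penalize, melting a helix is uphill — but its absolute values are not
calibrated against Turner parameters, and results obtained with it
are only comparable to each other.

## Mutation strategies

All five strategies draw from a single seeded random source, retry up
to `retry_limit` (default 50) rejected draws, and return either a
valid chain or nothing.

* **M1 (relocate)** moves one uniformly chosen action to a new
  position inside its *feasible interval* — the contiguous block of
  target positions around the origin for which the resulting chain
  revalidates. The target is drawn with linearly decaying weights:
  front-loaded for additions, back-loaded for deletions (pairing early
  and unpairing late keeps intermediates stacked). The weight exponent
  β (default 1) is configurable. Should chain validity ever be
  non-contiguous in the target position, only the block around the
  origin is used. A single-action chain has no distinct rearrangement
  and yields nothing.
* **M2 (swap)** exchanges two uniformly chosen actions, restarting on
  invalid draws.
* **M3 (complementary pair)** inserts `add(i,j)` after a uniformly
  chosen anchor and the matching `del(i,j)` at a back-loaded later
  position (or a deletion first and its re-addition later, chosen with
  equal probability). The pair is drawn uniformly from those neither
  conflicting nor clashing with the anchor structure — this is the
  operator that makes pathways indirect. The back-loaded placement of
  the complementary action is used for both orientations: a transient
  pair should live long enough to matter, and an equivalent argument
  applies to transient deletions.
* **M4 (force a stack)** picks a helix from STA(x) compatible with the
  structure after a random step and forces its missing pairs to form
  there consecutively, innermost pair first; each addition is either
  an existing later action relocated forward (M1 mechanics) or a fresh
  complementary add/del insertion (M3 mechanics).
* **M5 (convert stacks)** anchors at a random deletion action, picks a
  helix *incompatible* with the structure there, and forces it:
  compatible member pairs are placed as in M4; for an incompatible
  member pair, every blocking pair currently in the structure is
  deleted immediately beforehand, innermost blocker first — relocating
  its existing deletion or inserting a transient del/add pair. This
  realizes the cooperative melt-one-helix-while-forming-another motif;
  on geometries where the two helices only partially overlap it
  produces pathways that never pass through a fully unpaired
  intermediate.

STA(x), the stack set, contains every *maximal* run of ≥ 4 consecutive
allowable pairs along an anti-diagonal of the complementarity matrix
(the threshold is the `min_stack_len` knob). Sub-stacks are not
enumerated separately: the operators work with the difference set
{stack − S}, so sub-stacks add no reachable moves while inflating the
candidate list.

## The evolutionary loop

The initial population holds the four *stackwise simple pathways*:
delete all of A−B stack by stack (5′→3′ by outer pair), then add all
of B−A, each helix traversed outermost-first or innermost-first
(2 × 2 choices). Deleting first can never clash, so these chains are
always valid and have length equal to the base-pair distance.

Each generation, every parent produces ℓ_y offspring per strategy y;
the best l2 per parent plus the l1 elites form the candidate list, of
which the best l3 survive (duplicate chains are dropped, best kept —
the reference procedure is silent on duplicates and deduplication
protects diversity). The allocation for the next generation gives
strategy y a share of the budget L proportional to its success ratio
b_y/ℓ_y — offspring selected into the surviving population over
offspring allocated — floored at L_min, with a uniform split when
there is no history or no successes; the shares need not sum to
exactly L. Defaults: MAX = 10 iterations, plateau window γ = 5,
L = 100, l1 = 10, l2 = 5, l3 = 100, L_min = 3.

The loop stops when (1) the incumbent barrier reaches the theoretical
floor max(0, E(B) − E(A)) within 10⁻⁶ — the literal |E(B) − E(A)|
variant, which is not a true lower bound when E(B) < E(A), is
available behind a compatibility flag; (2) the incumbent fitness has
not improved over γ consecutive iterations; or (3) MAX iterations have
passed and the last one brought no improvement — the search may run
beyond MAX while successive iterations keep improving, bounded by a
hard cap (default 100). Elitism makes the incumbent barrier
non-increasing in every run.

## Exact direct oracle

For small |A ∪ B| the minimum barrier over *direct* pathways is
computed exactly: the states are the valid structures S ⊆ A ∪ B, the
moves are single additions/deletions, and the objective — minimize the
maximum node energy — is a bottleneck shortest path, solved by a
lexicographic Dijkstra on (bottleneck energy, steps) with ties broken
on a canonical state ordering so the certificate chain is
deterministic. The state space is 2^|A∪B| in the worst case; the cap
defaults to |A ∪ B| ≤ 16. The oracle upper-bounds the full problem
(indirect detours can only help), which is exactly how the tests use
it: the evolutionary barrier must never exceed the oracle's.

## Synthetic instances

The generator plants 4–5-pair complementary helix arms at random
disjoint position blocks of a random sequence (arms may still *cross*
in pair space, which is what makes helix conversion profitable), then
assembles each endpoint structure as a union of up to k mutually
compatible stacks drawn from the sequence's own stack set, requiring
A ≠ B. Everything is deterministic under the seed. What the generator
does **not** emulate: natural sequence composition and length (real
switches are 60–200 nt), multi-branch architectures, and endpoint
structures that are local energy minima. Tests passing on these
instances therefore certify the combinatorial contracts (validity,
elitism, oracle dominance, determinism) — not predictive accuracy on
biological switches.

## Problem sizes in tests

The test and verification runs use deliberately small search budgets —
instances of 24–30 nt with 1–2 stacks per structure, populations of
10–30 pathways, offspring budgets of 15–30 and 2–3 productive
generations; the oracle-dominance battery checks 25 instances with
|A ∪ B| ≤ 10 at best-of-5 seeds. These sizes keep the combinatorics
honest (chains of 8–40 actions) while the full default configuration
remains what a production run would use.

## Known limitations

* Pseudoknots, non-canonical pairs, modified nucleotides and
  multi-strand complexes are out of scope.
* The simplified energy model is a test vehicle, not a Turner
  replacement; quantitative barriers require the ViennaRNA backend.
* The position-choice bias inside M1/M3 is a linear power law; the
  search is not sensitive to its exact shape in our runs, but no claim
  is made that it is optimal.
* The exact oracle covers only direct pathways; no exact reference
  exists here for the indirect optimum (that problem is NP-hard).
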