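# stackpath

Low energy-barrier refolding pathways between two secondary structures
of one RNA molecule, found by a stack-guided evolutionary search.

## The problem

Conformational switches — riboswitches, metastable phage and plasmid
RNAs — carry out their function by refolding from one secondary
structure *A* into another, *B*. The kinetic difficulty of that
transition is summarized by the **energy barrier**: along a pathway
*A = S₀, S₁, …, Sₘ = B* in which consecutive structures differ by one
base pair, the barrier is

```
barrier(p) = max_t E(S_t) − E(S₀)
```

and the interesting quantity is the minimum barrier over all pathways.
Pathways may be *direct* (every intermediate uses only pairs of
*A ∪ B*) or *indirect* (transient extra pairs allowed); the
unrestricted minimization is NP-hard, so practical tools are
heuristics.

Most heuristics walk the energy landscape greedily and get trapped in
its ruggedness. `stackpath` instead searches in the space of
**action chains** — ordered sequences of `add(i,j)` / `del(i,j)` moves
that provably transform *A* into *B* — and mutates them by operations
phrased in terms of whole **stacks** (helices): reordering moves,
transient complementary add/del pairs, forced formation of a
compatible helix, and cooperative conversion between incompatible
helices. Candidate pathways are still *selected* by their energy
barrier, but they are *constructed* by coarse-grained stack movements,
which makes it easier to jump out of local optima.

The search is a (μ+λ)-style evolutionary algorithm with elitism: each
generation every pathway produces offspring through five mutation
strategies, the per-strategy budget adapts to which strategies
produced surviving offspring, and the best-ever pathway is always
retained.

## Worked example

The 16-nt toy switch `GGGGAAAACCCCUUUU` refolds from a GC helix into
an AU helix. `python examples/toy_refolding.py` prints:

```
sequence: GGGGAAAACCCCUUUU
E(A) = -6.60 kcal/mol
E(B) = 2.80 kcal/mol

simple pathway: barrier 12.10 kcal/mol, saddle  5.50 at step 5
simple pathway: barrier 12.10 kcal/mol, saddle  5.50 at step 5
simple pathway: barrier 12.90 kcal/mol, saddle  6.30 at step 5
simple pathway: barrier 12.90 kcal/mol, saddle  6.30 at step 5

best simple pathway (structure-by-structure):
step  action      structure        energy
   0  -           ((((....))))....    -6.60
   1  del(4,9)    (((......)))....    -5.30
   2  del(3,10)   ((........))....    -1.80
   3  del(2,11)   (..........)....     2.40
   4  del(1,12)   ................     0.00
   5  add(8,13)   .......(....)...     5.50
   6  add(7,14)   ......((....))..     4.60
   7  add(6,15)   .....(((....))).     3.70
   8  add(5,16)   ....((((....))))     2.80
```

Every pair of the two helices crosses or conflicts, so a direct
pathway must fully melt the GC helix; the saddle is the first AU pair
(5.50 kcal/mol) and the barrier is 5.50 − (−6.60) = 12.10 kcal/mol.
Forming the AU helix innermost-pair-first rather than outermost-first
is worth 0.80 kcal/mol at the saddle.

The other example scripts exercise the remaining capabilities:
`evolutionary_search.py` (full search with per-generation trace),
`exact_direct_oracle.py` (exact bottleneck-path optimum over direct
pathways on small instances, used as a cross-check on the search) and
`stack_enumeration.py` (the helix move-alphabet).

## Command line

```
stackpath run    --instance toy.txt --energy turner --seed 1 --runs 5 --out out/
stackpath oracle --instance toy.txt --energy simple
stackpath eval   --instance toy.txt
```

An instance file holds three lines: the sequence and the two
structures in dot-bracket notation. `run` writes a pathway table, a
JSON run report (config, barrier, saddle, full energy profile,
per-generation statistics) and a CSV barrier trace.

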