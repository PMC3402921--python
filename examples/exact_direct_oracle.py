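"""Exact direct-pathway optimum vs the evolutionary search.

Direct pathways only use base pairs of the two endpoint structures, so
for small |A u B| the minimum barrier over ALL direct pathways can be
computed exactly as a bottleneck shortest path on the state graph.
The evolutionary search also explores indirect detours, so its barrier
should never exceed the direct optimum.
"""

from stackpath import (
    EAConfig,
    exact_direct_barrier,
    load_energy_backend,
    run_ea,
    simple_pathway,
    energy_profile,
)
from stackpath.synthetic import RandomInstanceSpec, random_instance

inst = random_instance(RandomInstanceSpec(n=24, k_stacks=1, seed=11))
model = load_energy_backend("simple")

naive = energy_profile(model, inst.x, simple_pathway(inst.A, inst.B))
oracle_barrier, certificate = exact_direct_barrier(
    model, inst.x, inst.A, inst.B
)
ea_barrier = min(
    run_ea(
        inst.x, inst.A, inst.B,
        EAConfig(seed=s, offspring=20, l1=4, l2=3, l3=12, max_gen=3, gamma=2),
        model=model,
    ).best.barrier
    for s in range(5)
)

print(f"instance {inst.label}: |A u B| = {len(inst.A.pairs | inst.B.pairs)}")
print(f"stackwise simple pathway barrier: {naive.barrier:6.2f} kcal/mol")
print(f"exact direct optimum:             {oracle_barrier:6.2f} kcal/mol "
      f"({len(certificate)} actions)")
print(f"evolutionary search (best of 5):  {ea_barrier:6.2f} kcal/mol")
print(
    "\nThe exact value bounds every direct pathway from below; the "
    "search matches it here and may beat it on instances where a "
    "transient helix outside A u B lowers the saddle."
)
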