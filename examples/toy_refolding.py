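"""The 16-nt toy switch: four simple direct pathways and their barriers.

GGGGAAAACCCCUUUU can form a GC helix ((((....))))....  or an AU helix
....((((....)))).  Every pair of one helix crosses or conflicts with
every pair of the other, so a direct refolding must melt the first
helix completely before forming the second.  The script enumerates the
four stackwise orderings (melt outermost- or innermost-first, form
outermost- or innermost-first) and prints each energy profile.
"""

from stackpath import initial_population, load_energy_backend
from stackpath.io import format_pathway_table
from stackpath.synthetic import toy_switch

inst = toy_switch()
model = load_energy_backend("turner", "turner1999")

print(f"sequence: {inst.x}")
print(f"E(A) = {model.evaluate(inst.x, inst.A):.2f} kcal/mol")
print(f"E(B) = {model.evaluate(inst.x, inst.B):.2f} kcal/mol\n")

population = initial_population(model, inst.x, inst.A, inst.B)
for rec in population:
    saddle = max(rec.energies)
    print(
        f"simple pathway: barrier {rec.barrier:5.2f} kcal/mol, "
        f"saddle {saddle:5.2f} at step {rec.saddle_index}"
    )

best = population[0]
print("\nbest simple pathway (structure-by-structure):")
print(format_pathway_table(best, inst.x))
print(
    "The barrier is the saddle energy minus E(A).  What separates the "
    "two barrier values is the formation direction: growing the AU "
    "helix from its innermost pair keeps the partial helix stacked and "
    "lowers the saddle by 0.80 kcal/mol."
)
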