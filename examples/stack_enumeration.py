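"""Helix (stack) enumeration: the move alphabet of the search.

The mutation strategies operate on whole helices: the set STA(x) of
maximal runs of at least four consecutive allowable pairs (Watson-Crick
plus G-U wobble, hairpin gap >= 3).  For the toy switch this includes a
GU helix that belongs to neither endpoint structure — exactly the kind
of transient element an indirect pathway can exploit.
"""

from stackpath import enumerate_stacks, stack_relation
from stackpath.synthetic import toy_switch

inst = toy_switch()
stacks = enumerate_stacks(inst.x, min_stack_len=4)

print(f"sequence: {inst.x}\n{len(stacks)} stacks with >= 4 pairs:")
for st in stacks:
    rel_a = stack_relation(st, inst.A)
    rel_b = stack_relation(st, inst.B)
    pairs = ", ".join(f"({i},{j})" for i, j in st.pairs)
    print(f"  {pairs:<44} A:{rel_a:<12} B:{rel_b}")

print(
    "\nStacks incompatible with the current structure are the targets "
    "of the helix-conversion move; compatible ones can be forced to "
    "form as a block."
)
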