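"""Mapping character changes onto the cladogram.

For each branch the unit-cost dynamic program decides whether a
character changes there in *every* most-parsimonious reconstruction
(an unambiguous transformation).  Changes of characters that fit the
tree perfectly are synapomorphies — unique derivations diagnosing a
clade; the rest are homoplasies (parallel gains or reversals).
"""

from fitchclade import (
    SearchConfig,
    branch_and_bound,
    condense,
    diagnose_clade,
    load_fixture,
    unambiguous_changes,
)
from fitchclade.datasets import NAMED_CLADES, OUTGROUP

matrix = load_fixture()
binary = branch_and_bound(
    matrix, SearchConfig(seed=1, starts=10, move="spr")
).best_tree
mpt = condense(binary, matrix, outgroup=OUTGROUP)
rmap = unambiguous_changes(mpt, matrix, outgroup=OUTGROUP)

for name in ("Ectateus clade", "Selinus clade", "planus group"):
    diag = diagnose_clade(
        mpt, matrix, NAMED_CLADES[name], outgroup=OUTGROUP, rmap=rmap
    )
    syn = ", ".join(
        f"char {r.char}: state {r.derived_state}" for r in diag.synapomorphies
    )
    hom = ", ".join(
        f"char {r.char}: state {r.derived_state}" for r in diag.homoplasies
    )
    print(f"{name}")
    print(f"  synapomorphies: {syn or '(none)'}")
    print(f"  homoplasies:    {hom or '(none)'}")

# e.g. the Ectateus clade is diagnosed by slender male profemora
# (30:1) and hook-shaped clavae (33:1); narrow male protarsi (28:0)
# also change on its stem but arise more than once on the tree.
for r in rmap.for_char(30):
    print(f"char 30 change on branch of {len(r.branch)} taxa: "
          f"{r.from_states} -> {r.to_states}, "
          f"{'unambiguous' if r.unambiguous else 'ambiguous'}")
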