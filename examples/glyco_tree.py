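"""Build a UPGMA glyco-tree from motif profiles.

Entities (here: individuals) are compared by cosine distance of their
mean motif-abundance profiles; UPGMA yields an ultrametric dendrogram
exported as newick.
"""

import glycolac as gl

table, truth = gl.simulate_cohort(gl.CohortDesign(seed=11))
motifs = gl.quantify_motifs(table, table._structures, gl.builtin_library())

profiles = motifs.data.groupby(table.meta["individual"]).mean()
profiles = profiles.loc[:, (profiles > 0).any()]
tree = gl.upgma(gl.cosine_distance_matrix(profiles))
print("cosine-distance UPGMA over individuals:")
print(" ", gl.to_newick(tree))
print("  ultrametric:", tree.is_ultrametric())

# presence/absence variant over terminal motifs
lib = gl.builtin_library()
presence = {}
for name, g in list(table._structures.items())[:8]:
    terms = gl.terminal_motifs(g, lib)
    presence[name[:30]] = {m: int(m in terms) for m in lib.names()}
import pandas as pd

pm = pd.DataFrame(presence).T
pm = pm.loc[pm.sum(axis=1) > 0, pm.sum(axis=0) > 0]
if len(pm) >= 2:
    t2 = gl.upgma(gl.binary_distance_matrix(pm))
    print("terminal-motif presence tree over glycans:")
    print(" ", gl.to_newick(t2))
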