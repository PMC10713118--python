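"""Build and query a cell-type hierarchy from pseudo-bulk profiles.

Sums counts per cell type, TP10K-normalizes the profiles, clusters them
with Ward's method into a binary tree, and shows lineages (root-to-leaf
node paths) and lineage-overlap similarity between types. Similar types
share longer lineage prefixes, so their similarity score is higher.
"""

import census as cs

ref, _, _ = cs.generate(cs.GeneratorSpec(seed=1))
profiles = cs.tp10k(cs.aggregate_pseudobulk(ref))
tree = cs.build_hierarchy(profiles)

print("newick:", tree.to_newick())
print(f"{tree.n_leaves} leaves, {tree.n_nodes} nodes "
      f"({len(tree.internal_nodes)} classification points)")
for label in ("ductal", "acinar", "T cell"):
    print(f"lineage({label!r}) = {tree.lineage(label)}")
for a, b in [("ductal", "acinar"), ("ductal", "T cell"), ("T cell", "NK cell")]:
    print(f"label_similarity({a!r}, {b!r}) = {tree.label_similarity(a, b):.3f}")
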