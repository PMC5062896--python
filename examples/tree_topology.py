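"""Canonical forms of clonal hierarchies.

Rooted unordered trees are encoded by recursively sorting child encodings:
two hierarchies get the same string iff they are isomorphic.  Restricting
to significant clones first contracts invisible intermediate clones, which
is how simulated hierarchies are compared with sequencing-derived patient
trees (those only show clones above detection threshold).
"""
from hemaclone import CloneNode, CloneParams, HierarchyTree, canonical_topology

def chain_tree(sig):
    t = HierarchyTree()
    for i, s in enumerate(sig, start=1):
        t.add(CloneNode(id=i, parent=i - 1 if i > 1 else None, birth_time=float(i),
                        depth=i, params=CloneParams(0.9, 0.3),
                        significant={"terminal": s}))
    return t

star = HierarchyTree()
star.add(CloneNode(id=1, parent=None, birth_time=0.0, depth=1,
                   params=CloneParams(0.9, 0.3), significant={"terminal": True}))
for i in (2, 3):
    star.add(CloneNode(id=i, parent=1, birth_time=float(i), depth=2,
                       params=CloneParams(0.9, 0.3), significant={"terminal": True}))

chain = chain_tree([True, True, True])
print("3-chain :", canonical_topology(chain, mode="terminal"))
print("3-star  :", canonical_topology(star, mode="terminal"))
print("different strings -> different architectures")

hidden = chain_tree([True, False, True])
print("chain with invisible middle clone, contracted:",
      canonical_topology(hidden, significant_only=True, mode="terminal"))
print("-> indistinguishable from a direct 2-chain, as for sequencing data")
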