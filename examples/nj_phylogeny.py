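"""Simulate a clade of mitogenomes and recover its tree by neighbor joining.

A root genome is evolved along a known 6-leaf tree under Jukes-Cantor
substitution; p-distances (pairwise deletion) between the leaf genomes feed
Saitou-Nei neighbor joining, and the Robinson-Foulds distance to the
generating topology measures recovery (0 = identical topology).
"""

import mitocomp as mc
from mitocomp.phylo import Alignment

NWK = "(((a:0.05,b:0.05):0.03,c:0.08):0.02,(d:0.05,e:0.05):0.04,f:0.09);"

genomes, truth = mc.simulate_clade(
    mc.CladeSpec(tree=NWK, root=mc.SimSpec(seed=1), seed=2))
print(f"simulated {len(genomes)} leaf genomes of "
      f"{truth['root'].length} bp from one root")
print("realized substitutions per branch:", truth["substitutions"])

aln = Alignment({gid: g.sequence for gid, g in genomes.items()})
dm = mc.p_distance_matrix(aln)
tree = mc.nj_tree(dm)
rf = mc.robinson_foulds(tree, mc.parse_newick(NWK))
print("\nNJ tree:", tree.to_newick())
print(f"Robinson-Foulds distance to the generating topology: {rf}")
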