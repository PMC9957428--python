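"""Group circular gene orders into patterns and explain their differences.

Canonical rotation (anchored at cox1) makes circular gene orders comparable;
identical canonical orders share a pattern.  Differences between patterns
are reported as deletions, insertions and minimal translocation sets.
"""

import mitocomp as mc
from mitocomp.simulate import GROUND_PATTERN, architecture_tokens, \
    make_pattern_fixture

orders = make_pattern_fixture()               # 25 genomes, 8 architectures
catalog = mc.group_patterns(orders)
sizes = {lab: len(catalog.members(lab)) for lab in sorted(catalog.patterns)}
print(f"{len(orders)} genomes group into {len(catalog.patterns)} "
      f"gene-order patterns: {sizes}")

A = mc.GeneOrder(GROUND_PATTERN)
rep = mc.diff_orders(A, mc.GeneOrder(architecture_tokens("E")))
e = rep.events[0]
print(f"\nground pattern vs single-tRNA-loss pattern: {e.kind} of {e.token} "
      f"between {e.old_neighbors[0]} and {e.old_neighbors[1]}")

rep = mc.diff_orders(A, mc.GeneOrder(architecture_tokens("B")))
moved = [ev.token for ev in rep.of_kind("translocation")]
print(f"ground pattern vs double-swap pattern: {rep.moved_set_size} "
      f"translocated tRNAs ({', '.join(moved)}) explain both pair swaps")
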