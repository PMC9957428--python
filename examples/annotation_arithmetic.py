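"""Circular-coordinate arithmetic on a transcribed mitogenome annotation.

Feature lengths, intergenic spacers and overlaps, and per-region totals are
pure arithmetic on the printed 1-based inclusive coordinates of the
14,814 bp reference annotation.
"""

import mitocomp as mc

g = mc.load_tukubana_annotation()
print(f"{g.genome_id}: {g.length} bp, {len(g.features)} features "
      f"({len(g.features_of_class('PCG'))} PCGs, "
      f"{len(g.features_of_class('tRNA'))} tRNAs, "
      f"{len(g.features_of_class('rRNA'))} rRNAs, 1 control region)")

pcg_bp = mc.region_length(g, "PCG")
print(f"protein-coding region: {pcg_bp} bp "
      f"({100 * pcg_bp / g.length:.2f}% of the genome)")
for tok in ("CR", "rrnS", "rrnL"):
    print(f"{tok}: {mc.feature_length(g.feature(tok), g.length)} bp")

# spacers: positive = intergenic gap, negative = overlap between neighbors
print("cob -> trnW spacer:",
      mc.spacer_length(g.feature("cob"), g.feature("trnW"), g.length), "bp")
print("atp8 -> trnY spacer:",
      mc.spacer_length(g.feature("atp8"), g.feature("trnY"), g.length),
      "bp (overlap)")
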