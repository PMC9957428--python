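"""Recompute AT/GC skews for 25 leech mitogenomes from published percentages.

AT skew = (A-T)/(A+T) and GC skew = (G-C)/(G+C) summarize which strand is
enriched for each base of a pair.  Recomputing them from the published
1-decimal base percentages reproduces the published 3-decimal skews.
"""

import mitocomp as mc

df = mc.composition_report(table=mc.packaged_fixture("hirudinea_table1.tsv"))
ok = df[df["error"] == ""]
print(ok[["species", "at_pct", "at_skew", "gc_skew"]].head(5).to_string(index=False))
print(f"\n{len(ok)} of {len(df)} rows validated "
      "(one row has a typographic percentage and cannot be recomputed).")

at, gc = mc.skews_from_percent(38.4, 14.5, 35.2, 11.9)
print(f"\nFocal genome: AT skew {mc.round_display(at, 3)}, "
      f"GC skew {mc.round_display(gc, 3)}")
print("Negative AT skew: more T than A on the heavy strand; "
      "negative GC skew: more C than G.")
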