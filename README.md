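# mitocomp

Comparative analysis of circular mitochondrial genomes, built around the
standard workflow for newly sequenced metazoan (here: leech / Hirudinea)
mitogenomes: annotation arithmetic on the circular molecule, nucleotide
composition and strand-asymmetry skews, codon-usage bias, circular
gene-order rearrangements, tRNA cloverleaf validation, and a distance-based
phylogeny on concatenated protein-coding genes.  A synthetic-data generator
produces annotated genomes, clades and tRNA structures with known ground
truth, so every stage is testable without downloading anything.

## What it computes

* **Composition and skews.** For a sequence or region with base counts
  A, C, G, T: `AT skew = (A − T)/(A + T)`, `GC skew = (G − C)/(G + C)`,
  and A+T content.  Skews can also be recomputed from published rounded
  percentages, matching the convention of comparative tables.
* **Circular annotation arithmetic.** 1-based inclusive GenBank
  coordinates; features may wrap the origin (`end < start`); gene lengths,
  signed intergenic spacers (negative = overlap), per-region totals.
* **RSCU.** Relative synonymous codon usage
  `RSCU_ij = n_ij · k_i / Σ_j n_ij` under the invertebrate mitochondrial
  code (NCBI table 5), with incomplete stop codons (`T--`, `TA-`) handled.
* **Gene-order patterns.** Circular orders are canonicalized (rotation to
  cox1, reflection normalized); identical canonical orders define a
  pattern; differences between orders are explained as deletions,
  insertions, inversions and a minimal translocated set relative to a
  maximum common circular subsequence.
* **tRNA cloverleaves.** Dot-bracket structures partitioned into acceptor
  stem and DHU / anticodon / TΨC arms; a DHU stem with fewer than two
  complementary pairs is flagged atypical.
* **Phylogeny.** Gene concatenation, a conserved-block column filter,
  p-distances with pairwise deletion, Saitou–Nei neighbor joining, and
  Robinson–Foulds comparison.

## Worked example

```python
import mitocomp as mc

g = mc.load_tukubana_annotation()          # transcribed published annotation
pcg_bp = mc.region_length(g, "PCG")
print(pcg_bp, round(100 * pcg_bp / g.length, 2))
at, gc = mc.skews_from_percent(38.4, 14.5, 35.2, 11.9)
print(mc.round_display(at, 3), mc.round_display(gc, 3))
```

prints

```
11097 74.91
-0.043 -0.098
```

— the protein-coding region is 11,097 bp (74.91% of the 14,814 bp genome),
and the genome's AT and GC skews are −0.043 and −0.098: the heavy strand
carries slightly more T than A and more C than G.

The `examples/` directory has one short script per capability
(`python examples/gene_order_patterns.py`, etc.); for instance the
gene-order example groups 25 synthetic genomes into 8 patterns and reports
that the single-tRNA-loss pattern differs from the ground pattern by a
deletion of trnH between the control region and nad5.

A thin CLI mirrors the library:

```
mitocomp features annotation.tsv --lengths --spacers
mitocomp composition --from-percent table.tsv
mitocomp rscu genome.gb --table 5
mitocomp gene-order all.order --catalog catalog.tsv
mitocomp trna-check structures.txt
mitocomp nj-tree --genes cox1.fa cob.fa --trim --out tree.nwk
mitocomp simulate --seed 1 --pattern H --out outdir/
```

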