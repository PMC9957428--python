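# Methods

This note records the models, conventions and design choices behind
`mitocomp`, and what the synthetic-data generator does and does not emulate.

## Coordinates and annotation model

Features use GenBank convention: 1-based, inclusive on both ends, on a
circular molecule.  A feature spanning the origin is stored with
`end < start` (`wraps_origin`), serialized to GenBank as
`join(start..L,1..end)`.  Strand `+` is the heavy strand; the leech genomes
that motivated the package encode all 37 genes plus the control region on
it, but both strands are supported throughout (minus-strand features are
reverse-complemented on extraction and carry a sign in gene orders).

Gene names are normalized to the standard 37-gene tokens (cox1..3, cob,
atp6/8, nad1-6, nad4l, rrnS/rrnL, trnX, CR) through a synonym map covering
the common GenBank dialects (COI, cytb, 12S rRNA, D-loop, tRNA-Leu(UUR),
...).  The leucine and serine isoacceptors are disambiguated by suffix,
anticodon, or codon-family notation: trnL1 = CUN (anticodon TAG), trnL2 =
UUR (TAA), trnS1 = AGN (TCT), trnS2 = UCN (TGA).  Unknown names pass
through verbatim with a warning rather than failing, since annotation
dialects vary.  Duplicated genes (the extra trnD of one observed
architecture) take a `_2` suffix.

The shipped annotation table transcribes the published reference
annotation.  Its printed intergenic column is reproduced exactly by
`spacer_length` for all 16 verified consecutive pairs; the final circular
gap (last gene back to cox1) prints 25 bp while the recorded coordinates
imply 26 bp — the table keeps the printed value flagged unverified, and
the code reports what the coordinates say.  Similarly, the printed
protein-coding size range (159–1698 bp) is inconsistent with the printed
nad5 coordinates (1702 bp); the implementation follows coordinates.
One comparison-table row ("Whitmania laevis 1") prints a typographic
percentage (`160.`) and is carried verbatim but flagged unverifiable.

## Composition and skews

`AT skew = (A − T)/(A + T)`, `GC skew = (G − C)/(G + C)`.  Ambiguity codes
are excluded from numerators and denominators (not redistributed); counts
are reported so users can audit.  Skews computed from published rounded
percentages can differ from count-based skews in the third decimal; both
paths exist and the percentage path validates published tables.  Display
rounding is half-away-from-zero, 3 decimals for skews and 1 for
percentages, matching how comparative tables print.  A region's
composition concatenates per-gene extractions, so bases shared by
overlapping genes count once per gene — this is the convention under which
the published protein-coding region total (11,097 bp) equals the sum of
the individual gene lengths.

## Codon usage

Default genetic code: NCBI translation table 5 (invertebrate
mitochondrial; AGA/AGG = Ser, TGA = Trp, ATA = Met), consistent with the
serine-AGN anticodon TCT in the reference annotation; other tables are
selectable.  Codons are read in frame 0; a 1–2 nt terminal remainder is
the incomplete stop (`T--` / `TA-`, completed by polyadenylation) and
never enters codon counts.  Start codons count as ordinary Met-family
codons in RSCU — the simplest defensible convention.  With stops included
they form their own family.  `RSCU_ij = n_ij k_i / Σ_j n_ij`; a zero-total
family keeps RSCU 0 and is flagged degenerate.

## Gene orders and rearrangements

Canonical form: rotate the circuit so cox1 is first (fallback anchors cob,
then rrnL); if the anchor lies on the minus strand the circuit is reversed
and signs flipped first.  Canonical identity is therefore invariant to
rotation and reflection, and defines pattern membership.  Pattern labels
are assigned A, B, C... by descending group size, ties broken by the
lexicographically earliest genome id; note that historically assigned
letters in the literature do not follow group size, so catalog labels are
a deterministic convention of this package, while the eight reconstructed
architectures keep their conventional letters in `architecture_tokens`.

`diff_orders` explains one order against another at the descriptive level
used in comparative mitogenomics: content differences are deletions and
insertions; among shared genes, a maximum common circular subsequence is
computed exactly (any common cyclic subsequence can be linearized at one
of its own elements, so rotating both circles to each shared gene and
taking an ordinary LCS explores every candidate; orders are ≤ ~40 tokens,
so the O(n³) cost is negligible), and the genes outside it are the minimal
translocated set under that model.  This is deliberately *not* a
genome-rearrangement edit distance (DCJ/breakpoint variants are a
different, partly NP-hard problem); it matches statements of the form
"pattern X differs by a translocation of gene Y".  Sign mismatches of
shared genes are reported as inversions (none occur in the all-plus-strand
data the package targets, but the contract is tested).

`apply_events` replays an event list; a moved or inserted gene is placed
after its recorded left new-neighbor when present, else before its right
one.  This tolerant rule is what makes sequential replay of diff-generated
events exact even when adjacent genes moved together; an event whose
neighbors are both absent is an error.

The 25-genome pattern fixture is a reconstruction from described events
(double tRNA swap; trnH loss; extra trnD; trnR/trnC moves with a trnK/trnI
swap, in two variants differing in trnR/trnW order), with multiplicities
11/6/2/2/1/1/1/1 summing to 25.  Where a description pins only *which*
genes moved but not the exact landing position (patterns C, D, F, G), the
generator uses fixed documented choices; the grouping and diff claims
tested on the fixture do not depend on those choices.

## tRNA structures

The module validates given secondary structures rather than folding
sequences — structure prediction belongs to annotation pipelines and
energy models, out of scope here.  Dot-bracket input is limited to one
bracket level (cloverleafs are nested; pseudoknots unsupported).  Helices
are maximal stacks of directly nested pairs; the acceptor stem is the
enclosing helix and the branch helices are assigned 5'→3' to DHU,
anticodon and TΨC arms.  With only two branch helices the DHU arm is taken
as the absent one — the arm metazoan mitochondrial tRNAs actually lose;
with one, only the anticodon arm is assigned.  "Typical" means acceptor
≥ 6 pairs, every arm present with ≥ 2 pairs, anticodon loop ≥ 5 nt
(configurable); the threshold of 2 is chosen so that precisely the
described one-pair DHU stem is atypical.  Stems with internal bulges would
be read as extra branch helices; the generator emits perfect stems, so
this limitation does not affect the shipped tests.

## Phylogeny stage

The external maximum-likelihood step of the motivating workflow is out of
scope; the in-house, fully testable substitute is p-distance + neighbor
joining, with optional export of the trimmed concatenated alignment for
external ML.  Distances use pairwise deletion (sites with a gap/N in
either member of a pair are skipped) — robust to per-taxon missing genes;
a pair with no comparable sites is undefined (NaN) and rejected by NJ.
p-distance is a premetric only; no triangle inequality is asserted.

The conserved-block trimmer is a simplified analogue of the usual
block-filtering tools and deliberately not compatible with any of them:
keep columns with gap fraction ≤ `max_gap_frac` (default 0.2) and majority
residue ≥ `min_conserved_frac` of taxa (default 0.5), then keep only runs
of ≥ `min_block_len` kept columns (default 10).  It never adds columns and
is idempotent.

NJ is the standard Saitou–Nei agglomeration on the Q criterion; ties are
broken by the lexicographically smallest taxon pair, so results are
deterministic; negative branch lengths are clamped to zero.  On additive
matrices the true topology and branch lengths are recovered exactly (and
the tests cross-check topologies against an independent NJ/RF
implementation from dendropy).  Robinson–Foulds counts bipartitions
present in exactly one tree.

## Synthetic data

`simulate_mitogenome` lays genes out clockwise without overlaps following
a chosen architecture, with per-gene lengths defaulting to the reference
annotation's values; the spare length (22 bp at the default 14,814 bp
genome) is spread over intergenic gaps multinomially.  Protein-coding
genes start with ATG (ATA/ATT for the two genes annotated that way) and
end with TAA/TAG or the incomplete form their length modulo 3 dictates;
bodies contain no in-frame stops.

Codon generation is positionwise: third positions receive extra A/T mass
(`codon_AT3_bias`, default 0.35, i.e. `P(AT at position 3) =
β + (1−β)·t` for target A+T fraction `t`), and first/second positions are
solved by bisection so that the stop-codon-conditioned codon distribution
has expected A+T exactly `t`.  This keeps whole-genome composition on
target (the package's composition-recovery tests hold to within ±1.5
percentage points at 14.8 kb) while guaranteeing the NNA/NNT codon
preference (mean RSCU > 1) seen in AT-rich mitogenomes.  An alternative —
uniform amino-acid sampling with biased synonym choice — was rejected
because it pins first/second positions near 50% A+T and cannot reach the
~74% A+T of the genomes being emulated.  Non-coding regions are i.i.d.
bases at the target composition.

Randomness is hierarchical: each gene's stream is keyed by (seed, token),
so adding or removing a gene leaves every other gene's sequence unchanged,
and the same seed reproduces genomes byte-for-byte.

`simulate_clade` evolves the root sequence along a tree under Jukes–Cantor:
per branch of length `b` each site substitutes with probability
`3/4·(1 − e^{−4b/3})`, uniformly to one of the other three bases;
annotations are carried through unchanged and realized substitution counts
are recorded as ground truth.  No indels, no selection, no rate variation,
no strand-asymmetric mutation — so passing recovery tests demonstrates the
correctness of the distance/NJ machinery, not robustness to the alignment
error, compositional heterogeneity or saturation that real multi-family
datasets contain.  `simulate_trna` builds cloverleaf sequences with
perfectly Watson–Crick stems at exact requested stem/loop sizes (default
geometry 67 nt, inside the 59–69 nt range of observed mitochondrial
tRNAs), with the anticodon written at the center of an odd-length
anticodon loop.

## Problem sizes used in checks

The shipped checks run at desk scale: whole-genome simulations at the
14.8 kb reference length, clade simulations at the same length on 6–8
leaf trees, JC recovery checks at 50 kb sites, binomial recovery checks at
10 kb, and 200–1000 random count vectors for the RSCU normalization
property.  These sizes make the stochastic tolerances (quoted as ~3σ
binomial bounds) comfortable.
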