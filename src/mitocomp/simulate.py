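"""Synthetic mitogenomes, clades, and tRNA structures with known ground truth.

The generator emulates the architecture of leech (Hirudinea) mitochondrial
genomes: a circular ~14.8 kb molecule carrying 13 protein-coding genes,
22 tRNAs, 2 rRNAs and a control region, all on the heavy strand, laid out
following one of the eight observed circular gene-order patterns (A-H;
pattern A is the ground pattern).  Sequences are generated with a target
base composition and an elevated A/T fraction at third codon positions, so
compositional and codon-usage statistics have known expectations.  Clades
evolve a root genome along a tree under Jukes-Cantor substitution.

Every generator is deterministic under a fixed seed; per-gene streams are
keyed by the gene token, so adding or removing one gene leaves the others'
sequences unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .gene_order import GeneOrder, canonicalize
from .genome import AnnotatedGenome, Feature
from .phylo import PhyloTree, TreeNode
from .tokens import classify_token

# -------------------------------------------------------------- architectures

#: The Hirudinea ground gene order (pattern A): one clockwise circuit
#: starting at cox1, all genes on the heavy strand, CR included.
GROUND_PATTERN = (
    "cox1", "trnN", "cox2", "trnD", "atp8", "trnY", "trnG", "cox3", "trnQ",
    "nad6", "cob", "trnW", "atp6", "trnR", "CR", "trnH", "nad5", "trnF",
    "trnE", "trnP", "trnT", "nad4l", "nad4", "trnC", "trnM", "rrnS", "trnV",
    "rrnL", "trnL1", "trnA", "trnS2", "trnL2", "nad1", "trnI", "trnK",
    "nad3", "trnS1", "nad2",
)


def _swap(tokens: list, a: str, b: str) -> None:
    ia, ib = tokens.index(a), tokens.index(b)
    tokens[ia], tokens[ib] = tokens[ib], tokens[ia]


def _move_after(tokens: list, tok: str, after: str) -> None:
    tokens.remove(tok)
    tokens.insert(tokens.index(after) + 1, tok)


def architecture_tokens(label: str) -> tuple:
    """Token circuit of one of the eight observed gene-order patterns.

    Pattern A is the ground pattern.  B swaps trnG with trnY and trnA with
    trnS2; C adds a relocation of trnH to pattern B and D relocations of
    trnA/trnS2; E deletes trnH (between CR and nad5) from A; H inserts an
    extra trnD (trnD_2) between cox2 and atp8; F and G move trnR and trnC
    next to cob and swap trnK/trnI, differing only in the order of trnR and
    trnW.  Patterns not pinned down base-by-base in the comparative record
    (C, D, F, G target positions) use fixed, documented choices.
    """
    t = list(GROUND_PATTERN)
    if label == "A":
        pass
    elif label == "B":
        _swap(t, "trnY", "trnG")
        _swap(t, "trnA", "trnS2")
    elif label == "C":
        t = list(architecture_tokens("B"))
        _move_after(t, "trnH", "trnF")
    elif label == "D":
        t = list(architecture_tokens("B"))
        _move_after(t, "trnA", "trnV")
        _move_after(t, "trnS2", "trnA")
    elif label == "E":
        t.remove("trnH")
    elif label in ("F", "G"):
        _swap(t, "trnI", "trnK")
        t.remove("trnR")
        t.remove("trnC")
        if label == "F":
            t.insert(t.index("trnW"), "trnR")
        else:
            t.insert(t.index("trnW") + 1, "trnR")
        t.insert(t.index("atp6") + 1, "trnC")
    elif label == "H":
        t.insert(t.index("atp8"), "trnD_2")
    else:
        raise ValueError(f"unknown architecture label {label!r}")
    return tuple(t)


#: Genomes per pattern in the reconstructed 25-genome comparison set:
#: the ground pattern in most species, B in six, E and H in two each,
#: the remaining patterns in one species each.
PATTERN_MULTIPLICITIES = {"A": 11, "B": 6, "C": 1, "D": 1,
                          "E": 2, "F": 1, "G": 1, "H": 2}


def make_pattern_fixture() -> dict:
    """Deterministic 25-genome gene-order set realizing the 8 architectures.

    Genome ids are ``<architecture><index>`` (e.g. A01..A11, E01, E02).
    """
    orders = {}
    for label, n in PATTERN_MULTIPLICITIES.items():
        toks = architecture_tokens(label)
        for i in range(1, n + 1):
            orders[f"{label}{i:02d}"] = GeneOrder(toks)
    return orders


# ------------------------------------------------------------ genome simulator

#: Default per-gene lengths (bp), the annotated lengths of the reference
#: leech mitogenome.
DEFAULT_GENE_LENGTHS = {
    "cox1": 1537, "trnN": 64, "cox2": 678, "trnD": 64, "atp8": 159,
    "trnY": 66, "trnG": 61, "cox3": 781, "trnQ": 69, "nad6": 471,
    "cob": 1137, "trnW": 64, "atp6": 705, "trnR": 68, "CR": 402,
    "trnH": 64, "nad5": 1702, "trnF": 63, "trnE": 59, "trnP": 64,
    "trnT": 62, "nad4l": 294, "nad4": 1335, "trnC": 64, "trnM": 62,
    "rrnS": 735, "trnV": 63, "rrnL": 1160, "trnL1": 60, "trnA": 60,
    "trnS2": 67, "trnL2": 61, "nad1": 939, "trnI": 62, "trnK": 65,
    "nad3": 354, "trnS1": 66, "nad2": 1005,
}

DEFAULT_ANTICODONS = {
    "trnN": "GTT", "trnD": "GTC", "trnY": "GTA", "trnG": "TCC",
    "trnQ": "TTG", "trnW": "TCA", "trnR": "TCG", "trnH": "GTG",
    "trnF": "GAA", "trnE": "TTC", "trnP": "TGG", "trnT": "TGT",
    "trnC": "GCA", "trnM": "CAT", "trnV": "TAC", "trnL1": "TAG",
    "trnA": "TGC", "trnS2": "TGA", "trnL2": "TAA", "trnI": "GAT",
    "trnK": "TTT", "trnS1": "TCT",
}

_DEFAULT_STARTS = {"cox3": "ATA", "nad2": "ATT"}
_TAG_STOPPERS = frozenset({"atp8", "nad4", "nad3"})
_STOPS = ("TAA", "TAG")

#: Default intergenic budget: total spacer bp beyond the summed gene lengths
#: (the reference genome's net spacer budget at its 14,814 bp length).
DEFAULT_SPACER_BUDGET = 22


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one simulated mitogenome.

    ``architecture`` is a pattern label (A-H) or an explicit
    :class:`GeneOrder`.  Target percentages default to the reference leech
    mitogenome composition (A 35.2, T 38.4, C 14.5, G 11.9, i.e. A+T 73.6%).
    ``codon_AT3_bias`` is the extra probability mass pushed onto A/T at
    third codon positions (with first/second positions compensated so the
    coding region still matches the target composition overall).
    """

    genome_length: int | None = None
    architecture: str | GeneOrder = "A"
    gene_lengths: dict = field(default_factory=dict)
    target_pA: float = 35.2
    target_pC: float = 14.5
    target_pG: float = 11.9
    target_pT: float = 38.4
    codon_AT3_bias: float = 0.35
    seed: int = 0

    def __post_init__(self):
        total = self.target_pA + self.target_pC + self.target_pG + self.target_pT
        if abs(total - 100.0) > 0.01:
            raise ValueError(f"target percentages sum to {total}, not 100")
        if not 0.0 <= self.codon_AT3_bias <= 1.0:
            raise ValueError("codon_AT3_bias must be in [0, 1]")

    @property
    def tokens(self) -> tuple:
        if isinstance(self.architecture, GeneOrder):
            return self.architecture.names
        return architecture_tokens(self.architecture)

    def length_of(self, token: str) -> int:
        if token in self.gene_lengths:
            return self.gene_lengths[token]
        base = token[:-2] if token.endswith("_2") else token
        try:
            return self.gene_lengths.get(base, DEFAULT_GENE_LENGTHS[base])
        except KeyError:
            raise ValueError(f"no length known for gene {token!r}") from None

    @property
    def base_probs(self) -> np.ndarray:
        """P(A), P(C), P(G), P(T)."""
        p = np.array([self.target_pA, self.target_pC,
                      self.target_pG, self.target_pT], dtype=float)
        return p / p.sum()


_BASES = np.array(list("ACGT"))


def _gene_rng(seed: int, token: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, *token.encode()])


def _iid_bases(rng, n: int, probs: np.ndarray) -> str:
    return "".join(_BASES[rng.choice(4, size=n, p=probs)])


_SENSE_CODONS = tuple(a + b + c
                      for a in "ACGT" for b in "ACGT" for c in "ACGT"
                      if a + b + c not in _STOPS)
_SENSE_AT = np.array([sum(b in "AT" for b in c) for c in _SENSE_CODONS])
_SENSE_IDX = np.array([["ACGT".index(b) for b in c] for c in _SENSE_CODONS])


def _codon_distribution(spec: SimSpec) -> np.ndarray:
    """Probability over the 62 sense codons of the mitochondrial code.

    Codons factorize over positions; third positions get A/T mass
    ``beta + (1-beta)*t`` (t = target A+T fraction) and first/second
    positions are solved (bisection) so that, conditional on excluding stop
    codons, the expected A+T fraction of coding sequence equals the target.
    Third-position A/T enrichment above the within-family average makes
    NNA/NNT codons preferred (RSCU > 1) by construction.
    """
    q = spec.base_probs  # A C G T
    t = q[0] + q[3]
    beta = spec.codon_AT3_bias
    at3 = beta + (1 - beta) * t

    def rescale(target_at):
        out = q.copy()
        if 0 < t:
            out[[0, 3]] *= target_at / t
        if t < 1:
            out[[1, 2]] *= (1 - target_at) / (1 - t)
        s = out.sum()
        return out / s if s else out

    q3 = rescale(at3)

    def dist(at12):
        q12 = rescale(min(1.0, max(0.0, at12)))
        p = (q12[_SENSE_IDX[:, 0]] * q12[_SENSE_IDX[:, 1]]
             * q3[_SENSE_IDX[:, 2]])
        return p / p.sum()

    def mean_at(at12):
        return float((dist(at12) * _SENSE_AT).sum()) / 3.0

    lo, hi = 0.0, 1.0
    if mean_at(lo) > t or mean_at(hi) < t:  # target outside reachable range
        return dist(min(1.0, max(0.0, (3 * t - at3) / 2)))
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if mean_at(mid) < t:
            lo = mid
        else:
            hi = mid
    return dist(0.5 * (lo + hi))


def _sample_codons(rng, n: int, codon_probs: np.ndarray) -> list:
    """n sense codons drawn from the conditional codon distribution."""
    return [_SENSE_CODONS[i] for i in rng.choice(len(_SENSE_CODONS), size=n,
                                                 p=codon_probs)]


def _simulate_pcg(rng, token: str, length: int, spec: SimSpec):
    """(sequence, start_codon, stop_codon) for one protein-coding gene."""
    start = _DEFAULT_STARTS.get(token, "ATG")
    r = length % 3
    if r == 1:
        stop, tail = "T--", "T"
    elif r == 2:
        stop, tail = "TA-", "TA"
    else:
        stop = "TAG" if token in _TAG_STOPPERS else "TAA"
        tail = stop
    n_body = (length - 3 - len(tail)) // 3
    if n_body < 0:
        raise ValueError(f"{token}: length {length} too short for a CDS")
    body = _sample_codons(rng, n_body, _codon_distribution(spec))
    return start + "".join(body) + tail, start, stop


def simulate_mitogenome(spec: SimSpec) -> AnnotatedGenome:
    """Generate a circular annotated genome realizing a gene-order pattern.

    Genes are laid out clockwise without overlaps; the spare length (genome
    length minus summed gene lengths) is distributed over the intergenic
    gaps.  PCGs start with ATN, end with TAA/TAG or an incomplete stop as
    their length dictates, and avoid in-frame stops; the remaining regions
    are i.i.d. bases at the target composition.
    """
    tokens = spec.tokens
    lengths = {tok: spec.length_of(tok) for tok in tokens}
    total_genes = sum(lengths.values())
    genome_length = spec.genome_length
    if genome_length is None:
        genome_length = total_genes + DEFAULT_SPACER_BUDGET
    leftover = genome_length - total_genes
    if leftover < 0:
        raise ValueError(
            f"gene lengths sum to {total_genes} > genome length {genome_length}")

    gap_rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 0xFEED])
    gaps = gap_rng.multinomial(leftover, [1 / len(tokens)] * len(tokens))

    probs = spec.base_probs
    pos = 1
    features: list[Feature] = []
    chunks: list[str] = []
    for tok, gap in zip(tokens, gaps):
        rng = _gene_rng(spec.seed, tok)
        cls = classify_token(tok)
        L = lengths[tok]
        kwargs: dict = {}
        if cls == "PCG":
            seq, start_codon, stop_codon = _simulate_pcg(rng, tok, L, spec)
            kwargs = {"start_codon": start_codon, "stop_codon": stop_codon}
        else:
            seq = _iid_bases(rng, L, probs)
            base = tok[:-2] if tok.endswith("_2") else tok
            if cls == "tRNA" and base in DEFAULT_ANTICODONS:
                kwargs = {"anticodon": DEFAULT_ANTICODONS[base]}
        features.append(Feature(tok, pos, pos + L - 1, "+", cls, **kwargs))
        chunks.append(seq)
        if gap:
            chunks.append(_iid_bases(rng, int(gap), probs))
        pos += L + int(gap)

    return AnnotatedGenome(
        genome_id=f"sim_{spec.architecture if isinstance(spec.architecture, str) else 'custom'}"
                  f"_seed{spec.seed}",
        length=genome_length, circular=True,
        sequence="".join(chunks), features=features)


def rotate_genome(g: AnnotatedGenome, offset: int) -> AnnotatedGenome:
    """Rotate the circular origin by ``offset`` bp (features may wrap)."""
    if g.sequence is None:
        raise ValueError("rotation requires a sequence")
    offset %= g.length
    seq = g.sequence[offset:] + g.sequence[:offset]

    def shift(p):
        return (p - 1 - offset) % g.length + 1

    feats = [replace(f, start=shift(f.start), end=shift(f.end))
             for f in g.features]
    return AnnotatedGenome(g.genome_id, g.length, g.circular, seq, feats)


# ------------------------------------------------------------------- clades

@dataclass(frozen=True)
class CladeSpec:
    """A root genome evolved along a tree.

    ``tree`` is a :class:`PhyloTree` (or Newick string) whose branch lengths
    are expected substitutions per site.
    """

    tree: PhyloTree | str
    root: SimSpec = field(default_factory=SimSpec)
    seed: int = 0


def jc_substitution_probability(branch_length: float) -> float:
    """Expected fraction of sites differing after a Jukes-Cantor branch:
    3/4 * (1 - exp(-4b/3))."""
    return 0.75 * (1.0 - math.exp(-4.0 * branch_length / 3.0))


def evolve_sequence_jc(seq: str, branch_length: float,
                       rng: np.random.Generator):
    """One JC branch: each site substitutes with probability
    3/4(1-exp(-4b/3)), uniformly to one of the other three bases.
    Returns (sequence, realized substitution count)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    p = jc_substitution_probability(branch_length)
    hit = np.nonzero(rng.random(arr.size) < p)[0]
    if hit.size:
        codes = np.frombuffer(b"ACGT", dtype=np.uint8)
        cur = arr[hit]
        # choose uniformly among the three other bases
        idx = np.searchsorted(codes, cur)
        shift = rng.integers(1, 4, size=hit.size)
        arr[hit] = codes[(idx + shift) % 4]
    return arr.tobytes().decode(), int(hit.size)


def simulate_clade(c: CladeSpec):
    """Evolve a simulated root genome along a tree.

    Returns ``(genomes, truth)``: leaf name -> :class:`AnnotatedGenome`
    (annotations preserved from the root), and a ground-truth dict with the
    root genome and the realized substitution count per branch.
    """
    tree = parse_tree(c.tree)
    root_genome = simulate_mitogenome(c.root)
    genomes: dict[str, AnnotatedGenome] = {}
    truth = {"root": root_genome, "substitutions": {}}
    counter = [0]

    def walk(node: TreeNode, seq: str):
        if node.is_leaf():
            genomes[node.name] = AnnotatedGenome(
                node.name, root_genome.length, True, seq,
                list(root_genome.features))
            return
        for child, bl in node.children:
            counter[0] += 1
            rng = np.random.default_rng([c.seed & 0x7FFFFFFF, counter[0]])
            child_seq, nsub = evolve_sequence_jc(seq, bl, rng)
            key = child.name or f"node{counter[0]}"
            truth["substitutions"][key] = nsub
            walk(child, child_seq)

    walk(tree.root, root_genome.sequence)
    return genomes, truth


def parse_tree(tree: PhyloTree | str) -> PhyloTree:
    if isinstance(tree, PhyloTree):
        return tree
    from .phylo import parse_newick
    return parse_newick(tree)


# ------------------------------------------------------------------- tRNAs

_PAIRINGS = {"A": "T", "T": "A", "G": "C", "C": "G"}


def simulate_trna(arm_pairs=(7, 4, 5, 5), loop_sizes=(6, 7, 5),
                  variable_len: int = 3, anticodon: str | None = None,
                  seed: int = 0):
    """Build a cloverleaf (sequence, dot-bracket) with exact stem sizes.

    ``arm_pairs`` = (acceptor, DHU, anticodon, TΨC) stem pair counts;
    ``loop_sizes`` = (DHU, anticodon, TΨC) loop lengths.  Stems are perfectly
    Watson-Crick paired.  A DHU count of 1 reproduces the short-DHU anomaly
    of some mitochondrial serine tRNAs; 0 omits the arm entirely.
    """
    acc, dhu, ac, tps = arm_pairs
    dl, al, tl = loop_sizes
    if min(acc, dhu, ac, tps) < 0 or min(dl, al, tl) < 1 or variable_len < 0:
        raise ValueError("infeasible cloverleaf geometry")
    if anticodon is not None:
        if len(anticodon) != 3:
            raise ValueError("anticodon must be 3 nt")
        if al < 5:
            raise ValueError("anticodon loop must be >= 5 nt to hold an anticodon")
        if al % 2 == 0:
            raise ValueError("anticodon loop must have odd length to center "
                             "the anticodon")

    def hairpin(npairs, loop):
        if npairs == 0:
            return ""
        return "(" * npairs + "." * loop + ")" * npairs

    db = ("(" * acc + "."
          + hairpin(dhu, dl) + "."
          + hairpin(ac, al)
          + "." * variable_len
          + hairpin(tps, tl) + "."
          + ")" * acc + ".")

    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    at_rich = np.array([0.37, 0.13, 0.13, 0.37])  # A C G T
    seq = list(_iid_bases(rng, len(db), at_rich))
    # enforce Watson-Crick stems
    stack: list[int] = []
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            seq[i] = _PAIRINGS[seq[j]]
    if anticodon is not None and ac > 0:
        # 0-based start of the anticodon hairpin, then the loop center
        start = acc + 1 + (2 * dhu + dl if dhu else 0) + 1
        loop_start = start + ac
        mid = loop_start + al // 2
        seq[mid - 1:mid + 2] = list(anticodon)
    return "".join(seq), db
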