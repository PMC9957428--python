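"""Distance phylogenetics on concatenated protein-coding genes.

The stage mirrors the classic mitogenome workflow: per-gene alignments are
concatenated into a supermatrix, ambiguously aligned columns are removed by
a conserved-block filter (a simplified analogue of the usual block-trimming
tools, not compatible with any of them), pairwise p-distances are computed
with pairwise deletion, and an unrooted tree is built by Saitou–Nei
neighbor joining.  NJ recovers the true tree exactly whenever the distance
matrix is additive.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

GAP_CHARS = frozenset("-N?")


@dataclass
class Alignment:
    """taxon -> aligned sequence, all the same length."""

    sequences: dict

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")

    @property
    def taxa(self) -> list:
        return list(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def __getitem__(self, taxon: str) -> str:
        return self.sequences[taxon]


def concatenate_genes(per_gene: dict, gene_list=None):
    """Column-wise concatenation of per-gene alignments sharing a taxon set.

    Returns ``(supermatrix, partitions)`` where partitions is a list of
    ``(gene, start, end)`` 1-based inclusive column ranges.
    """
    genes = list(gene_list) if gene_list is not None else list(per_gene)
    if not genes:
        raise ValueError("no genes to concatenate")
    taxa = list(per_gene[genes[0]].taxa)
    taxon_set = set(taxa)
    for g in genes:
        missing = taxon_set - set(per_gene[g].taxa)
        extra = set(per_gene[g].taxa) - taxon_set
        if missing or extra:
            raise ValueError(
                f"gene {g}: taxon set mismatch (missing {sorted(missing)}, "
                f"extra {sorted(extra)})")
    parts = []
    col = 1
    seqs = {t: [] for t in taxa}
    for g in genes:
        aln = per_gene[g]
        n = aln.n_columns
        parts.append((g, col, col + n - 1))
        col += n
        for t in taxa:
            seqs[t].append(aln[t])
    return Alignment({t: "".join(chunks) for t, chunks in seqs.items()}), parts


def trim_blocks(a: Alignment, max_gap_frac: float = 0.2,
                min_conserved_frac: float = 0.5,
                min_block_len: int = 10) -> Alignment:
    """Conserved-block column filter.

    A column survives when its gap fraction is at most ``max_gap_frac`` and
    its majority residue (gaps excluded) reaches ``min_conserved_frac`` of
    the taxa; surviving columns are then kept only in runs of at least
    ``min_block_len``.  Never increases the column count and is idempotent.
    """
    taxa = a.taxa
    if not taxa:
        return a
    mat = np.array([list(a[t]) for t in taxa])
    ntax, ncol = mat.shape
    if ncol == 0:
        return a
    is_gap = np.isin(mat, list(GAP_CHARS))
    gap_frac = is_gap.mean(axis=0)
    keep = gap_frac <= max_gap_frac
    for j in np.nonzero(keep)[0]:
        col = mat[~is_gap[:, j], j]
        _, counts = np.unique(col, return_counts=True)
        if counts.size == 0 or counts.max() / ntax < min_conserved_frac:
            keep[j] = False
    # enforce minimum run length
    kept_cols = []
    run = []
    for j in range(ncol):
        if keep[j]:
            run.append(j)
        else:
            if len(run) >= min_block_len:
                kept_cols.extend(run)
            run = []
    if len(run) >= min_block_len:
        kept_cols.extend(run)
    if not kept_cols:
        import warnings
        warnings.warn("block trimming removed every column", stacklevel=2)
    return Alignment({t: "".join(a[t][j] for j in kept_cols) for t in taxa})


@dataclass
class DistanceMatrix:
    taxa: list
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.matrix, self.matrix.T, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.taxa.index(a), self.taxa.index(b)])


def p_distance_matrix(a: Alignment) -> DistanceMatrix:
    """Pairwise p-distance with pairwise deletion.

    Sites where either sequence has a gap or N are ignored for that pair;
    d = mismatches / compared sites.  A pair with no comparable sites gets
    NaN (undefined distance).
    """
    taxa = a.taxa
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    mat = np.array([np.frombuffer(a[t].encode(), dtype=np.uint8) for t in taxa])
    gap_codes = np.array([ord(c) for c in GAP_CHARS], dtype=np.uint8)
    valid = ~np.isin(mat, gap_codes)
    n = len(taxa)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        both = valid[i] & valid[j]
        m = int(both.sum())
        if m == 0:
            d[i, j] = d[j, i] = float("nan")
        else:
            mism = int((mat[i][both] != mat[j][both]).sum())
            d[i, j] = d[j, i] = mism / m
    return DistanceMatrix(taxa, d)


# ------------------------------------------------------------------ NJ trees

@dataclass
class TreeNode:
    name: str | None = None
    children: list = field(default_factory=list)  # (child, branch_length)

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary internal root."""

    root: TreeNode

    def leaf_names(self) -> list:
        out = []

        def walk(n):
            if n.is_leaf():
                out.append(n.name)
            for c, _ in n.children:
                walk(c)

        walk(self.root)
        return sorted(out)

    def to_newick(self, digits: int = 6) -> str:
        def fmt(x):
            return f"{x:.{digits}g}"

        def walk(n):
            if n.is_leaf():
                return n.name
            inner = ",".join(f"{walk(c)}:{fmt(bl)}" for c, bl in n.children)
            return f"({inner})"

        return walk(self.root) + ";"

    def bipartitions(self) -> set:
        """Non-trivial splits as frozensets of the smaller-side-with-anchor
        convention: each split is the frozenset of leaves on the side NOT
        containing the alphabetically first leaf."""
        leaves = set(self.leaf_names())
        anchor = min(leaves)
        splits = set()

        def walk(n):
            if n.is_leaf():
                return {n.name}
            below = set()
            for c, _ in n.children:
                below |= walk(c)
            if 1 < len(below) < len(leaves) - 1:
                side = below if anchor not in below else leaves - below
                splits.add(frozenset(side))
            return below

        walk(self.root)
        return splits


def nj_tree(d: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with the standard Q criterion.

    Ties in Q are broken by the lexicographically smallest taxon pair, so the
    result is deterministic.  Negative branch lengths are clamped to 0.
    """
    n = len(d.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if np.isnan(d.matrix).any():
        raise ValueError("distance matrix contains undefined entries")
    nodes = {t: TreeNode(name=t) for t in d.taxa}
    labels = list(d.taxa)
    D = {a: {b: d.get(a, b) for b in labels} for a in labels}

    def clamp(x):
        return max(0.0, x)

    next_id = 0
    while len(labels) > 3:
        r = len(labels)
        tot = {a: sum(D[a][b] for b in labels if b != a) for a in labels}
        best = None
        for a, b in itertools.combinations(sorted(labels), 2):
            q = (r - 2) * D[a][b] - tot[a] - tot[b]
            key = (q, a, b)
            if best is None or key < best:
                best = key
        _, f, g = best
        dfg = D[f][g]
        bl_f = clamp(0.5 * dfg + (tot[f] - tot[g]) / (2 * (r - 2)))
        bl_g = clamp(dfg - (0.5 * dfg + (tot[f] - tot[g]) / (2 * (r - 2))))
        new = f"_nj{next_id}"
        next_id += 1
        node = TreeNode()
        node.children = [(nodes[f], bl_f), (nodes[g], bl_g)]
        nodes[new] = node
        D[new] = {}
        for k in labels:
            if k in (f, g):
                continue
            dk = 0.5 * (D[f][k] + D[g][k] - dfg)
            D[new][k] = D[k][new] = dk
        labels = [k for k in labels if k not in (f, g)] + [new]
        for k in (f, g):
            del D[k]
            for row in D.values():
                row.pop(k, None)

    a, b, c = sorted(labels, key=lambda l: (l.startswith("_nj"), l))
    la = clamp(0.5 * (D[a][b] + D[a][c] - D[b][c]))
    lb = clamp(0.5 * (D[a][b] + D[b][c] - D[a][c]))
    lc = clamp(0.5 * (D[a][c] + D[b][c] - D[a][b]))
    root = TreeNode()
    root.children = [(nodes[a], la), (nodes[b], lb), (nodes[c], lc)]
    return PhyloTree(root)


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Number of non-trivial bipartitions present in exactly one tree."""
    if t1.leaf_names() != t2.leaf_names():
        raise ValueError("trees have different leaf sets")
    return len(t1.bipartitions() ^ t2.bipartitions())


def parse_newick(s: str) -> PhyloTree:
    """Minimal Newick reader (names, branch lengths, nesting)."""
    s = s.strip()
    if s.endswith(";"):
        s = s[:-1]
    pos = 0

    def parse_node():
        nonlocal pos
        node = TreeNode()
        if s[pos] == "(":
            pos += 1
            while True:
                child, bl = parse_branch()
                node.children.append((child, bl))
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos]
        if label and node.is_leaf():
            node.name = label
        return node

    def parse_branch():
        nonlocal pos
        node = parse_node()
        bl = 0.0
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",();":
                pos += 1
            bl = float(s[start:pos])
        return node, bl

    return PhyloTree(parse_node())
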