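"""Concatenation, block trimming, p-distances, NJ, and RF distance."""

import random

import numpy as np
import pytest

import dendropy

from mitocomp import (Alignment, DistanceMatrix, concatenate_genes,
                      evolve_sequence_jc, jc_substitution_probability,
                      nj_tree, p_distance_matrix, parse_newick,
                      robinson_foulds, trim_blocks)


def rf_dendropy(nwk1, nwk2):
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=nwk1, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=nwk2, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(t1, t2)


class TestConcatenate:
    def test_two_single_column_genes(self):
        a = Alignment({"x": "A", "y": "C"})
        b = Alignment({"x": "G", "y": "T"})
        sm, parts = concatenate_genes({"g1": a, "g2": b}, ["g1", "g2"])
        assert sm["x"] == "AG" and sm["y"] == "CT"
        assert parts == [("g1", 1, 1), ("g2", 1 + 1, 2)]

    def test_single_gene_identity(self):
        a = Alignment({"x": "ACGT", "y": "ACGA"})
        sm, parts = concatenate_genes({"g": a})
        assert sm.sequences == a.sequences and parts == [("g", 1, 4)]

    def test_total_columns_from_printed_gene_lengths(self):
        """13 genes at the printed protein-coding lengths, truncated to
        codon multiples, concatenate to the expected supermatrix width."""
        from mitocomp.simulate import DEFAULT_GENE_LENGTHS
        pcg_lengths = {g: DEFAULT_GENE_LENGTHS[g] for g in (
            "cox1", "cox2", "cox3", "cob", "atp6", "atp8",
            "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6")}
        rng = np.random.default_rng(0)
        per_gene = {}
        for g, L in pcg_lengths.items():
            n = L // 3 * 3
            per_gene[g] = Alignment({
                t: "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
                for t in ("t1", "t2")})
        sm, _ = concatenate_genes(per_gene)
        assert sm.n_columns == sum(L // 3 * 3 for L in pcg_lengths.values())

    def test_taxon_mismatch_is_error(self):
        a = Alignment({"x": "A", "y": "C"})
        b = Alignment({"x": "G"})
        with pytest.raises(ValueError, match="taxon"):
            concatenate_genes({"g1": a, "g2": b})

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            Alignment({"x": "AC", "y": "A"})


class TestTrimBlocks:
    def test_identical_gapless_untouched(self):
        a = Alignment({"x": "ACGT" * 10, "y": "ACGT" * 10})
        out = trim_blocks(a, min_block_len=1)
        assert out.sequences == a.sequences

    def test_all_gap_column_removed(self):
        a = Alignment({"x": "A" * 20 + "-" + "A" * 20,
                       "y": "A" * 20 + "-" + "A" * 20})
        out = trim_blocks(a, min_block_len=1)
        assert out.n_columns == 40

    def test_matches_independent_column_filter(self):
        """Surviving columns equal a two-pass per-column reimplementation."""
        rng = random.Random(8)
        taxa = [f"t{i}" for i in range(6)]
        cols = []
        for _ in range(400):
            col = [rng.choice("ACGT-") for _ in taxa]
            cols.append(col)
        a = Alignment({t: "".join(c[i] for c in cols)
                       for i, t in enumerate(taxa)})
        max_gap, min_cons, min_block = 0.2, 0.5, 10

        keep = []
        for c in cols:
            gaps = sum(x in "-N?" for x in c)
            if gaps / len(c) > max_gap:
                keep.append(False)
                continue
            residues = [x for x in c if x not in "-N?"]
            best = max((residues.count(b) for b in set(residues)), default=0)
            keep.append(best / len(c) >= min_cons)
        expected_cols = []
        i = 0
        while i < len(keep):
            if keep[i]:
                j = i
                while j < len(keep) and keep[j]:
                    j += 1
                if j - i >= min_block:
                    expected_cols.extend(range(i, j))
                i = j
            else:
                i += 1

        out = trim_blocks(a, max_gap, min_cons, min_block)
        expected = {t: "".join(a[t][j] for j in expected_cols) for t in taxa}
        assert out.sequences == expected

    def test_idempotent_and_never_grows(self):
        rng = random.Random(9)
        taxa = ["a", "b", "c", "d"]
        a = Alignment({t: "".join(rng.choice("ACGT-") for _ in range(300))
                       for t in taxa})
        once = trim_blocks(a)
        twice = trim_blocks(once)
        assert once.n_columns <= a.n_columns
        assert twice.sequences == once.sequences


class TestPDistance:
    def test_identical_zero(self):
        a = Alignment({"x": "ACGT", "y": "ACGT"})
        assert p_distance_matrix(a).get("x", "y") == 0

    def test_closed_form_quarter(self):
        a = Alignment({"x": "AAAA", "y": "AAAT"})
        assert p_distance_matrix(a).get("x", "y") == 0.25

    def test_pairwise_deletion(self):
        a = Alignment({"x": "AC-T", "y": "ANGT"})
        # comparable sites: positions 1 and 4 only; one of them... both match
        assert p_distance_matrix(a).get("x", "y") == 0.0

    def test_no_comparable_sites_is_nan(self):
        a = Alignment({"x": "--", "y": "AA"})
        assert np.isnan(p_distance_matrix(a).get("x", "y"))

    def test_binomial_recovery_of_true_proportion(self):
        rng = np.random.default_rng(21)
        n = 10_000
        root = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
        p = 0.1
        # substitute exactly with probability p per site
        other = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
        mut = [rng.choice(other[b]) if rng.random() < p else b for b in root]
        a = Alignment({"x": root, "y": "".join(mut)})
        d = p_distance_matrix(a).get("x", "y")
        assert abs(d - p) < 0.01  # ~3 sigma at this length


class TestNJ:
    def test_additive_four_taxon_exact(self):
        # tree ((A:2,B:3):1,C:4,D:5) -> additive distances
        dist = {("A", "B"): 5, ("A", "C"): 7, ("A", "D"): 8,
                ("B", "C"): 8, ("B", "D"): 9, ("C", "D"): 9}
        taxa = ["A", "B", "C", "D"]
        m = np.zeros((4, 4))
        for (a, b), v in dist.items():
            i, j = taxa.index(a), taxa.index(b)
            m[i, j] = m[j, i] = v
        tree = nj_tree(DistanceMatrix(taxa, m))
        # topology: AB | CD
        assert tree.bipartitions() == {frozenset({"C", "D"})} or \
            tree.bipartitions() == {frozenset({"B", "A"})}
        # branch lengths reproduce the additive matrix exactly
        nwk = tree.to_newick()
        tns = dendropy.TaxonNamespace()
        dt = dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=tns)
        pdm = dt.phylogenetic_distance_matrix()
        for (a, b), v in dist.items():
            ta = tns.get_taxon(a)
            tb = tns.get_taxon(b)
            assert pdm.distance(ta, tb) == pytest.approx(v)

    def test_three_taxa_closed_form(self):
        m = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], m))
        lengths = {c.name: bl for c, bl in tree.root.children}
        assert lengths["a"] == pytest.approx(0.5 * (4 + 6 - 8))
        assert lengths["b"] == pytest.approx(0.5 * (4 + 8 - 6))
        assert lengths["c"] == pytest.approx(0.5 * (6 + 8 - 4))

    def test_matches_dendropy_on_random_additive_matrices(self):
        """Topology agrees with dendropy's independent NJ on additive
        matrices from random trees."""
        rng = random.Random(5)
        for _ in range(5):
            taxa = [f"t{i}" for i in range(8)]
            nwk = _random_tree_newick(rng, taxa)
            tns = dendropy.TaxonNamespace()
            src = dendropy.Tree.get(data=nwk, schema="newick",
                                    taxon_namespace=tns)
            pdm = src.phylogenetic_distance_matrix()
            m = np.zeros((8, 8))
            for i, a in enumerate(taxa):
                for j, b in enumerate(taxa):
                    if i != j:
                        m[i, j] = pdm.distance(tns.get_taxon(a),
                                               tns.get_taxon(b))
            ours = nj_tree(DistanceMatrix(taxa, m))
            assert rf_dendropy(ours.to_newick(), nwk) == 0

    def test_negative_branch_clamped(self):
        m = np.array([[0, 1, 10, 10], [1, 0, 10, 10],
                      [10, 10, 0, 0.1], [10, 10, 0.1, 0]])
        tree = nj_tree(DistanceMatrix(list("abcd"), m))
        def walk(n):
            for c, bl in n.children:
                assert bl >= 0
                walk(c)
        walk(tree.root)

    def test_asymmetric_rejected(self):
        m = np.array([[0, 1.0, 2], [1.1, 0, 3], [2, 3, 0]])
        with pytest.raises(ValueError):
            DistanceMatrix(list("abc"), m)


def _random_tree_newick(rng, taxa):
    nodes = [f"{t}:{rng.uniform(0.05, 0.3):.3f}" for t in taxa]
    while len(nodes) > 3:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        nodes.append(f"({a},{b}):{rng.uniform(0.05, 0.3):.3f}")
    return "(" + ",".join(n.rsplit(':', 0)[0] for n in nodes) + ");"


class TestRobinsonFoulds:
    def test_identical_zero(self):
        t = parse_newick("((a:1,b:1):1,(c:1,d:1):1,e:1);")
        assert robinson_foulds(t, t) == 0

    def test_distinct_quartets(self):
        t1 = parse_newick("((a:1,b:1):1,c:1,d:1);")
        t2 = parse_newick("((a:1,c:1):1,b:1,d:1);")
        assert robinson_foulds(t1, t2) == 2

    def test_leaf_mismatch_rejected(self):
        t1 = parse_newick("(a:1,b:1,c:1);")
        t2 = parse_newick("(a:1,b:1,d:1);")
        with pytest.raises(ValueError):
            robinson_foulds(t1, t2)

    def test_matches_bruteforce_bipartitions(self):
        """RF equals the symmetric difference of explicitly enumerated
        bipartition sets on random small trees (checked via dendropy too)."""
        rng = random.Random(31)
        taxa = [f"t{i}" for i in range(7)]
        for _ in range(10):
            n1 = _random_tree_newick(rng, taxa)
            n2 = _random_tree_newick(rng, taxa)
            ours = robinson_foulds(parse_newick(n1), parse_newick(n2))
            assert ours == rf_dendropy(n1, n2)


class TestJCRecovery:
    def test_jc_expected_difference(self):
        rng = np.random.default_rng(3)
        n = 10_000
        root = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
        b = 0.1
        child, nsub = evolve_sequence_jc(root, b, rng)
        observed = sum(a != c for a, c in zip(root, child)) / n
        expected = jc_substitution_probability(b)
        sigma = (expected * (1 - expected) / n) ** 0.5
        assert abs(observed - expected) < 3 * sigma + 1e-9

    def test_eight_leaf_topology_recovered(self):
        """NJ on p-distances from JC-evolved sequences recovers the
        generating 8-leaf topology (RF = 0) at 50 kb."""
        nwk = ("(((a:0.05,b:0.05):0.05,(c:0.05,d:0.05):0.05):0.05,"
               "((e:0.05,f:0.05):0.05,g:0.05):0.05,h:0.1);")
        tree = parse_newick(nwk)
        rng = np.random.default_rng(13)
        n = 50_000
        root = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
        leaves = {}

        def walk(node, seq):
            if node.is_leaf():
                leaves[node.name] = seq
                return
            for child, bl in node.children:
                s2, _ = evolve_sequence_jc(seq, bl, rng)
                walk(child, s2)

        walk(tree.root, root)
        est = nj_tree(p_distance_matrix(Alignment(leaves)))
        assert robinson_foulds(est, tree) == 0
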