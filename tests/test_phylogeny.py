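"""Progressive alignment, supermatrix concatenation, NJ, bootstrap."""

import numpy as np
import pytest

from ploidtrace.phylogeny import (
    MultipleAlignment,
    bootstrap_support,
    concatenate,
    distance_matrix,
    nj_tree,
    progressive_align,
)


def nw_oracle(a, b, match=5, mismatch=-4, gap_open=-10, gap_extend=-1):
    """Independent global affine-gap DP score (nucleotide scoring)."""
    na, nb = len(a), len(b)
    NEG = -1e30
    M = np.full((na + 1, nb + 1), NEG)
    X = np.full((na + 1, nb + 1), NEG)
    Y = np.full((na + 1, nb + 1), NEG)
    M[0, 0] = 0
    for i in range(1, na + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, nb + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    return max(M[na, nb], X[na, nb], Y[na, nb])


def score_alignment(rows, match=5, mismatch=-4, gap_open=-10, gap_extend=-1):
    """Score a pairwise alignment with affine gaps (for oracle comparison)."""
    a, b = rows
    total, in_gap_a, in_gap_b = 0.0, False, False
    for x, y in zip(a, b):
        if x == "-" and y == "-":
            continue
        if x == "-":
            total += gap_extend if in_gap_a else gap_open
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            total += gap_extend if in_gap_b else gap_open
            in_gap_b, in_gap_a = True, False
        else:
            total += match if x == y else mismatch
            in_gap_a = in_gap_b = False
    return total


class TestProgressiveAlign:
    def test_identical_sequences_gapless(self):
        seqs = {"x": "ACGTACGT", "y": "ACGTACGT", "z": "ACGTACGT"}
        msa = progressive_align(seqs, alphabet="nucleotide")
        assert all(r == "ACGTACGT" for r in msa.rows)

    def test_two_sequence_score_matches_global_dp(self):
        a, b = "ACGTTACGATTT", "ACGACGATT"
        msa = progressive_align({"a": a, "b": b}, alphabet="nucleotide")
        got = score_alignment([msa.row("a"), msa.row("b")])
        assert got == nw_oracle(a, b)

    def test_alignment_at_least_longest_input(self):
        seqs = {"a": "ACGTACGTAA", "b": "ACGCGTAA", "c": "ACGTAA"}
        msa = progressive_align(seqs, alphabet="nucleotide")
        assert msa.n_columns >= 10
        for t, s in seqs.items():
            assert msa.row(t).replace("-", "") == s

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            progressive_align({})


class TestConcatenate:
    def aln(self, ids, width, ch="A"):
        return MultipleAlignment(ids=list(ids), rows=[ch * width] * len(ids),
                                 alphabet="nucleotide")

    def test_width_additivity(self):
        sm, parts = concatenate(
            [("f1", self.aln("AB", 10)), ("f2", self.aln("AB", 20)),
             ("f3", self.aln("AB", 30))],
            ["A", "B"],
        )
        assert sm.n_columns == 60
        assert parts == [("f1", 0, 10), ("f2", 10, 30), ("f3", 30, 60)]

    def test_missing_taxon_gap_fill(self):
        sm, _ = concatenate(
            [("f1", self.aln("AB", 10)), ("f2", self.aln("A", 5))], ["A", "B"]
        )
        assert sm.row("B") == "A" * 10 + "-" * 5

    def test_unknown_taxon_rejected(self):
        with pytest.raises(ValueError, match="not in supermatrix"):
            concatenate([("f1", self.aln("AC", 10))], ["A", "B"])


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        msa = MultipleAlignment(ids=["a", "b"], rows=["ACGT", "ACGT"])
        _, D = distance_matrix(msa)
        assert D[0, 1] == 0

    def test_jc_closed_form(self):
        # 10% mismatches over 100 comparable columns
        a = "A" * 100
        b = "C" * 10 + "A" * 90
        _, D = distance_matrix(
            MultipleAlignment(ids=["a", "b"], rows=[a, b]), model="jukes_cantor"
        )
        assert D[0, 1] == pytest.approx(0.10733, abs=1e-5)

    def test_pairwise_deletion(self):
        msa = MultipleAlignment(ids=["a", "b"], rows=["AC-T", "ACG-"])
        _, D = distance_matrix(msa)
        assert D[0, 1] == 0  # only the first two columns are comparable

    def test_no_comparable_columns_rejected(self):
        msa = MultipleAlignment(ids=["a", "b"], rows=["A-", "-A"])
        with pytest.raises(ValueError, match="comparable"):
            distance_matrix(msa)


def additive_matrix(tree_dists, taxa):
    n = len(taxa)
    D = np.zeros((n, n))
    for (a, b), d in tree_dists.items():
        i, j = taxa.index(a), taxa.index(b)
        D[i, j] = D[j, i] = d
    return D


class TestNJ:
    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) with internal edge 1
        taxa = ["A", "B", "C", "D"]
        dists = {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
                 ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7}
        tree = nj_tree(taxa, additive_matrix(dists, taxa))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        # every pairwise path length is reproduced
        plens = path_lengths(tree)
        for (a, b), d in dists.items():
            assert plens[frozenset((a, b))] == pytest.approx(d, abs=1e-9)

    def test_three_taxon_closed_form(self):
        taxa = ["A", "B", "C"]
        D = additive_matrix({("A", "B"): 3, ("A", "C"): 4, ("B", "C"): 5}, taxa)
        tree = nj_tree(taxa, D)
        plens = path_lengths(tree)
        assert plens[frozenset(("A", "B"))] == pytest.approx(3, abs=1e-9)
        assert plens[frozenset(("A", "C"))] == pytest.approx(4, abs=1e-9)
        assert plens[frozenset(("B", "C"))] == pytest.approx(5, abs=1e-9)

    def test_five_taxon_matches_reference_nj(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(0)
        # random additive tree: caterpillar ((((A,B),C),D),E)
        taxa = ["A", "B", "C", "D", "E"]
        # leaf depths along a caterpillar with all edges length 1..
        dists = {("A", "B"): 2, ("A", "C"): 4, ("A", "D"): 6, ("A", "E"): 7,
                 ("B", "C"): 4, ("B", "D"): 6, ("B", "E"): 7,
                 ("C", "D"): 4, ("C", "E"): 5, ("D", "E"): 3}
        D = additive_matrix(dists, taxa)
        mine = nj_tree(taxa, D)
        ref = skbio_nj(DistanceMatrix(D, taxa))
        ref_bps = set()
        for node in ref.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(taxa) - 1:
                if "A" in side:
                    side = frozenset(taxa) - side
                ref_bps.add(side)
        assert mine.bipartitions() == ref_bps
        plens = path_lengths(mine)
        for (a, b), d in dists.items():
            assert plens[frozenset((a, b))] == pytest.approx(d, abs=1e-9)

    def test_star_tie_is_deterministic(self):
        taxa = ["A", "B", "C", "D"]
        D = np.full((4, 4), 2.0)
        np.fill_diagonal(D, 0)
        t1 = nj_tree(taxa, D)
        t2 = nj_tree(taxa, D)
        assert t1.newick() == t2.newick()

    def test_asymmetric_rejected(self):
        D = np.array([[0, 1, 2], [1, 0, 3], [2, 3.5, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(["A", "B", "C"], D)


def path_lengths(tree):
    """Leaf-to-leaf path lengths from the PhyloTree structure."""
    out = {}

    def walk(node, acc):
        if node.is_leaf:
            return [(node.name, acc)]
        below = []
        for child, blen in node.children:
            below.extend(walk(child, acc + blen))
        return below

    # collect distances through every node treated as a junction
    def rec(node):
        lists = []
        for child, blen in node.children:
            lists.append(walk(child, blen))
        for i in range(len(lists)):
            for j in range(i + 1, len(lists)):
                for a, da in lists[i]:
                    for b, db in lists[j]:
                        out[frozenset((a, b))] = da + db
        for child, _ in node.children:
            rec(child)

    rec(tree.root)
    return out


def collect_supports(tree):
    out = []

    def rec(node):
        if node.support is not None:
            out.append(node.support)
        for child, _ in node.children:
            rec(child)

    rec(tree.root)
    return out


class TestBootstrap:
    def strong_alignment(self, n_cols=1000, seed=5):
        rng = np.random.default_rng(seed)
        base = rng.choice(list("ACGT"), size=n_cols)
        clade2 = base.copy()
        flip = rng.random(n_cols) < 0.2  # 20% divergence between clades
        repl = rng.choice(list("ACGT"), size=n_cols)
        clade2[flip] = repl[flip]
        def jitter(row, s):
            r2 = row.copy()
            f = np.random.default_rng(s).random(n_cols) < 0.01
            r2[f] = np.random.default_rng(s + 50).choice(list("ACGT"), size=n_cols)[f]
            return "".join(r2)
        return MultipleAlignment(
            ids=["a1", "a2", "b1", "b2"],
            rows=[jitter(base, 1), jitter(base, 2), jitter(clade2, 3), jitter(clade2, 4)],
            alphabet="nucleotide",
        )

    def test_reproducible_under_seed(self):
        msa = self.strong_alignment()
        t1 = bootstrap_support(msa, n_reps=50, seed=42)
        t2 = bootstrap_support(msa, n_reps=50, seed=42)
        assert t1.newick(with_support=True) == t2.newick(with_support=True)

    def test_supports_in_range_and_strong_signal(self):
        msa = self.strong_alignment()
        tree = bootstrap_support(msa, n_reps=100, seed=7)
        supports = collect_supports(tree)
        assert supports, "expected at least one internal edge"
        assert all(0 <= s <= 100 for s in supports)
        assert max(supports) >= 99  # the clade split is unambiguous

    def test_cultivar_monophyly_on_synthetic_families(self):
        """Cultivars of each species group together in the NJ tree."""
        from ploidtrace.synthetic_data import FixtureConfig, generate_fixture
        from ploidtrace.phylogeny import concatenate, nj_tree, distance_matrix

        cfg = FixtureConfig(
            n_shared_single_copy=10, n_shared_multi_copy=0, n_species_specific=0,
            n_paralog_pairs=0, gene_length=150, seed=21, n_cultivars=2,
        )
        man = generate_fixture(cfg)
        fams = sorted(next(iter(man.cultivars.values())))
        taxa = sorted(man.cultivars)
        alns = []
        for fam in fams:
            rows = {t: man.cultivars[t][fam] for t in taxa}
            alns.append((fam, MultipleAlignment(
                ids=taxa, rows=[rows[t] for t in taxa], alphabet="nucleotide")))
        sm, _ = concatenate(alns, taxa)
        labels, D = distance_matrix(sm)
        tree = nj_tree(labels, D)
        bps = tree.bipartitions()
        for sp in ("T1", "T2", "T3"):
            clade = frozenset(t for t in taxa if t.startswith(sp))
            comp = frozenset(taxa) - clade
            assert clade in bps or comp in bps, f"{sp} cultivars not monophyletic"
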