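"""Distance-based phylogenetics: progressive MSA, NJ, bootstrap.

The tree-building stage mirrors a classical single-copy-ortholog workflow:
each family is aligned (guide-tree progressive profile alignment with
affine gaps), alignments are concatenated into a supermatrix with gap fill
for missing taxa, pairwise distances are computed under p-distance or
Jukes–Cantor with pairwise deletion, and an unrooted tree is built with the
Saitou–Nei neighbor-joining criterion. Branch lengths are in substitutions
per site; internal-edge support comes from nonparametric bootstrap over
alignment columns (default 1000 replicates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "MultipleAlignment",
    "PhyloNode",
    "PhyloTree",
    "progressive_align",
    "concatenate",
    "distance_matrix",
    "nj_tree",
    "bootstrap_support",
]


@dataclass
class MultipleAlignment:
    """Equal-length gapped sequences over a shared alphabet."""

    ids: list[str]
    rows: list[str]
    alphabet: str = "protein"  # or "nucleotide"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids / rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate taxon id in alignment")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.ids.index(taxon)]


@dataclass
class PhyloNode:
    name: str | None = None
    children: list[tuple["PhyloNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary internal root."""

    root: PhyloNode

    def leaves(self) -> list[str]:
        out = []

        def rec(node: PhyloNode) -> None:
            if node.is_leaf:
                out.append(node.name)
            for child, _ in node.children:
                rec(child)

        rec(self.root)
        return sorted(out)

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the leaf side not containing
        the lexicographically smallest taxon."""
        all_leaves = set(self.leaves())
        ref = min(all_leaves)
        parts: set[frozenset[str]] = set()

        def rec(node: PhyloNode) -> set[str]:
            if node.is_leaf:
                return {node.name}
            below: set[str] = set()
            for child, _ in node.children:
                below |= rec(child)
            if 1 < len(below) < len(all_leaves) - 1:
                side = below if ref not in below else all_leaves - below
                parts.add(frozenset(side))
            return below

        rec(self.root)
        return parts

    def newick(self, with_support: bool = False) -> str:
        def rec(node: PhyloNode) -> str:
            if node.is_leaf:
                return node.name
            inner = ",".join(
                f"{rec(child)}:{blen:.10g}" for child, blen in node.children
            )
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}"

        return rec(self.root) + ";"


# ---------------------------------------------------------------------------
# progressive alignment

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _char_score(a: str, b: str, alphabet: str) -> float:
    if a == "-" and b == "-":
        return 0.0
    if a == "-" or b == "-":
        return -4.0
    if alphabet == "protein":
        try:
            return float(_BLOSUM62[a, b])
        except (KeyError, IndexError):
            return -1.0
    return 5.0 if a == b else -4.0


def _profile_nw(
    prof_a: list[tuple[str, ...]],
    prof_b: list[tuple[str, ...]],
    alphabet: str,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> tuple[list[tuple[str, ...]], float]:
    """Global affine-gap alignment of two profiles (lists of columns).

    Column-column score is the average pairwise character score; gap
    columns inserted against a profile use the affine penalties.
    """
    na, nb = len(prof_a), len(prof_b)
    wa, wb = len(prof_a[0]) if prof_a else 1, len(prof_b[0]) if prof_b else 1

    score_cache: dict[tuple[int, int], float] = {}

    def colscore(i: int, j: int) -> float:
        key = (i, j)
        if key not in score_cache:
            ca, cb = prof_a[i], prof_b[j]
            s = 0.0
            for x in ca:
                for y in cb:
                    s += _char_score(x, y, alphabet)
            score_cache[key] = s / (wa * wb)
        return score_cache[key]

    NEG = -1e30
    M = np.full((na + 1, nb + 1), NEG)
    X = np.full((na + 1, nb + 1), NEG)  # gap in B (consume A)
    Y = np.full((na + 1, nb + 1), NEG)  # gap in A (consume B)
    M[0, 0] = 0.0
    for i in range(1, na + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, nb + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            s = colscore(i - 1, j - 1)
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    # traceback
    i, j = na, nb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    best = [M[i, j], X[i, j], Y[i, j]][state]
    merged: list[tuple[str, ...]] = []
    gap_a = tuple("-" * wa)
    gap_b = tuple("-" * wb)
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            s = colscore(i - 1, j - 1)
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            state_next = int(np.argmax(prev))
            merged.append(prof_a[i - 1] + prof_b[j - 1])
            i, j = i - 1, j - 1
            state = state_next
        elif state == 1 and i > 0:
            merged.append(prof_a[i - 1] + gap_b)
            state = 0 if X[i, j] == M[i - 1, j] + gap_open else 1
            i -= 1
        elif state == 2 and j > 0:
            merged.append(gap_a + prof_b[j - 1])
            state = 0 if Y[i, j] == M[i, j - 1] + gap_open else 2
            j -= 1
        else:  # boundary
            if i > 0:
                merged.append(prof_a[i - 1] + gap_b)
                i -= 1
            else:
                merged.append(gap_a + prof_b[j - 1])
                j -= 1
    merged.reverse()
    return merged, float(best)


def _kmer_distance(a: str, b: str, k: int) -> float:
    sa = {a[i : i + k] for i in range(max(len(a) - k + 1, 0))}
    sb = {b[i : i + k] for i in range(max(len(b) - k + 1, 0))}
    if not sa or not sb:
        return 1.0
    return 1.0 - len(sa & sb) / min(len(sa), len(sb))


def progressive_align(
    seqs: dict[str, str], alphabet: str = "protein"
) -> MultipleAlignment:
    """Guide-tree progressive profile alignment.

    Pairwise k-mer distances define the merge order (greedy
    nearest-neighbor agglomeration, the join order an NJ guide tree would
    visit on these star-like distances); profiles are merged by global
    affine-gap profile alignment. Deterministic: ties break on sorted ids.
    """
    if not seqs:
        raise ValueError("no sequences to align")
    ids = sorted(seqs)
    if len(ids) == 1:
        return MultipleAlignment(ids=ids, rows=[seqs[ids[0]]], alphabet=alphabet)
    k = 3 if alphabet == "protein" else 6
    # active profiles: tag -> (taxa list, profile columns)
    profiles: dict[str, tuple[list[str], list[tuple[str, ...]]]] = {
        t: ([t], [tuple(c) for c in seqs[t]]) for t in ids
    }
    reps: dict[str, str] = {t: seqs[t] for t in ids}  # representative seq per profile
    dist: dict[tuple[str, str], float] = {}
    active = sorted(profiles)
    for i, a in enumerate(active):
        for b in active[i + 1 :]:
            dist[(a, b)] = _kmer_distance(reps[a], reps[b], k)
    while len(active) > 1:
        best_pair = min(
            ((a, b) for i, a in enumerate(active) for b in active[i + 1 :]),
            key=lambda p: (dist[p], p),
        )
        a, b = best_pair
        ta, pa = profiles.pop(a)
        tb, pb = profiles.pop(b)
        merged, _ = _profile_nw(pa, pb, alphabet)
        tag = min(a, b)
        profiles[tag] = (ta + tb, merged)
        reps[tag] = reps[min(a, b)]
        active = sorted(profiles)
        for other in active:
            if other == tag:
                continue
            key = (min(other, tag), max(other, tag))
            dist[key] = _kmer_distance(reps[tag], reps[other], k)
    taxa, columns = profiles[active[0]]
    rows = ["".join(col[i] for col in columns) for i in range(len(taxa))]
    order = sorted(range(len(taxa)), key=lambda i: taxa[i])
    return MultipleAlignment(
        ids=[taxa[i] for i in order],
        rows=[rows[i] for i in order],
        alphabet=alphabet,
    )


def concatenate(
    alignments: list[tuple[str, MultipleAlignment]], taxa: list[str]
) -> tuple[MultipleAlignment, list[tuple[str, int, int]]]:
    """Column-wise concatenation into a supermatrix with a partition table.

    Taxa missing from a family are filled with gaps over that family's
    width; families are concatenated in the given order. Returns the
    supermatrix and (family_id, start, end) partitions (0-based half-open).
    """
    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    offset = 0
    alphabet = alignments[0][1].alphabet if alignments else "protein"
    for fam_id, aln in alignments:
        extra = set(aln.ids) - set(taxa)
        if extra:
            raise ValueError(f"{fam_id}: taxa {sorted(extra)} not in supermatrix taxa")
        width = aln.n_columns
        for t in taxa:
            chunks[t].append(aln.row(t) if t in aln.ids else "-" * width)
        parts.append((fam_id, offset, offset + width))
        offset += width
    sm = MultipleAlignment(
        ids=list(taxa), rows=["".join(chunks[t]) for t in taxa], alphabet=alphabet
    )
    return sm, parts


def _msa_array(msa: MultipleAlignment) -> np.ndarray:
    return np.frombuffer("".join(msa.rows).encode(), dtype="S1").reshape(
        len(msa.ids), msa.n_columns
    )


def _distances_from_array(
    arr: np.ndarray, ids: list[str], model: str
) -> np.ndarray:
    gap = arr == b"-"
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            comparable = int(ok.sum())
            if comparable == 0:
                raise ValueError(
                    f"no comparable columns between {ids[i]} and {ids[j]}"
                )
            p = float((arr[i, ok] != arr[j, ok]).mean())
            if model == "jukes_cantor":
                if p >= 0.75:
                    raise ValueError("Jukes-Cantor saturation (p >= 3/4)")
                d = -0.75 * math.log1p(-4.0 * p / 3.0)
            else:
                d = p
            D[i, j] = D[j, i] = d
    return D


def distance_matrix(
    msa: MultipleAlignment, model: str = "p_distance"
) -> tuple[list[str], np.ndarray]:
    """Pairwise-deletion distances over the alignment.

    ``p_distance`` is the mismatch fraction over columns where both rows
    are ungapped; ``jukes_cantor`` applies d = -(3/4) ln(1 - 4p/3).
    """
    if model not in ("p_distance", "jukes_cantor"):
        raise ValueError(f"unknown model {model!r}")
    if len(msa.ids) < 2:
        raise ValueError("need >= 2 taxa")
    return list(msa.ids), _distances_from_array(_msa_array(msa), list(msa.ids), model)


def nj_tree(labels: list[str], D: np.ndarray) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    Iteratively joins the pair minimising Q(i,j) = (n-2) d(i,j) - R_i - R_j
    with the standard branch-length formulas; ties break on the
    lexicographically smallest (label_i, label_j); negative branch length
    estimates are clamped to zero.
    """
    n = len(labels)
    if n < 3:
        raise ValueError("need >= 3 taxa for NJ")
    D = np.asarray(D, dtype=float)
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    nodes: dict[str, PhyloNode] = {lab: PhyloNode(name=lab) for lab in labels}
    # mutable working copies keyed by label
    labs = list(labels)
    M = D.copy()
    while len(labs) > 2:
        m = len(labs)
        R = M.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * M[i, j] - R[i] - R[j]
                key = (q, min(labs[i], labs[j]), max(labs[i], labs[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        la, lb = labs[i], labs[j]
        d_ij = M[i, j]
        bl_i = 0.5 * d_ij + (R[i] - R[j]) / (2 * (m - 2))
        bl_j = d_ij - bl_i
        bl_i, bl_j = max(bl_i, 0.0), max(bl_j, 0.0)
        new_label = min(la, lb)
        parent = PhyloNode(
            children=[(nodes[la], bl_i), (nodes[lb], bl_j)]
        )
        # distances from the new node to the others
        keep = [k for k in range(m) if k not in (i, j)]
        new_d = np.array([0.5 * (M[i, k] + M[j, k] - d_ij) for k in keep])
        new_d = np.maximum(new_d, 0.0)
        M = M[np.ix_(keep, keep)]
        M = np.pad(M, ((0, 1), (0, 1)))
        M[-1, :-1] = new_d
        M[:-1, -1] = new_d
        labs = [labs[k] for k in keep] + [f"__internal_{new_label}"]
        nodes[labs[-1]] = parent
    # join the last two nodes with the remaining distance on one edge
    la, lb = labs
    root = PhyloNode(children=[(nodes[la], max(M[0, 1], 0.0)), (nodes[lb], 0.0)])
    return PhyloTree(root=root)


def bootstrap_support(
    msa: MultipleAlignment,
    n_reps: int = 1000,
    seed: int = 0,
    model: str = "p_distance",
) -> PhyloTree:
    """NJ tree with bootstrap supports (% of replicates containing each
    internal bipartition of the point-estimate tree)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels, D = distance_matrix(msa, model=model)
    tree = nj_tree(labels, D)
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    n_cols = msa.n_columns
    arr = _msa_array(msa)
    done = 0
    while done < n_reps:
        cols = rng.integers(0, n_cols, size=n_cols)
        try:
            D_r = _distances_from_array(arr[:, cols], labels, model)
        except ValueError:
            done += 1  # all-gap column draw for some pair; counts as a failed rep
            continue
        rep_tree = nj_tree(labels, D_r)
        rep_bps = rep_tree.bipartitions()
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
        done += 1

    def annotate(node: PhyloNode, all_leaves: set[str], ref: str) -> set[str]:
        if node.is_leaf:
            return {node.name}
        below: set[str] = set()
        for child, _ in node.children:
            below |= annotate(child, all_leaves, ref)
        if 1 < len(below) < len(all_leaves) - 1:
            side = below if ref not in below else all_leaves - below
            node.support = 100.0 * counts[frozenset(side)] / n_reps
        return below

    leaves = set(tree.leaves())
    annotate(tree.root, leaves, min(leaves))
    return tree
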