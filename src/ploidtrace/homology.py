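"""Cross-species protein homology graph, Markov clustering, copy-classes.

Homology edges come from Smith–Waterman local alignment (BLOSUM62, affine
gap open 11 / extend 1) with a Karlin–Altschul style e-value proxy
E = K * m * n * exp(-lambda * S) computed over a fixed per-pair search
space; pairs with E at or below the threshold (default 1e-7) are homologs.
Families are delimited by Markov clustering (MCL): alternate random-walk
expansion (matrix squaring) and inflation (elementwise power + column
renormalisation) until the flow matrix converges, then read clusters off as
the connected attractor sets. Families are classified into single-copy
(exactly one gene in each species), multi-copy (all species present, some
with >= 2 genes), partial-shared (two species) and species-specific (one
species), with three-set Venn accounting of both family and gene counts.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "SimilarityEdge",
    "GeneFamily",
    "HOMOLOGY_EVALUE_THRESHOLD",
    "pairwise_similarity",
    "all_vs_all_edges",
    "mcl_cluster",
    "classify_families",
]

HOMOLOGY_EVALUE_THRESHOLD = 1e-7
# gapped Karlin-Altschul parameters for BLOSUM62 with 11/1 affine gaps
_KA_LAMBDA = 0.267
_KA_K = 0.041

_AA_ALPHABET = set("ARNDCQEGHILKMFPSTWYVBZX*")


@dataclass(frozen=True)
class SimilarityEdge:
    """Undirected homology edge; ``gene_a < gene_b`` canonical order."""

    gene_a: str
    gene_b: str
    score: float
    identity: float
    aligned_len: int
    evalue_proxy: float


@dataclass
class GeneFamily:
    """A cluster of homologous genes with a copy-class label."""

    family_id: str
    members: dict[str, list[str]]  # species -> gene ids
    copy_class: str = "unclassified"

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.members.values())

    @property
    def species_present(self) -> tuple[str, ...]:
        return tuple(sorted(s for s, g in self.members.items() if g))


_LOCAL_ALIGNER: PairwiseAligner | None = None


def _local_aligner() -> PairwiseAligner:
    global _LOCAL_ALIGNER
    if _LOCAL_ALIGNER is None:
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        _LOCAL_ALIGNER = aligner
    return _LOCAL_ALIGNER


def pairwise_similarity(
    prot_a: str,
    prot_b: str,
    gene_a: str = "a",
    gene_b: str = "b",
    evalue_threshold: float = HOMOLOGY_EVALUE_THRESHOLD,
    search_space: float | None = None,
) -> SimilarityEdge | None:
    """Best local alignment of two proteins as a homology edge, or None.

    ``search_space`` defaults to len(a)*len(b); the proxy is monotone in the
    score, so the threshold acts like a (nominal) BLAST e-value cutoff.
    """
    if not prot_a or not prot_b:
        raise ValueError("empty protein sequence")
    for p in (prot_a, prot_b):
        bad = next((c for c in p if c not in _AA_ALPHABET), None)
        if bad is not None:
            raise ValueError(f"invalid amino-acid character {bad!r}")
    if gene_b < gene_a:
        gene_a, gene_b = gene_b, gene_a
        prot_a, prot_b = prot_b, prot_a
    alignments = _local_aligner().align(prot_a, prot_b)
    score = alignments.score
    if score <= 0:
        return None
    mn = search_space if search_space is not None else len(prot_a) * len(prot_b)
    evalue = _KA_K * mn * float(np.exp(-_KA_LAMBDA * score))
    if evalue > evalue_threshold:
        return None
    aln = alignments[0]
    counts = aln.counts()
    aligned_len = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / aligned_len if aligned_len else 0.0
    return SimilarityEdge(
        gene_a=gene_a,
        gene_b=gene_b,
        score=float(score),
        identity=float(identity),
        aligned_len=int(aligned_len),
        evalue_proxy=float(evalue),
    )


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def all_vs_all_edges(
    proteins: dict[str, str],
    evalue_threshold: float = HOMOLOGY_EVALUE_THRESHOLD,
    prefilter_k: int = 4,
    prefilter_min_shared: int = 2,
) -> list[SimilarityEdge]:
    """All-vs-all homology edges with a shared-k-mer prefilter.

    Only pairs sharing >= ``prefilter_min_shared`` distinct k-mers are
    aligned; random unrelated proteins almost never pass, keeping the
    quadratic alignment cost bounded to near-homologous pairs.
    """
    ids = sorted(proteins)
    kmers = {g: _kmer_set(proteins[g], prefilter_k) for g in ids}
    index: dict[str, list[str]] = defaultdict(list)
    for g in ids:
        for km in kmers[g]:
            index[km].append(g)
    shared: Counter[tuple[str, str]] = Counter()
    for members in index.values():
        if len(members) < 2:
            continue
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                shared[(members[i], members[j])] += 1
    edges = []
    for (a, b), n_shared in sorted(shared.items()):
        if n_shared < prefilter_min_shared:
            continue
        edge = pairwise_similarity(
            proteins[a], proteins[b], a, b, evalue_threshold=evalue_threshold
        )
        if edge is not None:
            edges.append(edge)
    return edges


def mcl_cluster(
    edges: list[SimilarityEdge],
    inflation: float = 2.0,
    genes: list[str] | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> list[set[str]]:
    """Markov clustering of the weighted homology graph.

    Adjacency is score-weighted with self-loops (loop weight = max incident
    weight); columns are stochastic-normalised; iteration alternates
    expansion (matrix square) and inflation (elementwise power +
    renormalise) until the flow matrix changes by < ``tol``. Clusters are
    the connected components of the converged flow graph; genes listed in
    ``genes`` but absent from edges become singletons.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    node_set = set(genes or [])
    for e in edges:
        node_set.update((e.gene_a, e.gene_b))
    nodes = sorted(node_set)
    if not nodes:
        return []
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for e in edges:
        i, j = idx[e.gene_a], idx[e.gene_b]
        w = max(e.score, 0.0)
        M[i, j] = max(M[i, j], w)
        M[j, i] = M[i, j]
    loop = M.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(M, loop)
    M = M / M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = M @ M
        inflated = expanded**inflation
        inflated /= inflated.sum(axis=0, keepdims=True)
        if np.abs(inflated - M).max() < tol:
            M = inflated
            break
        M = inflated
    G = nx.Graph()
    G.add_nodes_from(range(n))
    sig = np.argwhere(M > 1e-5)
    G.add_edges_from((int(i), int(j)) for i, j in sig if i != j)
    clusters = [
        {nodes[i] for i in comp} for comp in nx.connected_components(G)
    ]
    clusters.sort(key=lambda c: min(c))
    return clusters


@dataclass
class VennCounts:
    """Per-region family and gene counts of the 3-set (species) Venn diagram."""

    families: dict[str, int] = field(default_factory=dict)
    genes: dict[str, int] = field(default_factory=dict)

    def total_families(self) -> int:
        return sum(self.families.values())

    def total_genes(self) -> int:
        return sum(self.genes.values())


def classify_families(
    clusters: list[set[str]],
    species_of: dict[str, str],
    n_species: int = 3,
) -> tuple[list[GeneFamily], VennCounts]:
    """Label clusters with copy-classes and accumulate Venn counts.

    shared_single_copy: one gene from each species; shared_multi_copy: all
    species present, some species with >= 2 genes; partial_shared: exactly
    two species; species_specific: one species.
    """
    families: list[GeneFamily] = []
    venn = VennCounts()
    for k, cluster in enumerate(clusters):
        members: dict[str, list[str]] = defaultdict(list)
        for g in sorted(cluster):
            if g not in species_of:
                raise ValueError(f"unknown gene id {g!r}")
            members[species_of[g]].append(g)
        present = sorted(members)
        sizes = [len(members[s]) for s in present]
        if len(present) == n_species:
            copy_class = (
                "shared_single_copy" if all(c == 1 for c in sizes) else "shared_multi_copy"
            )
        elif len(present) == 1:
            copy_class = "species_specific"
        else:
            copy_class = "partial_shared"
        fam = GeneFamily(
            family_id=f"FAM{k:05d}", members=dict(members), copy_class=copy_class
        )
        families.append(fam)
        region = "&".join(present)
        venn.families[region] = venn.families.get(region, 0) + 1
        venn.genes[region] = venn.genes.get(region, 0) + fam.n_genes
    return families, venn
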