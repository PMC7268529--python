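"""NG86 Ka/Ks estimation on protein-guided codon alignments.

The Nei–Gojobori (1986) counting method estimates the number of synonymous
substitutions per synonymous site (Ks) and nonsynonymous substitutions per
nonsynonymous site (Ka) between two protein-coding sequences:

1. every sense codon contributes fractional synonymous/nonsynonymous *sites*
   based on which of its nine single-base mutants preserve the amino acid
   (mutations to stop codons are excluded from the denominator);
2. observed codon differences are decomposed into synonymous and
   nonsynonymous *steps* by averaging over all minimal mutational pathways
   between the two codons, skipping pathways that pass through stop codons;
3. the raw proportions p = Sd/S and Nd/N are corrected for multiple hits
   with the one-parameter Jukes–Cantor formula d = -(3/4) ln(1 - 4p/3).

Ka/Ks > 1 indicates positive (diversifying) selection, ~1 neutrality and
< 1 purifying selection; the classifier below uses the finer operational
bins (strong positive > 1, weak positive 0.5–1, neutral 0.1–0.5,
purifying < 0.1) and excludes pairs whose Ks <= 0.1 (potential paralogs /
assembly redundancy) or whose distances are saturated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from scipy.stats import fisher_exact

__all__ = [
    "SENSE_CODONS",
    "STOP_CODONS",
    "CodonAlignment",
    "OrthologPairStats",
    "ng86_site_fraction",
    "ng86_differences",
    "jukes_cantor",
    "back_translate",
    "align_proteins_pairwise",
    "codon_alignment_for_pair",
    "kaks_pair",
    "fisher_gate",
    "classify_selection",
]

_BASES = "ACGT"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
_CODON_TO_AA = dict(standard_dna_table.forward_table)
SENSE_CODONS = tuple(sorted(_CODON_TO_AA))

GAP_CODON = "---"

# finer Ka/Ks bins; boundary conventions: ratio == 1 -> weak_positive,
# ratio == 0.5 or == 0.1 -> neutral (closed middle bin)
STRONG_POSITIVE_MIN = 1.0
WEAK_POSITIVE_MIN = 0.5
NEUTRAL_MIN = 0.1
KS_PARALOG_BENCHMARK = 0.1


def _aa(codon: str) -> str:
    """Amino acid of a codon; '*' for stop."""
    return _CODON_TO_AA.get(codon, "*")


@lru_cache(maxsize=None)
def ng86_site_fraction(codon: str) -> float:
    """Number of synonymous sites in ``codon``, in [0, 3].

    Each position contributes (# synonymous non-stop single-base mutants) /
    (# non-stop single-base mutants); mutations creating stop codons are
    dropped from both numerator and denominator.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site decomposition")
    if codon not in _CODON_TO_AA:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa0 = _CODON_TO_AA[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        nonstop = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            nonstop += 1
            if _CODON_TO_AA[mutant] == aa0:
                syn += 1
        if nonstop:
            total += syn / nonstop
    return total


@lru_cache(maxsize=None)
def ng86_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) step counts.

    All minimal mutational pathways between the codons are enumerated;
    pathways whose intermediate codons are stops are excluded unless every
    pathway is blocked, in which case all pathways count (NG86 fallback,
    stop-involving steps scored as nonsynonymous).
    """
    for c in (codon_a, codon_b):
        if c not in _CODON_TO_AA:
            raise ValueError(f"not a sense codon: {c!r}")
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return (0.0, 0.0)

    def walk(order: tuple[int, ...]) -> tuple[float, float, bool]:
        current = codon_a
        sd = nd = 0.0
        blocked = False
        for k, pos in enumerate(order):
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS and k < len(order) - 1:
                blocked = True
            if _aa(nxt) == _aa(current) and nxt not in STOP_CODONS and current not in STOP_CODONS:
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        return (sd, nd, blocked)

    valid: list[tuple[float, float]] = []
    all_paths: list[tuple[float, float]] = []
    for order in permutations(diff_positions):
        psd, pnd, blocked = walk(order)
        all_paths.append((psd, pnd))
        if not blocked:
            valid.append((psd, pnd))
    paths = valid if valid else all_paths
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return (sd, nd)


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3).

    Returns ``nan`` (not-applicable) at or beyond the saturation boundary
    p >= 3/4 rather than raising.
    """
    if p < 0:
        raise ValueError(f"proportion must be >= 0, got {p}")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class CodonAlignment:
    """A pair of gapped, codon-structured nucleotide sequences."""

    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.codons_a)


@dataclass
class OrthologPairStats:
    """NG86 statistics for one ortholog (or paralog) pair."""

    gene_a: str
    gene_b: str
    n_codons: int  # ungapped sense-codon columns compared
    S: float  # synonymous sites (averaged over the two sequences)
    N: float  # nonsynonymous sites
    Sd: float  # pathway-averaged synonymous differences
    Nd: float  # pathway-averaged nonsynonymous differences
    ka: float
    ks: float
    kaks: float
    fisher_p: float
    selection_class: str = "unclassified"
    filtered: bool = False
    filter_reason: str = ""


def back_translate(
    aligned_proteins: dict[str, str], cds_map: dict[str, str]
) -> dict[str, str]:
    """Replace each aligned residue by its source codon, gaps by ``---``.

    Raises if a protein row does not translate exactly from its CDS
    (position of the first mismatch is reported).
    """
    from .coding_regions import translate  # local import avoids cycle

    out: dict[str, str] = {}
    for name, row in aligned_proteins.items():
        cds = cds_map[name]
        prot = translate(cds)
        ungapped = row.replace("-", "")
        if ungapped != prot:
            for i, (a, b) in enumerate(zip(ungapped, prot)):
                if a != b:
                    raise ValueError(
                        f"{name}: aligned protein disagrees with CDS translation "
                        f"at residue {i} ({a!r} != {b!r})"
                    )
            raise ValueError(
                f"{name}: aligned protein length {len(ungapped)} != "
                f"translated CDS length {len(prot)}"
            )
        codons = []
        k = 0
        for ch in row:
            if ch == "-":
                codons.append(GAP_CODON)
            else:
                codons.append(cds[3 * k : 3 * k + 3])
                k += 1
        out[name] = "".join(codons)
    return out


_PROT_ALIGNER: PairwiseAligner | None = None


def _protein_aligner() -> PairwiseAligner:
    global _PROT_ALIGNER
    if _PROT_ALIGNER is None:
        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        _PROT_ALIGNER = aligner
    return _PROT_ALIGNER


def align_proteins_pairwise(prot_a: str, prot_b: str) -> tuple[str, str]:
    """Global protein alignment (BLOSUM62, affine 11/1); first optimal alignment."""
    aln = _protein_aligner().align(prot_a, prot_b)[0]
    return str(aln[0]), str(aln[1])


def codon_alignment_for_pair(cds_a: str, cds_b: str) -> CodonAlignment:
    """Protein-guided codon alignment of two CDSs (align proteins, back-translate)."""
    from .coding_regions import translate

    pa, pb = translate(cds_a), translate(cds_b)
    ra, rb = align_proteins_pairwise(pa, pb)
    rows = back_translate({"a": ra, "b": rb}, {"a": cds_a, "b": cds_b})
    ca = tuple(rows["a"][i : i + 3] for i in range(0, len(rows["a"]), 3))
    cb = tuple(rows["b"][i : i + 3] for i in range(0, len(rows["b"]), 3))
    return CodonAlignment(ca, cb)


def kaks_pair(
    aln: CodonAlignment, gene_a: str = "a", gene_b: str = "b"
) -> OrthologPairStats:
    """NG86 Ka/Ks over the ungapped sense-codon columns of ``aln``.

    Columns containing a gap codon, an ambiguous base, or a stop codon are
    skipped. S + N equals 3x the number of compared columns exactly.
    """
    s_a = s_b = 0.0
    sd = nd = 0.0
    n_cols = 0
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        if ca not in _CODON_TO_AA or cb not in _CODON_TO_AA:
            continue
        n_cols += 1
        s_a += ng86_site_fraction(ca)
        s_b += ng86_site_fraction(cb)
        dsd, dnd = ng86_differences(ca, cb)
        sd += dsd
        nd += dnd
    if n_cols == 0:
        raise ValueError("alignment has no comparable (ungapped sense) codon columns")
    S = (s_a + s_b) / 2.0
    N = 3.0 * n_cols - S
    ps = sd / S if S > 0 else math.nan
    pn = nd / N if N > 0 else math.nan
    ks = jukes_cantor(ps) if not math.isnan(ps) else math.nan
    ka = jukes_cantor(pn) if not math.isnan(pn) else math.nan
    if math.isnan(ka) or math.isnan(ks) or ks == 0:
        ratio = math.nan
    else:
        ratio = ka / ks
    p = fisher_gate(S, N, sd, nd)
    stats = OrthologPairStats(
        gene_a=gene_a,
        gene_b=gene_b,
        n_codons=n_cols,
        S=S,
        N=N,
        Sd=sd,
        Nd=nd,
        ka=ka,
        ks=ks,
        kaks=ratio,
        fisher_p=p,
    )
    stats.selection_class = classify_selection(stats)
    stats.filtered = stats.selection_class == "excluded"
    if stats.filtered:
        if math.isnan(ka) or math.isnan(ks):
            stats.filter_reason = "ka_or_ks_not_applicable"
        else:
            stats.filter_reason = "ks_below_paralog_benchmark"
    return stats


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def fisher_gate(S: float, N: float, Sd: float, Nd: float) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[Sd, S-Sd], [Nd, N-Nd]].

    Fractional site/difference counts (pathway averages) are rounded
    half-up to integers, as the exact test requires.
    """
    if min(S, N, Sd, Nd) < 0:
        raise ValueError("counts must be non-negative")
    s, n = _round_half_up(S), _round_half_up(N)
    sd, nd = min(_round_half_up(Sd), s), min(_round_half_up(Nd), n)
    table = [[sd, s - sd], [nd, n - nd]]
    return float(fisher_exact(table, alternative="two-sided")[1])


def classify_selection(stats: OrthologPairStats) -> str:
    """Selection class from Ka/Ks with the Ks > 0.1 keep-filter applied first."""
    if math.isnan(stats.ka) or math.isnan(stats.ks) or math.isnan(stats.kaks):
        return "excluded"
    if stats.ks <= KS_PARALOG_BENCHMARK:
        return "excluded"
    r = stats.kaks
    if r > STRONG_POSITIVE_MIN:
        return "strong_positive"
    if r > WEAK_POSITIVE_MIN:
        return "weak_positive"
    if r >= NEUTRAL_MIN:
        return "neutral"
    return "purifying"
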