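"""WGD dating from paralog Ks age distributions.

Ancient whole-genome duplications leave bursts of paralog pairs with
similar synonymous divergence; the Ks values of within-species duplicate
pairs therefore pile up into peaks. The stage: (1) detect paralog pairs as
intra-species CDS pairs whose best local nucleotide alignment reaches 40%
identity over >= 300 bp; (2) compute each pair's Ks (NG86 on the
protein-guided codon alignment); (3) keep 0 < Ks <= 2 (older pairs are
saturated); (4) bin into a bandwidth-0.03 histogram and fit a k-component
univariate Gaussian mixture by EM; (5) convert each fitted peak mean to an
age with T = Ks / (2 r), r being the per-site synonymous substitution rate
per year (plant average 6.1e-9).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner

from .codon_evolution import codon_alignment_for_pair, kaks_pair

__all__ = [
    "ParalogPair",
    "KsMixtureFit",
    "PLANT_KS_RATE_PER_YEAR",
    "PARALOG_MIN_IDENTITY",
    "PARALOG_MIN_ALIGNED_NT",
    "KS_SATURATION_CAP",
    "KS_HISTOGRAM_BANDWIDTH",
    "find_paralog_pairs",
    "ks_for_pairs",
    "ks_distribution",
    "ks_histogram",
    "em_fit",
    "age_from_ks",
]

PLANT_KS_RATE_PER_YEAR = 6.1e-9
PARALOG_MIN_IDENTITY = 0.40
PARALOG_MIN_ALIGNED_NT = 300
KS_SATURATION_CAP = 2.0
KS_HISTOGRAM_BANDWIDTH = 0.03


@dataclass
class ParalogPair:
    species: str
    gene_a: str
    gene_b: str
    identity: float
    aligned_nt: int
    ks: float = math.nan


@dataclass
class KsMixtureFit:
    """Fitted Gaussian mixture over paralog Ks values, with derived ages."""

    k: int
    weights: list[float]
    mus: list[float]
    sigmas: list[float]
    loglik: float
    n_iter: int
    converged: bool
    ages_years: list[float] = field(default_factory=list)


_NT_ALIGNER: PairwiseAligner | None = None


def _nt_aligner() -> PairwiseAligner:
    global _NT_ALIGNER
    if _NT_ALIGNER is None:
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 2
        aligner.mismatch_score = -3
        aligner.open_gap_score = -5
        aligner.extend_gap_score = -2
        _NT_ALIGNER = aligner
    return _NT_ALIGNER


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def find_paralog_pairs(
    cds_by_gene: dict[str, str],
    species: str = "",
    min_identity: float = PARALOG_MIN_IDENTITY,
    min_aligned_nt: int = PARALOG_MIN_ALIGNED_NT,
    seed_k: int = 11,
) -> list[ParalogPair]:
    """Intra-species duplicate (paralog) pairs by local nucleotide alignment.

    Candidate pairs must share a contiguous ``seed_k``-mer (word seeding);
    each candidate's best local alignment is kept iff identity >=
    ``min_identity`` over >= ``min_aligned_nt`` aligned columns.
    """
    ids = sorted(cds_by_gene)
    index: dict[str, list[str]] = defaultdict(list)
    for g in ids:
        for km in _kmer_set(cds_by_gene[g], seed_k):
            index[km].append(g)
    candidates: set[tuple[str, str]] = set()
    for members in index.values():
        if len(members) < 2:
            continue
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                candidates.add((members[i], members[j]))
    pairs = []
    for a, b in sorted(candidates):
        alignments = _nt_aligner().align(cds_by_gene[a], cds_by_gene[b])
        if alignments.score <= 0:
            continue
        aln = alignments[0]
        counts = aln.counts()
        aligned = counts.identities + counts.mismatches + counts.gaps
        if aligned < min_aligned_nt:
            continue
        identity = counts.identities / aligned
        if identity < min_identity:
            continue
        pairs.append(
            ParalogPair(
                species=species,
                gene_a=a,
                gene_b=b,
                identity=float(identity),
                aligned_nt=int(aligned),
            )
        )
    return pairs


def ks_for_pairs(
    pairs: list[ParalogPair], cds_by_gene: dict[str, str]
) -> list[ParalogPair]:
    """Attach NG86 Ks (protein-guided codon alignment) to each pair in place."""
    for p in pairs:
        aln = codon_alignment_for_pair(cds_by_gene[p.gene_a], cds_by_gene[p.gene_b])
        stats = kaks_pair(aln, p.gene_a, p.gene_b)
        p.ks = stats.ks
    return pairs


def ks_distribution(
    pairs: list[ParalogPair], cap: float = KS_SATURATION_CAP
) -> list[float]:
    """Applicable Ks values with 0 < Ks <= cap (saturation filter)."""
    return [p.ks for p in pairs if not math.isnan(p.ks) and 0 < p.ks <= cap]


def ks_histogram(
    ks: list[float], bandwidth: float = KS_HISTOGRAM_BANDWIDTH, cap: float = KS_SATURATION_CAP
) -> list[tuple[float, float, int]]:
    """Fixed-width histogram of Ks on (0, cap]; bins of width ``bandwidth``.

    Returns (bin_start, bin_end, count) rows; counts sum to len(ks).
    Values outside (0, cap] must be pre-filtered and raise.
    """
    if not ks:
        raise ValueError("empty Ks list")
    n_bins = math.ceil(cap / bandwidth)
    counts = [0] * n_bins
    for v in ks:
        if not (0 < v <= cap):
            raise ValueError(f"Ks value {v} outside (0, {cap}]; filter first")
        b = min(int(v / bandwidth), n_bins - 1)
        counts[b] += 1
    return [
        (round(i * bandwidth, 10), round((i + 1) * bandwidth, 10), c)
        for i, c in enumerate(counts)
    ]


def _em_once(
    x: np.ndarray,
    mus0: np.ndarray,
    sigmas0: np.ndarray,
    weights0: np.ndarray,
    tol: float,
    max_iter: int,
    sigma_floor: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool]:
    mus, sigmas, weights = mus0.copy(), sigmas0.copy(), weights0.copy()
    n = len(x)
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step in log space
        logpdf = (
            -0.5 * ((x[:, None] - mus[None, :]) / sigmas[None, :]) ** 2
            - np.log(sigmas[None, :])
            - 0.5 * math.log(2 * math.pi)
            + np.log(weights[None, :])
        )
        mx = logpdf.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(logpdf - mx).sum(axis=1))
        ll = float(lse.sum())
        resp = np.exp(logpdf - lse[:, None])
        # M-step
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-12):
            raise FloatingPointError("component collapsed to zero weight")
        weights = nk / n
        mus = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mus[None, :]) ** 2).sum(axis=0) / nk
        sigmas = np.sqrt(var)
        if np.any(sigmas < sigma_floor):
            raise FloatingPointError("sigma collapse")
        if ll - prev_ll < tol and it > 1:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    return mus, sigmas, weights, prev_ll, it, converged


def em_fit(
    ks: list[float],
    k: int = 3,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 5,
    rate: float = PLANT_KS_RATE_PER_YEAR,
) -> KsMixtureFit:
    """EM fit of a k-component univariate Gaussian mixture to Ks values.

    Restart 0 initialises means at evenly spaced sample quantiles with the
    pooled standard deviation; further restarts draw means from the data.
    The best-log-likelihood solution is returned with components sorted by
    mean and ages T = mu / (2 * rate).
    """
    x = np.asarray(ks, dtype=float)
    if len(x) < 10 * k:
        raise ValueError(f"need >= {10 * k} values for k={k}, got {len(x)}")
    rng = np.random.default_rng(seed)
    pooled_sd = float(x.std(ddof=1))
    if pooled_sd <= 0:
        raise ValueError("degenerate sample (zero variance)")
    best = None
    failures = []
    for r in range(n_restarts):
        if r == 0:
            qs = np.quantile(x, (np.arange(k) + 0.5) / k)
            mus0 = qs.astype(float)
        else:
            mus0 = np.sort(rng.choice(x, size=k, replace=False))
        sigmas0 = np.full(k, pooled_sd / k)
        weights0 = np.full(k, 1.0 / k)
        try:
            mus, sigmas, weights, ll, it, conv = _em_once(
                x, mus0, sigmas0, weights0, tol, max_iter
            )
        except FloatingPointError as exc:
            failures.append(str(exc))
            continue
        if best is None or ll > best[3]:
            best = (mus, sigmas, weights, ll, it, conv)
    if best is None:
        raise RuntimeError(f"all EM restarts collapsed: {failures}")
    mus, sigmas, weights, ll, it, conv = best
    order = np.argsort(mus)
    mus, sigmas, weights = mus[order], sigmas[order], weights[order]
    return KsMixtureFit(
        k=k,
        weights=[float(w) for w in weights],
        mus=[float(m) for m in mus],
        sigmas=[float(s) for s in sigmas],
        loglik=ll,
        n_iter=it,
        converged=conv,
        ages_years=[age_from_ks(float(m), rate) for m in mus],
    )


def age_from_ks(ks_mode: float, rate: float = PLANT_KS_RATE_PER_YEAR) -> float:
    """Duplication age in years: T = Ks / (2 r)."""
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if ks_mode < 0:
        raise ValueError("Ks must be >= 0")
    return ks_mode / (2.0 * rate)
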