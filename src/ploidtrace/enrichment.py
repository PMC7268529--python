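"""Hypergeometric over-representation test with Bonferroni correction.

For a query gene set drawn from an annotated background of N genes, a term
annotating M background genes and m of the n annotated query genes is
tested with the upper-tail hypergeometric probability

    P = 1 - sum_{i=0}^{m-1} C(M,i) C(N-M, n-i) / C(N,n)  =  P(X >= m),

corrected across the tested terms by Bonferroni (terms with m >= 1 are the
tested set and define the correction factor).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom

__all__ = ["EnrichmentResult", "hypergeom_tail", "enrich"]

SIGNIFICANCE_ALPHA = 0.05


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    N: int  # annotated genes in background
    M: int  # background genes carrying the term
    n: int  # annotated query genes
    m: int  # query genes carrying the term
    p: float
    p_bonf: float
    significant: bool


def hypergeom_tail(N: int, M: int, n: int, m: int) -> float:
    """Upper-tail hypergeometric probability P(X >= m).

    Evaluated through the survival function (log-space internally for
    large binomial coefficients).
    """
    if not (0 <= M <= N):
        raise ValueError(f"need 0 <= M <= N, got M={M}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= m <= min(n, M)):
        raise ValueError(f"need 0 <= m <= min(n, M), got m={m}")
    if m == 0:
        return 1.0
    # X ~ Hypergeom(population N, successes M, draws n)
    return float(hypergeom.sf(m - 1, N, M, n))


def enrich(
    query: set[str],
    annotation: dict[str, set[str]],
    background: set[str],
    alpha: float = SIGNIFICANCE_ALPHA,
    correct: bool = True,
) -> list[EnrichmentResult]:
    """Term-by-term over-representation of ``query`` against ``background``.

    Only genes with at least one term count toward N and n (annotated
    universe); only terms present in the query (m >= 1) are tested, and
    that count is the Bonferroni factor. Results are sorted by (p,
    term_id).
    """
    missing = query - background
    if missing:
        raise ValueError(f"query genes absent from background: {sorted(missing)[:5]}")
    annotated_bg = {g for g in background if annotation.get(g)}
    annotated_q = {g for g in query if annotation.get(g)}
    N, n = len(annotated_bg), len(annotated_q)
    term_bg: dict[str, int] = {}
    term_q: dict[str, int] = {}
    for g in annotated_bg:
        for t in annotation[g]:
            term_bg[t] = term_bg.get(t, 0) + 1
            if g in annotated_q:
                term_q[t] = term_q.get(t, 0) + 1
    tested = sorted(t for t, m in term_q.items() if m >= 1)
    factor = len(tested) if correct else 1
    results = []
    for t in tested:
        M, m = term_bg[t], term_q[t]
        p = hypergeom_tail(N, M, n, m)
        p_bonf = min(1.0, p * factor)
        results.append(
            EnrichmentResult(
                term_id=t,
                N=N,
                M=M,
                n=n,
                m=m,
                p=p,
                p_bonf=p_bonf,
                significant=p_bonf < alpha,
            )
        )
    results.sort(key=lambda r: (r.p, r.term_id))
    return results
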