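"""Coding-region identification for assembled transcripts (unigenes).

Two routes mirror a typical annotation-first workflow: when precomputed
protein-database hit tables are available (columns: unigene_id, database,
evalue, strand, frame, start, end), the best hit from the highest-priority
database (Nr > Swiss-Prot > KEGG > COG, then smallest e-value) fixes the
reading frame and strand; otherwise a deterministic six-frame longest-ORF
scan is used as the coding-potential heuristic. Unigenes with neither an
acceptable hit nor a qualifying ORF are dropped from downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "Unigene",
    "CodingRegion",
    "DATABASE_PRIORITY",
    "ANNOTATION_EVALUE_CUTOFF",
    "translate",
    "reverse_complement",
    "find_coding_region",
    "resolve_coding",
]

DATABASE_PRIORITY = ("Nr", "SwissProt", "KEGG", "COG")
ANNOTATION_EVALUE_CUTOFF = 1e-5
DEFAULT_MIN_ORF_NT = 150

_VALID = set("ACGTN")
_STOPS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class Unigene:
    """One assembled transcript."""

    id: str
    species: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"{self.id}: empty sequence")


@dataclass(frozen=True)
class CodingRegion:
    """The chosen coding interval of a unigene.

    ``start``/``end`` are 0-based half-open coordinates on the forward
    strand regardless of ``strand``; ``cds`` is already 5'->3' (i.e. the
    reverse complement of seq[start:end] when strand is '-') and includes
    the stop codon when one terminates the ORF.
    """

    unigene_id: str
    strand: str
    frame: int
    start: int
    end: int
    cds: str
    protein: str
    source: str  # "annotation" | "orf_heuristic"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Standard-code translation; a single trailing stop codon is dropped.

    Codons containing N translate to 'X' (never treated as stop). Raises on
    length not divisible by 3 or an internal stop codon.
    """
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    bad = next((i for i, c in enumerate(cds) if c not in _VALID), None)
    if bad is not None:
        raise ValueError(f"invalid nucleotide {cds[bad]!r} at position {bad}")
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise ValueError(f"internal stop codon at residue {prot.index('*')}")
    return prot


def _scan_frame(seq: str, frame: int) -> list[tuple[int, int]]:
    """(start, end) nt intervals of ORFs (ATG..stop-or-end) in one frame."""
    orfs = []
    i = frame
    start = None
    while i + 3 <= len(seq):
        codon = seq[i : i + 3]
        if start is None:
            if codon == "ATG":
                start = i
        elif codon in _STOPS:
            orfs.append((start, i + 3))
            start = None
        i += 3
    if start is not None:
        orfs.append((start, i))  # runs to the last complete codon
    return orfs


def find_coding_region(
    unigene: Unigene, min_len_nt: int = DEFAULT_MIN_ORF_NT
) -> CodingRegion | None:
    """Longest ORF (ATG through stop or sequence end) over all six frames.

    Ties are broken deterministically: '+' strand first, then lower frame
    index, then smaller start. Returns None when no ORF reaches
    ``min_len_nt``.
    """
    seq = unigene.seq.upper()
    bad = next((i for i, c in enumerate(seq) if c not in _VALID), None)
    if bad is not None:
        raise ValueError(f"{unigene.id}: invalid nucleotide {seq[bad]!r} at position {bad}")
    L = len(seq)
    rc = reverse_complement(seq)
    best = None  # (-length, strand_rank, frame, start_on_scan, interval_fwd, cds)
    for strand, s in (("+", seq), ("-", rc)):
        for frame in range(3):
            for a, b in _scan_frame(s, frame):
                if b - a < min_len_nt:
                    continue
                if strand == "+":
                    interval = (a, b)
                else:
                    interval = (L - b, L - a)
                cds = s[a:b]
                key = (-(b - a), 0 if strand == "+" else 1, frame, interval[0])
                if best is None or key < best[0]:
                    best = (key, strand, frame, interval, cds)
    if best is None:
        return None
    _, strand, frame, (start, end), cds = best
    return CodingRegion(
        unigene_id=unigene.id,
        strand=strand,
        frame=frame,
        start=start,
        end=end,
        cds=cds,
        protein=translate(cds),
        source="orf_heuristic",
    )


def _region_from_hit(unigene: Unigene, hit: pd.Series) -> CodingRegion:
    """Coding region implied by an annotation hit's strand/frame/interval.

    The aligned interval is snapped to codon boundaries in the hit's frame
    and truncated at the first in-frame stop codon (if any) so the type
    invariants (length % 3 == 0, no internal stop) always hold.
    """
    seq = unigene.seq.upper()
    L = len(seq)
    strand = str(hit["strand"])
    frame = int(hit["frame"])
    a, b = int(hit["start"]), int(hit["end"])
    a, b = max(0, a), min(L, b)
    s = seq if strand == "+" else reverse_complement(seq)
    # map interval onto the scanned strand
    sa, sb = (a, b) if strand == "+" else (L - b, L - a)
    # snap to the codon grid of `frame`
    sa = sa + ((frame - sa) % 3)
    sb = sa + ((sb - sa) // 3) * 3
    if sb <= sa:
        raise ValueError(f"{unigene.id}: annotation hit interval collapses under frame snap")
    cds = s[sa:sb]
    # truncate at first internal stop; keep that stop codon as terminator
    for i in range(0, len(cds) - 3, 3):
        if cds[i : i + 3] in _STOPS:
            cds = cds[: i + 3]
            sb = sa + len(cds)
            break
    interval = (sa, sb) if strand == "+" else (L - sb, L - sa)
    return CodingRegion(
        unigene_id=unigene.id,
        strand=strand,
        frame=frame,
        start=interval[0],
        end=interval[1],
        cds=cds,
        protein=translate(cds),
        source="annotation",
    )


def resolve_coding(
    unigene: Unigene,
    hits: pd.DataFrame | None = None,
    min_len_nt: int = DEFAULT_MIN_ORF_NT,
    evalue_cutoff: float = ANNOTATION_EVALUE_CUTOFF,
) -> CodingRegion | None:
    """Annotation-first coding-region resolution.

    The best hit from the highest-priority database wins (Nr > Swiss-Prot >
    KEGG > COG; within a database, smallest e-value); without hits the ORF
    heuristic is the fallback; without either, None (the unigene is dropped
    downstream).
    """
    if hits is not None and len(hits):
        unknown = set(hits["unigene_id"]) - {unigene.id}
        if unknown:
            raise ValueError(f"hit table references unknown unigene ids: {sorted(unknown)}")
        usable = hits[hits["evalue"] < evalue_cutoff]
        for db in DATABASE_PRIORITY:
            db_hits = usable[usable["database"] == db]
            if len(db_hits):
                best = db_hits.sort_values(
                    ["evalue", "start"], kind="mergesort"
                ).iloc[0]
                return _region_from_hit(unigene, best)
    return find_coding_region(unigene, min_len_nt=min_len_nt)
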