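"""Standard-format I/O: FASTA in; TSV / JSON / Newick out.

All tabular output is plain TSV with a header row; coordinates are 0-based
half-open internally and exported as-is with column names stating so.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .coding_regions import Unigene

__all__ = [
    "read_fasta",
    "read_hit_table",
    "read_annotation_tsv",
    "write_tsv",
    "write_json",
]


def read_fasta(path: str | Path, species: str = "") -> list[Unigene]:
    """Read unigenes from FASTA; species defaults to the id's 'T?' prefix."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        sp = species or rec.id.split("_")[0]
        records.append(Unigene(id=rec.id, species=sp, seq=str(rec.seq).upper()))
    return records


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Annotation hit table: unigene_id, database, evalue, strand, frame, start, end."""
    df = pd.read_csv(path, sep="\t")
    required = {"unigene_id", "database", "evalue", "strand", "frame", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing hit-table columns {sorted(missing)}")
    if (df["evalue"] < 0).any():
        raise ValueError(f"{path}: negative e-value")
    return df


def read_annotation_tsv(path: str | Path) -> dict[str, set[str]]:
    """gene_id -> set of term ids from a (gene_id, term_id, ontology) TSV."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for gid, term in zip(df["gene_id"], df["term_id"]):
        out.setdefault(str(gid), set()).add(str(term))
    return out


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
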