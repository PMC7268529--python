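"""End-to-end orchestration of the transcriptome molecular-evolution run.

Stage order follows the analysis design: coding-region identification ->
homology graph + gene families -> (single-copy Ka/Ks + enrichment,
phylogeny, WGD dating). Every stage writes its artifact (TSV / JSON /
Newick) into the output directory and records filter bookkeeping
(input = output + removed) in a RunReport, so the whole run is auditable
and, for a fixed seed, byte-deterministic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import coding_regions as cr
from . import homology as hg
from . import codon_evolution as ce
from . import phylogeny as ph
from . import wgd
from . import enrichment as en
from .io import read_fasta, read_hit_table, read_annotation_tsv, write_tsv, write_json

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one run; defaults are the study values."""

    fasta_by_species: dict[str, str] = field(default_factory=dict)
    annotation_tsv: str | None = None  # gene -> term table for enrichment
    hits_tsv: str | None = None  # optional database hit table
    out_dir: str = "ploidtrace_out"
    seed: int = 0
    annotation_evalue: float = 1e-5
    homology_evalue: float = 1e-7
    min_orf_nt: int = 150
    mcl_inflation: float = 2.0
    ks_ortholog_filter: float = 0.1
    ks_paralog_cap: float = 2.0
    paralog_min_identity: float = 0.40
    paralog_min_aligned_nt: int = 300
    ks_bandwidth: float = 0.03
    bootstrap_reps: int = 1000
    mixture_k: int = 3
    ks_rate_per_year: float = 6.1e-9
    distance_model: str = "p_distance"

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class RunReport:
    seed: int
    stages: list[dict] = field(default_factory=list)

    def add(self, stage: str, **info) -> None:
        self.stages.append({"stage": stage, **info})

    def filter_record(self, stage: str, name: str, n_in: int, n_out: int) -> None:
        self.add(stage, filter=name, n_in=n_in, n_out=n_out, removed=n_in - n_out)


def _stage_seed(seed: int, index: int) -> int:
    return (seed * 1000 + index) % (2**31)


def run_pipeline(config: PipelineConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)

    # ---- stage 1: read + coding regions ------------------------------------
    unigenes: list[cr.Unigene] = []
    for sp in sorted(config.fasta_by_species):
        recs = read_fasta(config.fasta_by_species[sp], species=sp)
        unigenes.extend(recs)
        report.add("read", species=sp, n_unigenes=len(recs))
    hits = read_hit_table(config.hits_tsv) if config.hits_tsv else None

    regions: dict[str, cr.CodingRegion] = {}
    species_of: dict[str, str] = {}
    for u in unigenes:
        sub = None
        if hits is not None:
            sub = hits[hits["unigene_id"] == u.id]
        region = cr.resolve_coding(
            u, sub if sub is not None and len(sub) else None,
            min_len_nt=config.min_orf_nt, evalue_cutoff=config.annotation_evalue,
        )
        if region is not None:
            regions[u.id] = region
            species_of[u.id] = u.species
    report.filter_record("coding", "coding_region_found", len(unigenes), len(regions))
    coding_df = pd.DataFrame(
        [
            {
                "unigene_id": r.unigene_id,
                "species": species_of[r.unigene_id],
                "strand": r.strand,
                "frame": r.frame,
                "start_0based": r.start,
                "end_exclusive": r.end,
                "source": r.source,
            }
            for r in (regions[k] for k in sorted(regions))
        ]
    )
    write_tsv(coding_df, out / "coding_regions.tsv")

    proteins = {g: regions[g].protein for g in regions}
    cds = {g: regions[g].cds for g in regions}

    # ---- stage 2: homology graph + families --------------------------------
    edges = hg.all_vs_all_edges(proteins, evalue_threshold=config.homology_evalue)
    report.add("homology", n_edges=len(edges), n_genes=len(proteins))
    write_tsv(
        pd.DataFrame(
            [
                {
                    "gene_a": e.gene_a,
                    "gene_b": e.gene_b,
                    "score": e.score,
                    "identity": round(e.identity, 6),
                    "aligned_len": e.aligned_len,
                    "evalue_proxy": f"{e.evalue_proxy:.6g}",
                }
                for e in edges
            ]
        ),
        out / "homology_edges.tsv",
    )
    clusters = hg.mcl_cluster(
        edges, inflation=config.mcl_inflation, genes=sorted(proteins)
    )
    families, venn = hg.classify_families(clusters, species_of)
    report.add(
        "families",
        n_families=len(families),
        n_single_copy=sum(1 for f in families if f.copy_class == "shared_single_copy"),
        n_multi_copy=sum(1 for f in families if f.copy_class == "shared_multi_copy"),
        n_species_specific=sum(1 for f in families if f.copy_class == "species_specific"),
        n_partial_shared=sum(1 for f in families if f.copy_class == "partial_shared"),
    )
    fam_rows = []
    for f in families:
        for sp in sorted(f.members):
            for g in f.members[sp]:
                fam_rows.append(
                    {"family_id": f.family_id, "copy_class": f.copy_class,
                     "species": sp, "gene_id": g}
                )
    write_tsv(pd.DataFrame(fam_rows), out / "families.tsv")
    write_json({"families": venn.families, "genes": venn.genes}, out / "venn.json")

    # ---- stage 3: single-copy ortholog Ka/Ks + selection classes -----------
    single = [f for f in families if f.copy_class == "shared_single_copy"]
    kaks_rows = []
    positive_genes: set[str] = set()
    for f in single:
        genes = [f.members[sp][0] for sp in sorted(f.members)]
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                a, b = genes[i], genes[j]
                aln = ce.codon_alignment_for_pair(cds[a], cds[b])
                st = ce.kaks_pair(aln, a, b)
                kaks_rows.append(
                    {
                        "gene_a": a,
                        "gene_b": b,
                        "species_pair": f"{species_of[a]}v{species_of[b]}",
                        "S": round(st.S, 4),
                        "N": round(st.N, 4),
                        "Sd": round(st.Sd, 4),
                        "Nd": round(st.Nd, 4),
                        "ka": "NA" if math.isnan(st.ka) else round(st.ka, 6),
                        "ks": "NA" if math.isnan(st.ks) else round(st.ks, 6),
                        "kaks": "NA" if math.isnan(st.kaks) else round(st.kaks, 6),
                        "fisher_p": round(st.fisher_p, 6),
                        "filtered": st.filtered,
                        "selection_class": st.selection_class,
                    }
                )
                if st.selection_class in ("strong_positive", "weak_positive"):
                    positive_genes.update((a, b))
    kaks_df = pd.DataFrame(kaks_rows)
    write_tsv(kaks_df, out / "kaks_pairs.tsv")
    n_pairs = len(kaks_rows)
    n_kept = sum(1 for r in kaks_rows if not r["filtered"])
    report.filter_record("kaks", "ks_gt_benchmark_and_applicable", n_pairs, n_kept)
    if n_pairs:
        class_counts = kaks_df["selection_class"].value_counts().to_dict()
        report.add("kaks_classes", **{str(k): int(v) for k, v in class_counts.items()})

    # ---- stage 4: enrichment on species-specific gene sets -----------------
    if config.annotation_tsv:
        annotation = read_annotation_tsv(config.annotation_tsv)
        background = set(proteins)
        enr_rows = []
        queries: dict[str, set[str]] = {}
        for sp in sorted(config.fasta_by_species):
            queries[f"{sp}_specific"] = {
                g
                for f in families
                if f.copy_class == "species_specific" and f.species_present == (sp,)
                for g in f.members[sp]
            }
        if positive_genes:
            queries["positive_selection"] = positive_genes
        for qname in sorted(queries):
            qset = queries[qname] & background
            if not qset:
                continue
            for r in en.enrich(qset, annotation, background):
                enr_rows.append({"query_set": qname, **asdict(r)})
        write_tsv(pd.DataFrame(enr_rows), out / "enrichment.tsv")
        report.add("enrichment", n_tests=len(enr_rows),
                   n_significant=sum(1 for r in enr_rows if r["significant"]))

    # ---- stage 5: phylogeny from concatenated single-copy alignments -------
    if len(config.fasta_by_species) >= 3 and single:
        alignments = []
        taxa = sorted(config.fasta_by_species)
        for f in single:
            fam_prots = {species_of[f.members[sp][0]]: proteins[f.members[sp][0]]
                         for sp in sorted(f.members)}
            msa = ph.progressive_align(fam_prots, alphabet="protein")
            fam_cds = {species_of[f.members[sp][0]]:
                       _strip_stop(cds[f.members[sp][0]]) for sp in sorted(f.members)}
            codon_rows = ce.back_translate(
                {t: msa.row(t) for t in msa.ids}, fam_cds
            )
            alignments.append(
                (f.family_id,
                 ph.MultipleAlignment(
                     ids=sorted(codon_rows), rows=[codon_rows[t] for t in sorted(codon_rows)],
                     alphabet="nucleotide"))
            )
        supermatrix, partitions = ph.concatenate(alignments, taxa)
        tree = ph.bootstrap_support(
            supermatrix, n_reps=config.bootstrap_reps,
            seed=_stage_seed(config.seed, 5), model=config.distance_model,
        )
        with open(out / "species_tree.nwk", "w") as fh:
            fh.write(tree.newick(with_support=True) + "\n")
        write_tsv(
            pd.DataFrame(partitions, columns=["family_id", "start", "end"]),
            out / "supermatrix_partitions.tsv",
        )
        report.add("phylogeny", n_taxa=len(taxa),
                   n_columns=supermatrix.n_columns, n_families=len(single))

    # ---- stage 6: WGD dating per species ------------------------------------
    wgd_summary = {}
    for sp in sorted(config.fasta_by_species):
        sp_cds = {g: _strip_stop(cds[g]) for g in cds if species_of[g] == sp}
        pairs = wgd.find_paralog_pairs(
            sp_cds, species=sp,
            min_identity=config.paralog_min_identity,
            min_aligned_nt=config.paralog_min_aligned_nt,
        )
        pairs = wgd.ks_for_pairs(pairs, sp_cds)
        ks_vals = wgd.ks_distribution(pairs, cap=config.ks_paralog_cap)
        report.filter_record(f"wgd_{sp}", "ks_in_(0,2]", len(pairs), len(ks_vals))
        write_tsv(
            pd.DataFrame(
                [
                    {"gene_a": p.gene_a, "gene_b": p.gene_b,
                     "identity": round(p.identity, 4), "aligned_nt": p.aligned_nt,
                     "ks": "NA" if math.isnan(p.ks) else round(p.ks, 6)}
                    for p in pairs
                ]
            ),
            out / f"paralog_pairs_{sp}.tsv",
        )
        if ks_vals:
            hist = wgd.ks_histogram(ks_vals, bandwidth=config.ks_bandwidth,
                                    cap=config.ks_paralog_cap)
            write_tsv(
                pd.DataFrame(hist, columns=["bin_start", "bin_end", "count"]),
                out / f"ks_histogram_{sp}.tsv",
            )
        if len(ks_vals) >= 10 * config.mixture_k:
            fit = wgd.em_fit(
                ks_vals, k=config.mixture_k, seed=_stage_seed(config.seed, 6),
                rate=config.ks_rate_per_year,
            )
            wgd_summary[sp] = {
                "n_pairs": len(ks_vals),
                "weights": [round(w, 6) for w in fit.weights],
                "mus": [round(m, 6) for m in fit.mus],
                "sigmas": [round(s, 6) for s in fit.sigmas],
                "loglik": round(fit.loglik, 6),
                "converged": fit.converged,
                "ages_years": [round(a, 1) for a in fit.ages_years],
                "ages_my": [round(a / 1e6, 2) for a in fit.ages_years],
            }
    write_json(wgd_summary, out / "wgd_fit.json")
    report.add("wgd", species_fitted=sorted(wgd_summary))

    write_json(
        {"seed": report.seed, "stages": report.stages}, out / "run_report.json"
    )
    return report


def _strip_stop(cds_seq: str) -> str:
    """Drop a trailing stop codon so protein/CDS lengths correspond."""
    if len(cds_seq) >= 3 and cds_seq[-3:] in ("TAA", "TAG", "TGA"):
        return cds_seq[:-3]
    return cds_seq
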