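"""Synthetic three-species transcript sets with known evolutionary truth.

The generator emulates the statistical structure the downstream stages
assume, so every stage is testable without real sequencing data:

* shared single-copy ortholog families (one gene per species, pairwise
  divergence driven to target (Ka, Ks) values),
* shared multi-copy families (an extra within-species duplicate),
* species-specific genes,
* within-species paralog pairs whose Ks values follow a truncated
  3-component Gaussian mixture (default parameters: the recent/medium/
  ancient WGD peaks at mu = 0.1144, 0.5281, 1.4347 with sigma = 0.0678,
  0.2294, 0.3103),
* term annotations with planted enriched terms in a designated query set.

Sequences evolve by substitution only: per-site substitution
probabilities are obtained by inverting the Jukes–Cantor correction at
the target Ka/Ks, so round-tripping through the NG86 estimator recovers
the targets. Paralog copies use Ka = 0.2 * Ks (purifying-dominated), which
keeps duplicate pairs detectable at the 40%-identity rule even for the
oldest peak.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codon_evolution import SENSE_CODONS, STOP_CODONS, ng86_site_fraction

__all__ = [
    "SPECIES_TAGS",
    "DEFAULT_PARALOG_MIXTURE",
    "FixtureConfig",
    "FixtureManifest",
    "mutate_to_target",
    "simulate_ks_sample",
    "generate_fixture",
]

SPECIES_TAGS = ("T1", "T2", "T3")

# (weight, mu, sigma): three WGD peaks; means/sds follow the recent, medium
# and ancient peak estimates for the first species; weights are free
# parameters of the generator.
DEFAULT_PARALOG_MIXTURE = (
    (0.40, 0.1144, 0.0678),
    (0.35, 0.5281, 0.2294),
    (0.25, 1.4347, 0.3103),
)

DEFAULT_ORTHOLOG_TARGETS = (
    (0.03, 0.15),
    (0.05, 0.25),
    (0.08, 0.40),
    (0.02, 0.30),
    (0.06, 0.20),
)

_BASES = "ACGT"
_UTR_ALPHABET = "CGT"  # no A: cannot form ATG starts or stop codons
_SENSE = list(SENSE_CODONS)


@dataclass
class FixtureConfig:
    n_shared_single_copy: int = 100
    n_shared_multi_copy: int = 20
    n_species_specific: int = 30  # per species
    gene_length: int = 200  # codons
    ortholog_ks_targets: tuple[tuple[float, float], ...] = DEFAULT_ORTHOLOG_TARGETS
    paralog_mixture: tuple[tuple[float, float, float], ...] = DEFAULT_PARALOG_MIXTURE
    n_paralog_pairs: int = 200  # per species
    planted_terms: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "GO:0000100": (0.05, 10.0),  # strongly enriched in the query set
            "GO:0000200": (0.10, 1.0),  # null term
            "GO:0000300": (0.20, 1.0),  # null term
        }
    )
    seed: int = 0
    utr_length: int = 30
    n_cultivars: int = 0  # per species; 0 = species-level only
    cultivar_ks: float = 0.02

    def __post_init__(self) -> None:
        w = sum(m[0] for m in self.paralog_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"mixture weights sum to {w}, not 1")
        if any(m[2] <= 0 for m in self.paralog_mixture):
            raise ValueError("mixture sigmas must be > 0")
        for name in ("n_shared_single_copy", "n_shared_multi_copy",
                     "n_species_specific", "n_paralog_pairs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gene_length < 100:
            raise ValueError("gene_length must be >= 100 codons")


@dataclass
class FixtureManifest:
    """Ground truth for every generated gene, family, pair and term."""

    genes: dict[str, dict[str, str]]  # species -> gene id -> full unigene seq
    cds: dict[str, str]  # gene id -> CDS (incl. stop codon)
    cds_interval: dict[str, tuple[int, int]]  # planted coding interval
    families: dict[str, dict[str, list[str]]]  # family id -> species -> genes
    family_class: dict[str, str]
    ortholog_truth: list[dict]  # gene_a, gene_b, ka, ks targets
    paralog_truth: list[dict]  # species, gene_a, gene_b, ka, ks targets
    annotations: dict[str, list[str]]  # gene id -> term ids
    query_genes: list[str]  # designated enriched query set (T1-specific genes)
    cultivars: dict[str, dict[str, str]]  # taxon -> family id -> CDS

    def all_gene_ids(self) -> list[str]:
        return sorted(g for sp in self.genes.values() for g in sp)


def _inverse_jc(d: float) -> float:
    """Per-site substitution probability whose JC correction equals d."""
    if d < 0 or not math.isfinite(d):
        raise ValueError(f"target distance must be finite and >= 0, got {d}")
    p = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    if p >= 0.75:
        raise ValueError(f"target distance {d} saturates (p >= 3/4)")
    return p


def _codon_position_choices(codon: str, pos: int) -> tuple[list[str], list[str]]:
    """(synonymous, nonsynonymous) non-stop single-base mutants at pos."""
    from .codon_evolution import _CODON_TO_AA  # shared codon table

    aa0 = _CODON_TO_AA[codon]
    syn, non = [], []
    for b in _BASES:
        if b == codon[pos]:
            continue
        mut = codon[:pos] + b + codon[pos + 1 :]
        if mut in STOP_CODONS:
            continue
        (syn if _CODON_TO_AA[mut] == aa0 else non).append(mut)
    return syn, non


def _mutate_once(
    codons: list[str], p_s: float, p_n: float, rng: np.random.Generator
) -> list[str]:
    """One pass of the per-site substitution process.

    Each codon position is treated as a fractional synonymous site f and
    nonsynonymous site (1 - f); a synonymous substitution lands with
    probability p_s * f, a nonsynonymous one with p_n * (1 - f); stop
    codons are never created.
    """
    out = []
    for codon in codons:
        current = codon
        for pos in range(3):
            syn, non = _codon_position_choices(current, pos)
            nonstop = len(syn) + len(non)
            if nonstop == 0:
                continue
            f = len(syn) / nonstop  # synonymous site fraction at this position
            u = rng.random()
            if u < p_s * f:
                current = syn[rng.integers(len(syn))]
            elif u < p_s * f + p_n * (1.0 - f) and non:
                current = non[rng.integers(len(non))]
        out.append(current)
    return out


def _estimate_gapless(codons_a: list[str], codons_b: list[str]) -> tuple[float, float]:
    """NG86 (ka, ks) of two equal-length ungapped codon lists."""
    from .codon_evolution import CodonAlignment, kaks_pair

    st = kaks_pair(CodonAlignment(tuple(codons_a), tuple(codons_b)))
    return st.ka, st.ks


def mutate_to_target(
    cds: str,
    target_ka: float,
    target_ks: float,
    seed: int | np.random.Generator,
    calibrate: int = 8,
    rel_tol: float = 0.03,
) -> str:
    """Mutated copy of ``cds`` whose re-estimated NG86 (Ka, Ks) hit the targets.

    The substitution process hits synonymous (resp. nonsynonymous) site
    fractions with per-site probability p_s (resp. p_n) obtained by
    inverting the Jukes–Cantor correction at target_ks (resp. target_ka).
    Because pathway averaging over multi-hit codons biases the NG86
    read-back at high divergence, the applied targets are refined over up
    to ``calibrate`` redraws until the re-estimated values fall within
    ``rel_tol`` of the requested ones (the closest draw is returned),
    making the operation an empirical inverse of the estimator. No stop
    codons are ever introduced. Deterministic per seed.
    """
    if len(cds) % 3:
        raise ValueError("CDS length must be divisible by 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if any(c in STOP_CODONS for c in codons):
        raise ValueError("input CDS contains a stop codon")
    if any(c not in SENSE_CODONS for c in codons):
        raise ValueError("input CDS contains a non-sense codon (ambiguity?)")
    # validates the targets (raises on saturation) before any drawing
    _inverse_jc(target_ks)
    _inverse_jc(target_ka)
    if target_ka == 0 and target_ks == 0:
        return cds
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ka_t, ks_t = target_ka, target_ks
    best: tuple[float, list[str]] | None = None
    for _ in range(max(calibrate, 1)):
        cand = _mutate_once(codons, _inverse_jc(ks_t), _inverse_jc(ka_t), rng)
        est_ka, est_ks = _estimate_gapless(codons, cand)
        errs = []
        for tgt, est in ((target_ka, est_ka), (target_ks, est_ks)):
            if tgt == 0:
                errs.append(0.0 if est == 0 else 1.0)
            elif math.isnan(est):
                errs.append(1.0)
            else:
                errs.append(abs(est - tgt) / tgt)
        err = max(errs)
        if best is None or err < best[0]:
            best = (err, cand)
        if err <= rel_tol:
            break
        # multiplicative retargeting toward the requested values
        new_targets = []
        for tgt, est, cur in ((target_ka, est_ka, ka_t), (target_ks, est_ks, ks_t)):
            if tgt == 0:
                new_targets.append(cur)
                continue
            factor = 0.7 if (math.isnan(est) or est <= 0) else tgt / est
            factor = min(max(factor, 0.25), 4.0)
            new_targets.append(min(cur * factor, 5.0))
        ka_t, ks_t = new_targets
    return "".join(best[1])


def simulate_ks_sample(
    mixture: tuple[tuple[float, float, float], ...],
    n: int,
    seed: int | np.random.Generator = 0,
    truncation: tuple[float, float] = (0.0, 2.0),
) -> np.ndarray:
    """n Ks values from a Gaussian mixture, rejection-truncated to (lo, hi].

    Components are (weight, mu, sigma); each draw picks a component then
    resamples until the value falls inside the truncation interval, which
    preserves within-interval component shapes.
    """
    if not mixture:
        raise ValueError("empty mixture")
    w = np.array([m[0] for m in mixture])
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = truncation
    out = np.empty(n)
    comps = rng.choice(len(mixture), size=n, p=w)
    for i, c in enumerate(comps):
        _, mu, sigma = mixture[c]
        while True:
            v = rng.normal(mu, sigma)
            if lo < v <= hi:
                out[i] = v
                break
    return out


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random sense-codon CDS starting with ATG; no stop appended here."""
    body = [_SENSE[rng.integers(len(_SENSE))] for _ in range(n_codons - 1)]
    return "ATG" + "".join(body)


def _random_utr(rng: np.random.Generator, n: int) -> str:
    return "".join(_UTR_ALPHABET[rng.integers(3)] for _ in range(n))


def _embed(rng: np.random.Generator, cds: str, utr: int) -> tuple[str, tuple[int, int]]:
    """CDS + stop codon embedded between A-free UTRs; returns (seq, interval)."""
    stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
    u5, u3 = _random_utr(rng, utr), _random_utr(rng, utr)
    seq = u5 + cds + stop + u3
    return seq, (utr, utr + len(cds) + 3)


def _draw_paralog_ks(rng: np.random.Generator, mixture) -> float:
    return float(simulate_ks_sample(mixture, 1, rng)[0])


def generate_fixture(
    config: FixtureConfig, out_dir: str | Path | None = None
) -> FixtureManifest:
    """Generate the three-species fixture; optionally write FASTA/TSV/JSON.

    Writes one FASTA per species, an annotation TSV (gene_id, term_id,
    ontology) and a JSON truth manifest when ``out_dir`` is given.
    Deterministic: identical (config, seed) give byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    genes: dict[str, dict[str, str]] = {sp: {} for sp in SPECIES_TAGS}
    cds_map: dict[str, str] = {}
    intervals: dict[str, tuple[int, int]] = {}
    families: dict[str, dict[str, list[str]]] = {}
    family_class: dict[str, str] = {}
    ortholog_truth: list[dict] = []
    paralog_truth: list[dict] = []
    cultivars: dict[str, dict[str, str]] = {}
    fam_counter = 0
    targets = list(config.ortholog_ks_targets)

    def add_gene(sp: str, gid: str, cds_nostop: str) -> None:
        # mutation may hit the initiator Met (all its mutants are nonsyn);
        # re-anchor ATG so the planted ORF keeps its start
        cds_nostop = "ATG" + cds_nostop[3:]
        seq, iv = _embed(rng, cds_nostop, config.utr_length)
        genes[sp][gid] = seq
        cds_map[gid] = seq[iv[0] : iv[1]]
        intervals[gid] = iv

    # shared single-copy families
    single_copy_fams: list[str] = []
    for i in range(config.n_shared_single_copy):
        fam = f"fam{fam_counter:05d}"
        fam_counter += 1
        ka, ks = targets[i % len(targets)]
        root = _random_cds(rng, config.gene_length)
        members: dict[str, list[str]] = {}
        per_species_cds = {}
        for sp in SPECIES_TAGS:
            gid = f"{sp}_gene{i:05d}"
            seq = root if sp == "T1" else mutate_to_target(root, ka, ks, rng)
            per_species_cds[sp] = seq
            add_gene(sp, gid, seq)
            members[sp] = [gid]
            if sp != "T1":
                ortholog_truth.append(
                    {"gene_a": f"T1_gene{i:05d}", "gene_b": gid, "ka": ka, "ks": ks}
                )
        families[fam] = members
        family_class[fam] = "shared_single_copy"
        single_copy_fams.append(fam)
        # cultivar sequences derived from each species copy
        if config.n_cultivars > 0:
            for sp in SPECIES_TAGS:
                for c in range(config.n_cultivars):
                    taxon = f"{sp}c{c + 1}"
                    cultivars.setdefault(taxon, {})[fam] = mutate_to_target(
                        per_species_cds[sp],
                        0.2 * config.cultivar_ks,
                        config.cultivar_ks,
                        rng,
                    )

    # shared multi-copy families (extra duplicate cycles through species)
    for i in range(config.n_shared_multi_copy):
        fam = f"fam{fam_counter:05d}"
        fam_counter += 1
        ka, ks = targets[i % len(targets)]
        root = _random_cds(rng, config.gene_length)
        members = {}
        for sp in SPECIES_TAGS:
            gid = f"{sp}_genem{i:05d}"
            seq = root if sp == "T1" else mutate_to_target(root, ka, ks, rng)
            add_gene(sp, gid, seq)
            members[sp] = [gid]
        dup_sp = SPECIES_TAGS[i % 3]
        dup_id = f"{dup_sp}_genem{i:05d}_copy2"
        dup_seq = mutate_to_target(cds_map[members[dup_sp][0]][:-3], 0.06, 0.3, rng)
        add_gene(dup_sp, dup_id, dup_seq)
        members[dup_sp] = sorted(members[dup_sp] + [dup_id])
        families[fam] = members
        family_class[fam] = "shared_multi_copy"

    # species-specific singletons
    for sp in SPECIES_TAGS:
        for i in range(config.n_species_specific):
            fam = f"fam{fam_counter:05d}"
            fam_counter += 1
            gid = f"{sp}_genes{i:05d}"
            add_gene(sp, gid, _random_cds(rng, config.gene_length))
            families[fam] = {sp: [gid]}
            family_class[fam] = "species_specific"

    # within-species paralog pairs (mixture-distributed Ks, Ka = 0.2 Ks)
    for sp in SPECIES_TAGS:
        for i in range(config.n_paralog_pairs):
            fam = f"fam{fam_counter:05d}"
            fam_counter += 1
            root = _random_cds(rng, config.gene_length)
            ks = _draw_paralog_ks(rng, config.paralog_mixture)
            ka = 0.2 * ks
            a_id = f"{sp}_genep{i:05d}"
            b_id = f"{sp}_genep{i:05d}_copy2"
            add_gene(sp, a_id, root)
            add_gene(sp, b_id, mutate_to_target(root, ka, ks, rng))
            families[fam] = {sp: [a_id, b_id]}
            family_class[fam] = "species_specific"
            paralog_truth.append(
                {"species": sp, "gene_a": a_id, "gene_b": b_id, "ka": ka, "ks": ks}
            )

    # term annotations with planted enrichment in T1-specific singletons
    query = sorted(
        g for g in genes["T1"] if g.startswith("T1_genes")
    )
    annotations: dict[str, list[str]] = {}
    all_ids = sorted(cds_map)
    for term, (bg_freq, factor) in sorted(config.planted_terms.items()):
        for g in all_ids:
            p = bg_freq * factor if g in set(query) else bg_freq
            if rng.random() < min(p, 1.0):
                annotations.setdefault(g, []).append(term)

    manifest = FixtureManifest(
        genes=genes,
        cds=cds_map,
        cds_interval=intervals,
        families=families,
        family_class=family_class,
        ortholog_truth=ortholog_truth,
        paralog_truth=paralog_truth,
        annotations={g: sorted(t) for g, t in annotations.items()},
        query_genes=query,
        cultivars=cultivars,
    )
    if out_dir is not None:
        _write_fixture(manifest, Path(out_dir))
    return manifest


def _write_fixture(manifest: FixtureManifest, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for sp, sp_genes in manifest.genes.items():
        with open(out_dir / f"{sp}.fasta", "w") as fh:
            for gid in sorted(sp_genes):
                fh.write(f">{gid}\n")
                seq = sp_genes[gid]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
    with open(out_dir / "annotations.tsv", "w") as fh:
        fh.write("gene_id\tterm_id\tontology\n")
        for gid in sorted(manifest.annotations):
            for term in manifest.annotations[gid]:
                fh.write(f"{gid}\t{term}\tGO\n")
    truth = {
        "families": manifest.families,
        "family_class": manifest.family_class,
        "ortholog_truth": manifest.ortholog_truth,
        "paralog_truth": manifest.paralog_truth,
        "query_genes": manifest.query_genes,
        "cds_interval": {g: list(v) for g, v in manifest.cds_interval.items()},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
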