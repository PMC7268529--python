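# ploidtrace

Transcriptome molecular-evolution analysis for sets of related species:
coding-region identification, gene-family delimitation, single-copy-ortholog
phylogeny, Ka/Ks selection screening, functional enrichment, and
whole-genome-duplication (WGD) dating from paralog Ks age distributions.

## Who this is for

Researchers with assembled transcriptomes (unigene FASTA files) for two or
more related species — typically non-model plants without reference
genomes — who want the classical comparative-transcriptomics readouts:
which gene families are shared or species-specific, how the taxa relate,
which single-copy orthologs show positive selection, and when ancient
polyploidization events occurred.

## The models at the core

**Ka/Ks (NG86).** For a pair of coding sequences, each sense codon
contributes fractional synonymous sites
`s = Σ_pos (#synonymous non-stop mutants / #non-stop mutants)` and
nonsynonymous sites `3 − s`; codon differences are decomposed into
synonymous/nonsynonymous steps by averaging over all minimal mutational
pathways (stop-crossing pathways excluded); proportions `p = Sd/S`,
`Nd/N` are corrected for multiple hits with Jukes–Cantor
`d = −(3/4) ln(1 − 4p/3)`. Pairs with Ks ≤ 0.1 (potential paralogs) or
saturated distances are excluded; the rest are classed as strong positive
(Ka/Ks > 1), weak positive (0.5 < Ka/Ks ≤ 1), neutral (0.1 ≤ Ka/Ks ≤ 0.5)
or purifying (Ka/Ks < 0.1), with a two-sided Fisher's exact test on
`[[Sd, S−Sd], [Nd, N−Nd]]` as a validity gate.

**Gene families.** All-vs-all Smith–Waterman (BLOSUM62, affine 11/1) with
a Karlin–Altschul-style E-value proxy at a 1e-7 cutoff defines the
homology graph; Markov clustering (expansion/inflation, inflation 2.0)
delimits families, classified as shared single-copy, shared multi-copy,
partial-shared or species-specific, with three-set Venn accounting.

**Phylogeny.** Per-family progressive alignment → concatenated
supermatrix → pairwise-deletion distances (p-distance or Jukes–Cantor) →
Saitou–Nei neighbor joining, with column-bootstrap support (1000
replicates by default).

**Enrichment.** Upper-tail hypergeometric probability
`P(X ≥ m) = 1 − Σ_{i<m} C(M,i) C(N−M, n−i) / C(N,n)` per annotation term,
Bonferroni-corrected over the tested terms, significant at corrected
p < 0.05.

**WGD dating.** Within-species paralog pairs (≥ 40% nucleotide identity
over ≥ 300 bp of local alignment) give a Ks sample; values in (0, 2] are
binned at bandwidth 0.03 and fitted with a 3-component Gaussian mixture
by EM; each peak mean μ converts to an age `T = Ks / (2r)` with
`r = 6.1 × 10⁻⁹` synonymous substitutions/site/year, so modal Ks values
of 0.11, 0.53 and 1.42 date duplication bursts to 9.02, 43.44 and 116.39
million years ago.

## Worked example

Fit the three-peak Ks age distribution and date the duplication events:

```python
from ploidtrace import simulate_ks_sample, em_fit, age_from_ks

mix = ((0.40, 0.1144, 0.0678), (0.35, 0.5281, 0.2294), (0.25, 1.4347, 0.3103))
x = simulate_ks_sample(mix, 5000, seed=7)          # paralog Ks values in (0, 2]
fit = em_fit(list(x), k=3, seed=7)
print("means :", [round(m, 4) for m in fit.mus])
print("sigmas:", [round(s, 4) for s in fit.sigmas])
print("ages  :", [round(a / 1e6, 2) for a in fit.ages_years], "million years")
```

prints

```
means : [0.1195, 0.556, 1.4313]
sigmas: [0.0596, 0.2198, 0.257]
ages  : [9.8, 45.57, 117.32] million years
```

— the three fitted peaks recover the generating mixture (recent peak
thinnest, oldest thickest, as post-WGD diploidization predicts), and the
peak means divided by `2r` date the three duplication bursts. The exact
conversion at the modal Ks values is
`round(age_from_ks(0.11) / 1e6, 2) == 9.02` million years.

End-to-end on files:

```bash
ploidtrace simulate --seed 11 --out fixture/           # synthetic 3-species data
ploidtrace run-all --fasta T1=fixture/T1.fasta --fasta T2=fixture/T2.fasta \
    --fasta T3=fixture/T3.fasta --annotation fixture/annotations.tsv \
    --out run/ --seed 3
```

`run/` then contains `coding_regions.tsv`, `homology_edges.tsv`,
`families.tsv` + `venn.json`, `kaks_pairs.tsv`, `enrichment.tsv`,
`species_tree.nwk`, per-species `paralog_pairs_*.tsv` and
`ks_histogram_*.tsv`, `wgd_fit.json` (mixture parameters and ages), and a
`run_report.json` whose per-filter bookkeeping (`n_in = n_out + removed`)
audits every stage. Identical config and seed give byte-identical
artifacts.

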