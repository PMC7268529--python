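# Methods

`ploidtrace` re-implements, as a tested library, a transcriptome-only
molecular-evolution workflow for sets of related plant species: identify
coding regions in assembled transcripts (unigenes), delimit gene families
across species, build a phylogeny from single-copy families, screen
single-copy ortholog pairs for selection with Ka/Ks, test gene sets for
functional enrichment, and date whole-genome duplications (WGD) from the
Ks age distribution of within-species paralog pairs. This note records the
models, the defaults and why, and what the synthetic data does and does
not establish.

## Coding regions

Annotation-first resolution mirrors the usual transcriptome practice:
when a protein-database hit table is supplied (columns `unigene_id,
database, evalue, strand, frame, start, end`), hits with E-value >= 1e-5
are discarded and the surviving hit from the highest-priority database
(Nr > Swiss-Prot > KEGG > COG, then smallest E-value) fixes the strand and
reading frame; the hit interval is snapped to the frame's codon grid and
truncated at the first in-frame stop so the coding-region invariants
(length divisible by 3, no internal stop) always hold. Without hits, a
deterministic six-frame scan returns the longest ORF (ATG through stop or
through the last complete codon) of at least 150 nt; ties prefer the `+`
strand, then the lower frame index, then the smaller start. The 150 nt
floor (50 codons) is the conventional minimum for a credible ORF in
transcript data; it is exposed as `min_len_nt`. Codons containing `N`
translate to `X` and are never treated as stops. The heuristic is a
deliberate, provenance-tagged stand-in for a trained coding-potential
model: the `source` field (`annotation` vs `orf_heuristic`) keeps the two
routes distinguishable downstream.

## Homology graph and gene families

Protein pairs are aligned with Smith–Waterman (BLOSUM62, affine gaps
open 11 / extend 1, via Biopython's `PairwiseAligner`). Significance uses
a Karlin–Altschul-style proxy `E = K * m * n * exp(-lambda * S)` with the
published gapped BLOSUM62-11/1 parameters (lambda = 0.267, K = 0.041) and
per-pair search space `m * n`; edges with E <= 1e-7 are homologs. Because
the search space is fixed rather than database-dependent, the proxy is an
ordering device with a nominal cutoff, not a calibrated BLAST E-value —
determinism was preferred over absolute fidelity. All-vs-all cost is
bounded by a k-mer prefilter (>= 2 shared 4-mers before any alignment);
unrelated 200-residue proteins essentially never pass it.

Families come from Markov clustering (MCL) of the score-weighted graph:
self-loops at each node's maximum incident weight, column-stochastic
normalisation, then alternating expansion (matrix square) and inflation
(elementwise power 2.0 + renormalisation) to convergence (max change
< 1e-6, <= 200 iterations); clusters are connected components of the
converged flow matrix (entries > 1e-5). This is a simplification of
OrthoMCL's ortholog/in-paralog weighting; the inflation parameter is
exposed. Copy-classes: `shared_single_copy` (exactly one gene in each of
the three species), `shared_multi_copy` (all species present, some with
>= 2), `partial_shared` (two species), `species_specific` (one). Venn
accounting reports family and gene counts per region of the three-set
diagram and must conserve totals.

## Ka/Ks (NG86)

The estimator is Nei–Gojobori (1986) pathway counting on protein-guided
codon alignments (proteins aligned globally with BLOSUM62 11/1, then
back-translated; gaps become whole gap codons). Per sense codon, each
position contributes a fractional synonymous site (synonymous non-stop
single-base mutants over non-stop mutants); `S + N = 3 x` compared columns
exactly. Codon differences are averaged over all minimal mutational
pathways, excluding pathways through stop codons unless all are blocked.
Proportions are corrected with Jukes–Cantor `d = -(3/4) ln(1 - 4p/3)`;
`p >= 3/4` yields a not-applicable (NaN) value rather than an error.
NG86 was chosen over ML codon models for determinism and transparency;
its known bias at high divergence is one reason the paralog stage caps
Ks at 2.

Validity of each pair is screened with a two-sided Fisher's exact test on
`[[Sd, S-Sd], [Nd, N-Nd]]` (fractional counts rounded half-up — the exact
test needs integers; the rounding rule is fixed for determinism).
Selection classes follow the operational bins: excluded if Ka or Ks is
not applicable or Ks <= 0.1 (potential paralogs / assembly redundancy);
then strong positive (Ka/Ks > 1), weak positive (0.5 < Ka/Ks <= 1),
neutral (0.1 <= Ka/Ks <= 0.5), purifying (Ka/Ks < 0.1). Boundary values
land in the closed middle bins; a pair with Ka = 0 and applicable Ks is
kept with ratio 0 (purifying) rather than dropped. A posterior-probability
site gate has no defined meaning in a pairwise counting framework and is
not implemented; the Fisher gate is the only validity screen.

## Phylogeny

Per-family multiple alignment is guide-tree progressive profile alignment:
k-mer distances (k = 3 for protein, 6 for nucleotide) define a greedy
nearest-pair merge order; profiles are merged by global affine-gap
dynamic programming (sum-of-pairs column scores; BLOSUM62 or +5/-4;
open -10 / extend -1). Family alignments are concatenated into a
supermatrix (missing taxa gap-filled; a partition table records family
boundaries). Distances use pairwise deletion — complete deletion would
discard most columns whenever one taxon is missing from one family —
under p-distance (default) or Jukes–Cantor; "substitutions per site" is
the branch-length unit either way, which is why p-distance is an
acceptable default at the low divergences involved. Trees are Saitou–Nei
neighbor joining with the Q-criterion, deterministic lexicographic
tie-breaks, and negative branch-length estimates clamped to zero.
Bootstrap support (default 1000 replicates) resamples supermatrix columns
with replacement and reports the percentage of replicates containing each
internal bipartition of the point tree; replicates whose resample leaves
some pair with no comparable columns count as failed replicates.

## Enrichment

The upper-tail hypergeometric probability
`P(X >= m) = 1 - sum_{i<m} C(M,i) C(N-M,n-i) / C(N,n)` is evaluated
through scipy's survival function (log-space internally). `N` and `n`
count only annotated genes (the annotated universe); only terms observed
in the query (m >= 1) are tested and their number is the Bonferroni
factor; significance means corrected p < 0.05. The "corrected" reading of
the significance threshold is an interpretation choice (the workflow
description is ambiguous) and is configurable via `correct=False`.
The query is any gene set — species-specific genes and positively
selected orthologs are the two sets the pipeline tests by default.

## WGD dating

Within-species duplicate (paralog) pairs are CDS pairs whose best local
nucleotide alignment (match +2 / mismatch -3, gap open 5 / extend 2,
contiguous 11-mer seeding as a prefilter) reaches >= 40% identity over
>= 300 aligned columns. Discontiguous-seed searching was traded for
contiguous seeding because the 40%/300 bp acceptance thresholds, not the
seeding scheme, carry the method. Each pair's Ks comes from the NG86
route above; values outside (0, 2] are discarded (saturation), the rest
are binned at bandwidth 0.03 (67 bins over (0, 2.01]; the last bin is
only partially covered by the data range) and fitted with a k = 3
univariate Gaussian mixture by EM: quantile-spaced means with pooled-sd
initialisation, log-space E-step, weighted-moment M-step, convergence
when the log-likelihood improves by < 1e-6, best of 5 seeded restarts,
failure (sigma < 1e-4 or an emptied component) triggers a restart. The
three peaks model the recent, medium and ancient duplication bursts; k is
fixed at 3 by design and exposed for criticism. Each fitted mean converts
to an age with `T = Ks / (2 r)`, `r = 6.1e-9` synonymous substitutions
per site per year (plant average): modal Ks of 0.11, 0.53 and 1.42 give
9.02, 43.44 and 116.39 million years.

Two deliberate fidelity choices: the mixture is fitted on the raw Ks axis
despite the (0, 2] truncation (no truncated-likelihood correction), which
biases the oldest peak's mean slightly downward — the fitted mean of the
1.43 component on truncated data sits near 1.41; and all pairs of a
multi-copy family are kept (c copies contribute c(c-1)/2 pairs), since
only the Ks > 2 filter is part of the method. A per-family weighting mode
would be the natural correction but is intentionally not the default.

## Synthetic data

The generator emulates three species' transcript sets with known truth:
shared single-copy families (one gene per species; the second and third
species evolve from the first at per-family (Ka, Ks) targets), shared
multi-copy families (one species carries an extra duplicate at Ks ~ 0.3),
species-specific singletons, and within-species paralog pairs whose Ks
follow the three-peak mixture above (weights 0.40 / 0.35 / 0.25 — free
parameters of the generator; peak positions and widths are the study
values) with Ka = 0.2 Ks, a purifying-dominated ratio that keeps even
Ks ~ 1.4 duplicates above the 40% nucleotide-identity detection rule.
Genes are uniform random sense codons behind an ATG (no codon-usage
bias), embedded between A-free UTRs so the planted ORF is provably the
unique qualifying one, and evolve by substitution only.

`mutate_to_target` inverts the estimator: per-site substitution
probabilities come from inverting the Jukes–Cantor correction at the
targets, and because pathway averaging over multi-hit codons biases the
NG86 read-back at high divergence, the applied rates are refined over up
to 8 seeded redraws until the re-estimated (Ka, Ks) fall within 3% of the
request (closest draw wins). Truncation of Ks samples is by rejection,
not clipping, preserving within-interval component shapes.

What passing tests on this data do not show: robustness to assembly
artifacts (chimeras, fragmented ORFs, redundant isoforms), indels and
alignment error, codon-usage and rate heterogeneity, or database-driven
annotation noise — real transcriptomes add all of these. The fixture
establishes that the machinery is correct, deterministic and internally
consistent, not that the biological estimates from any particular dataset
are accurate.

## Problem sizes and numerical choices

Test fixtures use tens of families per class, 200-codon genes and ~40
paralog pairs per species — large enough that every stage's statistical
behaviour is exercised (family recovery >= 95%, mixture means within
0.05, classification accuracy >= 95%) while the full pipeline remains a
desk-scale computation; mixture-recovery checks use n = 5000 Ks values
per seed. Floating-point policy: NaN is the universal not-applicable
marker; all orderings (gene ids, taxa, terms, tie-breaks) are explicit so
identical seeds give byte-identical artifacts; EM log-likelihood is
asserted non-decreasing; NJ clamps negative branch lengths to zero with
the standard justification that they are estimation noise.

## Known limitations

- The ORF heuristic under-calls genuinely non-ATG or frame-shifted coding
  regions; real ESTScan-style output can be supplied through the hit
  table instead.
- The E-value proxy is nominal; at other search-space scales the 1e-7
  cutoff corresponds to a different score threshold.
- NG86 saturates above Ks ~ 2 and is biased at high Ka; cross-checking
  with ML codon models is out of scope.
- The species tree is built at species level (three taxa); cultivar-level
  trees are supported by the phylogeny module given per-cultivar
  sequences but the pipeline does not fabricate cultivars from species
  data.
- Gaussian peaks on a truncated axis underestimate the oldest peak's mean
  by a few hundredths of a Ks unit; a truncated-mixture likelihood would
  remove this at the cost of departing from the reference procedure.
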