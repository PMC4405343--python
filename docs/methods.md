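# Methods

This note records the models, rules, and design choices behind each stage,
what the synthetic generator does and does not emulate, and the numerical
conventions that make runs reproducible.

## Coordinates and gene models

All coordinates are 0-based half-open internally; GFF3 and VCF are 1-based
at the I/O boundary and converted exactly once, in `leafscreen.io`. A gene
carries 1–3 transcripts, each with CDS / 5'UTR / 3'UTR blocks; introns are
the gaps between exonic blocks; the total CDS length of every transcript is
a positive multiple of 3 (validated at construction). The promoter is a
2,000 bp strand-aware window upstream of the TSS, truncated at chromosome
edges. 2 kb is a common convention for rice regulatory windows; the width is
a constructor parameter, not a constant.

Every position gets exactly one region label with the precedence
**CDS > 5'UTR > 3'UTR > intron > promoter > intergenic**. The precedence
exists so that a SNP lands in exactly one class and per-region percentages
are disjoint and sum to 100.

Amino-acid property classes are pinned to: hydrophobic {A,V,L,I,M,F,W,P},
polar-uncharged {S,T,N,Q,C,Y}, basic {K,R,H}, acidic {D,E}, special {G},
stop {\*}. Glycine is kept as its own "special" class because the screen's
canonical consequence call is a glycine→serine substitution in a sulfate
transporter, where the interesting fact is the small/flexible residue being
replaced by a phosphorylatable polar one.

## Variant calling and annotation

Calling is the per-site threshold rule: called iff depth ≥ 10 AND mismatch
count ≥ 5 AND mismatch fraction ≥ 35%. The fraction is interpreted as
`alt_count / depth ≥ 0.35` (configurable); there is deliberately no
genotype-likelihood model — the rule itself is the method. Mapping-region
filtering keeps a variant only when its region reaches 95% identity and
100% HSP coverage; variants with no region statistics are dropped
conservatively and counted in a log message.

Consequence annotation reconstructs the codon strand-aware from the
transcript's spliced CDS. When several transcripts' CDS cover the site, all
are annotated and the reported effect is the worst case
(stop_gain > stop_loss > nonsynonymous > synonymous) — the choice of
"longest transcript vs. all transcripts" is a convention; we report
per-transcript results and summarise worst-case. Multi-allelic sites are
one `VariantCall` per alternative allele.

Region summaries report counts and one-decimal percentages per accession
plus an across-accession average row: counts are averaged and rounded to
the nearest integer, percentages recomputed from the averaged counts. The
same convention reproduces the reference tables' printed averages exactly
(e.g. 713,114 average SNPs, 14.5% CDS, 16.4% intron — the intron average
recomputes to 16.4 from the per-accession rows even though the narrative
mean of the per-accession percentages is 16.3; we report the computed
value).

## Structural events

A coverage gap is a maximal run of bases at depth < 4 whose two full 1-kb
flanks average > 20×. *Mean* flank depth was chosen over *min* for
robustness to single-base noise (min is available via `flank_stat="min"`);
runs truncated by a chromosome end have no full flank and are rejected.
Gene loss is decided directly from per-base depth — a gene is lost iff the
fraction of its CDS bases (union over transcripts) covered at ≥ 4× is
< 20% — rather than from gap overlap; detected gaps are attached as
evidence only. The ≥ 4× breadth threshold deliberately reuses the gap
threshold; whether "coverage" means ≥1× or ≥4× breadth is an assumption,
flagged here, and both are parameters.

Gain contigs are filtered to ≥ 2 kb and deduplicated greedily longest-first:
a contig is redundant when it aligns (either strand, infix edit-distance
via edlib) to an already-retained contig within a combined budget of 5%
divergence plus 5% unaligned length. Assembly and functional annotation of
contigs are upstream concerns; classification consumes a contig→class map.

## Population structure

Genotypes are coded 0/1/missing per accession × site; distance is the
mismatch fraction over pairwise-complete sites (pairwise deletion; raw
counts by flag). Neighbor joining is the standard Saitou–Nei agglomeration
with two pinned conventions: ties in the Q-matrix minimisation go to the
lowest index pair, and negative branch-length estimates are clamped to zero
with the deficit logged. On additive matrices the algorithm is exact, which
the tests verify against path-length oracles and cross-check against an
independent NJ implementation. Bootstrap support resamples site columns
with replacement and counts, per internal bipartition of the original tree,
the fraction of replicate trees containing it. Admixture/ancestry
estimation and tree rendering are out of scope.

## Expression and enrichment

Fold change is `log2((FPKM_a + ε) / (FPKM_ref + ε))` with ε = 1 by default;
a gene is differentially expressed at |log2| ≥ 1 (2-fold) at *any* of the
three stages (all-stage rule by flag). The GSEA running sum adds
`|r|^p / Σ_hits |r|^p` on set members and subtracts `1/(N − N_hit)`
otherwise; ES is the signed extremum of the curve. Defaults pin what the
emulated design leaves open: ranking metric = per-gene log2 fold change vs.
the reference accession (mean over stages for category calls), weight
exponent p = 1 (p = 0 available), and — because the design has exactly one
library per accession × stage, so sample permutation is impossible —
**gene-label permutation** as the null. The permutation p-value is
`(1 + #{|ES_perm| ≥ |ES_obs|}) / (n_perm + 1)`, always in (0, 1]. A gene set
covering the whole ranking has ES defined as 0; an all-zero metric falls
back to unweighted (p = 0) increments. The reference accession is reported
neutral against itself without testing.

## Disruption screen and candidate integration

A transcript is broken in an accession when a gap overlaps its CDS or a CDS
indel has length ≢ 0 (mod 3); gap wins ties so the mechanism column is
deterministic. Disruption matrices (broken = 1) are clustered with
Euclidean distance — two accessions differing in k entries sit at √k — and
average linkage (complete/single by flag); scipy's agglomeration order
makes the dendrogram deterministic.

Pathway enrichment is a two-sided Fisher's exact test (one-sided "greater"
by flag) on the 2×2 table (DE∩pathway, DE\pathway, pathway\DE, rest) at
p ≤ 0.05. Candidates are genes of enriched pathways that are additionally
disrupted in ≥ 1 accession **or** DE at ≥ 1 stage. This integration rule is
our pinned formalisation of a screen whose exact filter combination was
never fully specified; the literature-mining step that produced the
original pathway collections is replaced by user-supplied GMT gene sets, so
the original candidate counts are not reproducible and are not targets.

## The synthetic generator

`simulate_study` produces the default desk-scale study: 1 chromosome of
500 kb, 60 genes, 10 accessions (Dongjin reference, Jado, Hwangdo, and
seven mutant lines), 3 stages. Scales were chosen so the full pipeline and
test suite run in seconds on one CPU while every downstream statistic still
has enough signal to be scored against truth.

* **SNPs**: private SNPs at rate 0.002/bp per accession (~0.2%, the order
  of magnitude separating rice cultivars from the reference), clade-shared
  blocks for {D052, D056, D120} and {D122, D128, D131}, and a 10× rate for
  Hwangdo, emulating its divergent background. Five forced CDS SNPs per
  accession carry known synonymous/nonsynonymous truth labels, plus the
  canonical GGC→AGC (G→A, Gly→Ser) substitution implanted into the six
  bright-leaf mutant lines.
* **Depth**: Poisson with mean 40 (negative binomial overdispersion
  optional); deleted intervals are forced to residual 0–3× reads.
  Poisson was chosen because the emulated design states only a mean depth.
* **Losses/gains/disruptions**: 12 deletions (full gene ± pad, or an
  interval covering ~90% of the CDS), 8 novel contigs of 2–5 kb plus short
  and duplicate decoys to exercise the contig filter, 6 frameshift indels
  (1–2 bp) placed in transporter-family CDS. Because transcripts of a gene
  share one CDS, a frameshift breaks all of them, and the truth set records
  all.
* **Expression**: baseline FPKM log-normal (ln-mean 3, ln-σ 1; median ≈ 20),
  multiplicative log-normal noise with σ = 0.2 per measurement. Implants
  (fold 4, sustained across stages): photosynthesis set down and
  cellular-homeostasis set up in every non-reference accession, flavonoid
  set up in Jado / down in Hwangdo, and disrupted transporter genes down in
  their damaged accession.

What the generator does **not** emulate: read-level data (no FASTQ; mapping
is out of scope, so depth is simulated directly), selection on coding
changes (random SNPs are mostly nonsynonymous, unlike real cultivar
polymorphism where synonymous changes dominate), linkage structure beyond
the clade blocks, biological replicates, and genome-scale pathway
collections. Consequently, at desk scale the implanted expression
categories make the DE background dense (≈ half the 60-gene universe), so
the small transporter pathways do not reach Fisher significance in the
default study and the macronutrient-transport group surfaces through the
disruption clustering rather than the enrichment route; passing tests show
the machinery is correct under the stated conditions, not that a real
40k-gene screen would have the same power profile.

## Reproducibility and numerics

Every stochastic stage takes an explicit seed; the pipeline derives
per-stage seeds from one master seed via `numpy.random.SeedSequence`, and
reruns are byte-identical. Bootstrap and permutation counts default to
1,000. Fisher p-values come from `scipy.stats.fisher_exact` and are tested
to ≤ 1e-12 against an exhaustive hypergeometric enumeration; GSEA scores
are tested against a brute-force walk; NJ against path-length oracles. The
acceptance script (`scripts/acceptance.py`) re-derives all headline
quantities from scratch at problem sizes noted in its output (10-row
summary tables, the 60-gene default study, 200 null GSEA simulations,
~2,000 Fisher tables, 20 additive matrices, 1,000 bootstrap replicates).

## Known limitations

* Consequence calls handle single-base substitutions in CDS; splice-site
  and regulatory effect prediction are out of scope.
* The contig redundancy test is an edit-distance heuristic, not a full
  self-alignment; highly repetitive contigs may be over-collapsed.
* Gene-label permutation under-represents inter-gene correlation, so GSEA
  p-values are anti-conservative on strongly co-expressed sets; the type-I
  calibration in the acceptance suite covers the independent-gene null
  only.
* With a single library per condition, DE calls are threshold rules, not
  statistical tests; no FDR control is applied across pathways (the screen
  uses a fixed p ≤ 0.05, as designed).
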