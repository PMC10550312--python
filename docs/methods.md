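# Methods

This note documents the models, rules, and numerical choices behind `panepi`,
and what the synthetic-data generator does and does not emulate.

## Epiallele model

Each gene in each genome carries one of three heritable methylation states
over its coding sequence (CDS):

* **UM** (unmethylated): mCG and mCHG both ≤ 0.05;
* **gbM** (gene-body methylation): mCG ≥ 0.2 with mCHG ≤ 0.05 — methylation
  solely in the CG context;
* **teM** (TE-like methylation): mCG and mCHG both ≥ 0.4 — the
  heterochromatin-like joint signature of transposons.

Methylation levels are measured over CDS only. UTRs are excluded because
their boundaries are often imprecisely annotated and can overlap nearby TEs;
introns are excluded because TE insertions give them methylation unrelated to
the flanking exons. A gene must have at least 40 CG and 40 CHG cytosines each
spanned by at least one read to be called at all (`low_coverage` otherwise);
genes with intermediate levels are `undetermined`. Neither counts as a
defined epiallele anywhere downstream.

Two wording conventions exist for the thresholds (strict `<`/`>` versus
inclusive `≤`/`≥`). The package defaults to inclusive comparisons
(`ThresholdConfig(boundary_inclusive=True)`) because the boundary itself
carries negligible probability mass at ≥ 20× depth with ≥ 40 sites; the
strict variant is one flag away and changes essentially nothing in practice.

The per-gene level is read-weighted: `Σ n_meth / Σ n_total` over covered
cytosines in the region. A per-site average (mean of `n_meth/n_total`) is
available behind `weighted=False` for sensitivity analysis; the read-weighted
form is the default because it is robust to uneven coverage and matches the
thresholding semantics (a level is a proportion of methylated cytosine
observations). On simulated data the two differ by less than the sampling
noise of either.

## Metagene profiles

Genes are aligned at TSS and polyA; methylation is averaged in 100-bp bins
over 3 kb upstream, 3 kb downstream, and an internal window inside each gene
end. The internal window defaults to 1.5 kb and is configurable to 2 kb (both
conventions are in circulation; the default follows the narrower one).
Within a gene and bin, levels are read-weighted over covered sites; across
genes, bins are unweighted means over contributing genes, so deeply
sequenced genes do not dominate. Internal bins that would extend beyond a
short gene are skipped for that gene, and for the 3′-anchored window the
surviving bins occupy the slots nearest the polyA. When a gene is shorter
than twice the internal window the two internal windows overlap by
construction; they are computed independently, as in standard
fragmented-region metagene tools.

## Pangene analysis

A pangene is the set of homologous genes at one syntenic position across the
pan-genome. Cells of the pangene table hold one gene (singleton), several
genes (tandem-duplicate array), a coordinate placeholder (homologous DNA,
no annotated gene), or nothing.

1. **Core selection.** A pangene is core iff no cell is missing. Coordinate
   placeholders preserve core status but contribute no genes.
2. **Intact filter.** Tandem duplications often capture gene fragments, and
   split annotations can masquerade as duplicates. Every gene is therefore
   required to have a cumulative CDS length within (strictly less than) 10%
   of the median CDS length of the pangene's *singletons*. Pangenes with no
   singleton are excluded from pangene analyses. Filtering never revokes
   core status. Partial duplicates are ignored when deciding whether a cell
   is a singleton or a duplicate array.
3. **Classes.** After filtering: `one_to_N` (≥ 1 intact duplicate array,
   ≥ 2 singletons with defined epialleles, all of one type), `stable_1to1`
   (all singletons, ≥ 2 defined epialleles, one type), `unstable_1to1` (all
   singletons, ≥ 2 types, every represented type in ≥ 2 genomes; subtype is
   the sorted type combination), else `other`. Undefined epialleles are
   neutral: they never qualify or disqualify a uniformity requirement. For
   a pangene with three represented types where one type has a single gene,
   the "every represented type ≥ 2" reading is applied, so it falls to
   `other`.
4. **Duplicate epiallele counts.** For 1-to-N pangenes, duplicate genes are
   pooled by their singleton type; the `min_copy` stratification (2 or 4)
   uses the post-filter intact copy count of each cell, since fragments are
   not evidence of an extra functional copy.

## Expression statistics

Per-pangene mean TPM per epiallele type uses the indicator form
`mean_i(e) = Σ_j DT[i,j]·I_e[i,j] / Σ_j I_e[i,j]`. The gbM−UM analysis runs
over unstable UM-gbM pangenes (each type present in ≥ 2 genomes by
construction) and reports, per tissue: the median and mean of the
differences d_i, an exact two-sided binomial sign test on the counts of
positive versus negative d_i (ties excluded from n — the classical sign-test
convention; a tie-inclusive p is reported alongside because the convention is
not universal), a two-sided Wilcoxon signed-rank test (zeros dropped; exact
distribution for ≤ 25 untied values, tie-corrected normal approximation
otherwise), and the median difference normalized by the mean UM TPM of the
same pangene set and tissue, in percent. Medians are preferred because a few
highly expressed epialleles dominate means. No multiple-testing correction
is applied across tissues; tissues are reported independently.

The quantitative analysis treats mCG (or mCHG) as a continuous variable:
per-pangene Pearson r against TPM across genomes, over singleton cells with
coverage ≥ 40/40, after dropping genes with mCHG > 0.05 in the mCG variant
(to exclude the TE-like confound). A pangene is informative only if its
methylation range across genomes is ≥ 0.2, it has ≥ 3 usable genes, and both
variables have non-zero spread. The summary is the median/mean r and the
positive:negative count ratio.

The chi-square comparison of duplicate epiallele proportions between
copy-number strata is Pearson's test without continuity correction.

## Synthetic-data generator

The generator emulates the statistical structure of a 26-genome maize-like
NAM panel: 2,000 pangenes by default, ten tissues, ~20× methylome depth.

* **Epiallele structure.** Ancestral frequencies UM 0.57 / gbM 0.31 /
  teM 0.12 (within the observed per-genome ranges; they must sum to 1).
  3.5% of pangenes are epiallelically unstable, with pair weights
  UM-gbM : UM-teM : gbM-teM : UM-gbM-teM = 0.930 : 0.028 : 0.031 : 0.011
  (the observed subtype proportions) and a per-pangene minor-type fraction
  uniform on [0.2, 0.5].
* **Duplication.** Each gene cell becomes a tandem array with probability
  0.012; copy numbers are 2 plus a geometric tail capped at 47. Duplicate
  copies switch epiallele from the cell's singleton state at rates
  UM→gbM 0.007, UM→teM 0.015, gbM→UM 0.069, gbM→teM 0.036 (observed duplicate
  proportions); teM→UM 0.03 and teM→gbM 0.02 are the package's own choices
  (not reported in the source material because teM 1-to-N pangenes are too
  few to quantify). 10% of duplicate copies are partial (40–85% of the base
  CDS length), exercising the intact filter. The copy-number dependence of
  switch rates (the observed enrichment of teM duplicates at copy number
  ≥ 4) is *not* emulated; switch rates are uniform across copy numbers.
* **Methylation.** Two-level Beta model: a gene-level mean drawn around the
  type mean (UM mCG/mCHG ≈ 0.01; gbM mCG 0.80, mCHG 0.02; teM mCG/mCHG 0.85),
  then per-cytosine levels around the gene level (concentration 2, giving
  realistically dispersed site levels), with binomial methylated counts at
  Poisson(20) read depth. Low-methylation contexts use a high gene-level
  concentration (600) so the per-type distributions are genuinely well
  separated from the 0.05 boundary — real UM/gbM genes have near-zero mCHG,
  and the classifier-correctness tests presuppose this separation; with
  heavy-tailed gene-level spread the residual misclassification is a
  property of the data, not the caller. High-methylation means use
  concentration 50. 5% of genes are simulated with fewer than 40 CG/CHG
  sites to exercise the `low_coverage` path. Genic cytosines are placed on
  an even grid with random phase inside CDS (distinct residue classes per
  context, so no position collisions); flanks get sparse sites whose level
  follows the type — teM genes are methylated straight across the TSS,
  UM/gbM genes get an mCHH bump within 500 bp upstream (0.08 versus 0.02
  background).
* **Expression.** log TPM = pangene baseline N(log 20, 0.3²) + per-tissue
  effect N(0, 0.2²) + per-gene noise N(0, 0.15²), exponentiated, times an
  epiallele multiplier: gbM ×(1+δ) with δ = 0.03 by default, attenuated to
  δ = 0.005 in endosperm (the epigenetically distinct tissue); teM ×0.02
  (strong silencing). The moderate baseline spread models the within-subset
  spread of comparable pangenes rather than the full dynamic range of a
  transcriptome; with a heavier-tailed baseline the mean-normalized *median*
  difference systematically understates δ (the median of d_i scales with the
  median baseline while the normalizer is the mean), and even at these
  settings the recovered normalized median runs slightly below 100·δ
  (≈ 2.6–2.9% for δ = 3%). This shrinkage is a property of the estimator,
  shared with any analysis that normalizes a median by a mean on skewed
  data.
* **Determinism.** All randomness derives from one integer seed through
  named substreams, so any product is byte-identical regardless of the order
  in which products are requested.

What passing tests show — and do not. The generator produces idealized TPM
(no count noise unless the Poisson `counts()` product is used), independent
genomes (no phylogenetic structure among inbreds), a single chromosome with
uniform intergenic spacing, and no sequence context. Recovery results
therefore validate the analysis machinery (filters, matrix algebra, tests),
not robustness to alignment artifacts, mapping bias, or population structure
in real panels.

## Problem sizes

Defaults are sized so a full validation runs on a laptop-class single CPU:
2,000 pangenes × 26 genomes (~52,000 genes, ~14M cytosines) for classifier
validation; 50 replicates of 2,000 pangenes for effect recovery; 200
replicates of 300 pangenes for null calibration; 10,000 pangenes with
elevated duplication probability (0.12) when estimating duplicate switch
rates, which is purely a measurement-precision choice — more duplicate genes
tighten the binomial error on the pooled proportions without touching the
rates being estimated.

## Known limitations

* The intact filter recomputes the singleton median from the current table;
  re-filtering an already-filtered table is a fixed point for realistically
  clustered singleton lengths but is not guaranteed idempotent for
  adversarial length configurations.
* The mCHG-variant correlation keeps the full 40 CG / 40 CHG coverage rule
  (the written requirement emphasizes the CG part; the package applies the
  same low-confidence rule used everywhere else).
* `counts_to_tpm` sums replicate columns as raw counts before normalizing,
  which approximates merging replicate reads but is not identical to
  realignment of pooled reads.
* Metagene bins use genomic coordinates (introns included), as in standard
  metagene tools; they are not spliced-transcript coordinates.
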