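# Methods

## The analysis model

`rrbsdmf` analyses reduced representation bisulfite sequencing (RRBS)
methylomes at the resolution the library itself defines: the MspI fragment.
RRBS enriches CpG-dense DNA by digesting the genome with MspI (which cleaves
C^CGG) and size-selecting 40–220 bp fragments, so every sequenced molecule
comes from one of a fixed, genome-determined catalogue of intervals. Pooling
per-CpG counts within a fragment gives a stable methylation estimate and a
natural two-sample count test.

The chain is:

1. **In-silico digestion** (`digest`). Cut sites are placed one base after
   each CCGG occurrence (overlap-allowed, case-insensitive, ambiguous bases
   never match), so a fragment begins with `CGG` and ends with `C`. Only
   internal fragments — those bounded by two cut sites — enter the
   catalogue; terminal contig pieces have a single MspI end and are
   excluded, as in a real library. Size selection keeps 40–220 bp inclusive.
   Whether real fragment coordinates include the filled-in overhang bases is
   a convention; this one is declared and test-pinned rather than inferred.
   CpG sites are recorded as forward-strand `CG` start positions; a CG whose
   G falls outside the fragment is excluded.
2. **Aggregation and filtering** (`methylation`). Input is the 6-column
   Bismark-coverage dialect (1-based positions). Because CpG methylation is
   palindromic, a call at the G of a forward-strand CG is merged into the C
   position by summing counts. A fragment's level is
   `pooled_M / (pooled_M + pooled_U)` over **all** covered CpGs (not a mean
   of per-CpG proportions: pooled counts are what the downstream exact test
   consumes). A fragment is analysable when it has at least `min_cpgs = 2`
   distinct CpG sites each with at least `min_reads = 10` reads. The
   alternative reading of that rule (≥10 reads summed over the fragment) is
   rejected; the per-site reading is stricter and matches the stated intent
   of requiring independently informative sites.
3. **DMF calling** (`diffmeth`). For each fragment passing the filter in
   both samples of a pair, the 2×2 table (methylated/unmethylated ×
   tissue/cell line) is tested with a two-sided Fisher exact test: p is the
   total hypergeometric probability of tables (same margins) no more
   probable than the observed one. A relative tie tolerance of 1e-7 makes
   floating-point ties deterministic; a degenerate margin returns p = 1.
   Bonferroni correction uses family size = fragments actually tested in
   that comparison (the only defensible family: fragments untestable in one
   sample contribute no test). A DMF requires `p ≤ alpha/n_tests`
   (`alpha = 0.01`) **and** an absolute methylation difference ≥ 0.25
   (inclusive). The order of the two filters does not affect the final set;
   both are recorded per fragment.
4. **Cross-pair intersection** (`intersect_common`). DMFs from two pairs are
   matched by exact fragment coordinates — all samples are aggregated on one
   catalogue, so identity is well defined — and classified as
   both-hyper / both-hypo / discordant. Concordance percentages are
   100·count/total rounded half-up to one decimal.
5. **Annotation** (`annotate`). Each fragment gets exactly one gene context
   with precedence promoter > junction > exon > intron > intergenic
   (the categories partition, as in a pie chart; junction outranks its parts
   because it is reported as its own category) and one CGI context with
   precedence core > shore > shelf > open sea. The promoter is the
   strand-aware window from 2 kb upstream to 1 kb downstream of the TSS;
   shores are 2 kb island flanks and shelves the next 2 kb band (the
   community convention — the terms have no universal widths). "Intergenic"
   is operationalised as "overlapping no promoter window and no gene span".
   All interval assignments use an any-overlap (≥1 bp) rule; with fragments
   ≤220 bp, overlap and containment are nearly equivalent. Gene-set
   enrichment is a one-sided hypergeometric tail against a user-supplied
   background (the genes the assay can see), Benjamini–Hochberg-corrected
   across sets.
6. **Summaries** (`summarize`). Level histograms over 50 equal bins (last
   bin right-closed; counts always conserve the fragment count). Pearson
   correlation between paired samples over fragments passing in both.
   Hierarchical clustering of samples with distance 1 − Pearson r and
   average linkage on fragments passing in every sample — a declared,
   deterministic choice; ties break by sample-name order. Element-wise
   medians with two-sided Wilcoxon rank-sum tests: exact by enumeration of
   all label assignments (midranks for ties) when the combined n ≤ 12,
   otherwise the tie-corrected normal approximation with continuity
   correction. Medians are reported to 2 decimals in the JSON report; TSVs
   keep full precision.

## The synthetic study

Real tumour/cell-line RRBS data are controlled-access and large; the
generator (`simulate`) builds a study whose truth is known by construction
so every downstream stage is testable offline.

* **Genome.** Four 150 kb contigs. Fragments are laid out as chains of
  CCGG-delimited intervals with lengths uniform on 60–200 bp (safely inside
  the 40–220 bp selection); chains are separated by 250–600 bp A/T spacers
  that digest into oversize fragments, exercising size selection. Filler
  sequence uses only A and T, so no CCGG or CpG arises by accident and the
  CpG count per fragment (1 from the cut overhang + 3–8 placed `CG`s) is
  exact. Gene models (25 per contig, 2–5 exons, random strand) and CpG
  islands (anchored on ~20 fragments per contig, merged to disjointness)
  give the annotator non-trivial inputs.
* **Methylation.** Per-fragment true levels come from a two-component beta
  mixture, Beta(1, 9) with weight 0.55 and Beta(9, 1) with weight 0.45 —
  a bimodal fragment-level distribution with most mass near 0 and 1, with
  the unmethylated mode slightly heavier as in tumour methylomes. CpGs
  within a fragment share the fragment's level.
* **Counts.** Per-CpG depth is negative binomial with mean 30 and dispersion
  8 (variance ≈ 142 at the default mean; Poisson is the dispersion → ∞
  limit), matching overdispersed RRBS coverage; no coverage distribution is
  published for such libraries, so these are modelling choices. Methylated
  counts are binomial(depth, level).
* **Planted truth.** 200 fragments (of 2000) are planted as DMFs shared by
  both pairs, shifted by ±0.5 in the cell-line sample with 88% shifted
  upward — the direction skew observed when cell lines are compared with
  their tissue of origin. Planted base levels are drawn from the mixture
  mode compatible with the shift direction and rescaled into the feasible
  range ([0, 1−δ] for hyper, [δ, 1] for hypo), so the full shift never
  clips and |true difference| ≥ δ holds for every planted fragment;
  clipping remains as a guard and the truth table records post-clip levels.
  Only fragments with ≥2 CpGs are eligible, so planted truth is not
  confounded by the coverage filter.
* **Nulls.** Unplanted fragments have identical true levels in tissue and
  cell line: every unplanted call is a genuine false positive. An optional
  `global_shift` parameter adds a uniform cell-line offset to unplanted
  fragments (emulating the ~10% global hypermethylation of cultured lines)
  for distribution-level demonstrations; it defaults to 0 so that
  sensitivity and family-wise error are measured against exact nulls.
* **Determinism.** All randomness flows from the single config seed through
  named substreams (genome, planting, per-pair levels, per-sample counts),
  so identical configurations produce byte-identical files, and replicate
  studies can reuse one genome and planted set with fresh count noise.

**What passing tests do and do not show.** The generator matches the
analysis model well (fragment-homogeneous methylation, binomial counts
given depth, exact nulls). Real RRBS data additionally have intra-fragment
heterogeneity, incomplete bisulfite conversion, mapping bias, copy-number
variation and biological replicate variance, none of which are simulated;
measured sensitivity (~1.0 at δ = 0.5, 30× coverage) and family-wise error
(≤ alpha) are therefore statements about the implementation's correctness
under its own model, not forecasts of performance on patient data.

## Numerical choices

* Fisher p-values are computed from a gammaln-based hypergeometric pmf over
  the table support, renormalised to sum to one; the whole-support case
  returns exactly 1.0. Agreement with exact integer enumeration is ≤ 1e-13
  relative over all tables with row margins ≤ 60 (asserted at 1e-10).
* The tie tolerance (1e-7 relative) is applied identically in the
  implementation and in the integer-arithmetic test oracle.
* Percentages destined for reports are rounded half-up (not banker's
  rounding) to one decimal via `decimal.Decimal`.
* Degenerate inputs fail loudly: zero-read levels, zero-variance
  correlations and empty backgrounds raise `ValueError`; empty test sets
  warn and return empty tables.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` use the standard study
(2 pairs × 2000 fragments, 200 planted shared DMFs, δ = 0.5, 30×), 50
replicate seeds for recovery statistics, 200 null replicates for
family-wise error, an exhaustive Fisher sweep over row margins ≤ 60, and
1000 random 10 kb sequences for the digestion oracle — sizes at which the
Monte-Carlo error of each measured proportion is far below the margin it is
compared against.

## Known limitations

* Only MspI single-enzyme digestion; no double-enzyme protocols and no
  methylation-sensitive digestion.
* Bonferroni only (as appropriate for the per-comparison family); no FDR
  or dispersion-aware (beta-binomial) models.
* Gene annotation assumes exons tile the gene span (true of the generated
  models); a gene whose first exon starts inside its annotated span would
  leave a gap classified by the remaining precedence rules.
* The clustering and histogram-bin choices are conventions, not estimates;
  conclusions should not depend on them.
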