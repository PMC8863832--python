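# Methods

## Data model

An LFQ study is runs nested in samples nested in groups. The default design
mirrors a typical whole-liver comparison: 4 groups × 5 biological samples,
each sample injected twice (40 MS runs). Intensities are MaxQuant-style
normalized LFQ values; 0 always means "not quantified in this run" and is
never treated as a measured value. All statistics operate on a proteins ×
columns matrix with an explicit missingness mask.

## Preprocessing

Stage order: identification filtering → run-level matrix → duplicate
averaging (raw scale) → minimum-quantification filter (sample level) → log2 →
imputation (sample level).

* **Duplicate averaging** uses the arithmetic mean of the two raw run
  intensities and only when both are > 0; a single dropout makes the sample
  value missing. Averaging happens before the log transform because the
  incoming LFQ values are already normalized linear intensities.
* **Minimum quantification**: a protein is retained if observed in at least
  `ceil(min_frac × n_samples)` samples (default 0.25, i.e. 5 of 20). The
  filter counts samples, not runs; an alternative run-level ordering
  (`impute_level="run"`) imputes the run matrix before averaging, for
  workflows that impute at the technical-replicate level.
* **Imputation** is per sample column. With observed mean m and sample SD s
  (n−1 denominator; a deliberate small-n choice), each missing cell is drawn
  independently from N(m − down_shift·s, (width·s)²), defaults
  down_shift = 1.8, width = 0.3 — the standard down-shifted-normal MNAR
  parameterisation, which places imputed values in the low-abundance tail.
  The draw is seeded and the imputation mask is returned so observed cells
  can be proven untouched. A column with fewer than two observed values is
  an error rather than a silent fallback.

## Significance cascade

Per protein, a classic fixed-effects one-way ANOVA (F with k−1, N−k df);
p-values are corrected by Benjamini–Hochberg (step-up; implemented via
`statsmodels.multipletests`). The BH gate (q < 0.05) is global: a protein
failing it is non-significant in every contrast. Within each contrast
(default: every non-reference group vs the reference; log2fc = group mean −
reference mean), Tukey's HSD p must be < 0.05 and |log2fc| must strictly
exceed the fold-change cutoff.

The cutoff is not user-chosen: it is the sample SD (n−1) of all contrasts'
log2 fold-changes pooled within the study, computed over all quantified
proteins (not only ANOVA-significant ones; this is configurable via
`ContrastThresholds.fc_cutoff`). Typical values on realistic data fall in
the 0.3–0.7 range and adapt to each study's overall variability.

Tukey p-values use the studentized range with the pooled within-group MSE
and N−k df, and the Tukey–Kramer harmonic-mean convention for unequal group
sizes. Degenerate rows are handled explicitly: an all-equal row gives
F = 0, p = 1; zero residual variance with unequal means gives the smallest
representable positive p rather than literal 0.

### Numerical choice: studentized-range tail

`scipy.stats.studentized_range.sf` integrates numerically (~6 ms per value),
which is prohibitive for thousands of proteins × all pairs. For batches
larger than 64 values the package evaluates a cached monotone PCHIP
interpolant of log-sf on a 400-point grid over q ∈ [0, 30] per (k, df);
beyond the grid the tail is below ~1e-12 and is clamped to 0. The test
suite asserts agreement with the exact quadrature to a relative 5e-4 across
the decision-relevant range, far inside the p < 0.05 gating tolerance.
Small inputs (k-group toys, single proteins) always use the exact routine.

## Structure analysis

* **PCA**: samples are observations, proteins centered features (full SVD).
  Any two components may be plotted; variance fractions are
  eigenvalue/total.
* **Z-scores**: per protein across all samples ((x − row mean)/row SD, n−1),
  then averaged within groups to give the per-group mean z profile used for
  heatmaps and clustering. Zero-variance rows become zero rows with a
  warning. Z-scoring across samples before group-averaging (rather than
  z-scoring the group means) is the package's default; both orderings are
  reachable by feeding `zscore_proteins` the matrix of choice.
* **Clustering**: agglomerative, default Euclidean distance with complete
  linkage (both exposed), cut into a user-chosen k — cluster number is an
  analyst input, not inferred.
* **ORA**: one-sided Fisher exact (hypergeometric upper tail) per GMT term
  against the universe of quantified proteins of the study — the standard
  over-representation background. Raw p < 0.05 flags significance; a
  BH-adjusted column is also emitted. ID matching is case-insensitive on
  the first gene symbol, falling back to the protein-group accession.

## Cross-contrast and cross-study comparison

Contrast pairs are aligned on harmonised protein-group ids (first majority
accession). Proteins significant in both contrasts split into consistently
up / consistently down / discordant; the remainder of the
significant-in-≥1 set is attributed to single-study cells, and the five
cells are provably disjoint and exhaustive. For cross-study comparisons the
classification can be re-run under one shared fold-change cutoff
(`reclassify`) instead of each study's own data-derived value — both modes
are supported because either convention appears in practice.

## Mitochondrial stress-test metrics

Phase rates per well summarise each injection phase; the default summary is
the phase mean, with last/min/max per phase available because instrument
conventions differ — the chosen rule travels with the output. Metric
definitions are fixed identities: ATP-linked = baseline − oligomycin,
proton leak = oligomycin − non-mitochondrial, basal = baseline −
non-mitochondrial, maximal = FCCP − non-mitochondrial, spare = maximal −
basal. Negative derived metrics are flagged as QC warnings, never clamped.
Conditions are compared per metric by the same one-way ANOVA used for
proteins; no outlier-well rejection is applied by default.

## Synthetic data: what it emulates and what it does not

`SyntheticSpec` defaults (chosen once as a realistic liver-LFQ regime):
2,000 protein groups; 4 groups × 5 samples × 2 duplicates; per-protein
baseline log2 abundance ~ N(25, 2) (typical LFQ log2 range); 10 %
differential proteins with per-group signed shifts |Δ| ~ U(1.0, 2.0) log2;
biological noise SD 0.25 and duplicate noise SD 0.10 log2; MNAR dropout
P(missing | x) = logistic(23 − x) on the run-level latent log2 value,
giving ≈ 20 % run-level missingness concentrated at low abundance; 2 %
contaminant, 1 % reverse and 1 % site-only flagged rows. Generated tables
round-trip through the MaxQuant reader byte-stably under a fixed seed.

The generator emulates design structure, effect sizes, MNAR dropout and
flagged rows. It does **not** emulate peptide-level roll-up, shared-peptide
ambiguity, normalization artefacts, batch effects, or correlated proteins
(co-regulation); passing tests therefore demonstrate the pipeline's
statistical behaviour under its stated model, not robustness to those
real-data complications.

## Calibration scenarios

* **Null calibration**: 200 replicate studies with no planted effects and
  abundance-independent (MCAR, 20 %) dropout; the mean fraction of
  ANOVA-BH-rejected proteins must stay within the nominal FDR plus 3
  Monte-Carlo SEs. MCAR is used so the null is exactly exchangeable across
  groups after imputation.
* **Power calibration**: planted shifts of ≥ 4× the residual SD
  (U(1.0, 2.0) vs noise 0.25) with dropout disabled, so the realised
  signal-to-noise equals the planted one; the full cascade must reach
  recall ≥ 0.9 at observed FDR ≤ 0.1. Under the default MNAR dropout the
  same cascade loses power on heavily-imputed low-abundance proteins
  (recall ≈ 0.78 at these settings) because down-shift imputation inflates
  their within-group variance — a real and intended property of this
  imputation family, reported separately by the acceptance script rather
  than hidden. Problem sizes (2,000 proteins, 200 null replicates) were
  chosen to make Monte-Carlo error small relative to the thresholds while
  the whole suite stays quick to run.

## Known limitations

* Imputation ignores protein identity (column-global down-shift); per-protein
  MNAR models (e.g. MinProb per protein) are out of scope.
* No moderated variance estimation (limma-style shrinkage) — with n = 5 per
  group the classic ANOVA is noisier than an empirical-Bayes test.
* ORA treats terms independently; no ontology-topology correction.
* Cross-species/ortholog mapping is not provided; cross-study joins assume
  a shared accession space or gene symbols.
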