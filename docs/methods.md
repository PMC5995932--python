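# Methods

## The model and its assumptions

The package discovers a binary gene-expression classifier from a
case-control bulk RNA-seq cohort under these assumptions:

- counts per gene and sample are negative-binomial with a gene-wise mean
  and a common dispersion scale (over-dispersed Poisson, the standard bulk
  RNA-seq model);
- class signal is multivariate: a set of genes shifts its mean expression
  between classes by modest log2 fold changes, in both directions, and the
  discriminative value of the set exceeds that of its members;
- classes are imbalanced, so the primary evaluation measure is the
  per-class F-measure (harmonic mean of precision and recall), not
  accuracy or AUC alone;
- a useful clinical panel must be *small*, so model selection ranks
  candidates by F-measure **divided by panel size** (the adapted score)
  rather than raw F.

## Procedure

For each of `n_repeats` stratified 120/30 training/holdout splits of the
development cohort:

1. **Panel selection per ranker (LR-RFE, SVM-RFE).** Within each of
   `k_outer` outer CV folds of the training split, `k_inner` inner folds
   choose the panel size: features are recursively eliminated along the
   schedule `k → ⌊0.9k⌋ → … → 1`, refitting the L2 linear model at each
   step on the inner training samples and scoring the step's model on the
   inner test samples; k\* maximizes the mean asthma F (ties to the
   smaller k — the parsimony-consistent choice). The outer training split
   is then ranked the same way and its top-k\* genes kept. The
   per-training-set panel is the intersection of the outer folds' sets;
   an empty intersection falls back to genes present in all but one fold
   (flagged in provenance), and an empty fallback is an error recorded
   against that ranker's four combinations.
2. **Classification.** Logistic (L2, C = 1), linear SVM (C = 1, Platt-style
   probability link fit on the training decision values), AdaBoost (100
   depth-1 learners) and random forest (500 trees) are trained on the
   panel; linear models see per-gene standardized values (statistics from
   the fitting split only), ensembles the raw log2 values. The threshold
   maximizing asthma F on the holdout becomes the model's operating point;
   candidates are the midpoints between consecutive distinct probabilities
   plus {0, 1}, ties resolve to the largest threshold, and a probability
   exactly at the threshold is called asthma.
3. **Selection.** The adapted scores form an `n_repeats × 8` matrix; the
   Friedman statistic `χ²_F = 12N/(K(K+1)) ΣR_j² − 3N(K+1)` (ties averaged,
   χ² approximation with K−1 df; splits with any failed combination are
   excluded, with the failure logged) tests for rank differences and the
   Nemenyi critical difference `q_α √(K(K+1)/6N)` (q tabulated for
   K = 2..10, α ∈ {0.05, 0.10}) marks significant pairs. The best
   combination has the lowest mean rank (ties: higher mean raw F, then
   smaller mean panel); its representative model is the split with the
   highest holdout F (ties: mean F of the same panel across the four
   classifiers on the same holdout, then smaller panel, then lower split
   index). The final classifier refits the representative algorithm and
   panel on the **entire development set** and carries the representative
   threshold unchanged (`final_fit="training_split"` restores the
   refit-on-training-split alternative; whether the threshold should be
   re-optimized after the refit is genuinely open — we carry it over).

## Differential expression stand-in

Normalization and DE deliberately use transparent primitives rather than a
full RNA-seq inference engine: median-of-ratios size factors, the
`log2(count/sf + 1)` transform as the variance-stabilizing step, and a
Welch t-test with BH adjustment. The classifier pipeline only needs a
monotone homoskedastic expression matrix and a DE gene list; regularized
dispersion estimation would change individual p-values but not the
pipeline's structure. Consequences: transformed values are not
numerically comparable to any specific DE package's VST output, and
zero-variance genes follow an explicit convention (equal means → p = 1;
unequal means with zero pooled variance → smallest positive float,
flagged) instead of propagating NaN.

## Synthetic study

The generator emulates the data such a study produces, not any particular
dataset:

- **Development cohort**: 53 cases / 97 controls (150 samples); **test
  cohort**: 13 / 27 (40 samples) of *new* subjects on the same gene
  universe — gene-level parameters (baselines, effects) are drawn from a
  seed stream separate from sample-level noise, so dev/test/external
  cohorts share biology while being fully independent draws.
- **Genes**: 2000 at desk scale, baselines log10-uniform on [0.5, 3.5] so
  the <100-count filter bites (roughly half the genes, including about
  half the planted ones, are removed — discovery operates on the
  survivors); an 11587-gene emulation is a config choice, not the default.
- **Signal**: 40 informative genes at |log2FC| = 1.5 with alternating
  sign (mirroring mixed over/under-expression); NB dispersion 0.1
  (bulk-RNA-seq-typical; the DE stand-in recovers ≥ 90 % of planted genes
  at FDR ≤ 0.05 for dispersions up to 0.2 at n = 150).
- **Library sizes**: mean-one log-normal with CV 0.3, making size-factor
  normalization consequential.
- **External cohorts**: continuous log-scale intensities,
  `probes_per_gene` probes per gene with independent N(0, 0.25²) noise,
  sample-level N(0, 0.5²) noise, optional platform scale/shift, and a
  seeded random subset of the gene universe (`gene_overlap_fraction`,
  informative genes always retained). With `disjoint_signal` the cohort
  represents a different condition: its signal genes are sampled outside
  the asthma set, its asthma label is uniformly negative, and its own
  case/control status is a covariate.

What the synthetic study does **not** model: batch effects, covariate
confounding (age/sex/race), gene-length effects, correlated co-expression
modules, or single-cell structure. Passing tests therefore demonstrate
the pipeline's correctness and its statistical behavior under the assumed
generative model, not clinical performance on real cohorts.

A property worth knowing: with the desk-scale effect size the inner-CV
F-measure saturates at 1.0 over a wide range of k, so the smaller-k
tie-break yields very small panels (1–5 genes) — the parsimony objective
working as designed on strongly separable data. On noisier real data the
optimum sits at much larger k. The package's own cross-checks that need a
multi-gene panel (e.g. enrichment tests) use a moderate-signal
configuration (|log2FC| = 1.0, dispersion 0.2) where the optimum exceeds
one gene.

## Cross-platform application

How an RNA-seq-trained model should rescale microarray intensities is not
derivable from first principles; the package offers two conventions:

- `standardize=True` (default): each external gene is z-scored within the
  external dataset and the z-scores are mapped onto the development-scale
  distribution via the model's stored per-gene training mean/sd. Robust
  to arbitrary platform scale and shift, but anchors the external dataset
  mean to the development *mixed* (case+control) mean — appropriate only
  when the external cohort actually contains both classes in comparable
  proportion.
- `standardize=False`: collapsed gene values are used directly —
  appropriate when the platform already reports values on the development
  log2 scale, and exactly equivalent to the internal evaluation path in
  that case. Specificity cohorts (no positive class present) must use
  this mode, since z-scoring an all-control cohort would re-center it
  onto the case/control boundary by construction.

Missing panel genes are imputed at the training mean (standardized 0) with
a logged warning; more than 20 % missing is a hard error.

## Permutation null

Null models rerun the *identical* discovery procedure on label-permuted
development data and are evaluated on the untouched test set. At desk
scale each null pipeline uses 3 splits (vs 10 for the real model) so that
20 nulls remain computable in minutes; the comparison — real F must exceed
the null mean by > 3 null SDs, and the null mean should sit near the
all-positive baseline 2p/(1+p) — is unaffected by the split count, which
only widens the null's internal variability slightly.

## Numerical and design choices

- Seed fan-out: every stage derives its seed as
  `sha256(master_seed / stage / index…) mod 2³¹`, giving independent,
  restart-stable streams.
- All linear fits use liblinear (deterministic); rankings break |weight|
  ties by gene id; the k-schedule uses `max(⌊0.9k⌋, 1)` (floor; rounding
  direction is a stated choice).
- The inner-CV metric is the asthma-class F-measure; accuracy/AUC would
  be defensible alternatives, F is consistent with the pipeline's primary
  measure.
- The inner evaluation reuses the RFE refit at each schedule step as the
  classifier evaluated on the inner test split — one fit per step instead
  of two, with identical semantics.
- Friedman uses the χ² approximation (N is large in the intended design);
  the Nemenyi q-table is embedded for K = 2..10.
- Desk-scale defaults: 10 splits, 3×3 nested CV, 2000 genes, 20 nulls;
  the full-scale configuration (100 splits, 5×5, 100 nulls) is the `full`
  preset. The desk sizes are chosen so a complete discovery runs in
  under a minute and the full test suite in minutes on one CPU.

## Known limitations

- The DE stand-in is not a drop-in replacement for shrinkage-based DE
  engines at low counts.
- The adapted score makes panel size a hard divisor; on strongly
  separable data it aggressively favors near-singleton panels (see above).
- Probability calibration of the SVM link is Platt-style on training
  decision values (no cross-validated calibration).
- No bootstrap confidence intervals on the evaluation measures; the
  permutation null is the only uncertainty quantification provided.
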