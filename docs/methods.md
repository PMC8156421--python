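# Methods

## Problem and model

Somatic point mutations in tumor genomes split into *drivers* (selected for,
disease-relevant) and *passengers* (neutral). `drivercontext` classifies a
mutation using only, or primarily, the raw reference-genome sequence
surrounding it: the neighborhood of window size `n` is the forward-strand
string of `2n + 1` bases centered on the mutated position (`n` from 1 to 10,
so strings of length 3 through 21). The premise is that mutational processes
leave class-dependent signatures in the immediate sequence context (CpG- and
TpC-type effects being the classical examples), so the *distribution* of
neighborhoods differs between classes and is learnable.

Two questions are treated separately:

1. **Are the class-conditional neighborhood distributions different?**
   (density analysis: KDE + Jensen-Shannon distance against a
   label-randomization null)
2. **Can a classifier exploit the difference?** (generative KDE Bayes
   classifier, discriminative baselines, and a deployed soft-voting
   ensemble)

## Feature representations

Seven representations per window size:

* **One-hot (OHE).** Each of the `2n` flanking bases becomes a 4-slot
  indicator; the center wild-type base is not encoded (the `8n + 2`
  dimension count forces this), and the chromosome code and
  substitution-type code are the `+2` ordinals. Slot order is A, G, C, T,
  matching the convention "A" → ⟨1,0,0,0⟩, "G" → ⟨0,1,0,0⟩.
* **k-mer counts (CV, k = 2, 3, 4).** The neighborhood (center base
  included) is decomposed into its `2n + 2 − k` overlapping k-mers;
  the vocabulary (sorted distinct k-mers with document frequencies) is
  fitted on training data only, and transforms of new data ignore unseen
  k-mers.
* **TF-IDF (TF, k = 2, 3, 4).** Two variants: `paper_formula` scores cell
  (j, i) as `freq_ij · ln(N / d_i)` with no normalization (the textbook
  formula, natural log); `smoothed_l2` — the default — uses the
  scikit-learn convention `idf = ln((1 + N)/(1 + d)) + 1` with row-wise L2
  normalization. Both are implemented in-package; the smoothed variant is
  cross-checked against `sklearn.feature_extraction.text.TfidfVectorizer`
  in the test suite.

Substitution types are ordered A>T, A>G, A>C, T>A, T>G, T>C, G>A, G>C,
G>T, C>T, C>A, C>G (codes 0–11). Chromosomes encode as 1–22, X=23, Y=24;
any other contig hashes into a stable bucket ≥ 25 with a warning.
Coordinates are 1-based fully closed on the forward strand; the 0-based
half-open conversion used for substring math is pinned by a toy-contig
test. When a record's ref allele disagrees with the genome, the genome
base is kept and a warning is emitted (the neighborhood is a property of
the reference, not of the record).

## Density analysis

For one (window, representation) cell and one run: draw `n_pc` driver and
`n_pc` passenger rows with replacement, fit a Gaussian KDE per class
(bandwidth selected from a log-spaced grid by 5-fold CV mean held-out
log-density; default grid 20 points in [1e-2, 10]), evaluate both
densities on the union of the two samples, clip at 1e-300, normalize each
to a probability vector, and take the Jensen-Shannon *distance* (base-2
logs, square root), which is bounded in [0, 1]. The matched null run
resamples `2·n_pc` rows ignoring labels and splits them randomly in half.
An experiment is 30 original + 30 null runs; the empirical p-value is the
fraction of null runs whose distance strictly exceeds the median original
distance.

Numerical choices: evaluation on the union of the run's own samples keeps
the discretization deterministic given the run seed; bandwidth ties
resolve to the smallest grid value; per-class bandwidths are tuned
independently in both arms. `n_pc` defaults to the smaller class size.

A caveat found while validating the null: when the class pools are small
relative to `n_pc`, the original arm repeatedly measures the fixed
empirical gap between the two finite pools and the p-value is
anti-conservative even for identical generating processes. Exchangeability
checks should keep pool size ≫ per-run sample size (the test suite uses
400 per class with 30 per run).

## Classifiers

* **Generative KDE classifier.** One bandwidth-tuned Gaussian KDE per
  class plus log class-fraction priors;
  `P(driver|x) = P(x|driver)P(driver) / Σ_c P(x|c)P(c)` computed in log
  space with logsumexp. Posterior ties go to passenger (conservative).
  Classifier-internal bandwidth grids default to 10 log-spaced points in
  [0.1, 10].
* **Discriminative baselines.** Random forest, extra trees, and a linear
  SVM behind one fit/score contract, each grid-searched (trees ∈ {100,
  250, 500}, depth ∈ {None, 10, 20}; SVM C ∈ {0.01, 0.1, 1, 10}; 3-fold
  tuning CV, AUROC objective). The SVM is Platt-calibrated
  (`CalibratedClassifierCV(..., ensemble=False)`) so it emits
  probabilities.
* **Deployed pipeline** (`train_driver_classifier`): TF-IDF 4-mers of
  window-10 neighborhoods (+chromosome, +substitution type), optionally
  merged with a user-supplied descriptive genomic feature table →
  gene-aware k-NN imputation of missing cells (neighbors restricted to
  same-gene complete rows when at least k exist, else global; k = 5) →
  repeated edited nearest neighbors (RENN, k = 3, max 100 passes) removes
  majority-class points misclassified by their k nearest neighbors until a
  fixed point; the minority class is never edited → extremely-randomized-
  trees impurity ranking keeps the top 50 features (top-30-percentile mode
  available for CV experiments) → soft-average ensemble of the calibrated
  linear SVM and the KDE classifier → decision threshold chosen from
  {0, 0.001, …, 1} to maximize the composite score on out-of-fold
  predictions (5-fold; ties to the lowest threshold). Soft averaging is
  required for a tunable threshold; the objective is configurable (MCC
  alternative) because threshold search cannot target AUROC, which is
  threshold-invariant.
* **Voting.** Panels of external per-tool binary calls combine by strict
  majority (even-panel ties → driver, favoring sensitivity) or by an
  at-least-p rule; abstentions are errors, never silently dropped.

## Evaluation protocol

Driver is the positive class. `compute_metrics` reports sensitivity,
specificity, PPV, NPV, accuracy, MCC and the composite score
(= sensitivity + specificity + PPV + NPV, range [0, 4]); any rate or MCC
with a zero denominator is defined as 0. AUROC is rank-based (ties count
half). Repeated CV is stratified 10-fold × 3 repeats (30 values per
metric) with vocabulary fitting, feature selection and tuning strictly
inside each training fold — an instrumentation hook exposes the row
indices each fitting stage touched so leak-freedom is testable. CIs on CV
metrics are Student-t intervals on the mean of the 30 values; predictor
comparisons use percentile 95% bootstrap CIs (1000 resamples of the test
indices), calling a difference significant when the intervals are
disjoint or touch within 1e-12; degenerate resamples (single-class draws)
are redrawn and counted. Window-size comparisons emit Wilcoxon
signed-rank (paired) or Mann-Whitney U p-values for all 45 ordered window
pairs; identical paired vectors give p = 1 by convention.

## Synthetic data

The generator emulates the two properties the method needs and nothing
else. Genomes are uniform-background FASTA contigs (optionally GC-biased).
Mutation sites are spaced ≥ 21 bp so ±10 windows never overlap; each
site's 21-base window is rewritten with a draw from its class's
first-order Markov model over {A, C, G, T} (defaults: GC-favoring
transitions for drivers, AT-favoring for passengers, strength 0.7), so
extraction from the written FASTA reproduces the class context exactly.
The ref allele is the rewritten center base; alt is uniform over the other
three. Descriptive features default to a PTM-site-like flag (rates 0.31
drivers / 0.004 passengers), a region-of-interest-like flag (0.37 / 0.11),
and two Gaussian conservation-like scores with unit-SD class shifts of 1.0
and 0.5; missing values are injected completely at random at rate 0.001.
All generators are bit-reproducible under fixed seeds.

What this does *not* emulate: real mutational signatures (trinucleotide
spectra), gene structure, recurrence/hotspots, correlated descriptive
features, label noise, or class imbalance mechanisms. Passing tests
demonstrate that the pipeline recovers planted context differences and
stays at chance under exchangeability — not that real drivers are
separable at any particular accuracy.

Problem sizes used in the test suite and acceptance script: end-to-end
runs use 2000 mutations (500 drivers / 1500 passengers, roughly the 1:3.6
imbalance of curated training compilations) with a 70/30 split; density
experiments use 400 per class, 30 resampled per run, 30 runs per arm, and
a reduced 4-point bandwidth grid on window-2 TF-IDF 2-mer features.

## Known limitations

* KDE density comparison in high-dimensional encodings saturates (JS
  distances near 1 in both arms); the null-calibrated p-value remains
  meaningful, but raw distances should not be compared across
  dimensionalities.
* RENN uses Euclidean k-NN on the encoded matrix; with mixed-scale columns
  (ordinals beside TF-IDF weights) the neighborhood structure is dominated
  by the larger-scale columns. This mirrors the usual practice of running
  the balancer on the feature matrix as given.
* The gene-aware imputer falls back to a global neighbor pool whenever a
  gene has fewer than k complete rows, which is the common case for small
  panels.
* Multi-allelic and duplicated records are de-duplicated on
  (chrom, pos, ref, alt) with a logged count; indels, CNAs, SVs, protein
  coordinates, and liftover are out of scope.
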