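# Methods

`panelgrid` implements a comparative biomarker-refinement workflow for
balanced case-control transcriptome classification: many defensible
analysis pipelines exist for deriving a diagnostic gene panel from one
expression study, and the package makes the whole cross-product of common
choices runnable and comparable under honest performance estimation. The
motivating design is a kidney-transplant rejection study — 24 subjects with
biopsy-confirmed acute rejection (AR) and 24 matched non-rejectors (NR)
profiled on a ~54,613 probe-set expression array — but every stage works on
any two-class log2 expression matrix.

## Pipeline

1. **Pre-filtering** (unsupervised, label-blind): ECMR (top-half IQR),
   PVAC-style probe-consistency, BI2005 (clamp-at-5 then max ≥ 7.25),
   a FARMS-style informative/non-informative call, and PROOF1 (a
   configurable rule chain). Each filter defines one analysis data set.
2. **Class comparison**: two-group moderated t with empirical-Bayes
   variance shrinkage and Benjamini-Hochberg FDR.
3. **Ranking/filtering rules**: FDR50, COMBO0.05 (FDR < 0.05 bounded to
   [50, 500]), FDR0.10.FC0.5, FC0.5.TOP50 and FDR0.10.RFE50 (one-shot
   linear-SVM weight ranking, cost 1, standardized features).
4. **Classification**: eight configurations — elastic-net logistic
   regression at α ∈ {0.10, 0.50, 0.90} (tuned λ), LDA over the top-n
   ranked features (tuned n), nearest shrunken centroids (tuned Δ,
   native implementation), random forest (500 trees, untuned), linear
   SVM (tuned cost, Platt-style calibration), XGBoost (depth 2, tuned
   boosting rounds). All return the probability of the case class;
   0.5 is the decision threshold for sensitivity/specificity.
5. **Evaluation**: stratified 8-fold cross-validation over m partitions
   (k·m fold-level metrics averaged; SE = sd/√(k·m)); extreme-value or
   one-standard-error model selection; nested CV for unbiased estimates;
   a fold-wise optimism correction as a cheap alternative to nesting.
6. **Aggregation**: feature-inclusion matrix over all pre-filter × rule ×
   classifier combinations, recurrence-frequency filtering, gene-level
   summary tables, sample score summaries, and hypergeometric gene-set
   over-representation with BH correction.

## Statistical details

**Moderated t.** Per feature g, the pooled residual variance s_g² on
d_g = n − 2 degrees of freedom is shrunk toward a prior (d₀, s₀²)
estimated by the method of moments on log s_g² (the mean and variance of
log residual variances are matched to their log-F implied moments; the
trigamma inversion uses Newton iteration to 1e-10). The statistic
t_g = logFC_g / (s̃_g·√(1/n₁+1/n₂)) with
s̃_g² = (d₀s₀² + d_g s_g²)/(d₀+d_g) is referred to t on d₀+d_g degrees of
freedom, two-sided. A zero-weight prior recovers the classical pooled t
exactly; the implementation agrees with the reference empirical-Bayes
implementation in Bioconductor to ~10 significant digits on a frozen
fixture (see tests). On default synthetic cohorts the generator's noise is
homoscedastic across features, so the fitted prior is typically d₀ = ∞
(complete shrinkage to the common variance) — expected behavior, not a
failure of the fit; heterogeneous real data yield finite d₀.

**Shrunken centroids.** Standardized centroid differences
d_ik = (x̄_ik − x̄_i)/(m_k(s_i + s₀)) with m_k = √(1/n_k − 1/n) and
s₀ = median(s_i) are soft-thresholded by Δ; class discriminants are
δ_k(x) = Σ_i (x_i − x̄′_ik)²/(s_i+s₀)² − 2·log π_k and probabilities are
∝ exp(−δ_k/2). The Δ grid spans 0 to max|d_ik|, computed from the data
handed to the tuner (the outer-training set in nested CV, so the test fold
never informs the grid).

**Selection rules.** Tuning grids are ordered most → least regularized
(λ descending; LDA n ascending; Δ descending; SVM cost ascending; boosting
rounds ascending). The one-SE rule takes the earliest grid value whose
mean CV metric lies within one standard error of the best — the
"preference for smaller panels" reading of the rule.

**Optimism correction.** For a fold × grid matrix of metrics,
B = mean_k[metric_k(best_k) − metric_k(selected)] (sign flipped for
error), clipped at zero; the corrected flat estimate is the flat estimate
minus B for maximized metrics (plus B for error). This is the natural
adaptation of the classical classification-error bias correction to AUC,
sensitivity and specificity; the exact published adaptation is not
specified anywhere we could follow, so the sign-symmetric form is used and
documented here.

**No leakage.** Inside every training fold the DE table and the rule
panel (including the RFE SVM and all standardization statistics) are
recomputed from the training samples only. Flipping test-fold labels
provably leaves training-fold panels unchanged (tested).

**AUC** is the Mann-Whitney pair-concordance form with half credit for
ties; a single-class fold raises rather than imputes. Stratified dealing
makes single-class folds impossible for balanced designs.

## Synthetic data generator

Because the motivating cohort is not publicly deposited, `simdata`
generates cohorts with the statistical structure the analysis assumes,
on the log2 scale:

    intensity(p, j) = baseline(s) + affinity(p) + effect(s)·case(j)
                      + shared_signal(s, j) + noise(p, j)

* `baseline ~ N(7.5, 1.5²)` per probe-set — log2 abundances near the 7–10
  range typical of summarized arrays.
* `effect`: a `de_fraction` (default 5%) of probe-sets get a signed log2
  shift of magnitude uniform in [0.5, 1.5], half up / half down
  (configurable via `frac_up`).
* `shared_signal ~ N(0, 1.25²)` per (probe-set, array): biological
  sample-to-sample variation common to all probes of a set.
* `noise ~ N(0, 0.7²)` per probe; a fraction (default 30%) of probe-sets
  are built *inconsistent* — their shared signal is replaced by
  independent per-probe wander of the same magnitude — so that
  probe-consistency pre-filters have something to reject.
* The probe-set-level matrix (used when probe-level processing is
  skipped) carries residual noise of sd `noise_sd/√probes_per_set`,
  i.e. what a summary over the probes of a set would retain; with the
  default signal scale the median-polish summary of consistent blocks
  correlates with this matrix at mean Pearson r ≈ 0.96.
* Annotations map probe-sets to synthetic gene symbols (about 10% of
  genes own two probe-sets); gene sets are GMT records, a configurable
  few of which draw ≥ 50% of members from planted differential genes.

One master seed feeds named `SeedSequence` sub-streams (labels, baseline,
effects, signal, noise, affinity, inconsistency, gene sets, annotation),
so identical (seed, config) pairs are byte-identical and adding a stream
never perturbs earlier ones.

The noise scale was chosen once so that cross-validated AUCs of the grid
on default cohorts land in the high-0.8/0.9 range and planted features are
recoverable but not trivially so. What the generator does **not** emulate:
batch and spatial artifacts, RNA degradation, heavy-tailed or
intensity-dependent noise, correlated gene modules beyond the single
shared factor, probe sequence effects, and class imbalance. Passing tests
therefore certify the machinery (contracts, selection logic, bias
structure), not performance claims about any real cohort.

## Numerical and design choices

* Quantile normalization maps each column onto the across-column mean of
  sorted values; ties receive the mean of the reference over their rank
  span. Median polish starts with row sweeps, cap 10 iterations,
  tolerance 0.01. The RMA convolution background correction is omitted:
  inputs are already log2 expression values.
* The FARMS-style call fits value(p,j) = mean_p + loading_p·z_j + ε by
  alternating least squares with a ridge penalty (0.1) on loadings, the
  factor normalized to unit length per sweep; the informativeness score
  is var(fit)/(var(fit)+residual variance). Non-convergence after 100
  sweeps flags the set non-informative. This preserves the
  informative/non-informative selection contract with a transparent
  statistic rather than a Bayesian factor model.
* PROOF1's original criteria are semi-automated and partly rely on
  time-course data unavailable in a single-timepoint design; the module
  ships an ordered-conjunction rule engine (expression cutoff, annotation
  whitelist, within-class CV robustness) with a default chain sized to
  retain roughly 10% of a default synthetic cohort. The time-course
  criterion is unsupported and documented as such.
* ECMR retains floor(N/2) (54,613 → 27,306); ties on IQR break
  lexicographically. BI2005's clamped matrix is the analysis data set for
  that arm, including differential expression.
* FDR cuts are strict (<); fold-change cuts are inclusive (≥), applied
  separately for up- and down-regulation. The RFE step is one-shot, not
  iterative elimination.
* Elastic net uses the 1/n-scaled objective (scikit-learn C = 1/(nλ));
  features standardized on training samples. The SVM classification
  kernel is linear, matching the RFE filter; probabilities come from a
  monotone logistic map of training decision values (any monotone
  calibration preserves AUC).
* One inner partition is used for nested tuning by default; outer
  partitions default to m = 5. Demonstration runs in the test suite and
  the acceptance script use 250–300 probe-sets and m = 2 partitions —
  the package's chosen desk-scale configuration; all counts that matter
  (200 combinations, 48 × 200 = 9,600 scores, 3+3 fold balance) are
  invariant to that scale.
* Degenerate cases: empty panels raise at training and are recorded as
  missing folds (estimates flagged partial); zero-variance features are
  handled by the shrunken variance denominator (s₀² > 0); constant rows
  standardize to zeros.

## Known limitations

* The optimism correction's published adaptation to AUC/sensitivity/
  specificity is under-specified; ours is one defensible reading.
* Flat-CV scores, not nested scores, feed the default score matrix;
  nested score matrices are produced only when nested mode is requested
  (they cost k_inner times more).
* The generator's independence assumptions make classification somewhat
  easier than real cohorts at matched effect sizes; absolute AUC values
  on synthetic data should not be read as clinical performance.
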