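# Methods

This note documents the statistical procedure `uridx` implements, the
defaults that matter, what the synthetic cohorts do and do not emulate,
and the design choices made where the procedure was genuinely open.

## Normalization chain

Input is a proteins × samples table of nonnegative iBAQ abundances in
which 0 encodes "not detected". Undetected and truly-absent proteins are
deliberately conflated — label-free data cannot distinguish them — and
zeros are treated as *missing* only at the final imputation step.

**Quantifiability.** A protein is quantifiable when it has at least two
distinct strict peptides: spectrum matches passing 1% FDR with ion score
strictly greater than 20. The filter operates on a precomputed
peptide-evidence table; peptide-spectrum matching itself is upstream of
this package.

**iFOT.** Each column is scaled to sum to 10⁵ (fraction-of-total × 10⁵).
This removes per-sample loading depth exactly; it is idempotent up to
scale, and an all-zero sample is a hard error naming the sample.

**Quantile normalization.** Classic algorithm: rank each column, replace
rank *r* everywhere by the mean of the columns' *r*-th order statistics;
ties within a column receive the mean of the normalized values they span.
Two caveats discovered during development and reflected in the defaults:

* The tie rule makes the transform non-idempotent and breaks the
  "columns share one multiset" property in the presence of ties; both
  properties hold exactly on tie-free data, which is what the test suite
  asserts.
* With `preserve_zeros` (default on), cells that were exactly 0 on input
  remain 0 on output. Without this, zero-inflated columns with unequal
  zero counts would smear small positive values into undetected cells and
  destroy the detection semantics that the reference model and the
  absent-from-healthy-urine rule depend on.

**log2 + imputation.** Zeros are replaced by the global minimum nonzero
value of the matrix and all cells are log2-transformed; the imputation
value (log2 scale) is recorded on the result and logged. Alternatives
(per-sample minimum, fixed pseudo-value) were considered; the global
minimum keeps imputed cells exchangeable across samples, which matters
because rank-sum tests downstream see imputed cells as ties.

## Reference intervals and outlier calls

From a healthy cohort, each protein gets `ri_low`/`ri_high` (2.5th/97.5th
percentiles, linear interpolation between order statistics — the
convention is configurable), the IQR, and an outlier cutoff
`ri_high + 2·IQR`. "95% CI of the reference interval" is read as the 95%
reference interval's upper bound — the only monotone one-sided reading —
not as a confidence interval around a statistic. Outliers are upper-tail
only: over-expression. A disease-sample cell is called when it strictly
exceeds the cutoff, or, for proteins never detected in the healthy cohort
(`expressed_in_normal = False`), when it is detected at all.

Outlier screening runs on the **iFOT stage** by default. The criterion is
stated on iFOT values, and quantile normalization has a degenerate edge:
it pins extreme ranks to identical values in every column, so the most
abundant protein gets IQR = 0 and a cutoff equal to its own constant
value — a hair trigger that flags it in the majority of samples of any
independently normalized cohort. Both stages remain supported.

Small reference cohorts have a related caveat: a protein detected in only
one or two of *n* reference samples gets a near-zero cutoff, so its
occasional detections elsewhere all flag. With the 495-sample reference
cohort the pipeline was designed around, resampled healthy data trigger
any given protein in at most ~7% of samples (measured); with a 100-sample
reference the worst protein reaches ~14%. Reference cohorts below 8
samples produce degenerate 2.5/97.5 percentiles and emit a warning.

## Outlier pools

Per disease group, over the set S of proteins with ≥1 call: standard (1)
admits an expressed-in-normal protein whose own outlier cutoff exceeds
the 75th percentile of cutoffs over S **and** whose outlier frequency is
at least the 90th percentile of frequencies over S; standard (2) admits a
never-expressed protein whose frequency is at least the 95th percentile.
Readings fixed here: the abundance comparison uses the protein's *cutoff*
value (the literal reading; comparing the observed iFOT instead is
available via `compare_observed_ifot`); frequency thresholds are
inclusive ("at least"); the cutoff threshold is strict. A percentile
threshold of 0 disables its constraint, so all-zero thresholds return
every called protein. Pools are monotone in all three thresholds.

## Differential screen and panel selection

Candidates are the union of the AA and CON pools. Each candidate gets a
two-sided unpaired Wilcoxon rank-sum (Mann–Whitney) p-value on
log2-imputed abundances: exact enumeration when both arms have ≤10
samples and no ties, otherwise the normal approximation with midrank tie
correction. Constant rows get p = 1. Raw p < 0.05 passes, with no
multiplicity correction by default (a Benjamini–Hochberg switch exists);
the screen's type-I rate on null cohorts is checked empirically, and it
runs slightly conservative (~3–4%) because imputation ties discretize the
null for sparsely detected proteins.

The feature-selection algorithm is unspecified in the procedure this
package implements, so the default is the package's own choice: seeded
random-forest permutation importance with backward elimination, halving
the candidate set each round until k = 10 remain, stable-sorted so
p-value order breaks importance ties. Deterministic for a fixed seed.
Alternatives: `top_p` (k smallest p-values) and `l1_logistic`.

## Classifiers and evaluation

Defaults (all overridable): random forest with 500 trees and √k features
per split; SVM with RBF kernel, C = 1, γ = 1/(k·Var); Gaussian naive
Bayes. AA is the positive class; class assignment uses the estimators'
default 0.5 threshold. Design matrices are built in sorted-sample-id
order, which makes LOOCV predictions invariant to input row order.

**LOOCV.** n folds, each sample predicted once by a model trained on the
other n−1. A fold whose training set collapses to one class predicts the
majority class and warns. Two variants:

* `loocv` with a fixed panel selected once on the full cohort — the
  apparent published procedure. This is optimistically biased: on a null
  cohort (no true effect) it returns ~80% accuracy, because selection saw
  the held-out samples (the classic selection-leakage effect).
* `honest_loocv` re-runs the screen and selection inside every fold on
  the n−1 training samples only; on the same null cohort it sits at
  chance (~40–50%), and it is the variant used for the chance-level
  acceptance check. Its default in-fold selector is `top_p` to keep the
  n-fold re-selection affordable.

**Independent evaluation** requires validation samples disjoint from
training samples and reports confusion counts plus accuracy, sensitivity
and specificity, printed as percentages rounded to one decimal.
`confusion_from_rates` inverts that rounding: given printed sensitivity/
specificity and the class sizes, it searches all integer confusion tables
for the unique one consistent to half a printed unit.

**ROC.** Full curve (no intermediate points dropped), trapezoidal AUC
(equal to P(score⁺ > score⁻) + ½·P(=)), and the Youden-optimal operating
point. AUC is invariant under strictly increasing score transforms.

## Synthetic cohorts

`SyntheticCohortSpec` encodes the study conditions: 32 AA + 41 CON
discovery samples (16/45 for validation cohorts), a healthy reference
cohort (default 100 samples, `full_scale_spec()` for the full
5335-protein/495-sample configuration), and a 2000-protein default
universe so the whole test suite runs in minutes on one CPU.

* **Abundance.** Per-protein baseline location drawn from a wide normal
  hyperprior in log2 space (mean 10, sd 4 → ~5 orders of magnitude of
  dynamic range); within-protein noise sd 0.5 log2; per-sample depth
  factor sd 0.25 log2, removed exactly by iFOT.
* **Detection.** Bernoulli per cell with probit link on the cell's log2
  abundance (detection-limit censoring, not missing-completely-at-
  random). The detection threshold is solved by root-finding so the
  expected detected-per-sample count hits the target mean
  (1561·n_proteins/5335), and a per-sample threshold jitter is sized via
  the local slope so the count's sd hits the target (432 scaled),
  after subtracting Bernoulli sampling variance.
* **Markers.** Each spiked marker adds its log2 fold-change in the
  affected group. `absent_in_normal` markers are zeroed in the healthy
  cohort and the unaffected group. Markers can pin their baseline to a
  hyperprior quantile; `strong_effect_spec()` places 10 markers
  (|log2FC| = 2.5, alternating groups, two absent-in-normal) at quantiles
  0.55–0.95, spanning borderline to comfortable detectability.
* **Universe sharing.** `generate_cohort(..., universe_seed=...)` fixes
  the per-protein baselines independently of sampling noise so a
  validation cohort can be drawn from the same biological universe as
  its discovery cohort.

What the generator does **not** emulate: correlated protein modules,
subgroup-specific (CHO/PAN/GP/IO/OTH) effects, instrument batch shifts
beyond a scalar depth factor, peptide-level evidence, or heavy-tailed
contamination. Passing tests therefore demonstrate the pipeline's
statistical correctness and calibration under its own assumptions, not
clinical performance on real urine.

Fold-change recovery through the full normalization chain is accurate to
±0.5 log2 only for markers detected in both groups; below the detection
limit the observed group difference is censoring-driven (the affected
group shows real values, the other the imputation floor), which inflates
apparent effects — a real phenomenon in label-free data, and the reason
the recovery test uses high-baseline markers.

## Problem sizes and numerics

Default test/acceptance runs use 2000-protein universes, 30/30 discovery
groups, 100-sample references (495 where the reference-interval
calibration itself is under test), 10 simulation seeds for recall
medians, and 500-tree forests — sizes chosen so the full suite completes
in a few minutes on a single CPU while keeping every Monte-Carlo check
comfortably inside its tolerance. Percentile computations default to
linear interpolation everywhere and are configurable through a single
`percentile_method` argument; matrix round-trips through TSV are exact
(`%.17g` write, round-trip float parsing on read).
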