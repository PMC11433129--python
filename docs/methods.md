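# Methods

## The analysis in brief

The pipeline studies access to medications for opioid use disorder (MOUD) in
admission-level coded records. Each admission carries ~25–57 categorical or
ordinal variables (service setting, living arrangement, state, referral
source, substance-use history, …) and a binary treatment outcome. Three
questions are addressed: (1) which variables predict MOUD receipt, via a
gradient-boosted tree classifier interpreted with Shapley values; (2) how
treatment rates differ by living arrangement, overall and within service
settings; (3) how much of the housed/unhoused rate gap is attributable to
*which settings* each group enters, via direct standardization.

## Synthetic-data generator

The generator is first-class, tested code, not a fixture. Its probabilistic
model is:

1. living status `g` ~ Categorical over {independent, dependent, unhoused,
   unknown};
2. service setting `s | g` ~ Categorical over 8 settings with
   status-specific shares `w_g`;
3. covariates drawn independently from per-variable level distributions;
4. outcome ~ Bernoulli with logit `b(g, s) + Σ_v e_v(level_v)`, where the
   `e_v` are per-level log-odds effects;
5. "Unknown" contamination applied last, independently per variable: the
   drawn value is replaced by the unknown label and the true value is
   discarded (unknownness is modelled as its own, potentially informative,
   category — never imputed);
6. the outcome itself is set to Unknown with probability 0.073, mirroring
   the exclusion rate of the real cohort.

**Mean-preserving effects.** Before sampling, each cell's base logit
`b(g, s)` is recentred by a monotone root-find so that the cell's *marginal*
outcome rate equals the configured `r_g(s)` exactly, with the effect
distribution integrated out (the exact distribution of the summed shift is
enumerated over effect-bearing covariates). Covariate effects therefore
create learnable within-cell signal without moving any planted rate. This
makes the planted truth closed-form:

    E[rate | g] = Σ_s w_g(s) · r_g(s)
    R_cf        = Σ_s w_ref(s) · r_target(s)

and every downstream estimator can be checked against exact expectations.

**Default calibration.** The per-cell rates `r_g(s)` and four share values
(independent: 56.18 % / 16.69 %; unhoused: 23.56 % / 34.74 %) are taken
verbatim from the published cross-tab. The remaining share parameters are not
published; they were solved once (quadratic program with equality
constraints) so that the expected group rates are exactly 44.92 / 34.54 /
28.56 %, the overall rate is exactly 40.40 %, the mixture of shares over the
living-status prior (0.70 / 0.10 / 0.12 / 0.08) approximates the published
overall setting mix, and every cell share is at least 0.4 % so no cell is
near-empty at realistic cohort sizes. Unknown-living cells use a scaled
dependent-living rate profile chosen to close the overall rate; state and
substance-use-frequency covariates carry modest (±0.8, ±0.25 log-odds)
effects so that geography is genuinely predictive.

One caveat is intrinsic: the published margins are mutually inconsistent at
full precision. With the two printed independent-living share anchors fixed
and the expected independent rate constrained to 44.92 %, the maximum
achievable standardized rate `Σ w_ind · r_unh` is 41.60 % — the published
43.20 % (and hence the 89.50 % elimination share) is reachable only from the
unrounded full-data vectors, which are not printed. The default calibration
balances closeness to that target against a realistic setting mix and lands
at a planted counterfactual rate of 38.44 % (elimination share 60.38 %). The
desk-scale quantities (16.36, 1.72, 89.49 %) are always re-derived from the
printed operands themselves, not from the generator.

**What the generator does not emulate**: privacy swapping, suppressed
metropolitan areas, the full 627-subgroup taxonomy, admission-level serial
correlation (patients admitted multiple times per year), or dependence
between covariates. Passing tests demonstrate that the *methods* recover
planted structure under the stated sampling model, not that real-data
estimates are unbiased.

## Preprocessing

Fixed order: opioid filter on the primary substance (heroin, non-prescription
methadone, other opiates/synthetics) → drop unknown outcomes (fraction
reported) → drop excluded features (admission year, case ID) → detail-variable
merges → balance → split → encode.

* **Merges.** The not-in-labor-force detail is substituted into the
  employment variable where employment equals the trigger level; likewise the
  detailed criminal-justice referral into the referral source. Merged levels
  keep the child label verbatim; a label collision with a parent level is
  namespaced `CHILD:label`; unknown child under a triggering parent becomes
  `<trigger>-Unknown` so unknownness stays visible. The trigger level is
  configurable because real codebooks differ on which referral code carries
  detail.
* **Balancing** randomly undersamples the majority outcome class to exact
  equality (minority rows all kept), before splitting, so all three partitions
  are balanced.
* **Splitting** is 70/15/15 and stratified by outcome. Stratification is a
  package choice (it removes an avoidable variance source at desk-scale n);
  validation selects hyperparameters, test is held out for final metrics.
* **Encoding** maps ordinal variables to their codebook rank (e.g. AGE bands
  youngest → oldest) and categorical variables to stable positional integer
  codes; "Unknown" is an ordinary level, never a missing value, and no
  imputation is performed anywhere.

Determinism: every stage takes an explicit seed; the pipeline expands one
root seed per stage via `numpy.random.SeedSequence`, and identical
configurations produce byte-identical report bundles.

## Model and tuning

XGBoost, binary logistic objective, histogram tree method, single-threaded
(bit-reproducibility). The hyperparameter search space (depth 2–10, 50–2000
trees, learning rate 10⁻³–0.3 log-scale, row/column subsampling 0.5–1.0,
min-child-weight 0–10, L1/L2 regularization) is conventional and
configurable — the source analysis does not publish its space, budget or
search implementation, so none of these are treated as facts. The Bayesian
loop fits a Matern-5/2 Gaussian-process surrogate to (combination,
validation-AUC) pairs on the unit-cube-normalized space and maximizes
expected improvement over random candidates; the first quarter of the budget
(at least 4 trials) is random. The winner is the trialed combination with
the highest validation AUC; the full trial log is retained. Desk-scale runs
use a trimmed space (30–300 trees, depth ≤ 8) and budgets of ~10–20 trials.

## Interpretation

Shapley values are computed with the tree-exact algorithm built into the
boosting library (`pred_contribs`), on the log-odds scale; additivity
(base value + row sum = margin) is enforced to 1e-4. Importance is the mean
absolute Shapley value over the **test** partition, normalized to sum to
100 % — interpreting predictions rather than training fit. Category
aggregation sums member shares and conserves the total. Subgroup summaries
report median and linear-interpolation quartiles of a variable's own Shapley
column within each of its levels. Shapley importances are relative to the
feature set in the model; adding or removing variables reallocates shares.

## Disparity statistics

Rates are percents; all comparisons are computed at full precision and
rounded only for display. The significance test behind the stars
(\* p<0.1, \*\* p<0.05, \*\*\* p<0.01, \*\*\*\* p<0.001) is a two-sided
pooled-variance two-proportion z-test — the source tables do not name their
test, so this minimal standard choice is a configuration, and no
multiple-testing correction is applied to mirror the published presentation.
Flow tables give each group's share of admissions per setting (summing to
100 %) and the per-setting treated rate, plus a (source, target, value) edge
list for any Sankey renderer.

## Counterfactual decomposition

`standardized_rate` is linear in rates and invariant to consistent setting
permutations; `decompose` reads shares and rates off the cross-tab at full
precision. The disparity sign convention is reference − target (positive =
target disadvantaged). A setting where the target group has no admissions
but the reference share is nonzero has an undefined standardized term; the
default policy substitutes the setting's pooled all-group rate, and a strict
mode raises instead — the choice is explicit because the published analysis
never encounters it. Admissions with unknown living arrangement form their
own group and are excluded from both the reference and target vectors. The
decomposition is a standardization, not a causal estimate: it assumes the
target group could enter the reference group's settings at will.

## Numerical choices and limitations

* Probability vectors validated to 1e-9; importance normalization conserved
  to better than 1e-6 (attributions are accumulated in float64).
* The elimination share is a ratio of differences; near-zero observed
  disparities are flagged undefined rather than returned as huge ratios, and
  its sampling noise is visibly larger than that of the underlying rates.
* Quantile rule: linear interpolation (the published figures do not specify
  one).
* Problem sizes in the test and acceptance runs (200,000 admissions for
  rate/decomposition recovery, 60,000 for the end-to-end modelled pipeline,
  5,000 for planted-feature recovery) are the package's desk-scale defaults,
  chosen so the full suite runs comfortably on a single CPU; all scale up
  unchanged.
* The model/interpretation stage on default synthetic data yields AUC ≈ 0.78
  with service setting ranked first — the planted structure is deliberately
  simpler than real data, where richer covariate dependence yields higher
  discrimination. Published headline metrics that depend on the real extract
  (AUC 0.9411, accuracy 85.97 %, the exact importance shares) are out of
  scope for synthetic tests.
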