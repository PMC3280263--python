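# Methods

## The MDR procedure

`mdrkit` implements classical multifactor dimensionality reduction for a
binary phenotype and categorical attributes (SNP genotypes with 2–3 levels,
binary exposures, BMI quartiles). For an attribute combination of order k,
subjects are tabulated into the joint level cells; a cell is labeled *high
risk* when its case/control ratio strictly exceeds the case/control ratio T
of the fitting sample, *low risk* otherwise. The labeled table is a binary
classifier (high = predicted case) scored by balanced accuracy,
BA = (sensitivity + specificity)/2.

MDR is model-free: no penetrance form, no additivity, no
Hardy-Weinberg assumption enters the classifier itself. What the procedure
does assume is (i) a strictly binary phenotype, (ii) listwise-complete
values on the attributes being searched (subjects with missing values are
removed first), and (iii) enough subjects per class for stratified
cross-validation (each class at least F members).

### Labeling details

* T is computed from the **training subjects only** — the "sample
  population" against which cells are compared is the data used to fit, so
  labeling never sees held-out subjects.
* Ratio comparisons are exact integer cross-multiplications
  (`n_case·C_train > N_train·n_ctrl`); no floating point is involved, so a
  cell exactly at T is unambiguous. The default tie rule is strict `>`
  (a cell exactly at T is low); `gte` is available for compatibility with
  other MDR implementations.
* A cell with cases but no controls has ratio +∞ and is high; no cases
  means low.
* Cells unseen during fitting are labeled low by default, which keeps the
  classifier total and testing BA always defined; an `exclude` policy (drop
  such subjects from scoring) is available.

### Cross-validation and selection

Folds are stratified (cases and controls dealt round-robin after separate
shuffles, per-class fold sizes within 1) and reproducible from a seed.
Per fold, every combination of the order is fitted on the other F−1 folds
and scored on the held-out fold; the fold winner is the combination with
the highest training BA, compared by the integer score
`TP_cells·C_train + TN_cells·N_train` (a strictly monotone transform of
training BA), so winner selection is exact and ties break deterministically
to the lexicographically smallest combination. CVC is the number of folds a
combination wins; the best model per order has the highest CVC with mean
testing BA as tie-break, and the overall selection across orders maximises
testing BA, then CVC, then parsimony (smaller order). Reported training and
testing BAs are arithmetic means over folds (the pooled-confusion
alternative was considered and rejected as the less common convention;
per-fold values are retained on every `ModelEvaluation`).

### Two testing-accuracy quantities

A subtlety worth stating explicitly: the mean testing BA attached to the
*best model* of an order is a property of a combination whose identity was
chosen using the whole sample, and therefore carries winner's-curse
selection bias — on pure-noise data it averages ≈0.56 rather than 0.50 at
n=200 with 5 attributes. The unbiased cross-validated estimate of what the
MDR procedure's chosen model would do on new data is the **prediction
estimate** (`OrderSummary.prediction_ba`): for each fold, the testing BA of
that fold's winner — selected on training data alone — averaged over folds.
This is the quantity that centres on 0.50 under the null and is what
"cross-validation guards against over-fitting" refers to; the calibration
tests assert it. Both quantities are reported. This is also why the final
models are re-validated by permutation: the permutation null re-runs the
full cross-validated evaluation, so it absorbs the selection bias of the
table quantities.

### Validation tests

* **Permutation test** — phenotype labels permuted; folds redrawn; the full
  cross-validated statistic (mean testing BA of the fixed candidate
  combination, by default) recomputed per replicate. This is the statistic
  the result tables attach p-values to; re-running the entire exhaustive
  search per replicate would test a different (familywise) hypothesis and
  is intentionally not the default.
* **Explicit test of epistasis** — every combination attribute's column is
  shuffled independently *within cases* and *within controls*. Each
  resample preserves every single-attribute contingency table with the
  phenotype exactly (asserted in tests), so main effects survive under the
  null and rejection specifically evidences joint structure. A model with a
  strong marginal attribute can be permutation-significant yet
  explicit-nonsignificant; the tests reproduce this mechanism on
  main-effect-only simulations.
* Resampling p-values use the add-one convention p = (r+1)/(B+1), so p ≥
  1/(B+1) and never exactly zero. B defaults to 1000.
* **Likelihood-ratio test** — logistic (binomial GLM) fit on grouped
  per-cell data: reduced = intercept + treatment-coded main effects
  (reference = most frequent level, for determinism; the deviance is
  invariant to the coding); full = main effects plus *all* interaction
  terms among the combination's attributes. The full model is saturated on
  the realised joint cells, so its deviance is exactly 0 and the statistic
  equals the reduced model's residual deviance; df = realised cells −
  rank(main-effects design). Non-convergence or unbounded estimates are
  flagged and the p-value reported as not estimable rather than guessed.
* **Chi-square** — Pearson 1-df test, no continuity correction, of the 2×2
  table predicted-risk × phenotype.

### Entropy analysis

Interaction information II(A;B;C) = I(A,B;C) − I(A;C) − I(B;C), plug-in
(maximum-likelihood) estimates in bits. Positive = synergistic, negative =
redundant, |II| ≤ 0.001 bits labeled additive. The plug-in estimator is
upward-biased on the joint term (≈ extra degrees of freedom / (2N ln 2));
no bias correction is applied by default to match the MDR software family's
convention, and the synergy calls in the tests are made at planted effect
sizes whose exact population II (computed from the penetrance model without
sampling) is an order of magnitude above that bias.

## QC pipeline

Fixed order: attribute call-rate filter first (default minimum 0.98),
then listwise deletion of subjects incomplete on the analysis attributes.
The reverse order would needlessly delete subjects for attributes that are
about to be dropped. Hardy-Weinberg equilibrium is tested per three-level
SNP by 1-df Pearson chi-square against expectations at the sample allele
frequency (no continuity correction, no exact test); monomorphic SNPs get
χ²=0, p=1 with a warning flag. HWE results are reported, not used to drop
SNPs automatically — inclusion is a configuration decision, since panels
occasionally retain borderline-HWE SNPs deliberately.

Derived attributes: home dampness is the OR of three questionnaire items
(visible mould, mould odour, damp stains); a missing item is treated as
non-informative, so only all-three-missing propagates missing. BMI is cut
into quartiles at the empirical 25/50/75 percentiles of the non-missing
analysis sample, half-open at the top (a value exactly on a cut-point falls
in the lower quartile); fewer than four distinct values is an error rather
than a degenerate 4-level attribute.

## Synthetic data

The generator draws attributes independently — Hardy-Weinberg genotypes at
specified MAFs, Bernoulli exposures, uniform quartiles — assigns case
status from a penetrance table over the involved attributes, and
rejection-samples until the target case/control counts are exactly filled.
Rejection sampling is exact for any penetrance table and costs only a few
batches at the default prevalences.

`study_emulator` reproduces the *structure* of a childhood-asthma
candidate-gene panel: 15 three-level SNPs at their published MAFs
(0.045–0.493), two deletion polymorphisms (GSTT1, GSTM1) as present/null at
a default null frequency of 0.5 (no genotype frequencies are published for
them), eight binary exposures at a default prevalence of 0.3, one quartile
BMI attribute, and 235 cases / 1,075 controls. Exposure prevalences and all
effect sizes are emulator defaults, not estimates from any dataset, and are
labeled as such in the recipe metadata written next to each simulated file.

Planted structure, chosen as follows:

* **Three-SNP interaction** (GSTP1/IL4Ra/INSIG2 columns): penetrance
  baseline 0.10, +0.50 when all three loci carry at least one minor allele.
  The joint-carrier (AND) family was chosen over 2-of-3-carrier and parity
  alternatives because its exact population pairwise interaction
  information is positive for **every** pair of the triple at these MAFs
  (0.012/0.020/0.004 bits) — the all-positive pairwise synergy structure
  the analysis is designed to detect — whereas the alternatives leave one
  pair at effectively zero. The comparison was done on exact joint
  distributions (`population_interaction_information`), not samples.
* **Exposure-pair interaction** (preterm birth × dampness): +0.15 when both
  are present, on top of whatever the SNP term contributes.

`xor_penetrance` provides the canonical no-main-effect two-locus epistasis
fixture: penetrance baseline+effect on cells with odd level-code sum. When
each attribute puts probability 1/2 on its odd levels (binary at prevalence
0.5, or a Hardy-Weinberg SNP at MAF 0.5, whose heterozygote mass is exactly
1/2), both marginal penetrances equal the prevalence exactly — verified
symbolically in the constructor, which refuses frequencies that would leak
main effects. `parity_penetrance` generalises this to k loci.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, population stratification, genotyping error and missingness patterns,
correlated exposures, and quantitative phenotypes. Passing tests therefore
show that the machinery is correct and calibrated under independence, not
that any particular real-data finding is reproducible.

## Problem sizes in the test and acceptance runs

Simulation-based checks use desk-scale sizes chosen to give stable pass/
fail behaviour on one CPU: 500 random datasets (≤30 subjects) for oracle
agreement; 200 null datasets (100/100, 5 SNPs) with B=199 permutations for
calibration; 50 seeds each for XOR (400/400) and three-locus (235/1,075)
recovery; 200 replicates with B=99 for the main-effect/interaction
separation; 50 emulator replicates for the synergy property. The acceptance
script uses the same designs at equal or slightly reduced replicate counts.

## Known limitations

* The exhaustive search is O(C(n,k)·F); it is comfortable at the panel
  scale it targets (26 attributes, k ≤ 5) and is not a GWAS tool.
* No model-based MDR variants, covariate adjustment, or multiple-testing
  correction across ranked lists (the workflow validates individual
  candidate models instead).
* The explicit test destroys *all* joint structure among the combination's
  attributes, including attribute–attribute association unrelated to the
  phenotype; with strongly correlated attributes its null is therefore
  slightly conservative.
* PLINK .ped/.map input is read-only and collapses allele pairs to
  three-level genotypes; VCF is out of scope for this categorical data
  model.
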