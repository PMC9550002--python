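# Methods

## The model

The analysis treats a cohort of subjects with a binary outcome Y (postoperative
sepsis), a set of putative risk factors (exposures) and a set of potential
confounders, all categorical after clinical discretization. Adjustment is
performed in two stages:

**Stage 1 — stratification.** A regression tree on the 0/1 outcome is grown
over binary confounder indicators (each K-level confounder contributes K−1
one-vs-rest indicators for its non-reference levels). The split criterion is
the reduction of the within-node sum of squares of Y, which for a binary
outcome equals the weighted between-group incidence separation and is half the
Gini-impurity reduction — so an exhaustive single-split search or a Gini-based
tree can serve as an independent oracle. Growth stops at nodes below the
minimum split size, when no split reduces SSE, or when a child would fall
below the minimum leaf size. The full tree is pruned along the weakest-link
cost-complexity path (α non-decreasing, subtrees nested, ending at the
root-only tree); α is selected by stratified k-fold cross-validation, and ties
go to the largest α (the simplest tree). Candidate trees from nested
confounder sets (model 1: demographics; model 2: + comorbidities; model 3:
+ preoperative management) are ranked by

AIC = −2 Σᵢ [yᵢ ln p̂ₗ₍ᵢ₎ + (1−yᵢ) ln(1−p̂ₗ₍ᵢ₎)] + 2·L,

where p̂ₗ is the leaf incidence and L the number of leaves. Leaves of the
selected tree define the strata.

**Stage 2 — pooling.** For each exposure contrast (each non-reference level
versus the declared reference, other levels excluded), per-stratum 2×2 tables
(a,b,c,d) are pooled with the Mantel-Haenszel common odds ratio
Σ aᵢdᵢ/nᵢ ÷ Σ bᵢcᵢ/nᵢ (Robins-Breslow-Greenland variance) or the MH common
risk ratio Σ aᵢ(cᵢ+dᵢ)/nᵢ ÷ Σ cᵢ(aᵢ+bᵢ)/nᵢ (Greenland-Robins variance).
Crude estimates use the cross-product ratio with the Woolf CI (odds) or the
Katz log CI (risk). A logistic-regression sensitivity analysis fits exposure +
confounder main effects + any confounder interactions flagged by
likelihood-ratio screening (p < 0.05), reporting Wald CIs.

### Effect-measure convention

The adjusted effect table defaults to **odds ratios**: the published crude
column is reproduced exactly by the cross-product ratio (emergency surgery
8.30, CAR 3.46) and not by the risk ratio (6.46 for emergency), so the odds
ratio is the estimand that matches the reference results. Pairwise tree-node
comparisons, by contrast, reproduce as **risk ratios** (6.01 at the root
split), so the tree pipeline defaults to risk ratios. Every output row is
labeled with its measure. Both MH estimands are implemented; which one the
reference analysis used for its adjusted columns is not recoverable without
the raw data, so the OR reading is the default and is flagged as a convention.

## Parameters that matter

| Parameter | Default | Why |
|---|---|---|
| `min_split` | 20 subjects | smallest node eligible for splitting, the stated analysis default |
| `min_leaf` | 7 (= round(20/3)) | smallest admissible child, mirroring the recursive-partitioning tool family's default ratio |
| CV folds | 10, stratified on outcome | preserves the ~5% event rate in every fold |
| CV metric | held-out MSE (Brier) | see below; `deviance` and `accuracy` available |
| CI level | 95%, z = 1.959964 | reporting convention of the reference results |
| zero cells | +0.5 to all four cells (Haldane-Anscombe), flagged | keeps crude estimates finite |
| leaf ε | p clamped to 1/(2n) | finite AIC likelihood at pure leaves |
| fold seed | 20150901, logged | bit-reproducible pruning |

**Why MSE and not accuracy for CV.** At ~5% outcome prevalence every pruned
subtree predicts the majority class, so held-out classification accuracy is
constant in α; with the largest-α tie-break it would always select the
root-only tree and stratification would never happen. Held-out MSE (the
Brier score) is the natural test score of the regression-tree reading of the
sum-of-squares split criterion and discriminates properly at low prevalence;
held-out deviance behaves equivalently and is available via configuration.

**Imputation and discretization.** Missing continuous cells take the column
mean, categorical cells the most frequent level (ties broken toward the
lexicographically smallest label, for determinism), and imputation precedes
discretization. Interval boundaries follow the declared clinical groups
verbatim, including which side each boundary value joins (SCr 116 → "≤116",
CAR 0.278 → "≥0.278", BMI 24 → "≥24"). The albumin levels are declared as
printed in the reference table even though the reference level there shows
the *higher* incidence; the intake step emits a warning whenever a binary
exposure's reference level has higher incidence than its exposed level, so
inverted labels surface instead of silently flipping estimates.

**Chi-square convention.** 2×2 tables use the Yates continuity correction;
K>2 tables do not. Recomputing the sex row from the published counts gives
p = 0.0016 with the correction (printed: 0.002) versus 0.0014 without, which
fixes the convention.

## The synthetic generator

The generator emulates the study conditions at the categorical level:

- **Confounders** are drawn independently from the published marginal
  prevalences (the comorbidity count is derived from the seven comorbidity
  flags rather than drawn, so it is always consistent with them). Pairwise
  dependence is not simulated: only marginals are published, and independence
  reproduces the published comorbidity-count distribution to within a
  percentage point.
- **Baseline risk** is a seven-leaf tree anchored to the published
  incidences: 30.3% with cerebrovascular disease; aggregate 5.0% without
  (implying ≈5.39% overall against the reported 5.4%); risk ratio 1.92 for
  age ≥75 within the branch free of cerebrovascular disease, transfusion and
  pneumonia. The transfusion (0.125) and pneumonia (0.105) leaf risks and the
  tumor/diabetes leaf ratios (0.75, 2.0) are free parameters — the reference
  figures do not print them — fixed once at clinically plausible intermediate
  values; the remaining leaf risks are then solved in closed form so the
  anchors hold exactly.
- **Exposures** are drawn with a logistic (softmax for multi-level) dependence
  on the centered baseline log-odds; the dependence weight is what plants
  confounding. Intercepts are tuned by fixed-point iteration so marginal
  prevalences match their targets. Default effects are the published crude
  log odds ratios with weight 0.3.
- **Outcomes** are Bernoulli with linear predictor = leaf log-odds + centered
  exposure contributions β·(x − π). Centering alone leaves a Jensen-type bias
  in leaf incidence, so a per-leaf intercept is calibrated by Newton's method
  to make the expected incidence in each leaf equal its planted risk. The
  calibration only shifts leaf intercepts, so planted conditional odds ratios
  are exactly exp(β) throughout.

What the generator does **not** emulate: raw laboratory values before
discretization, confounder-confounder correlation, calendar time, center
effects, or outcome misclassification. Passing recovery tests therefore show
that the estimators undo the *planted* tree-structured confounding, not that
they would undo every bias structure present in real registry data.

## Problem sizes used in the checks

The simulation-based checks run at sizes chosen to make Monte Carlo noise
negligible relative to the tested margins: coverage of a planted conditional
OR 2.0 uses 200 replicate cohorts of n = 3,000 with a two-leaf risk tree
(crude OR inflated above 2.6 by design); root-split recovery uses 100
replicate cohorts at the full n = 7,302 with the complete default
configuration and 10-fold cross-validated pruning; the MH formula sweep is
exhaustive over two-stratum tables with cells ≤ 2 plus a seeded random sample
of the cells ≤ 12 space, cross-checked against statsmodels' StratifiedTable.

## Known limitations

- The MH estimators assume a common effect across strata; no homogeneity
  (Breslow-Day) test is provided, matching the reference analysis.
- Wald CIs only for the logistic fits; profile-likelihood CIs are not
  implemented. Quasi-separation is flagged, not resolved (no Firth
  correction).
- The published adjusted columns and printed tree AICs depend on the raw
  cohort and are not reproducible from summary counts; the package's
  substitute evidence is the oracle-equivalence and parameter-recovery checks
  above.
- The pairwise-node CI printed alongside the reference root split (3.91–9.04)
  does not match any standard risk-ratio CI recomputed from the printed
  counts (Katz: 4.46–8.10); only point estimates are treated as reproducible.
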