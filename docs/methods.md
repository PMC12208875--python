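# Methods

## Problem setting

Patients with polycythemia vera (PV) starting first-line hydroxyurea (HU) are
followed for 12 months from the index date (first HU prescription, day 0).
Resistance (HU-RES) is assessed in the 6–9-month post-index window; the goal
is to predict it from *pre-index* demographics and laboratory values, and to
find interpretable biomarker thresholds — in particular the red cell
distribution width (RDW) / hemoglobin (HGB) pair — that stratify risk.

## Synthetic cohort generator

Real EHR cohorts of this kind are proprietary, so the package ships a
generator whose output has the statistical structure the analysis assumes.

**Marginals.** Each continuous variable has group-specific (resistant /
non-resistant) marginal distributions. Truncated normals are used, with the
pre-truncation parameters solved numerically so the *post-truncation*
mean/SD equal the configured group moments (supports: labs ≥ 0, HCT ∈ (0,100),
age ≥ 18, weight ≥ 30 kg, diagnosis-to-treatment ≥ 1 day). The annualized
phlebotomy count is the exception: its configured coefficient of variation
(1.44/0.74 ≈ 1.95 in the resistant group) exceeds what any zero-truncated
normal can express (CV → 1 in the exponential limit), so it uses a
moment-matched gamma marginal — also the more realistic shape for a count
rate with a large mass near zero.

**Defaults.** Group moments for RDW, HGB, HCT, WBC, ANC, age, the phlebotomy
rate, gender, and thromboembolism history follow the observed cohort the
generator is meant to emulate (e.g. RDW 18.1 % (SD 3.22) resistant vs 17.1 %
(SD 3.05) non-resistant; resistant fraction 733/1304). No group-level
reference values exist for RBC, platelets, lymphocytes, weight, or
diagnosis-to-treatment time; their defaults are **invented** plausible values
and are flagged as such here. NLR is not sampled: it is defined as
ANC/lymphocytes (a record invariant), so its group moments are only emulated
approximately through the ANC and lymphocyte choices.

**Correlation.** A Gaussian copula with a one-factor correlation structure
Λ = λλᵀ + diag(1 − λ²) (the "myeloproliferation" factor; default loadings
0.65 on WBC/ANC down to ±0.15 on HGB/lymphocytes) makes blood counts co-vary
within groups. The loadings are package choices, not estimates.

**Outcome model.** Covariates are drawn from the two-group mixture; the
resistance flag is then Bernoulli with

    P(res | x) = logistic( baseline_logit + s · logLR(x) + δ · 1[RDW ≥ 17, HGB < 15.5] )

where logLR is the exact log likelihood ratio of the two group densities
(copula included), `s` = `separation_scale` and `δ` = `interaction_effect`.
With the defaults (`baseline_logit = logit(resistant_fraction)`, `s = 1`,
`δ = 0`) this is the exact Bayes posterior of group membership, so per-group
sample moments recover the configured moments in expectation — the
parameter-recovery property holds by construction rather than approximately.
`s = 0` removes all covariate information (outcome independent of the
record); `δ > 0` plants extra risk in the high-RDW/low-HGB quadrant on the
log-odds scale. The default is `δ = 0` (the generator emulates the observed
cohort); planted-signal studies in the tests use `δ = 2.0` ("strong": odds
ratio ≈ 7.4 inside the quadrant), a value fixed before those tests were run.

**Timelines.** Each patient gets a PV diagnosis at −(diagnosis-to-treatment)
days, HU prescriptions at day 0 and ~90, serial 8-analyte lab panels every 42
days from −183 to 365 (the last pre-index panel carries the exact baseline
values, so timeline-derived features equal the record), pre-index
phlebotomies as a Poisson process with the patient's annualized rate, and —
for resistant patients — one qualifying trigger inside the labeling window
(phlebotomy 50 %, HCT ≥ 45 % 30 %, WBC > 10 with PLT > 400 20 %).
Non-resistant timelines are kept free of qualifying events throughout the
tolerance-extended window, so window labeling recovers the ground-truth flag
(the tests require ≥ 99 % agreement; in practice it is exact). An optional
`n_ineligible` count appends patients violating one funnel criterion each.

**What the generator does not emulate:** coding systems, visit structure,
irregular measurement times, missing-not-at-random labs, dose information,
secular trends, or competing risks. Passing tests demonstrate correctness of
the *analysis machinery* under the assumed structure, not performance on real
EHR data.

## Labeling and funnel

The ELN consensus resistance definition is adapted to dose-free records: in
the window [183, 274) days (6–9 months at 30.44 days/month), extended ± 14
days, a patient is resistant if (a) any phlebotomy, else (b) any HCT ≥ 45 %,
else (c) WBC > 10 ×10⁹/L and PLT > 400 ×10⁹/L measured within 14 days of each
other (the (a) > (b) > (c) priority is a tie-break choice; the trigger day of
(c) is the day both conditions are confirmed). Non-resistant patients are
censored at day 365. Baseline labs use the *most recent* pre-index value per
analyte (configurable window, default 183 days); the annualized phlebotomy
count is the pre-index count × 365/183. Funnel stages run in a fixed,
documented order and counts are non-increasing by construction.

## Random-forest ranking

Stratified 80:20 split; stratified 5-fold CV inside the training set.
Hyperparameters not fixed by the study design default to 500 trees, √p
features per split, minimum leaf 5; missing values are median-imputed per
training fold. Importance defaults to permutation importance on the held-out
fold (ROC-AUC scoring, 5 repeats) — model-agnostic and fold-aware — with
impurity importance available as a faster option. Per fold, importances are
converted to ranks 1..p (ordinal tie-break); the rank score is the mean over
folds. The composite ROC-AUC is computed from pooled out-of-fold
predictions (per-fold AUCs reported alongside; a separate model fit on the
full training set is scored on the 20 % validation split). The direction of
association is the sign of the resistant-minus-non-resistant group mean.

## Threshold scans and synergy

"Best" split means the *most significant* (minimum) log-rank p-value over the
candidate grid: that is the only reading under which the synergy arithmetic
(expected = Pₐ·P_b vs observed P_ab, with scores ≫ 1) is coherent.
Candidates are unique observed values clipped to the 10th–90th percentile,
with ≥ 10 patients per side ("high" = value ≥ threshold; ties break toward
the smaller threshold). Pair scans test every quadrant with ≥ 10 patients on
both sides against the rest (two-group log-rank); the tie-break is smaller
t₁, then t₂, then quadrant order Q1 < Q2 < Q3 < Q4. For tractability the
pair grid subsamples each axis to ≤ 20 quantile-spaced candidates by default
(configurable; the single-variable grid is exhaustive). Scans use a
vectorized O−E/V tabulation validated against lifelines and a hand
tabulation; groupings with zero log-rank variance get (χ² = 0, p = 1). No
multiplicity adjustment is applied — the scans report raw maximally selected
p-values, which are strongly optimistic; the number of tests is implicit in
the grid and users should adjust post hoc if inference is intended.

**Calibration of the synergy score.** Because Pₐ, P_b, and P_ab are all
minima over (correlated) scan grids, S_ab is only interpretable on an
orders-of-magnitude scale. Under a complete null (outcome independent of
both variables) the median S_ab across replicates sits within one order of
magnitude of 1 (measured median ≈ 0.4, range spanning ~5 decades over 20
replicates at n = 1304). When both variables carry *marginal* signal but no
interaction, S_ab is typically ≪ 1: the combined split cannot beat the
product of two already-extremized single p-values. Values in the hundreds or
thousands therefore indicate genuine super-multiplicative structure.

**Survival endpoint.** Time-to-resistance with censoring at follow-up end is
used for all log-rank machinery (rather than recasting the 6–9-month binary
endpoint), which keeps KM curves and scans on one consistent scale.

## Reporting

KM curves come from the product-limit estimator; the RDW/HGB decision rule is
a fixed two-threshold classifier (it is presented as thresholds, not a fitted
tree). Group comparisons use the two-sided Mann-Whitney rank-sum test for
continuous labs and a two-proportion z-test for resistance rates (the tests
are package choices). The trial-precision helper is the normal-approximation
CI half-width z·√(p(1−p)/n).

## Numerical choices and degenerate inputs

- Truncated-normal moment matching solves a 2-D root problem (hybr) to
  residuals < 10⁻⁶·SD; copula CDF values are clipped to [10⁻¹³, 1−10⁻¹³]
  before the normal quantile transform.
- A variable constant within the pair grid degenerates to a single all-high
  threshold, so the pair scan reduces exactly to the other variable's single
  split.
- Empty quadrants have undefined (NaN) enrichment; when all four are
  populated the size-weighted mean enrichment is identically 1.
- Identical comparison groups short-circuit to p = 1 (rank-sum ties make the
  asymptotic statistic undefined).
- Pipeline text outputs are byte-identical across re-runs with the same
  configuration and seed; SVG figures use a fixed hash salt.

## Problem sizes used in the test suite

Oracle-equivalence checks run on ≤ 50-patient fixtures against brute-force
enumerations; calibration and planted-signal suites use 20 replicates at
n = 1304 with 200 trees and the 20-candidate pair grid; unit tests use
120–600 patients. These sizes are the package's choice of a thorough but
quick default suite; all of them are plain function arguments that scale up
directly.

## Known limitations

- The synthetic generator's copula and invented moments are stand-ins; none
  of the numerical results on synthetic cohorts estimate real-world effect
  sizes or model performance.
- Maximally selected p-values are reported unadjusted (see above).
- The ELN adaptation omits the dose-adequacy clause (dose is absent from the
  data model) and applies a fixed criterion priority; both choices are
  explicit stand-ins for unavailable operational detail.
- Labeling treats the tolerance-extended window as flat: an event at the
  window edge counts the same as one at its center.
- The composite AUC definition (pooled out-of-fold) is one of several
  reasonable "composite" readings; per-fold means are reported alongside.
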