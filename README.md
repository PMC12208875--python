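# hupred

Risk modelling of **hydroxyurea resistance (HU-RES) in polycythemia vera
(PV)** from routine pre-treatment laboratory data.

Polycythemia vera is a JAK2-driven myeloproliferative neoplasm; hydroxyurea
(HU) is its most common first-line cytoreductive drug, but a substantial
fraction of patients become resistant within the first 6–9 months of therapy
(by European LeukemiaNet-style criteria: continued phlebotomy need,
uncontrolled hematocrit ≥ 45%, or persistent leukocytosis plus
thrombocytosis). `hupred` is a library for building and validating early
predictors of that outcome from EHR-like cohorts. It is aimed at
biostatisticians and pharmaco-epidemiologists who want a fully testable,
simulation-backed version of this analysis chain:

1. **Synthetic cohorts** (`hupred.simulate`) — patient tables and event
   timelines with configurable per-outcome-group moments, a Gaussian-copula
   correlation structure, and a *plantable* RDW × HGB interaction on
   resistance risk, so every downstream stage can be validated against ground
   truth without access to any proprietary EHR database.
2. **Cohort selection and labeling** (`hupred.selection`) — the
   inclusion/exclusion funnel (adults, PV diagnosis before first HU, ≥ 2 HU
   prescriptions, no MF/ET, HU-only therapy, history/follow-up spans,
   pre-index labs) and ELN-adapted HU-RES labeling in the 6–9-month
   post-index window (± 14 days tolerance).
3. **Random-forest ranking** (`hupred.forest`) — stratified 80:20 split,
   5-fold cross-validation, per-fold feature-importance ranks averaged into a
   rank score, composite ROC-AUC of pooled out-of-fold predictions.
4. **Threshold synergy** (`hupred.synergy`) — maximally selected log-rank
   cutpoints for single variables and variable pairs, and the synergy score

   $$S_{ab} = \frac{P_a \cdot P_b}{P_{ab}}$$

   where $P_a$, $P_b$ are the most significant log-rank p-values attainable
   by dichotomizing variables $a$ and $b$ on a threshold grid, and $P_{ab}$
   is the most significant p-value of any threshold pair combined with one of
   its four quadrants (quadrant vs. rest). $S_{ab} \gg 1$ flags a
   super-multiplicative, i.e. synergistic, pair. Quadrant enrichment
   compares resistant prevalence per quadrant with the cohort prevalence.
5. **Reporting** (`hupred.reporting`, `hupred.pipeline`, `hupred` CLI) —
   Kaplan–Meier stratification, the two-threshold RDW/HGB risk rule
   (RDW ≥ 17 %, HGB < 15.5 g/dL ⇒ highest risk), high/low-RDW group
   comparisons, proportion-CI precision, and an end-to-end reproducible
   pipeline.

## Worked example

`examples/synergy_scan.py` generates a 1304-patient cohort with a planted
high-RDW/low-HGB effect (2.0 log-odds), labels resistance from the timelines,
and scans all 45 pairs of the ten standard pre-index variables:

```text
 var1          var2  synergy     t1      t2 quadrant  enrichment_Q1  enrichment_Q2  enrichment_Q3  enrichment_Q4
  RDW           HGB  751.869 16.804  15.406       Q1          1.348          1.008          0.684          0.807
 age_at_index   HGB    0.465 66.474  15.134       Q2          1.068          0.808          1.096          1.126
 ...
45 pairs evaluated (C(10,2) = 45).
```

The planted pair wins by orders of magnitude; the recovered thresholds
(16.8 %, 15.4 g/dL) sit one grid step from the planted (17, 15.5); quadrant
Q1 (high RDW, low HGB) is the winning quadrant and the most enriched in
resistant patients (1.35× the cohort prevalence), while Q3 (both low) is the
most depleted (0.68×) — exactly the structure the risk rule encodes. The
remaining examples cover cohort simulation and moment recovery, the funnel
and labeling (`100.0%` ground-truth agreement), feature ranking
(`composite ROC-AUC 0.740` on the planted cohort), and RDW/HGB risk
stratification.

The same analysis runs end-to-end from a config file:

```bash
hupred all --config examples/pipeline.yaml   # or any YAML/JSON config
```

writing `funnel.tsv`, `features.csv`, `ranking.tsv`, `eval.json`,
`pairs.tsv`, `associations.tsv`, `summary.json`, and SVG figures.

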