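# Methods

## The screening problem

High-alert drugs (HADs) are medications with a narrow therapeutic window or
severe failure modes — anticoagulants, opioids and sedatives, cytotoxic
chemotherapy, insulin, vasoactive agents. A HAD prescribed to a visit whose
diagnoses do not support it is a probable prescription error, but manual
review of every order does not scale. `hadscreen` treats error detection as
a *screening* problem: high recall is non-negotiable (a missed error can be
fatal), low precision is acceptable (a human adjudicates the short list).
The unit of analysis is the hospital visit (one TXN), never the patient, and
outpatient (OPD) and inpatient (IPD) data are modelled separately — their
prescribing patterns, class balance and thresholds differ too much to share.

## Cycle 1: binary HAD screen

Features per visit: a male indicator, integer age, one binary indicator per
ICD10 code in the training vocabulary, and the total number of drugs
prescribed. Drug identities are deliberately excluded — they define the
label (a visit is HAD iff it received at least one registry HAD). Codes
unseen at training time map to all-zero indicators.

The learner is a scikit-learn `GradientBoostingClassifier`; `max_depth` is
chosen by stratified 3-fold cross-validated accuracy over a small grid, ties
toward the shallowest tree (depth-1 stumps suffice when the signal is
additive per-diagnosis, and they keep the model auditable). The data are
shuffled with a fixed seed and split 75:25, the test quarter sized by
round-half-up. All stochastic steps take explicit seeds and are bit-
reproducible.

The decision threshold is selected by scanning cut points 0 … 1 (default
step 0.01, matching the two-decimal floor rounding of the winner) and
maximising S-index = F1 × recall on the HAD class. A visit is predicted HAD
strictly above the cut; at the boundary it is non-HAD. Degenerate grid
points are made total by defining precision = 0 with no positive predictions
and recall = 0 with no actual positives; ties in the scan break toward the
smaller cut point, again favouring recall.

## Prevalence readjustment

HAD percent for ICD10 *i* is the raw proportion (×100) of visits carrying
*i* that used any HAD; no smoothing or shrinkage is applied, matching the
protocol's use of plain proportions. A visit is *high likelihood* when any
of its codes reaches the threshold (default 50%). Codes absent from the
table contribute no evidence; a visit with no covered codes defaults to low
and is logged. Denominators below `min_visits` (default 5) are flagged
low-reliability but not excluded unless requested — tiny samples make the
proportion untrustworthy in either direction.

The confusion matrix is readjusted as
aFP = FP − FP_high, aTP = TP + FP_high, aFN = FN − FN_low, aTN = TN + FN_low;
the four adjusted counts always conserve the record total, and raising the
likelihood threshold can only move visits high→low (aFP non-decreasing, aFN
non-increasing). The per-diagnosis specific false-negative ratio
sFNR(i) = FN(i)/visits(i) localises residual misses; a visit contributes to
every code it carries.

When a prescription-level sample is requested, prescriptions are drawn
without replacement and aggregated back to the visits they touch; full-data
mode is the default for synthetic runs.

## Cycle 2: HAD types

Visits strictly above the cycle-1 cut point are expanded into one instance
per distinct HAD type prescribed (one non-HAD instance when none), sharing
the visit's feature row plus the cycle-1 probability as an extra feature. A
single multiclass gradient-boosted model produces a normalised probability
vector over the seven labels. Per type, P25 and P75 of the test-set
prediction distribution (linear interpolation between closest ranks; a
pooled option exists but per-type is the default) bound the uncertainty
zone: ≤ P25 → no use, > P75 → use, otherwise excluded from interpretation.
The non-HAD column is never interpreted. Per-type confusion counts are
readjusted with type-restricted HAD-percent tables by the same four
equations, independently within each type.

## Mismatch report

Every actual-HAD, predicted-non-HAD visit is categorised exactly once: low
likelihood → *mismatch candidate* (unsupported by both the model and the
prevalence evidence — the output of interest), high likelihood → *model
misclassification*. Candidates are tallied one row per distinct HAD drug
(a multi-HAD visit contributes several rows), summarised per drug with
OPD/IPD counts and a one-decimal proportion of all candidates. The pipeline
screens the test-set false negatives *and* the excluded (below-cut)
evaluation set, so every visit is covered. Deciding among the three causes —
incomplete ICD10 coding, incorrect ICD10 coding, genuinely wrong
prescription — requires clinical context absent from the data model and is
left to the reviewer; the report carries the evidence only.

## Synthetic data

The generator emulates the statistical structure the screen exploits, not
disease epidemiology. Per visit: gender Bernoulli(0.45 male), age
normal(50, 16) clipped to [0, 100] (only their presence as features
matters); a principal ICD10 from a power-law frequency distribution
(exponent 1.2 over 60 codes by default); Poisson comorbidities (mean 0.8);
Poisson ordinary-drug count (mean 2.5, minimum 1). Each code *c* carries an
association strength π(c) = P(HAD | c principal); by default 15% of codes
draw π uniformly from [0.8, 0.98] and the rest from [0, 0.1], spanning the
near-0 to ~0.98 spectrum seen in per-diagnosis prevalence tables. A HAD
visit receives one drug of the principal code's characteristic type (weight
0.7, remainder spread over the other five types).

Planted errors: with probability ε a visit receives a random HAD *only if
every one of its codes* has π at or below the unrelated bound (0.1). The
all-codes condition is deliberate — a high-π comorbidity would make the
prescription clinically supported, so labelling it an error would corrupt
the ground truth (and such visits are exactly the ones whose model
probability and likelihood are legitimately elevated).

Presets fix the study conditions: `clean` (ε = 0, no stage mixing, and
comorbidity mean 0 so that per-code prevalence estimates π exactly —
the preset isolates the association structure), `mismatch_rich` (ε = 0.01),
`eacip` (30% of HAD-indicated visits become follow-ups issued without the
drug, the complex-diagnosis-stage confound), `eamu` (ordinary-drug mean 5,
making 4+-drug visits common — the multi-drug accumulation confound). All
presets use 20,000 visits, a size at which frequent codes have hundreds of
visits while tail codes stay sparse.

What passing tests on this generator do **not** show about real data: real
ICD10 vocabularies are 50× larger and long-tailed beyond learnability; real
comorbidity is correlated with the principal diagnosis; prescriptions per
visit are not Poisson; and real mismatches are not uniformly random HADs.
The generator demonstrates that the protocol's machinery is correct and that
it recovers planted errors under its own assumptions — not a clinical
performance claim.

## Numerical choices

- Cut-point grid step 0.01; the selected cut is floored to two decimals and
  capped at 0.99 so the selected value stays in [0, 1).
- Percentiles: NumPy linear interpolation (`method="linear"`); with
  P25 = P75 the no-use rule applies first, removing the uncertainty zone.
- Round-half-up test-set sizing (`floor(n·(1−ratio)+0.5)`), clamped so both
  partitions are non-empty.
- Grid-search ties on `max_depth` resolve to the smallest depth (ascending
  grid order).
- Empty inputs are fatal wherever a statistic would be undefined; malformed
  prescription rows are rejected and counted, never silently dropped.

## Known limitations

- HAD percent is a marginal statistic; with multiple diagnoses per visit it
  cannot attribute a drug to a code, so stage-of-treatment confounds (the
  `eacip` preset) inflate false positives by construction.
- The P25/P75 rule is a fixed heuristic, not a learned threshold; the
  uncertainty zone is simply excluded rather than modelled.
- The mismatch report flags candidates; it cannot distinguish coding errors
  from prescription errors.
- Registry lookups are exact string matches on drug codes; mapping local
  formulary codes onto the registry is the caller's responsibility.
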