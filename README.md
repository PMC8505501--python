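# hadscreen

Screening visit-level prescription records for probable **high-alert-drug
(HAD) prescription errors** — drugs (anticoagulants, opioids, cytotoxic
agents, insulin, …) whose misuse carries a high risk of severe adverse drug
events.

Hospital pharmacists reviewing every HAD order is a bottleneck; `hadscreen`
implements a two-cycle machine-learning screening protocol that reduces the
manual workload to a short list of flagged visits:

1. **Binary HAD screen (cycle 1).** A gradient-boosted tree ensemble predicts,
   from a visit's demographics, one-hot ICD10 diagnosis codes and total drug
   count, the probability that the visit warrants any HAD. The decision
   threshold is chosen by maximising the **screening index**

   *S-index = F1-score × Recall*

   over a cut-point grid (the extra recall factor deliberately favours
   catching every true HAD use), and the winning cut point is floored to two
   decimals.

2. **Prevalence readjustment.** For each ICD10 code *i*, the **HAD percent**

   *HAD percent(i) = 100 × (HAD visits with code i) / (all visits with code i)*

   measures how often that diagnosis co-occurs with HAD use. A visit is
   high-likelihood when any of its codes reaches 50%. The confusion matrix
   is then readjusted:

   *aFP = FP − FP(high)*, *aTP = TP + FP(high)*,
   *aFN = FN − FN(low)*, *aTN = TN + FN(low)*,

   and a per-diagnosis specific false-negative ratio
   *sFNR(i) = FN(i) / visits(i)* localises residual misses.

3. **HAD-type screen (cycle 2).** Visits above the cycle-1 cut point are
   re-screened with a seven-class model over six pharmacological HAD types
   (ANS, BIG, CVS, CNS, END, Tumor) plus non-HAD. Per type, the 25th/75th
   percentiles of the test-set prediction distribution bound an *uncertainty
   zone*: ≤ P25 is read as no use, > P75 as use, in between is excluded from
   interpretation.

4. **HAD–ICD10 mismatch report.** A visit with an actual HAD prescription,
   a non-HAD prediction *and* low HAD-use likelihood is a **mismatch
   candidate** — a probable prescription error handed to a human reviewer,
   tallied per drug with outpatient/inpatient counts and proportions.

Because real hospital data of this kind cannot be redistributed, the package
ships a seeded synthetic EHR generator (`hadscreen.simulate`) with
configurable ICD10→HAD association strengths, comorbidity mixing, multi-drug
accumulation and *planted* prescription errors with ground truth, so the full
protocol is testable end to end.

## Worked example

```python
import dataclasses
import hadscreen as h
from hadscreen.simulate import preset, make_registry

cfg = preset("mismatch_rich")            # 20,000 visits, 1% planted errors
rows, truth = h.generate(cfg)
visits = h.aggregate_visits(rows)
registry = make_registry(cfg)

art = h.run_cycle1(h.RunConfig(max_depth_grid=(1,), seed=0),
                   visits=visits, registry=registry)
print("cut point:", art.cutpoint.value)
print("confusion:", art.adjustment.to_dict())

planted = set(truth.planted_txns)
flagged = {c.txn for c in art.candidates if c.category == "mismatch_candidate"}
print("planted errors:", len(planted),
      "recall:", len(planted & flagged) / len(planted))
```

prints

```
cut point: 0.3
confusion: {'TP': 2183, 'FP': 665, 'FN': 146, 'TN': 2006, 'FP_high': 665,
 'FN_low': 123, 'aTP': 2848, 'aFP': 0, 'aFN': 23, 'aTN': 2129}
planted errors: 70 recall: 1.0
```

The screen selects cut point 0.30 on the held-out quarter of the data; the
readjustment moves all 665 false positives (every one backed by a
high-HAD-percent diagnosis) to adjusted true positives and 123 of 146 false
negatives to adjusted true negatives; all 70 planted prescription errors are
recovered among the mismatch candidates.

The same pipeline runs from the shell:

```bash
hadscreen simulate --preset mismatch_rich --out sim/
hadscreen all --prescriptions sim/prescriptions.csv --registry sim/registry.csv --out run/
```

## Layout

| module | contents |
|---|---|
| `hadscreen.registry` | prescription/registry I/O, visit aggregation, default HAD registry |
| `hadscreen.preprocess` | labels, one-hot feature matrices, type-instance expansion, fixed split |
| `hadscreen.classifier` | family benchmark, gradient-boosted fits, Lasso feature relevance |
| `hadscreen.cycle1` | S-index scan, cut-point selection, binary metrics |
| `hadscreen.readjust` | HAD percent, likelihood classing, confusion readjustment, sFNR |
| `hadscreen.cycle2` | HAD filter, P25/P75 tri-state interpretation, ICD10 percent |
| `hadscreen.mismatch` | mismatch candidates and drug-level summaries |
| `hadscreen.simulate` | seeded synthetic EHR generator with ground truth |
| `hadscreen.pipeline` / `hadscreen.cli` | orchestration, artifacts, manifests, CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
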