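# kneestudy

How well do knee-radiograph features — the ordinal grades clinicians
assign, and features a computer extracts from the image itself — identify
people with frequent knee pain?  `kneestudy` implements that comparison
end to end as a tested, reusable pipeline, exercised on a fully synthetic
radiograph cohort with known ground truth, so every stage (landmark
localisation, appearance modelling, classification, inference) can be
validated without access to any restricted imaging cohort.

The package is aimed at researchers in musculoskeletal image analysis and
radiographic epidemiology who want a working reference implementation of:

* **synthetic cohort generation** — a latent osteoarthritis severity
  *z* ~ N(0,1) per knee drives (i) schematic radiograph geometry
  (joint-space narrowing, marginal osteophytes, subchondral sclerosis),
  (ii) 36 ordinal reader grades with per-feature signal strength (some at
  chance by design), (iii) three repeated binary pain reports with
  transient flip noise, (iv) a widespread-pain subgroup whose pain is
  independent of severity, and (v) age/BMI/sex covariates;
* **statistical shape models** — generalized Procrustes alignment and a
  PCA point-distribution model, s = T(x̄ + Pb), with the plausibility
  constraint |bⱼ| ≤ 3√λⱼ.  Two view topologies: posteroanterior
  (femur 37 + tibia 37 = 74 points) and lateral (patella 21, femoral
  condyles 24 + 25, tibia 32 = 102 points; femur = 49);
* **combined appearance models** — texture sampled by piecewise-affine
  warp into a shape-normalised frame, then a joint PCA of
  [W_s·b_s ; b_g] with W_s = √(Σλ_tex / Σλ_shape); the combined
  parameter vector c is the "automated" feature set;
* **constrained local models (CLM)** — a random-forest bounding-box
  detector followed by regression-voting landmark search under the shape
  constraint;
* **evaluation** — random forests (40 trees), stratified 5-fold
  cross-validation with 5 repeats, Mann–Whitney AUC on pooled
  out-of-fold scores, and a DeLong-based test for AUC differences with a
  between-repeat variance correction.

## Worked example

```python
import numpy as np
from kneestudy import (
    CohortConfig, CVConfig, generate_cohort_table, run_repeated_cv,
    derive_outcome, PainRecord, GRADE_COLUMNS,
)
from kneestudy.outcomes import derive_labels

tab = generate_cohort_table(CohortConfig(n_subjects=2756, seed=1))

# consistent pain: unanimous yes vs unanimous no, disagreements excluded
labels = derive_labels(tab, "CONSISTENT")
keep = labels.notna()
res = run_repeated_cv(
    tab.loc[keep, GRADE_COLUMNS].to_numpy(float),
    labels[keep].astype(int).to_numpy(),
    CVConfig(seed=0),
)
print(f"manual grades, consistent pain: "
      f"{100*res.auc_mean:.1f} +- {100*res.auc_sd:.1f} % AUC (n={keep.sum()})")
```

which prints:

```
manual grades, consistent pain: 66.4 +- 0.3 % AUC (n=1689)
```

Of 2756 knees, 1689 answered all three pain questions the same way; on
those, the 36 reader grades separate consistent pain from consistent
no-pain at 66% AUC — several points above what the same grades achieve
against any single pain question (~61–62%), because the repeated-report
outcome filters transient pain noise.

Representative output from the analysis drivers (`analysis/01_…` through
`06_…`, which write their tables under `results/`), on the default
synthetic cohort of 2756 knees:

```
kl_grade_pa                          58.3 +- 0.3   (strongest single grade)
osteophytes_patella_superior_pf_la   56.7 +- 0.3
...
zero-loading features: mean AUC 49.8 %            (chance, as constructed)

manual grades,  clinic pain (one question):  61.6 +- 0.1 % AUC  (n=2756)
manual grades,  consistent pain (3x yes/no): 66.6 +- 0.3 % AUC  (n=1670)
```

The ordering mirrors the study design the generator emulates: repeated
pain reports give a cleaner outcome and a higher AUC than a single
question; grades generated without severity signal stay at chance; and on
the rendered cohort the automated appearance features perform no better
than the manual grades.  The fully automatic landmark search localises
the 74 PA points with ~0.5 px median error on held-out synthetic images.

A CLI mirrors the pipeline stages
(`kneestudy simulate | train-shape | train-appearance | extract-features |
fit-landmarks | classify | compare | run-table`); see
`configs/cohort_example.yaml` for a simulation config.

## Layout

```
src/kneestudy/     library: cohort, render, landmarks, grading, shape,
                   appearance, search, outcomes, evaluate, cli
analysis/          numbered narrative drivers writing results/ tables
tests/             pytest suite (unit, property and end-to-end checks)
docs/methods.md    modelling assumptions, parameter choices, limitations
```
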