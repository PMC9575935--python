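# kdtriage

Kawasaki disease (KD) is an acute pediatric vasculitis and the leading cause
of acquired heart disease in children. Its five principal clinical signs —
rash, conjunctival injection, extremity changes, oropharyngeal changes and
cervical lymphadenopathy (>1.5 cm) — overlap heavily with common febrile
illnesses, so children with KD are routinely missed at first presentation,
delaying the immunoglobulin treatment that prevents coronary-artery
aneurysms. `kdtriage` implements, for biostatisticians and clinical-ML
researchers, the two-step triage classifier that separates suspected KD
patients from febrile controls (FC) while *abstaining* when the evidence is
ambiguous, together with the full evaluation protocol used to validate it
and a synthetic cohort generator so every stage is testable without patient
data.

## The algorithm

Inputs per child: illness days (days of fever), the five principal criteria
as 0/1, and a laboratory panel (WBC, %eosinophils, hemoglobin, %monocytes,
%lymphocytes, %neutrophils, platelets, CRP, ALT by default; %bands, ESR and
GGT selectable where collected).

1. **Imputation.** Missing labs are filled by k-nearest-neighbor imputation
   (k = 5): features are standardized by median/IQR, distance is the RMS
   difference over features observed in both rows, and each missing analyte
   takes the mean over the k nearest reference rows that observe it.
2. **Step 1 — linear discriminant with dual thresholds.** A Fisher
   discriminant `s = w·x + b`, with `w = S_pooled⁻¹(μ_KD − μ_FC)` (ridge
   1e-6·tr(S)/p), scores each child. Two thresholds, calibrated so that
   calls `s ≥ τ_KD` attain PPV ≥ 95% and calls `s ≤ τ_FC` attain NPV ≥ 95%
   on the training cohort, split the score line into KD / indeterminate /
   FC.
3. **Step 2 — stratified random-forest rescue.** Indeterminate children are
   routed by criteria count (≤2, 3, 4, 5) to per-stratum random forests
   (500 trees); the KD vote fraction is thresholded by the same PPV/NPV
   procedure, so the final call may still abstain.

Evaluation uses the 2×3 confusion table (true class × call) with
sensitivity = KD calls among all KD (abstentions count against it),
specificity likewise for FC, and PPV/NPV computed over non-abstained calls
only; plus stratified reports (age, illness-day bin, criteria count,
coronary outcome), two-sided Fisher exact tests and Mann-Whitney U tests
for univariable group comparisons, and KD/FC lab median ratios by
illness-day bin.

## Worked example

```python
from kdtriage import TwoStepKD, generate, default_spec

train = generate(default_spec(n_kd=418, n_fc=259, seed=7))
results = TwoStepKD(train).fit(seed=7)
print(results.summary())

test = generate(default_spec(n_kd=418, n_fc=259, seed=8))
print(results.evaluate(test).render())
```

```
Two-step KD triage model
================================================================
training cohort         KD=418  FC=259
features (15)           illness_days, rash, conjunctival_injection, extremity_changes, ...
imputer                 kNN, k=5, median/IQR standardized
seed / fingerprint      7 / dbb2ddbb8143cf18

step 1: linear discriminant with dual thresholds
  tau_kd (call KD if score >= ) -0.0738
  tau_fc (call FC if score <= ) -0.0738
  target PPV/NPV                0.95 / 0.95
  achieved PPV/NPV (training)   0.960 / 0.957
...
            call KD   call FC   indeterminate
true KD        405        13             0
true FC         15       244             0

             sensitivity: 96.9%
             specificity: 94.2%
                     ppv: 96.4%
                     npv: 94.9%
```

Both calibrated thresholds collapsed to the same cut (−0.074): on this
synthetic cohort the PPV- and NPV-feasible zones overlap, so the
indeterminate zone is empty and every child gets a definite call; training
PPV/NPV (96.0% / 95.7%) clear their 95% targets, and on a freshly seeded
test cohort sensitivity and specificity are 96.9% and 94.2%. The stratum-5
forest fell back to a prior stub because that stratum held only 6 febrile
controls. On real cohorts, which separate less cleanly than the generator's
defaults, the indeterminate zone is typically non-empty.

The same pipeline is scriptable from a shell:

```sh
kdtriage simulate --n-kd 418 --n-fc 259 --seed 7 --out cohort.csv
kdtriage train --cohort cohort.csv --out bundle --seed 7
kdtriage classify --bundle bundle --cohort cohort.csv --out calls.csv
kdtriage evaluate --results calls.csv --cohort cohort.csv --stratify age --out report.json
```

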