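# Methods

## Problem and model

The package classifies children evaluated for suspected Kawasaki disease
(KD) against febrile controls (FC) — children with unexplained fever and at
least one KD principal sign but another final diagnosis. The classifier is
a cascade with a reject option: a linear discriminant produces a score with
two calibrated thresholds (call KD above the upper, FC below the lower,
abstain between), and abstentions are rescued by random forests trained per
criteria-count stratum. Abstention is a first-class outcome: a clinical
triage tool that admits uncertainty on ambiguous children is safer than one
forced to guess, and the thresholds are calibrated directly to the
predictive values a clinician needs (PPV and NPV of 95%).

Inclusion rules mirror the validated protocol: fever (≥38.0 °C, treated as
an enrollment precondition rather than a stored field) for at most 10 days,
and FCs must present ≥1 principal sign. Coronary-artery outcomes are
labelled from RCA/LAD Z-score trajectories: normal (< 2.5 throughout),
aneurysm (≥ 5 at any time), and for peak Z in [2.5, 5): dilated if resolved
by 8 weeks, unresolved if still ≥ 2.5 at ≥ 8 weeks, no-follow-up if never
re-measured. "8 weeks" is implemented as day ≥ 56 (closed boundary), since
the source protocol states weeks only.

## Step 1: discriminant and threshold calibration

- Features: illness days (integer, untransformed), the five criteria as
  0/1, and the configured lab profile. The default "taiwan" profile holds
  nine analytes — WBC, %eosinophils, hemoglobin, %monocytes, %lymphocytes,
  %neutrophils, platelets, CRP, ALT — because %bands, ESR and GGT were not
  routinely collected at the Taiwan site; the "full" profile adds them
  back. The source descriptions of the variable count are internally
  inconsistent ("nine clinical or laboratory data points", "15 variables",
  "10 laboratory test variables"), so the schema stores all twelve analytes
  and the modeling subset is configuration.
- Fisher discriminant with pooled within-class covariance; a ridge of
  1e-6 × trace(S)/p is added because the 0/1 criteria columns can make S
  near-singular. Orientation is normalized so the mean KD score exceeds the
  mean FC score; the intercept centers the midpoint of the class means at
  zero.
- Threshold calibration scans a finite, exhaustive candidate set: midpoints
  between adjacent sorted unique scores plus ±∞. τ_KD is the smallest cut
  whose PPV on the calibration data reaches the target — the feasible cut
  that maximizes the number of KD calls; τ_FC symmetrically for NPV. The
  original protocol's wording ("PPV **or** NPV of 95%") is ambiguous; this
  implementation targets both, each on its own threshold. If the feasible
  zones overlap (τ_KD < τ_FC), both collapse to the midpoint of the
  overlap (clipped to just beyond the observed score range when a zone is
  unbounded), giving an empty indeterminate zone. Boundary scores are
  closed at both thresholds with KD checked first, so ties are
  deterministic. If a target is unattainable at every cut, calibration
  fails loudly and reports the best achievable value.

## Step 2: stratified forests

- Strata: criteria counts ≤2 / 3 / 4 / 5. The protocol states "four
  sub-cohorts" without listing the bins; published results repeatedly cut
  at ≤2 / 3 / ≥4, and splitting ≥4 into 4 and 5 yields four bins. The bins
  are configurable.
- Each forest trains on its **full stratum** of the training cohort, not
  only on step-1 indeterminates — whether the original did so is unstated,
  but stratum indeterminates alone are far too few to train on. Forests are
  sklearn RandomForestClassifier, 500 trees, unlimited depth, √p feature
  subsampling, seeded per stratum (hyperparameters unstated in the
  protocol; these are common defaults, all exposed in `ForestConfig`).
- The step-2 score is the KD vote fraction over trees. Vote thresholds are
  calibrated per stratum by the same PPV/NPV scan on the training stratum
  when both classes reach the minimum size (default 10 per class);
  otherwise a single 0.5 cut applies and the stratum never abstains. A
  stratum below the minimum size altogether gets a prior stub that votes
  the stratum's KD prevalence, flagged in the model manifest. Calibrating
  on training-set votes is optimistic (forests separate their own training
  data almost perfectly), which drives the calibrated vote thresholds
  toward a near-empty stratum indeterminate zone; out-of-bag votes would
  be a less optimistic alternative and are a known limitation.

## Imputation

k-nearest-neighbor (k = 5 by default; the original k is unpublished).
Standardization is median-centered and IQR-scaled (IQR/1.349) because labs
are right-skewed; constant features get unit scale. Distance between rows
is the root-mean-square difference over standardized features observed in
both rows, so heavy and heterogeneous missingness does not bias distances
toward rows with more shared features. Each missing analyte is imputed as
the mean of the k nearest reference rows observing that analyte; distance
ties break by ascending reference index for reproducibility. Queries are
imputed strictly from the fitted (training) reference set; whether the
original pooled train and test for imputation is unstated. A query sharing
no observed feature with the reference falls back to reference medians
with a warning. Binary criteria and illness days are required fields and
never imputed.

## Evaluation protocol

The 2×3 confusion table keeps abstentions explicit. Sensitivity and
specificity count abstentions in their denominators (an abstained KD is
still an undiagnosed KD); PPV and NPV exclude them (they condition on a
definite call). All metrics are exact `Fraction`s internally; rendering
rounds half-even to one decimal; zero-denominator metrics serialize as
null, never 0. By construction sensitivity + KD-indeterminate rate +
KD-misclassification rate = 1 exactly, and likewise for FC.

Fisher's exact test is two-sided by the minimum-likelihood convention
(summing hypergeometric probabilities of all tables, margins fixed, no
more probable than the observed one) — the scipy/R convention, stated in
the output because other two-sided conventions exist. Three of the
published sign-table p-values do not reproduce under this convention
(printed 0.158 / 0.1 / 0.341 vs computed 0.177 / 0.134 / 0.429); the tests
report these as convention-dependent deviations rather than resolving
them. Mann-Whitney U uses midranks; p is exact by enumeration when
n₁ + n₂ ≤ 20 without ties, otherwise a tie-corrected normal approximation
with continuity correction, with the method recorded in the result.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes, at
the published study conditions:

- **Criteria.** A count stratum (≤2 / 3 / ≥4) is drawn from the published
  per-group occupancy (14/36/368 of 418 KD; 158/59/42 of 259 FC), the
  exact count within the ≤2 and ≥4 bins from the distribution implied by
  the within-stratum sign-frequency sums, and then a sign subset of that
  size from a conditional-Bernoulli distribution whose inclusion
  probabilities are calibrated (fixed point on the Chen–Dempster–Liu
  identities) to the published within-stratum frequencies. Independent
  Bernoulli draws cannot match stratum occupancy and within-stratum
  frequencies simultaneously; conditioning on the count can, and the
  calibration is exact because the published tables are self-consistent
  (each stratum's frequency sum equals its mean count).
- **Labs.** Log-normal per analyte and group (hemoglobin: truncated
  normal), percentages clipped at 100. No group-wise lab summaries are
  published, so locations and scales are package-chosen stand-ins
  (e.g. CRP median 80 vs 25 mg/L, ALT 60 vs 20 U/L, WBC 13 vs 10 ×10³/µL
  for KD vs FC) — labelled as such, not published values.
- **Missingness.** MCAR per analyte (the source states rates, not a
  mechanism), with relative per-analyte rates dominated by bands/GGT/ESR
  (not routinely collected at the study site) and a per-group scale
  calibrated by bisection so the any-missing fraction hits the published
  54.3% (KD) and 98.8% (FC).
- **Demographics.** Illness-day categoricals matching the published bin
  occupancies (KD: 91/418 at days 8–10; FC: 7/259, median 2); age
  log-normal with published medians (1.3 vs 1.0 years); sex Bernoulli
  (60.5% vs 53.3% male). KD records get a coronary Z-trajectory drawn from
  the approximate published outcome mix; FCs were not imaged and get none.
  Criteria-count/lab coupling is available but defaults to zero.

What passing tests on this generator do **not** show: the synthetic
classes separate more cleanly than real KD/FC cohorts (real labs are not
log-normal, criteria and labs co-vary, missingness is informative), so the
near-empty indeterminate zones and ~97% test metrics seen on synthetic
data overstate real-world performance; the published evaluation itself
reports 90.7% sensitivity and 86.1% specificity. The synthetic experiments
validate the machinery (calibration meets its targets within sampling
error, recovery is far above chance), not the clinical performance level.

## Problem sizes and numerical choices

Distribution-level generator checks run at 10,000 records per group
(binomial 3-SE and DKW bounds); end-to-end recovery experiments at 1,000
per group over five seeds, chosen as the smallest sizes at which the
95%-target calibration has stable sampling error. All randomness flows
from explicit integer seeds; generation, fitting and classification are
bit-reproducible given seed and inputs. Degenerate inputs fail loudly
(empty cohorts, single-class calibration, k exceeding the reference size)
or fall back with a logged warning where the protocol demands an answer
(median fallback in imputation, prior stubs for unpopulated strata,
undefined metrics as null).

## Known limitations

- The original US-trained coefficients were never published; this package
  retrains the architecture on user or synthetic data, so numeric weights
  are not comparable to the original deployment.
- Step-2 vote thresholds calibrated on training votes are optimistic (see
  above).
- Single imputation only; imputation uncertainty is not propagated.
- Z-scores are consumed, not computed from echocardiographic measurements;
  longitudinal data beyond the coronary trajectory are out of scope.
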