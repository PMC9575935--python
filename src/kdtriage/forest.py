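"""Step 2: criteria-count-stratified random-forest rescue of indeterminates.

Patients abstained on by the LDA step are routed, by how many principal
criteria they present, to one of four sub-cohort forests (criteria count
<=2, 3, 4 or 5). Each forest is trained on its full stratum of the training
cohort — training only on the handful of step-1 indeterminates would leave
unusably small samples — and emits a KD vote fraction (the proportion of
trees voting KD). Vote thresholds per stratum are calibrated with the same
PPV/NPV procedure as step 1 when the stratum has enough of both classes;
otherwise a single 0.5 cut is used and the stratum never abstains. Strata
too small to train on at all fall back to a prior stub that votes the
stratum's (or cohort's) KD prevalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .lda import (
    FC,
    INDETERMINATE,
    KD,
    CalibrationError,
    LdaModel,
    ThresholdPair,
    calibrate_thresholds,
    design_matrix,
    score as lda_score,
)
from .impute import ImputerModel, impute
from .records import CohortTable, Diagnosis, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "StratumKey",
    "ForestConfig",
    "StratumForest",
    "TwoStepModel",
    "ClassificationResult",
    "fit_stratum_forests",
    "classify_two_step",
]


class StratumKey(str, Enum):
    """Criteria-count bins; the four bins partition counts 0-5."""

    LE2 = "le2"     # 0-2 criteria
    THREE = "3"
    FOUR = "4"
    FIVE = "5"

    @classmethod
    def for_count(cls, count: int) -> "StratumKey":
        if count <= 2:
            return cls.LE2
        if count == 3:
            return cls.THREE
        if count == 4:
            return cls.FOUR
        return cls.FIVE


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 500
    max_depth: int | None = None
    max_features: str | int = "sqrt"
    bootstrap: bool = True
    min_per_class: int = 10      # below this a stratum gets a prior stub
    seed: int = 0
    target_ppv: float = 0.95
    target_npv: float = 0.95


@dataclass
class StratumForest:
    """Forest (or prior stub) plus vote thresholds for one criteria stratum."""

    stratum: StratumKey
    features: tuple[str, ...]
    forest: RandomForestClassifier | None
    vote_thresholds: ThresholdPair
    prior_vote: float = 0.5       # used when forest is None (stub)
    is_stub: bool = False
    threshold_mode: str = "calibrated"   # or "fixed_0.5"

    def vote_fractions(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting KD for each row."""
        if self.forest is None:
            return np.full(len(X), self.prior_vote)
        votes = np.stack([
            tree.predict(X) for tree in self.forest.estimators_
        ])  # trees predict 0/1 with 1 = KD
        return votes.mean(axis=0)


@dataclass(frozen=True)
class ClassificationResult:
    id: str
    call: str                  # KD / FC / INDETERMINATE
    stage: str                 # STEP1 / STEP2
    score: float               # LDA score (STEP1) or vote fraction (STEP2)
    stratum: str | None = None


@dataclass
class TwoStepModel:
    """Fully fitted two-step classifier: imputer + LDA + stratum forests."""

    imputer: ImputerModel
    lda: LdaModel
    lda_thresholds: ThresholdPair
    forests: dict[StratumKey, StratumForest]


def _counts(cohort: CohortTable) -> np.ndarray:
    return np.array([r.criteria.count for r in cohort])


def fit_stratum_forests(
    cohort: CohortTable,
    features: Sequence[str],
    config: ForestConfig = ForestConfig(),
) -> dict[StratumKey, StratumForest]:
    """Fit one forest per criteria-count stratum on the (imputed) cohort."""
    if len(cohort) == 0:
        raise ValidationError("cannot fit stratum forests on an empty cohort")
    features = tuple(features)
    X = design_matrix(cohort, features)
    y = np.array([r.diagnosis is Diagnosis.KD for r in cohort])
    counts = _counts(cohort)
    global_prior = float(y.mean()) if len(y) else 0.5
    forests: dict[StratumKey, StratumForest] = {}
    for idx, key in enumerate(StratumKey):
        mask = np.array([StratumKey.for_count(c) is key for c in counts])
        n_kd, n_fc = int(y[mask].sum()), int((~y[mask]).sum())
        if min(n_kd, n_fc) < config.min_per_class:
            prior = float(y[mask].mean()) if mask.any() else global_prior
            logger.warning(
                "stratum %s has KD=%d FC=%d; using prior stub (vote %.2f)",
                key.value, n_kd, n_fc, prior,
            )
            forests[key] = StratumForest(
                stratum=key, features=features, forest=None,
                vote_thresholds=ThresholdPair(0.5, 0.5, config.target_ppv,
                                              config.target_npv),
                prior_vote=prior, is_stub=True, threshold_mode="fixed_0.5",
            )
            continue
        rf = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_depth=config.max_depth,
            max_features=config.max_features,
            bootstrap=config.bootstrap,
            random_state=config.seed + idx,
        )
        rf.fit(X[mask], y[mask].astype(int))
        sf = StratumForest(
            stratum=key, features=features, forest=rf,
            vote_thresholds=ThresholdPair(0.5, 0.5, config.target_ppv,
                                          config.target_npv),
            threshold_mode="fixed_0.5",
        )
        votes = sf.vote_fractions(X[mask])
        try:
            sf.vote_thresholds = calibrate_thresholds(
                votes, y[mask], config.target_ppv, config.target_npv
            )
            sf.threshold_mode = "calibrated"
        except CalibrationError as exc:
            logger.warning(
                "stratum %s vote calibration failed (%s); using 0.5 cut",
                key.value, exc,
            )
        forests[key] = sf
    return forests


def classify_two_step(
    model: TwoStepModel, cohort: CohortTable
) -> list[ClassificationResult]:
    """Run the full pipeline: impute, LDA call, forest rescue of abstentions.

    Every record receives exactly one result; KD/FC step-1 calls are final
    and the forests are consulted only for step-1 indeterminates.
    """
    imputed = impute(model.imputer, cohort)
    scores = lda_score(model.lda, imputed)
    step1 = [model.lda_thresholds.call(float(s)) for s in scores]
    results: list[ClassificationResult | None] = [None] * len(cohort)
    pending: dict[StratumKey, list[int]] = {}
    for i, (rec, call, s) in enumerate(zip(imputed, step1, scores)):
        if call != INDETERMINATE:
            results[i] = ClassificationResult(rec.id, call, "STEP1", float(s))
        else:
            pending.setdefault(StratumKey.for_count(rec.criteria.count), []).append(i)
    for key, idxs in pending.items():
        sf = model.forests[key]
        sub = CohortTable([imputed[i] for i in idxs], imputed.provenance)
        X = design_matrix(sub, sf.features)
        votes = sf.vote_fractions(X)
        for i, v in zip(idxs, votes):
            results[i] = ClassificationResult(
                imputed[i].id, sf.vote_thresholds.call(float(v)),
                "STEP2", float(v), stratum=key.value,
            )
    return [r for r in results if r is not None]
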