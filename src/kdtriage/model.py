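"""Model / Results facade for the two-step KD triage classifier.

`TwoStepKD` is constructed from a labeled cohort (a :class:`CohortTable` or a
flat DataFrame) and `fit()` returns a :class:`TwoStepKDResults` carrying the
fitted components (imputer, discriminant, thresholds, stratum forests), the
calibration diagnostics, `predict`, `evaluate` and a `summary()` table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd

from . import __version__
from .evaluate import ConfusionSummary, StratifiedReport, stratified_report, summarize
from .forest import (
    ClassificationResult,
    ForestConfig,
    TwoStepModel,
    classify_two_step,
    fit_stratum_forests,
)
from .impute import fit_imputer, impute
from .lda import (
    calibrate_thresholds,
    default_features,
    fit_lda,
    score,
)
from .records import (
    CohortTable,
    Diagnosis,
    TAIWAN_LAB_PROFILE,
    ValidationError,
)

__all__ = ["TwoStepKD", "TwoStepKDResults"]

BUNDLE_SCHEMA_VERSION = 1


class TwoStepKD:
    """Two-step Kawasaki-disease vs febrile-control triage model.

    Parameters
    ----------
    cohort
        Labeled training cohort (every record needs a KD/FC diagnosis).
    lab_profile
        Laboratory analytes entering the model; defaults to the nine analytes
        routinely collected at the Taiwan study site (bands, ESR and GGT
        excluded). The model features are illness days, the five principal
        criteria and this profile.
    target_ppv, target_npv
        Predictive-value targets for the dual score thresholds (default 0.95
        each; the zone between the two thresholds abstains).
    k_neighbors
        Neighborhood size of the kNN lab imputer.
    forest_config
        Hyperparameters of the step-2 stratum forests.
    """

    def __init__(
        self,
        cohort: CohortTable,
        lab_profile: Sequence[str] = TAIWAN_LAB_PROFILE,
        target_ppv: float = 0.95,
        target_npv: float = 0.95,
        k_neighbors: int = 5,
        forest_config: ForestConfig | None = None,
    ):
        for r in cohort:
            if r.diagnosis is None:
                raise ValidationError(
                    f"record {r.id} has no diagnosis label; training needs labels"
                )
        self.cohort = cohort
        self.lab_profile = tuple(lab_profile)
        self.features = default_features(self.lab_profile)
        self.target_ppv = target_ppv
        self.target_npv = target_npv
        self.k_neighbors = k_neighbors
        self.forest_config = forest_config

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "TwoStepKD":
        return cls(CohortTable.from_frame(df), **kwargs)

    def fit(self, seed: int = 0) -> "TwoStepKDResults":
        """Fit imputer, discriminant, thresholds and stratum forests."""
        fc = self.forest_config or ForestConfig(
            seed=seed, target_ppv=self.target_ppv, target_npv=self.target_npv
        )
        imputer = fit_imputer(self.cohort, k=self.k_neighbors,
                              features=self.lab_profile)
        imputed = impute(imputer, self.cohort)
        lda = fit_lda(imputed, self.features)
        scores = score(lda, imputed)
        labels = [r.diagnosis is Diagnosis.KD for r in imputed]
        thresholds = calibrate_thresholds(
            scores, labels, self.target_ppv, self.target_npv
        )
        forests = fit_stratum_forests(imputed, self.features, fc)
        model = TwoStepModel(imputer=imputer, lda=lda,
                             lda_thresholds=thresholds, forests=forests)
        return TwoStepKDResults(model=model, spec=self, seed=seed,
                                n_train_kd=int(sum(labels)),
                                n_train_fc=int(len(labels) - sum(labels)),
                                fingerprint=self._fingerprint(seed))

    def _fingerprint(self, seed: int) -> str:
        h = hashlib.sha256()
        h.update(repr((sorted(self.cohort.ids()), self.features,
                       self.target_ppv, self.target_npv,
                       self.k_neighbors, seed)).encode())
        return h.hexdigest()[:16]


@dataclass
class TwoStepKDResults:
    """Fitted two-step classifier plus training diagnostics."""

    model: TwoStepModel
    spec: TwoStepKD | None
    seed: int
    n_train_kd: int
    n_train_fc: int
    fingerprint: str

    # ------------------------------------------------------------- inference
    def predict(self, cohort: CohortTable) -> list[ClassificationResult]:
        """Per-record call (KD / FC / indeterminate) with stage and score."""
        return classify_two_step(self.model, cohort)

    def predict_frame(self, cohort: CohortTable) -> pd.DataFrame:
        rows = [(r.id, r.call, r.stage, r.score, r.stratum or "")
                for r in self.predict(cohort)]
        return pd.DataFrame(rows, columns=["id", "call", "stage", "score", "stratum"])

    def evaluate(self, cohort: CohortTable,
                 results: Sequence[ClassificationResult] | None = None
                 ) -> ConfusionSummary:
        """Confusion summary against the cohort's diagnosis labels."""
        truth = {}
        for r in cohort:
            if r.diagnosis is None:
                raise ValidationError(f"record {r.id} has no truth label")
            truth[r.id] = r.diagnosis.value
        return summarize(truth, results if results is not None
                         else self.predict(cohort))

    def evaluate_stratified(self, cohort: CohortTable, stratifier: str,
                            results: Sequence[ClassificationResult] | None = None
                            ) -> StratifiedReport:
        truth = {r.id: r.diagnosis.value for r in cohort}
        return stratified_report(cohort, truth,
                                 results if results is not None
                                 else self.predict(cohort), stratifier)

    # --------------------------------------------------------------- summary
    def summary(self) -> str:
        m = self.model
        th = m.lda_thresholds
        lines = [
            "Two-step KD triage model",
            "=" * 64,
            f"training cohort         KD={self.n_train_kd}  FC={self.n_train_fc}",
            f"features ({len(m.lda.features)})           "
            + ", ".join(m.lda.features[:4]) + ", ...",
            f"imputer                 kNN, k={m.imputer.k}, median/IQR standardized",
            f"seed / fingerprint      {self.seed} / {self.fingerprint}",
            "",
            "step 1: linear discriminant with dual thresholds",
            f"  tau_kd (call KD if score >= ) {th.tau_kd: .4f}",
            f"  tau_fc (call FC if score <= ) {th.tau_fc: .4f}",
            f"  target PPV/NPV                {th.target_ppv:.2f} / {th.target_npv:.2f}",
            f"  achieved PPV/NPV (training)   "
            f"{_fmt(th.achieved_ppv)} / {_fmt(th.achieved_npv)}",
            "",
            "step 2: stratum forests on the KD vote fraction",
            "  stratum  kind        thresholds (tau_fc, tau_kd)   mode",
        ]
        for key, sf in m.forests.items():
            kind = "prior stub" if sf.is_stub else f"{sf.forest.n_estimators} trees"
            lines.append(
                f"  {key.value:>7}  {kind:<10}  "
                f"({sf.vote_thresholds.tau_fc:.3f}, {sf.vote_thresholds.tau_kd:.3f})"
                f"{'':15}{sf.threshold_mode}"
            )
        return "\n".join(lines)

    # ------------------------------------------------------------ persistence
    def save(self, path) -> None:
        """Write a model bundle directory: JSON manifest + joblib payload."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "schema_version": BUNDLE_SCHEMA_VERSION,
            "package_version": __version__,
            "seed": self.seed,
            "fingerprint": self.fingerprint,
            "n_train_kd": self.n_train_kd,
            "n_train_fc": self.n_train_fc,
            "features": list(self.model.lda.features),
            "imputer_k": self.model.imputer.k,
            "lda": self.model.lda.to_dict(),
            "lda_thresholds": self.model.lda_thresholds.to_dict(),
            "forests": {
                key.value: {
                    "is_stub": sf.is_stub,
                    "prior_vote": sf.prior_vote,
                    "threshold_mode": sf.threshold_mode,
                    "vote_thresholds": sf.vote_thresholds.to_dict(),
                }
                for key, sf in self.model.forests.items()
            },
        }
        with open(path / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)
        joblib.dump(self.model, path / "model.joblib")

    @classmethod
    def load(cls, path) -> "TwoStepKDResults":
        path = Path(path)
        with open(path / "manifest.json", encoding="utf-8") as fh:
            manifest = json.load(fh)
        if manifest["schema_version"] != BUNDLE_SCHEMA_VERSION:
            raise ValidationError(
                f"unsupported bundle schema {manifest['schema_version']}"
            )
        model = joblib.load(path / "model.joblib")
        return cls(model=model, spec=None, seed=manifest["seed"],
                   n_train_kd=manifest["n_train_kd"],
                   n_train_fc=manifest["n_train_fc"],
                   fingerprint=manifest["fingerprint"])


def _fmt(x: float | None) -> str:
    return "n/a" if x is None else f"{x:.3f}"
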