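"""Step 1: linear-discriminant scoring and PPV/NPV threshold calibration.

The discriminant is the two-class Fisher solution with pooled within-class
covariance: w = S_pooled^{-1} (mu_KD - mu_FC), oriented so higher scores are
more KD-like, with the intercept placed at the midpoint of the class means.
A small ridge (1e-6 x trace/p) stabilizes the pooled covariance, which the
0/1 criteria columns can render near-singular.

Two score thresholds carve the line into three zones: scores >= tau_kd call
KD, scores <= tau_fc call FC, the gap abstains (indeterminate). tau_kd is
the smallest candidate cut whose positive predictive value on the
calibration data reaches the target (default 95%), which maximizes the
number of KD calls subject to the constraint; tau_fc is chosen symmetrically
for the negative predictive value. Candidate cuts are midpoints between
adjacent sorted unique scores plus the two infinities, so the scan is finite
and exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .records import (
    CRITERIA_FIELDS,
    CohortTable,
    Diagnosis,
    TAIWAN_LAB_PROFILE,
    ValidationError,
)

__all__ = [
    "LdaModel",
    "ThresholdPair",
    "CalibrationError",
    "default_features",
    "design_matrix",
    "fit_lda",
    "score",
    "calibrate_thresholds",
    "classify_step1",
]

RIDGE_FACTOR = 1e-6

KD, FC, INDETERMINATE = "KD", "FC", "INDETERMINATE"


class CalibrationError(ValueError):
    """A PPV/NPV target is unattainable on the calibration data."""

    def __init__(self, msg: str, best_achievable: float | None = None):
        super().__init__(msg)
        self.best_achievable = best_achievable


def default_features(lab_profile: Sequence[str] = TAIWAN_LAB_PROFILE) -> tuple[str, ...]:
    """Model features: illness days, the five criteria (0/1), the lab profile."""
    return ("illness_days",) + CRITERIA_FIELDS + tuple(lab_profile)


def design_matrix(cohort: CohortTable, features: Sequence[str]) -> np.ndarray:
    """Numeric (n, p) matrix in feature order; missing labs are an error
    (imputation must precede modeling)."""
    X = np.empty((len(cohort), len(features)))
    for i, r in enumerate(cohort):
        for j, f in enumerate(features):
            if f == "illness_days":
                X[i, j] = r.illness_days
            elif f in CRITERIA_FIELDS:
                X[i, j] = float(getattr(r.criteria, f))
            else:
                v = r.labs.get(f)
                if v is None:
                    raise ValidationError(
                        f"record {r.id}: missing modeled feature {f}; impute first"
                    )
                X[i, j] = v
    return X


def _labels(cohort: CohortTable) -> np.ndarray:
    y = []
    for r in cohort:
        if r.diagnosis is None:
            raise ValidationError(f"record {r.id} has no diagnosis label")
        y.append(r.diagnosis is Diagnosis.KD)
    return np.asarray(y, dtype=bool)


@dataclass(frozen=True)
class LdaModel:
    features: tuple[str, ...]
    weights: np.ndarray
    intercept: float

    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "weights": [float(w) for w in self.weights],
            "intercept": float(self.intercept),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LdaModel":
        return cls(tuple(d["features"]), np.asarray(d["weights"], dtype=float),
                   float(d["intercept"]))


@dataclass(frozen=True)
class ThresholdPair:
    """Dual thresholds on a KD-oriented score: >= tau_kd calls KD, <= tau_fc
    calls FC, between them abstains."""

    tau_kd: float
    tau_fc: float
    target_ppv: float = 0.95
    target_npv: float = 0.95
    achieved_ppv: float | None = None
    achieved_npv: float | None = None

    def __post_init__(self):
        if self.tau_fc > self.tau_kd:
            raise ValidationError(
                f"tau_fc={self.tau_fc} must not exceed tau_kd={self.tau_kd}"
            )

    def call(self, s: float) -> str:
        # closed at both boundaries, KD checked first
        if s >= self.tau_kd:
            return KD
        if s <= self.tau_fc:
            return FC
        return INDETERMINATE

    def to_dict(self) -> dict:
        return {
            "tau_kd": float(self.tau_kd), "tau_fc": float(self.tau_fc),
            "target_ppv": self.target_ppv, "target_npv": self.target_npv,
            "achieved_ppv": self.achieved_ppv, "achieved_npv": self.achieved_npv,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdPair":
        return cls(**d)


def fit_lda(cohort: CohortTable, features: Sequence[str] | None = None) -> LdaModel:
    """Fit the Fisher discriminant with ridge-stabilized pooled covariance."""
    features = tuple(features) if features is not None else default_features()
    X = design_matrix(cohort, features)
    y = _labels(cohort)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 < 2 or n0 < 2:
        raise ValidationError(
            f"need >= 2 records per class, got KD={n1}, FC={n0}"
        )
    mu1 = X[y].mean(axis=0)
    mu0 = X[~y].mean(axis=0)
    S1 = np.cov(X[y], rowvar=False, ddof=1)
    S0 = np.cov(X[~y], rowvar=False, ddof=1)
    pooled = ((n1 - 1) * S1 + (n0 - 1) * S0) / (n1 + n0 - 2)
    p = len(features)
    pooled = pooled + np.eye(p) * RIDGE_FACTOR * np.trace(pooled) / p
    try:
        w = np.linalg.solve(pooled, mu1 - mu0)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("pooled covariance singular after ridge") from exc
    intercept = -float(w @ (mu1 + mu0)) / 2.0
    model = LdaModel(features, w, intercept)
    # orientation: mean KD score must exceed mean FC score
    s = X @ w + intercept
    if s[y].mean() < s[~y].mean():
        model = LdaModel(features, -w, -intercept)
    return model


def score(model: LdaModel, cohort: CohortTable) -> np.ndarray:
    """Per-patient discriminant score w.x + b (higher = more KD-like)."""
    X = design_matrix(cohort, model.features)
    return X @ model.weights + model.intercept


def candidate_cuts(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent sorted unique scores, plus +-inf."""
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def calibrate_thresholds(
    scores: np.ndarray,
    labels: Sequence[bool] | np.ndarray,
    target_ppv: float = 0.95,
    target_npv: float = 0.95,
) -> ThresholdPair:
    """Calibrate (tau_kd, tau_fc) to the PPV / NPV targets.

    ``labels`` is True for KD. If the PPV-feasible and NPV-feasible zones
    overlap (tau_kd < tau_fc) both thresholds collapse to the midpoint of the
    overlap, leaving an empty indeterminate zone. Raises
    :class:`CalibrationError`, reporting the best achievable value, if a
    target cannot be met at any cut.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if len(scores) != len(y):
        raise ValidationError("scores and labels length mismatch")
    if y.all() or (~y).all():
        raise CalibrationError("calibration requires both classes")
    cuts = candidate_cuts(scores)

    tau_kd = None
    best_ppv = 0.0
    for c in cuts:  # ascending: the first feasible cut maximizes KD calls
        called = scores >= c
        n_called = int(called.sum())
        if n_called == 0:
            continue
        ppv = float((called & y).sum() / n_called)
        best_ppv = max(best_ppv, ppv)
        if ppv >= target_ppv:
            tau_kd = float(c)
            break
    if tau_kd is None:
        raise CalibrationError(
            f"PPV target {target_ppv:.3f} unattainable (best {best_ppv:.3f})",
            best_achievable=best_ppv,
        )

    tau_fc = None
    best_npv = 0.0
    for c in cuts[::-1]:  # descending: the first feasible cut maximizes FC calls
        called = scores <= c
        n_called = int(called.sum())
        if n_called == 0:
            continue
        npv = float((called & ~y).sum() / n_called)
        best_npv = max(best_npv, npv)
        if npv >= target_npv:
            tau_fc = float(c)
            break
    if tau_fc is None:
        raise CalibrationError(
            f"NPV target {target_npv:.3f} unattainable (best {best_npv:.3f})",
            best_achievable=best_npv,
        )

    if tau_kd < tau_fc:  # overlapping feasible zones: empty indeterminate zone
        # infinite endpoints (a target met by calling everyone) are clipped to
        # just beyond the observed scores so the midpoint stays finite
        lo = max(tau_kd, float(scores.min()) - 1.0)
        hi = min(tau_fc, float(scores.max()) + 1.0)
        mid = (lo + hi) / 2.0
        tau_kd = tau_fc = mid

    kd_called = scores >= tau_kd
    fc_called = (scores <= tau_fc) & ~kd_called  # KD takes the shared boundary
    achieved_ppv = float((kd_called & y).sum() / kd_called.sum()) if kd_called.any() else None
    achieved_npv = float((fc_called & ~y).sum() / fc_called.sum()) if fc_called.any() else None
    return ThresholdPair(tau_kd=tau_kd, tau_fc=tau_fc,
                         target_ppv=target_ppv, target_npv=target_npv,
                         achieved_ppv=achieved_ppv, achieved_npv=achieved_npv)


def classify_step1(
    model: LdaModel, thresholds: ThresholdPair, cohort: CohortTable
) -> list[str]:
    """Three-way step-1 call per record; the calls partition the cohort."""
    return [thresholds.call(float(s)) for s in score(model, cohort)]
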