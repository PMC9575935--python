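"""k-nearest-neighbor imputation of missing laboratory values.

Reference rows are retained from the fitted (training) cohort and queries are
imputed strictly from that reference set. Features are standardized robustly
(median center, IQR-derived scale) because laboratory values are right-skewed.
Distance between a query and a reference row is the root-mean-square
difference over the standardized features observed in both rows, so rows with
different missingness patterns remain comparable. Each missing analyte is
replaced by the mean of that analyte among the k nearest reference rows that
observe it; distance ties are broken by ascending reference row index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .records import CohortTable, PatientRecord, TAIWAN_LAB_PROFILE

logger = logging.getLogger(__name__)

__all__ = ["ImputerModel", "fit_imputer", "impute", "ImputeError"]

#: Normal-consistency factor: IQR of a Gaussian is 1.349 sigma.
_IQR_TO_SIGMA = 1.349


class ImputeError(ValueError):
    """Raised when the imputer cannot be fitted as requested."""


@dataclass(frozen=True)
class ImputerModel:
    """Fitted kNN imputer: standardization + retained reference matrix."""

    k: int
    features: tuple[str, ...]
    center: np.ndarray          # per-feature median
    scale: np.ndarray           # per-feature IQR/1.349, unit for constants
    reference: np.ndarray       # (n_ref, p) raw values with NaN for missing
    reference_std: np.ndarray   # standardized reference


def _lab_matrix(cohort: CohortTable, features: Sequence[str]) -> np.ndarray:
    X = np.full((len(cohort), len(features)), np.nan)
    for i, r in enumerate(cohort):
        for j, a in enumerate(features):
            v = r.labs.get(a)
            if v is not None:
                X[i, j] = v
    return X


def fit_imputer(
    cohort: CohortTable,
    k: int = 5,
    features: Sequence[str] = TAIWAN_LAB_PROFILE,
) -> ImputerModel:
    """Fit the imputer on a reference cohort.

    Raises :class:`ImputeError` if the cohort is empty, ``k`` exceeds the
    cohort size, or any feature has fewer than ``k`` observed values (each
    missing value needs k donors).
    """
    if len(cohort) == 0:
        raise ImputeError("cannot fit imputer on an empty cohort")
    if k < 1:
        raise ImputeError(f"k must be >= 1, got {k}")
    if k > len(cohort):
        raise ImputeError(f"k={k} exceeds cohort size {len(cohort)}")
    X = _lab_matrix(cohort, features)
    n_obs = (~np.isnan(X)).sum(axis=0)
    short = [f for f, n in zip(features, n_obs) if n < k]
    if short:
        raise ImputeError(
            f"features with fewer than k={k} observed values: {', '.join(short)}"
        )
    center = np.nanmedian(X, axis=0)
    q75 = np.nanpercentile(X, 75, axis=0)
    q25 = np.nanpercentile(X, 25, axis=0)
    scale = (q75 - q25) / _IQR_TO_SIGMA
    scale[scale <= 0] = 1.0  # constant features get unit scale
    return ImputerModel(
        k=k,
        features=tuple(features),
        center=center,
        scale=scale,
        reference=X,
        reference_std=(X - center) / scale,
    )


def _distances(q_std: np.ndarray, ref_std: np.ndarray) -> np.ndarray:
    """RMS distance over shared observed features; inf when nothing is shared."""
    shared = ~np.isnan(q_std) & ~np.isnan(ref_std)
    n_shared = shared.sum(axis=1)
    diff = np.where(shared, ref_std - q_std, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt((diff ** 2).sum(axis=1) / n_shared)
    d[n_shared == 0] = np.inf
    return d


def impute(model: ImputerModel, cohort: CohortTable) -> CohortTable:
    """Impute every modeled analyte in ``cohort`` from the fitted reference.

    Observed values are never altered, so the operation is idempotent. A query
    row that shares no observed feature with any reference row (including a
    row with no observed labs at all) falls back to the reference medians,
    with a warning.
    """
    X = _lab_matrix(cohort, model.features)
    X_std = (X - model.center) / model.scale
    out_records: list[PatientRecord] = []
    for i, record in enumerate(cohort):
        miss = np.isnan(X[i])
        if not miss.any():
            out_records.append(record)
            continue
        d = _distances(X_std[i], model.reference_std)
        if not np.isfinite(d).any():
            logger.warning(
                "record %s shares no observed feature with the reference; "
                "imputing medians", record.id,
            )
            filled = {f: float(c) for f, c, m in
                      zip(model.features, model.center, miss) if m}
        else:
            order = np.lexsort((np.arange(len(d)), d))  # ties -> ascending index
            filled = {}
            for j, f in enumerate(model.features):
                if not miss[j]:
                    continue
                donors = order[~np.isnan(model.reference[order, j])][: model.k]
                if len(donors) == 0:  # unreachable given fit precondition
                    filled[f] = float(model.center[j])
                else:
                    filled[f] = float(model.reference[donors, j].mean())
        out_records.append(replace(record, labs=replace(record.labs, **filled)))
    return CohortTable(out_records, cohort.provenance)
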