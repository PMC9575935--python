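"""Patient-cohort domain types, schema validation, inclusion filtering and delimited I/O.

A cohort is a flat table, one row per child evaluated for suspected Kawasaki
disease (KD) or enrolled as a febrile control (FC). Each record carries the
five principal clinical criteria as booleans, a laboratory panel with explicit
missingness, the number of illness (fever) days at evaluation, demographics,
and an optional coronary-artery Z-score trajectory.

Units are fixed per analyte (see :data:`LAB_UNITS`); no automatic unit
conversion is attempted, because silently rescaling a clinical analyte is a
safety hazard. Header variants commonly seen in exported files are mapped to
canonical names through :data:`COLUMN_ALIASES`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Diagnosis",
    "Sex",
    "Artery",
    "CoronaryLabel",
    "CriteriaSet",
    "LabPanel",
    "CoronaryStatus",
    "PatientRecord",
    "CohortTable",
    "SchemaError",
    "ValidationError",
    "read_cohort",
    "write_cohort",
    "apply_inclusion_filters",
    "label_coronary",
    "CRITERIA_FIELDS",
    "LAB_ANALYTES",
    "TAIWAN_LAB_PROFILE",
    "FULL_LAB_PROFILE",
]


class SchemaError(ValueError):
    """A cohort file is missing mandatory columns or otherwise malformed."""


class ValidationError(ValueError):
    """A record or table violates a domain invariant."""


class Diagnosis(str, Enum):
    KD = "KD"
    FC = "FC"


class Sex(str, Enum):
    M = "M"
    F = "F"
    UNKNOWN = "unknown"


class Artery(str, Enum):
    RCA = "RCA"
    LAD = "LAD"


class CoronaryLabel(str, Enum):
    NORMAL = "NORMAL"
    DILATED = "DILATED"
    ANEURYSM = "ANEURYSM"
    UNRESOLVED = "UNRESOLVED"
    NO_FOLLOWUP = "NO_FOLLOWUP"
    MISSING = "MISSING"


#: The five principal clinical criteria, in canonical order.
CRITERIA_FIELDS = (
    "rash",
    "conjunctival_injection",
    "extremity_changes",
    "oropharyngeal_changes",
    "cervical_lymphadenopathy",
)

#: Laboratory analytes, canonical order. Values are stored in the fixed units below.
LAB_ANALYTES = (
    "wbc",          # total white blood cells, 10^3 cells/uL
    "eos_pct",      # eosinophils, % of WBC
    "hemoglobin",   # g/dL
    "mono_pct",     # monocytes, %
    "lymph_pct",    # lymphocytes, %
    "neut_pct",     # neutrophils, %
    "bands_pct",    # immature neutrophils (bands), %
    "platelets",    # 10^3 cells/uL
    "crp",          # C-reactive protein, mg/L
    "alt",          # alanine aminotransferase, U/L
    "esr",          # erythrocyte sedimentation rate, mm/h
    "ggt",          # gamma-glutamyl transferase, U/L
)

LAB_UNITS = {
    "wbc": "10^3 cells/uL",
    "eos_pct": "%",
    "hemoglobin": "g/dL",
    "mono_pct": "%",
    "lymph_pct": "%",
    "neut_pct": "%",
    "bands_pct": "%",
    "platelets": "10^3 cells/uL",
    "crp": "mg/L",
    "alt": "U/L",
    "esr": "mm/h",
    "ggt": "U/L",
}

#: Physiologic validity range per analyte; values outside become missing on read.
LAB_RANGES = {
    "wbc": (0.0, 200.0),
    "eos_pct": (0.0, 100.0),
    "hemoglobin": (0.0, 25.0),
    "mono_pct": (0.0, 100.0),
    "lymph_pct": (0.0, 100.0),
    "neut_pct": (0.0, 100.0),
    "bands_pct": (0.0, 100.0),
    "platelets": (0.0, 3000.0),
    "crp": (0.0, 1000.0),
    "alt": (0.0, 10000.0),
    "esr": (0.0, 300.0),
    "ggt": (0.0, 5000.0),
}

#: Analytes routinely collected at the Taiwan study site (bands, ESR and GGT
#: were not, and are excluded from the default modeling profile).
TAIWAN_LAB_PROFILE = (
    "wbc", "eos_pct", "hemoglobin", "mono_pct", "lymph_pct",
    "neut_pct", "platelets", "crp", "alt",
)
FULL_LAB_PROFILE = LAB_ANALYTES

#: Map of lower-cased header variants onto canonical column names.
COLUMN_ALIASES = {
    "id": "id", "patient_id": "id", "subject_id": "id", "pid": "id",
    "diagnosis": "diagnosis", "dx": "diagnosis", "group": "diagnosis",
    "label": "diagnosis",
    "age_years": "age_years", "age": "age_years", "age_yrs": "age_years",
    "sex": "sex", "gender": "sex",
    "illness_days": "illness_days", "illness_day": "illness_days",
    "fever_days": "illness_days", "days_of_fever": "illness_days",
    "rash": "rash",
    "conjunctival_injection": "conjunctival_injection",
    "conj_injection": "conjunctival_injection",
    "conjunctivitis": "conjunctival_injection",
    "extremity_changes": "extremity_changes",
    "extremity": "extremity_changes",
    "oropharyngeal_changes": "oropharyngeal_changes",
    "oral_changes": "oropharyngeal_changes",
    "oral_and_pharyngeal_changes": "oropharyngeal_changes",
    "cervical_lymphadenopathy": "cervical_lymphadenopathy",
    "cervical_lymph_node": "cervical_lymphadenopathy",
    "lymphadenopathy": "cervical_lymphadenopathy",
    "wbc": "wbc", "wbc_k_per_ul": "wbc", "white_blood_cells": "wbc",
    "eos_pct": "eos_pct", "eosinophils_pct": "eos_pct", "eos": "eos_pct",
    "hemoglobin": "hemoglobin", "hgb": "hemoglobin", "hb": "hemoglobin",
    "mono_pct": "mono_pct", "monocytes_pct": "mono_pct",
    "lymph_pct": "lymph_pct", "lymphocytes_pct": "lymph_pct",
    "neut_pct": "neut_pct", "neutrophils_pct": "neut_pct",
    "bands_pct": "bands_pct", "bands": "bands_pct",
    "platelets": "platelets", "plt": "platelets", "platelets_k_per_ul": "platelets",
    "crp": "crp", "crp_mg_l": "crp",
    "alt": "alt", "alt_u_l": "alt",
    "esr": "esr", "esr_mm_h": "esr",
    "ggt": "ggt", "ggt_u_l": "ggt",
    "coronary_z": "coronary_z", "coronary_zscores": "coronary_z",
}

MANDATORY_COLUMNS = ("id", "illness_days") + CRITERIA_FIELDS

_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n"}


@dataclass(frozen=True)
class CriteriaSet:
    """The five principal clinical criteria of Kawasaki disease."""

    rash: bool
    conjunctival_injection: bool
    extremity_changes: bool
    oropharyngeal_changes: bool
    cervical_lymphadenopathy: bool

    @property
    def count(self) -> int:
        """Number of criteria present (0-5)."""
        return sum(getattr(self, f) for f in CRITERIA_FIELDS)

    def as_tuple(self) -> tuple[bool, ...]:
        return tuple(getattr(self, f) for f in CRITERIA_FIELDS)


@dataclass(frozen=True)
class LabPanel:
    """Laboratory panel; ``None`` marks a missing value."""

    wbc: float | None = None
    eos_pct: float | None = None
    hemoglobin: float | None = None
    mono_pct: float | None = None
    lymph_pct: float | None = None
    neut_pct: float | None = None
    bands_pct: float | None = None
    platelets: float | None = None
    crp: float | None = None
    alt: float | None = None
    esr: float | None = None
    ggt: float | None = None

    def __post_init__(self) -> None:
        for name in LAB_ANALYTES:
            v = getattr(self, name)
            if v is None:
                continue
            lo, hi = LAB_RANGES[name]
            if not (lo <= v <= hi) or not np.isfinite(v):
                raise ValidationError(
                    f"lab {name}={v!r} outside validity range [{lo}, {hi}]"
                )

    def get(self, name: str) -> float | None:
        return getattr(self, name)

    def n_missing(self, analytes: Sequence[str] = LAB_ANALYTES) -> int:
        return sum(getattr(self, a) is None for a in analytes)


@dataclass(frozen=True)
class CoronaryStatus:
    """Coronary-artery Z-score trajectory: (day from diagnosis, artery, z)."""

    z_scores: tuple[tuple[int, Artery, float], ...] = ()

    def __post_init__(self) -> None:
        for day, artery, z in self.z_scores:
            if not np.isfinite(z):
                raise ValidationError(f"non-finite coronary z-score {z!r}")
            if not isinstance(artery, Artery):
                raise ValidationError(f"invalid artery {artery!r}")

    @property
    def label(self) -> CoronaryLabel:
        return label_coronary(self)


#: Day offset implementing the "resolved by 8 weeks" boundary (closed).
EIGHT_WEEKS_DAYS = 56
Z_ABNORMAL = 2.5
Z_ANEURYSM = 5.0


def label_coronary(status: CoronaryStatus) -> CoronaryLabel:
    """Derive the coronary outcome label from a Z-score trajectory.

    Rules (Z in standard deviations, day counted from diagnosis):

    - ``MISSING``: no measurements.
    - ``NORMAL``: every Z < 2.5.
    - ``ANEURYSM``: any Z >= 5.
    - otherwise max Z in [2.5, 5):
        - ``UNRESOLVED`` if some measurement at day >= 56 is still >= 2.5,
        - ``DILATED`` if measurements at day >= 56 exist and are all < 2.5,
        - ``NO_FOLLOWUP`` if no measurement exists at day >= 56.
    """
    zs = status.z_scores
    if not zs:
        return CoronaryLabel.MISSING
    zvals = [z for _, _, z in zs]
    if max(zvals) < Z_ABNORMAL:
        return CoronaryLabel.NORMAL
    if max(zvals) >= Z_ANEURYSM:
        return CoronaryLabel.ANEURYSM
    late = [z for day, _, z in zs if day >= EIGHT_WEEKS_DAYS]
    if not late:
        return CoronaryLabel.NO_FOLLOWUP
    if max(late) >= Z_ABNORMAL:
        return CoronaryLabel.UNRESOLVED
    return CoronaryLabel.DILATED


@dataclass(frozen=True)
class PatientRecord:
    """One child's demographics, clinical criteria, labs and optional outcome."""

    id: str
    criteria: CriteriaSet
    illness_days: int
    labs: LabPanel = field(default_factory=LabPanel)
    diagnosis: Diagnosis | None = None
    age_years: float | None = None
    sex: Sex = Sex.UNKNOWN
    coronary: CoronaryStatus | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("record id must be non-empty")
        if self.illness_days < 1:
            raise ValidationError(
                f"record {self.id}: illness_days must be >= 1, got {self.illness_days}"
            )
        if self.age_years is not None and self.age_years < 0:
            raise ValidationError(
                f"record {self.id}: age_years must be >= 0, got {self.age_years}"
            )


class CohortTable:
    """Ordered collection of :class:`PatientRecord` with unique ids.

    Behaves as a sequence and converts losslessly to/from a flat
    :class:`pandas.DataFrame` (see :meth:`to_frame` / :meth:`from_frame`).
    """

    def __init__(self, records: Iterable[PatientRecord], provenance: str = ""):
        self.records: list[PatientRecord] = list(records)
        self.provenance = provenance
        seen: set[str] = set()
        for r in self.records:
            if r.id in seen:
                raise ValidationError(f"duplicate record id {r.id!r}")
            seen.add(r.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, keep) -> "CohortTable":
        """Return a new table with records for which ``keep(record)`` is true."""
        return CohortTable([r for r in self.records if keep(r)], self.provenance)

    # ------------------------------------------------------------------ frames
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row: dict = {
                "id": r.id,
                "diagnosis": r.diagnosis.value if r.diagnosis else "",
                "age_years": r.age_years if r.age_years is not None else np.nan,
                "sex": r.sex.value,
                "illness_days": r.illness_days,
            }
            for f in CRITERIA_FIELDS:
                row[f] = int(getattr(r.criteria, f))
            for a in LAB_ANALYTES:
                v = r.labs.get(a)
                row[a] = np.nan if v is None else v
            row["coronary_z"] = _format_coronary(r.coronary)
            rows.append(row)
        cols = (
            ["id", "diagnosis", "age_years", "sex", "illness_days"]
            + list(CRITERIA_FIELDS) + list(LAB_ANALYTES) + ["coronary_z"]
        )
        return pd.DataFrame(rows, columns=cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "") -> "CohortTable":
        return cls(
            (_record_from_row(row) for _, row in df.iterrows()), provenance
        )

    def __eq__(self, other) -> bool:
        return isinstance(other, CohortTable) and self.records == other.records


def _format_coronary(status: CoronaryStatus | None) -> str:
    if status is None or not status.z_scores:
        return ""
    return ";".join(f"{d}:{a.value}:{z:g}" for d, a, z in status.z_scores)


def _parse_coronary(cell: str) -> CoronaryStatus | None:
    if not cell or (isinstance(cell, float) and np.isnan(cell)):
        return None
    entries = []
    for part in str(cell).split(";"):
        day, artery, z = part.split(":")
        entries.append((int(day), Artery(artery), float(z)))
    return CoronaryStatus(tuple(entries))


def _parse_bool(cell, column: str, record_id: str) -> bool:
    s = str(cell).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValidationError(
        f"record {record_id}: cannot parse {column}={cell!r} as boolean"
    )


def _record_from_row(row: pd.Series) -> PatientRecord:
    rid = str(row["id"])
    criteria = CriteriaSet(
        **{f: _parse_bool(row[f], f, rid) for f in CRITERIA_FIELDS}
    )
    labs = {}
    for a in LAB_ANALYTES:
        v = row.get(a, np.nan)
        labs[a] = None if pd.isna(v) else float(v)
    diag = row.get("diagnosis", "")
    diagnosis = Diagnosis(diag) if isinstance(diag, str) and diag in ("KD", "FC") else None
    sex_raw = str(row.get("sex", "unknown")).strip()
    sex = {"m": Sex.M, "f": Sex.F}.get(sex_raw.lower(), Sex.UNKNOWN)
    age = row.get("age_years", np.nan)
    return PatientRecord(
        id=rid,
        criteria=criteria,
        illness_days=int(row["illness_days"]),
        labs=LabPanel(**labs),
        diagnosis=diagnosis,
        age_years=None if pd.isna(age) else float(age),
        sex=sex,
        coronary=_parse_coronary(row.get("coronary_z", "")),
    )


# ---------------------------------------------------------------------- I/O
def read_cohort(path, delimiter: str | None = None) -> CohortTable:
    """Read a delimited-text cohort file into a validated :class:`CohortTable`.

    Comma is the default delimiter; tab is accepted (auto-detected from the
    header line when ``delimiter`` is None). Header names are mapped through
    :data:`COLUMN_ALIASES`; unknown columns are ignored with a warning. Cells
    that fail to parse as numbers, and lab values outside their physiologic
    validity range, become missing with a logged warning. Missing values are
    encoded as empty cells or ``NA``.

    Raises
    ------
    SchemaError
        If mandatory columns (id, illness_days, the five criteria) are absent.
    ValidationError
        On duplicate ids or unparseable mandatory fields.
    """
    path = Path(path)
    if delimiter is None:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
        delimiter = "\t" if "\t" in header else ","
    df = pd.read_csv(
        path, sep=delimiter, dtype=str, keep_default_na=False,
        na_values=["NA", ""], comment="#", encoding="utf-8",
    )
    rename, unknown = {}, []
    for col in df.columns:
        canon = COLUMN_ALIASES.get(col.strip().lower())
        if canon is None:
            unknown.append(col)
        else:
            rename[col] = canon
    if unknown:
        logger.warning("ignoring unknown columns: %s", ", ".join(unknown))
    df = df.rename(columns=rename)[[c for c in rename.values()]]
    missing_cols = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory columns: {', '.join(missing_cols)}")
    for a in LAB_ANALYTES:
        if a not in df.columns:
            logger.warning("column %s absent; treating analyte as missing", a)
            df[a] = np.nan
        else:
            df[a] = _coerce_lab(df[a], a)
    for col in ("age_years",):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        else:
            df[col] = np.nan
    df["illness_days"] = pd.to_numeric(df["illness_days"], errors="raise")
    return CohortTable.from_frame(df, provenance=str(path))


def _coerce_lab(col: pd.Series, analyte: str) -> pd.Series:
    vals = pd.to_numeric(col, errors="coerce")
    bad_parse = vals.isna() & col.notna()
    if bad_parse.any():
        logger.warning(
            "%d unparseable %s cells set to missing", int(bad_parse.sum()), analyte
        )
    lo, hi = LAB_RANGES[analyte]
    out_of_range = vals.notna() & ~vals.between(lo, hi)
    if out_of_range.any():
        logger.warning(
            "%d %s values outside [%g, %g] set to missing",
            int(out_of_range.sum()), analyte, lo, hi,
        )
        vals[out_of_range] = np.nan
    return vals


def write_cohort(cohort: CohortTable, path, delimiter: str = ",") -> None:
    """Write a cohort as delimited text (UTF-8, header row, NA for missing)."""
    df = cohort.to_frame()
    df.to_csv(path, sep=delimiter, index=False, na_rep="NA", encoding="utf-8")


# ------------------------------------------------------------------ filtering
@dataclass(frozen=True)
class Exclusion:
    id: str
    reason_code: str
    reason: str
    diagnosis: str


def apply_inclusion_filters(
    cohort: CohortTable,
) -> tuple[CohortTable, list[Exclusion]]:
    """Apply the study inclusion rules, returning the retained cohort and a log.

    Two exclusion rules: fever for more than 10 days (any group), and febrile
    controls presenting none of the five principal criteria (an FC is defined
    as having at least one sign). Fever magnitude (>=38.0 C) is an enrollment
    precondition, not a stored field, so it is not re-checked here.

    Idempotent: filtering an already filtered cohort removes nothing.
    """
    kept, log = [], []
    for r in cohort:
        if r.illness_days > 10:
            log.append(Exclusion(r.id, "FEVER_GT_10D",
                                 "fever for more than 10 days",
                                 r.diagnosis.value if r.diagnosis else ""))
        elif r.diagnosis is Diagnosis.FC and r.criteria.count == 0:
            log.append(Exclusion(r.id, "FC_NO_CRITERIA",
                                 "febrile control without any principal criterion",
                                 "FC"))
        else:
            kept.append(r)
    return CohortTable(kept, cohort.provenance), log


def write_exclusion_log(log: Sequence[Exclusion], path, delimiter: str = ",") -> None:
    pd.DataFrame(
        [(e.id, e.reason_code, e.reason, e.diagnosis) for e in log],
        columns=["id", "reason_code", "reason", "diagnosis"],
    ).to_csv(path, sep=delimiter, index=False, encoding="utf-8")
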