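"""Three-way confusion accounting and univariable statistics.

The classifier can abstain, so the usual 2x2 confusion matrix becomes 2x3
(true class KD/FC by call KD/FC/indeterminate) and the four headline metrics
use different denominators:

- sensitivity = KD called KD / all KD (abstentions count against it),
- specificity = FC called FC / all FC,
- PPV = KD called KD / all called KD (abstentions excluded),
- NPV = FC called FC / all called FC.

Counts and metrics are kept as exact rationals internally; rendering rounds
half-even to one decimal. Zero-denominator metrics are ``None`` (serialized
as null), never 0.

Univariable comparisons use Fisher's exact test (two-sided by the
minimum-likelihood convention) for categorical variables and the
Mann-Whitney U test (midranks; exact for small untied samples, otherwise a
tie- and continuity-corrected normal approximation) for continuous ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from fractions import Fraction
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .forest import ClassificationResult, StratumKey
from .lda import FC, INDETERMINATE, KD
from .records import CohortTable, CoronaryLabel, Diagnosis, ValidationError

__all__ = [
    "ConfusionSummary",
    "StratifiedReport",
    "summarize",
    "stratified_report",
    "fisher_exact",
    "mann_whitney_u",
    "median_ratio_report",
    "MannWhitneyResult",
]

CALLS = (KD, FC, INDETERMINATE)


def _pct(x: Fraction | None) -> float | None:
    return None if x is None else float(x * 100)


def render_pct(x: Fraction | None, decimals: int = 1) -> str:
    """Round-half-even percentage rendering, e.g. Fraction(379,418) -> '90.7'."""
    if x is None:
        return "undefined"
    q = Decimal(x.numerator * 100) / Decimal(x.denominator)
    return str(q.quantize(Decimal(10) ** -decimals, rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class ConfusionSummary:
    """2 (true) x 3 (call) counts with the derived metrics as exact rationals."""

    counts: Mapping[tuple[str, str], int]   # (true, call) -> n

    def __post_init__(self):
        for (t, c), n in self.counts.items():
            if t not in (KD, FC) or c not in CALLS or n < 0:
                raise ValidationError(f"bad confusion cell ({t},{c})={n}")

    def n(self, true: str, call: str) -> int:
        return int(self.counts.get((true, call), 0))

    @property
    def total_kd(self) -> int:
        return sum(self.n(KD, c) for c in CALLS)

    @property
    def total_fc(self) -> int:
        return sum(self.n(FC, c) for c in CALLS)

    def _ratio(self, num: int, den: int) -> Fraction | None:
        return None if den == 0 else Fraction(num, den)

    @property
    def sensitivity(self) -> Fraction | None:
        return self._ratio(self.n(KD, KD), self.total_kd)

    @property
    def specificity(self) -> Fraction | None:
        return self._ratio(self.n(FC, FC), self.total_fc)

    @property
    def ppv(self) -> Fraction | None:
        return self._ratio(self.n(KD, KD), self.n(KD, KD) + self.n(FC, KD))

    @property
    def npv(self) -> Fraction | None:
        return self._ratio(self.n(FC, FC), self.n(FC, FC) + self.n(KD, FC))

    @property
    def indeterminate_rate_kd(self) -> Fraction | None:
        return self._ratio(self.n(KD, INDETERMINATE), self.total_kd)

    @property
    def indeterminate_rate_fc(self) -> Fraction | None:
        return self._ratio(self.n(FC, INDETERMINATE), self.total_fc)

    @property
    def misclassified_rate_kd(self) -> Fraction | None:
        return self._ratio(self.n(KD, FC), self.total_kd)

    @property
    def misclassified_rate_fc(self) -> Fraction | None:
        return self._ratio(self.n(FC, KD), self.total_fc)

    METRICS = (
        "sensitivity", "specificity", "ppv", "npv",
        "indeterminate_rate_kd", "indeterminate_rate_fc",
        "misclassified_rate_kd", "misclassified_rate_fc",
    )

    def to_dict(self) -> dict:
        """Counts plus metrics as percentages (floats; null when undefined)."""
        out: dict = {
            "counts": {f"{t}_called_{c}": self.n(t, c)
                       for t in (KD, FC) for c in CALLS},
        }
        for m in self.METRICS:
            out[f"{m}_pct"] = _pct(getattr(self, m))
        return out

    def render(self) -> str:
        lines = [
            "            call KD   call FC   indeterminate",
            f"true KD   {self.n(KD, KD):8d}  {self.n(KD, FC):8d}  "
            f"{self.n(KD, INDETERMINATE):12d}",
            f"true FC   {self.n(FC, KD):8d}  {self.n(FC, FC):8d}  "
            f"{self.n(FC, INDETERMINATE):12d}",
            "",
        ]
        for m in self.METRICS:
            lines.append(f"{m:>24s}: {render_pct(getattr(self, m))}%")
        return "\n".join(lines)


def summarize(
    truth: Mapping[str, str],
    results: Sequence[ClassificationResult],
) -> ConfusionSummary:
    """Tally a 2x3 confusion summary; ids must align one-to-one with truth."""
    ids = [r.id for r in results]
    if set(ids) != set(truth) or len(ids) != len(set(ids)):
        raise ValidationError("result ids do not align one-to-one with truth labels")
    counts: dict[tuple[str, str], int] = {}
    for r in results:
        key = (truth[r.id], r.call)
        counts[key] = counts.get(key, 0) + 1
    return ConfusionSummary(counts)


# -------------------------------------------------------------- stratification
STRATIFIERS: dict[str, Callable] = {}


def _age_stratum(record) -> str:
    if record.age_years is None:
        return "age unknown"
    return "<1 year" if record.age_years < 1.0 else ">=1 year"


def _illness_stratum(record) -> str:
    return "<8 days" if record.illness_days < 8 else "8-10 days"


def _criteria_stratum(record) -> str:
    return StratumKey.for_count(record.criteria.count).value


def _coronary_stratum(record) -> str:
    if record.coronary is None:
        return CoronaryLabel.MISSING.value
    return record.coronary.label.value


STRATIFIERS.update({
    "age": _age_stratum,
    "illness_days": _illness_stratum,
    "criteria_count": _criteria_stratum,
    "coronary": _coronary_stratum,
})


@dataclass(frozen=True)
class StratifiedReport:
    stratifier: str
    strata: Mapping[str, ConfusionSummary]

    def to_dict(self) -> dict:
        return {"stratifier": self.stratifier,
                "strata": {k: v.to_dict() for k, v in self.strata.items()}}


def stratified_report(
    cohort: CohortTable,
    truth: Mapping[str, str],
    results: Sequence[ClassificationResult],
    stratifier: str,
) -> StratifiedReport:
    """Per-stratum confusion summaries for one of the supported stratifiers
    (age, illness_days, criteria_count, coronary)."""
    if stratifier not in STRATIFIERS:
        raise ValidationError(
            f"unknown stratifier {stratifier!r}; choose from {sorted(STRATIFIERS)}"
        )
    fn = STRATIFIERS[stratifier]
    by_id = {r.id: r for r in results}
    groups: dict[str, list[ClassificationResult]] = {}
    truths: dict[str, dict[str, str]] = {}
    for rec in cohort:
        s = fn(rec)
        groups.setdefault(s, []).append(by_id[rec.id])
        truths.setdefault(s, {})[rec.id] = truth[rec.id]
    return StratifiedReport(
        stratifier,
        {s: summarize(truths[s], groups[s]) for s in groups},
    )


# ------------------------------------------------------------------ statistics
def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Two-sided by the minimum-likelihood convention: sum of hypergeometric
    probabilities (margins fixed) of all tables no more probable than the
    observed one. Alternative two-sided conventions (doubling, central) exist
    and give different values for some tables.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValidationError("fisher_exact requires a 2x2 table")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValidationError("fisher_exact requires non-negative integer entries")
    if t.sum() == 0:
        raise ValidationError("fisher_exact requires a non-empty table")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


class MannWhitneyResult(NamedTuple):
    u: float
    pvalue: float
    method: str     # "exact" or "asymptotic"


def mann_whitney_u(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> MannWhitneyResult:
    """Mann-Whitney U (midrank ties) with two-sided p.

    Exact p by enumeration when n_a + n_b <= 20 and the pooled sample is
    tie-free; otherwise the tie-corrected normal approximation with
    continuity correction. The method used is recorded in the result.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("mann_whitney_u requires non-empty samples")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), method)


# -------------------------------------------------------------- median ratios
@dataclass(frozen=True)
class MedianRatioEntry:
    analyte: str
    bin: str
    kd_median: float | None
    fc_median: float | None
    ratio: float | None          # None flags "undefined" (empty group / zero FC median)
    pvalue: float | None
    method: str | None


def median_ratio_report(
    cohort: CohortTable,
    analytes: Sequence[str],
    bins: Mapping[str, Callable] | None = None,
) -> list[MedianRatioEntry]:
    """KD/FC median ratio per analyte per illness-day bin, with Mann-Whitney p.

    Default bins are illness days < 8 and 8-10. Undefined ratios (an empty
    group in a bin, or FC median zero) are flagged, never raised.
    """
    if bins is None:
        bins = {"<8 days": lambda r: r.illness_days < 8,
                "8-10 days": lambda r: 8 <= r.illness_days <= 10}
    out = []
    for bname, pred in bins.items():
        sub = [r for r in cohort if pred(r)]
        for a in analytes:
            kd_vals = [r.labs.get(a) for r in sub
                       if r.diagnosis is Diagnosis.KD and r.labs.get(a) is not None]
            fc_vals = [r.labs.get(a) for r in sub
                       if r.diagnosis is Diagnosis.FC and r.labs.get(a) is not None]
            kd_med = float(np.median(kd_vals)) if kd_vals else None
            fc_med = float(np.median(fc_vals)) if fc_vals else None
            if kd_med is None or fc_med is None or fc_med == 0:
                ratio, p, method = None, None, None
                if kd_vals and fc_vals:
                    mw = mann_whitney_u(kd_vals, fc_vals)
                    p, method = mw.pvalue, mw.method
            else:
                ratio = kd_med / fc_med
                mw = mann_whitney_u(kd_vals, fc_vals)
                p, method = mw.pvalue, mw.method
            out.append(MedianRatioEntry(a, bname, kd_med, fc_med, ratio, p, method))
    return out
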