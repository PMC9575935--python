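"""Synthetic KD / febrile-control cohort generator.

Real cohorts of this kind are not publicly deposited, so the package ships a
generator that emulates the statistical structure the two-step classifier
assumes: group-specific principal-criteria patterns, right-skewed laboratory
distributions that separate Kawasaki disease (KD) from febrile controls (FC),
illness-day distributions, and heavy, group-specific missingness in the lab
panel.

Criteria are sampled in two stages. First a criteria-count stratum (<=2, 3,
>=4 signs) is drawn from the published stratum occupancy of each group; then
a subset of signs of the drawn size is sampled from a conditional-Bernoulli
(conditional Poisson) distribution whose inclusion probabilities are
calibrated, by a fixed-point on the Chen-Dempster-Liu identities, to the
published within-stratum sign frequencies. Five independent Bernoulli draws
cannot match stratum occupancy and within-stratum frequencies at the same
time; conditioning on the count can, which is why the generator works this
way.

Laboratory values are log-normal by default (labs are right-skewed);
hemoglobin is normal truncated at zero. The published study reports no lab
summary statistics by group, so the location/scale defaults here are
package-chosen stand-ins (documented in docs/methods.md), not published
values. Missingness is missing-completely-at-random per analyte, with
per-group rates calibrated so the fraction of records with at least one
missing analyte hits the published any-missing rates (54.3% KD, 98.8% FC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import yaml

from .records import (
    Artery,
    CohortTable,
    CoronaryStatus,
    CriteriaSet,
    Diagnosis,
    LAB_ANALYTES,
    LabPanel,
    PatientRecord,
    Sex,
    ValidationError,
    CRITERIA_FIELDS,
)

__all__ = ["CohortSpec", "default_spec", "generate", "spec_to_yaml", "spec_from_yaml"]

STRATA = ("le2", "3", "ge4")

# Published criteria-count stratum occupancy: 14/36/368 of 418 KD and
# 158/59/42 of 259 FC in the <=2 / 3 / >=4 bins.
_KD_STRATUM = {"le2": 14 / 418, "3": 36 / 418, "ge4": 368 / 418}
_FC_STRATUM = {"le2": 158 / 259, "3": 59 / 259, "ge4": 42 / 259}

# Published within-stratum sign frequencies (proportion positive per stratum).
_KD_SIGNS = {
    "le2": {"oropharyngeal_changes": 4 / 14, "conjunctival_injection": 10 / 14,
            "cervical_lymphadenopathy": 3 / 14, "extremity_changes": 3 / 14,
            "rash": 8 / 14},
    "3": {"oropharyngeal_changes": 27 / 36, "conjunctival_injection": 29 / 36,
          "cervical_lymphadenopathy": 6 / 36, "extremity_changes": 19 / 36,
          "rash": 27 / 36},
    "ge4": {"oropharyngeal_changes": 357 / 368, "conjunctival_injection": 357 / 368,
            "cervical_lymphadenopathy": 168 / 368, "extremity_changes": 355 / 368,
            "rash": 353 / 368},
}
_FC_SIGNS = {
    "le2": {"oropharyngeal_changes": 135 / 158, "conjunctival_injection": 5 / 158,
            "cervical_lymphadenopathy": 42 / 158, "extremity_changes": 9 / 158,
            "rash": 102 / 158},
    "3": {"oropharyngeal_changes": 51 / 59, "conjunctival_injection": 12 / 59,
          "cervical_lymphadenopathy": 44 / 59, "extremity_changes": 21 / 59,
          "rash": 49 / 59},
    "ge4": {"oropharyngeal_changes": 37 / 42, "conjunctival_injection": 34 / 42,
            "cervical_lymphadenopathy": 42 / 42, "extremity_changes": 22 / 42,
            "rash": 40 / 42},
}

#: Missingness: relative per-analyte rates, scaled per group so the
#: any-missing fraction hits its target. Bands, GGT and ESR dominate because
#: they were not routinely collected at the study site.
_MISSING_WEIGHTS = {
    "bands_pct": 0.40, "ggt": 0.40, "esr": 0.25,
    "crp": 0.15, "alt": 0.12,
    "eos_pct": 0.05, "mono_pct": 0.05, "lymph_pct": 0.05, "neut_pct": 0.05,
    "wbc": 0.03, "hemoglobin": 0.03, "platelets": 0.03,
}

# Stand-in lab distributions (no group-wise lab summaries are published).
# family: "lognormal" (median, sigma of log) or "truncnormal" (mean, sd, >=0).
_KD_LABS = {
    "wbc": ("lognormal", 13.0, 0.33),
    "eos_pct": ("lognormal", 1.5, 0.80),
    "hemoglobin": ("truncnormal", 10.8, 1.0),
    "mono_pct": ("lognormal", 5.0, 0.45),
    "lymph_pct": ("lognormal", 25.0, 0.35),
    "neut_pct": ("lognormal", 62.0, 0.22),
    "bands_pct": ("lognormal", 2.0, 0.70),
    "platelets": ("lognormal", 380.0, 0.30),
    "crp": ("lognormal", 80.0, 0.65),
    "alt": ("lognormal", 60.0, 0.70),
    "esr": ("lognormal", 55.0, 0.40),
    "ggt": ("lognormal", 50.0, 0.70),
}
_FC_LABS = {
    "wbc": ("lognormal", 10.0, 0.35),
    "eos_pct": ("lognormal", 1.5, 0.80),
    "hemoglobin": ("truncnormal", 11.5, 1.0),
    "mono_pct": ("lognormal", 6.0, 0.45),
    "lymph_pct": ("lognormal", 40.0, 0.35),
    "neut_pct": ("lognormal", 48.0, 0.25),
    "bands_pct": ("lognormal", 1.0, 0.70),
    "platelets": ("lognormal", 300.0, 0.30),
    "crp": ("lognormal", 25.0, 0.70),
    "alt": ("lognormal", 20.0, 0.60),
    "esr": ("lognormal", 30.0, 0.45),
    "ggt": ("lognormal", 20.0, 0.60),
}

_PCT_ANALYTES = {a for a in LAB_ANALYTES if a.endswith("_pct")}

# Illness-day categorical over days 1-10. FC peaks early (published median 2,
# 7/259 in the 8-10 bin); KD later (327/418 below day 8, 91/418 in 8-10).
_KD_ILLNESS = (0.02, 0.05, 0.09, 0.13, 0.16, 0.18, 0.15, 0.10, 0.07, 0.05)
_FC_ILLNESS = (0.25, 0.28, 0.18, 0.10, 0.07, 0.05, 0.04, 0.01, 0.01, 0.01)

# Coronary outcome mixture for KD (approximate published outcome mix; FCs were
# not imaged and get no trajectory).
_KD_CORONARY = {
    "NORMAL": 331 / 418, "DILATED": 31 / 418, "ANEURYSM": 8 / 418,
    "UNRESOLVED": 12 / 418, "NO_FOLLOWUP": 1 / 418, "MISSING": 35 / 418,
}


# ---------------------------------------------------------- conditional Bernoulli
def _esp(w: np.ndarray) -> np.ndarray:
    """Elementary symmetric polynomials e_0..e_n of the weights."""
    e = np.zeros(len(w) + 1)
    e[0] = 1.0
    for wi in w:
        e[1:] = e[1:] + wi * e[:-1]
    return e


def _cb_inclusion(w: np.ndarray, k: int) -> np.ndarray:
    """Inclusion probabilities of a conditional Bernoulli draw of size k."""
    n = len(w)
    if k <= 0:
        return np.zeros(n)
    if k >= n:
        return np.ones(n)
    ek = _esp(w)[k]
    out = np.empty(n)
    for i in range(n):
        out[i] = w[i] * _esp(np.delete(w, i))[k - 1] / ek
    return out


def _cb_sample(w: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a size-k subset from the conditional Bernoulli distribution."""
    n = len(w)
    chosen = np.zeros(n, dtype=bool)
    remaining = k
    for i in range(n):
        if remaining == 0:
            break
        rest = w[i + 1:]
        e_rest = _esp(rest)
        # P(include i | still need `remaining` from items i..n-1)
        denom = e_rest[remaining] if remaining <= len(rest) else 0.0
        denom = denom + w[i] * e_rest[remaining - 1]
        p = w[i] * e_rest[remaining - 1] / denom
        if rng.random() < p:
            chosen[i] = True
            remaining -= 1
    return chosen


def _calibrate_cb_weights(
    targets: np.ndarray, count_dist: Mapping[int, float], max_iter: int = 400
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Find sampling weights whose count-mixture inclusion probs match targets.

    Returns (weights for free items, forced-include mask, forced-exclude mask).
    Items with target ~1 are always included, ~0 always excluded; the rest are
    tuned by the fixed point w <- w * target / achieved.
    """
    forced_in = targets >= 1.0 - 1e-9
    forced_out = targets <= 1e-9
    free = ~forced_in & ~forced_out
    t_free = targets[free]
    w = t_free / (1.0 - t_free)
    n_forced = int(forced_in.sum())
    for _ in range(max_iter):
        pi = np.zeros_like(w)
        for k, pk in count_dist.items():
            kf = k - n_forced
            pi += pk * _cb_inclusion(w, kf)
        if np.allclose(pi, t_free, atol=1e-12):
            break
        w = w * t_free / np.clip(pi, 1e-12, None)
    return w, forced_in, forced_out


# ------------------------------------------------------------------- spec types
@dataclass
class GroupSpec:
    """Per-diagnosis-group sampling parameters."""

    stratum_probs: dict[str, float]
    count_dist: dict[str, dict[int, float]]      # per stratum: count -> prob
    sign_freq: dict[str, dict[str, float]]       # per stratum: criterion -> prob
    lab_dist: dict[str, tuple[str, float, float]]
    illness_day_probs: tuple[float, ...]
    missingness: dict[str, float]                # per analyte missing prob
    any_missing_target: float
    age_median: float
    age_sigma: float
    male_prob: float
    coronary_mix: dict[str, float] | None = None


@dataclass
class CohortSpec:
    """Full generator configuration; reproducible from its seed."""

    n_kd: int
    n_fc: int
    kd: GroupSpec
    fc: GroupSpec
    criteria_lab_coupling: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_kd < 0 or self.n_fc < 0:
            raise ValidationError("group sizes must be non-negative")
        for gname, g in (("kd", self.kd), ("fc", self.fc)):
            if not math.isclose(sum(g.stratum_probs.values()), 1.0, abs_tol=1e-9):
                raise ValidationError(f"{gname}: stratum probabilities must sum to 1")
            if not math.isclose(sum(g.illness_day_probs), 1.0, abs_tol=1e-9):
                raise ValidationError(f"{gname}: illness-day distribution must sum to 1")
            for s, freqs in g.sign_freq.items():
                for c, p in freqs.items():
                    if not 0.0 <= p <= 1.0:
                        raise ValidationError(f"{gname}/{s}/{c}: probability {p} not in [0,1]")
            for s, cd in g.count_dist.items():
                if not math.isclose(sum(cd.values()), 1.0, abs_tol=1e-9):
                    raise ValidationError(f"{gname}/{s}: count distribution must sum to 1")
            for a, (fam, loc, scale) in g.lab_dist.items():
                if scale <= 0:
                    raise ValidationError(f"{gname}/{a}: scale must be > 0")
                if fam not in ("lognormal", "truncnormal"):
                    raise ValidationError(f"{gname}/{a}: unknown family {fam!r}")
            for a, p in g.missingness.items():
                if not 0.0 <= p <= 1.0:
                    raise ValidationError(f"{gname}/{a}: missing probability {p} not in [0,1]")


def _count_dist_from_signs(stratum: str, sign_freq: Mapping[str, float],
                           le2_split: Mapping[int, float] | None = None) -> dict[int, float]:
    """Derive the within-stratum count distribution implied by the sign sums.

    The within-stratum sign frequencies must average to the mean criteria
    count, which pins down the split between the two admissible counts of the
    ">=4" (4 vs 5) and "<=2" bins; the "3" bin is a point mass.
    """
    total = sum(sign_freq.values())
    if stratum == "3":
        return {3: 1.0}
    if stratum == "ge4":
        p5 = min(max(total - 4.0, 0.0), 1.0)
        return {4: 1.0 - p5, 5: p5}
    if le2_split is not None:
        return dict(le2_split)
    # <=2 bin: counts 1 and 2 (count 0 is excluded by the enrollment rules)
    p2 = min(max(total - 1.0, 0.0), 1.0)
    return {1: 1.0 - p2, 2: p2}


def _calibrate_missingness(target: float, weights: Mapping[str, float]) -> dict[str, float]:
    """Scale relative per-analyte rates so P(>=1 analyte missing) = target."""
    def any_missing(s: float) -> float:
        keep = 1.0
        for wgt in weights.values():
            keep *= 1.0 - min(1.0, s * wgt)
        return 1.0 - keep

    lo, hi = 0.0, 1.0
    while any_missing(hi) < target:
        hi *= 2.0
        if hi > 1e6:
            raise ValidationError("any-missing target unattainable")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if any_missing(mid) < target:
            lo = mid
        else:
            hi = mid
    s = 0.5 * (lo + hi)
    return {a: min(1.0, s * wgt) for a, wgt in weights.items()}


def default_spec(n_kd: int = 418, n_fc: int = 259, seed: int = 0) -> CohortSpec:
    """The packaged default cohort spec.

    Criteria-count stratum occupancy and within-stratum sign frequencies match
    the published Taiwan single-center distribution; any-missing rates target
    54.3% (KD) and 98.8% (FC); lab separations are package-chosen stand-ins
    with KD elevated on CRP, ALT and WBC. Default group sizes mirror the
    published cohort (418 KD, 259 FC).
    """
    kd = GroupSpec(
        stratum_probs=dict(_KD_STRATUM),
        count_dist={s: _count_dist_from_signs(s, _KD_SIGNS[s]) for s in STRATA},
        sign_freq={s: dict(_KD_SIGNS[s]) for s in STRATA},
        lab_dist=dict(_KD_LABS),
        illness_day_probs=_KD_ILLNESS,
        missingness=_calibrate_missingness(0.543, _MISSING_WEIGHTS),
        any_missing_target=0.543,
        age_median=1.3,
        age_sigma=0.9,
        male_prob=0.605,
        coronary_mix=dict(_KD_CORONARY),
    )
    fc = GroupSpec(
        stratum_probs=dict(_FC_STRATUM),
        count_dist={s: _count_dist_from_signs(s, _FC_SIGNS[s]) for s in STRATA},
        sign_freq={s: dict(_FC_SIGNS[s]) for s in STRATA},
        lab_dist=dict(_FC_LABS),
        illness_day_probs=_FC_ILLNESS,
        missingness=_calibrate_missingness(0.988, _MISSING_WEIGHTS),
        any_missing_target=0.988,
        age_median=1.0,
        age_sigma=0.9,
        male_prob=0.533,
        coronary_mix=None,
    )
    return CohortSpec(n_kd=n_kd, n_fc=n_fc, kd=kd, fc=fc, seed=seed)


# ------------------------------------------------------------------- generation
def _sample_criteria(group: GroupSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample an (n, 5) boolean criteria matrix for one group."""
    out = np.zeros((n, len(CRITERIA_FIELDS)), dtype=bool)
    strata = list(group.stratum_probs)
    probs = np.array([group.stratum_probs[s] for s in strata])
    draws = rng.choice(len(strata), size=n, p=probs)
    # calibrate per-stratum conditional-Bernoulli weights once
    calib = {}
    for s in strata:
        targets = np.array([group.sign_freq[s][c] for c in CRITERIA_FIELDS])
        calib[s] = _calibrate_cb_weights(targets, group.count_dist[s])
    for i in range(n):
        s = strata[draws[i]]
        w, forced_in, forced_out = calib[s]
        counts, cps = zip(*sorted(group.count_dist[s].items()))
        k = counts[rng.choice(len(counts), p=np.array(cps) / sum(cps))]
        row = np.array(forced_in, copy=True)
        kf = k - int(forced_in.sum())
        free_idx = np.flatnonzero(~forced_in & ~forced_out)
        if kf > 0 and len(free_idx):
            row[free_idx] = _cb_sample(w, min(kf, len(free_idx)), rng)
        out[i] = row
    return out


def _sample_labs(group: GroupSpec, counts: np.ndarray,
                 coupling: Mapping[str, float], rng: np.random.Generator) -> dict[str, np.ndarray]:
    n = len(counts)
    labs = {}
    for a in LAB_ANALYTES:
        fam, loc, scale = group.lab_dist[a]
        shift = coupling.get(a, 0.0) * (counts - 3.0)
        if fam == "lognormal":
            vals = np.exp(rng.normal(np.log(loc) + shift, scale, size=n))
        else:
            vals = rng.normal(loc + shift, scale, size=n)
            vals = np.abs(vals)  # truncation at zero by reflection
        if a in _PCT_ANALYTES:
            vals = np.clip(vals, 0.0, 100.0)
        labs[a] = vals
    return labs


def _sample_coronary(mix: Mapping[str, float], rng: np.random.Generator) -> CoronaryStatus | None:
    labels = list(mix)
    lab = labels[rng.choice(len(labels), p=np.array([mix[l] for l in labels]) / sum(mix.values()))]
    a = Artery.RCA if rng.random() < 0.5 else Artery.LAD
    if lab == "MISSING":
        return None
    if lab == "NORMAL":
        return CoronaryStatus(((14, a, round(rng.uniform(0.0, 2.4), 2)),
                               (60, a, round(rng.uniform(0.0, 2.4), 2))))
    if lab == "DILATED":
        return CoronaryStatus(((14, a, round(rng.uniform(2.5, 4.9), 2)),
                               (60, a, round(rng.uniform(0.5, 2.4), 2))))
    if lab == "ANEURYSM":
        return CoronaryStatus(((14, a, round(rng.uniform(5.0, 9.0), 2)),))
    if lab == "UNRESOLVED":
        return CoronaryStatus(((14, a, round(rng.uniform(2.5, 4.9), 2)),
                               (60, a, round(rng.uniform(2.5, 4.9), 2))))
    # NO_FOLLOWUP
    return CoronaryStatus(((14, a, round(rng.uniform(2.5, 4.9), 2)),))


def _generate_group(group: GroupSpec, n: int, diagnosis: Diagnosis, prefix: str,
                    coupling: Mapping[str, float], rng: np.random.Generator) -> list[PatientRecord]:
    criteria = _sample_criteria(group, n, rng)
    counts = criteria.sum(axis=1)
    labs = _sample_labs(group, counts, coupling, rng)
    # mask labs per analyte (masking is a projection: observed values untouched)
    masks = {a: rng.random(n) < group.missingness.get(a, 0.0) for a in LAB_ANALYTES}
    illness = 1 + rng.choice(10, size=n, p=np.asarray(group.illness_day_probs))
    ages = np.exp(rng.normal(np.log(group.age_median), group.age_sigma, size=n))
    male = rng.random(n) < group.male_prob
    records = []
    for i in range(n):
        panel = {a: (None if masks[a][i] else float(np.round(labs[a][i], 3)))
                 for a in LAB_ANALYTES}
        coronary = None
        if group.coronary_mix is not None:
            coronary = _sample_coronary(group.coronary_mix, rng)
        records.append(PatientRecord(
            id=f"{prefix}{i:05d}",
            criteria=CriteriaSet(*(bool(criteria[i, j]) for j in range(5))),
            illness_days=int(illness[i]),
            labs=LabPanel(**panel),
            diagnosis=diagnosis,
            age_years=float(np.round(ages[i], 2)),
            sex=Sex.M if male[i] else Sex.F,
            coronary=coronary,
        ))
    return records


def generate(spec: CohortSpec) -> CohortTable:
    """Generate a synthetic cohort; fully reproducible from ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records = _generate_group(spec.kd, spec.n_kd, Diagnosis.KD, "KD",
                              spec.criteria_lab_coupling, rng)
    records += _generate_group(spec.fc, spec.n_fc, Diagnosis.FC, "FC",
                               spec.criteria_lab_coupling, rng)
    return CohortTable(records, provenance=f"synthetic(seed={spec.seed})")


# --------------------------------------------------------------- serialization
def spec_to_yaml(spec: CohortSpec, path) -> None:
    d = asdict(spec)
    # YAML-friendly: integer-keyed count dists to string keys
    for g in ("kd", "fc"):
        d[g]["count_dist"] = {s: {str(k): v for k, v in cd.items()}
                              for s, cd in d[g]["count_dist"].items()}
        d[g]["illness_day_probs"] = list(d[g]["illness_day_probs"])
        d[g]["lab_dist"] = {a: list(v) for a, v in d[g]["lab_dist"].items()}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def spec_from_yaml(path) -> CohortSpec:
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    groups = {}
    for g in ("kd", "fc"):
        gd = dict(d[g])
        gd["count_dist"] = {s: {int(k): v for k, v in cd.items()}
                            for s, cd in gd["count_dist"].items()}
        gd["illness_day_probs"] = tuple(gd["illness_day_probs"])
        gd["lab_dist"] = {a: (v[0], float(v[1]), float(v[2]))
                          for a, v in gd["lab_dist"].items()}
        groups[g] = GroupSpec(**gd)
    return CohortSpec(
        n_kd=int(d["n_kd"]), n_fc=int(d["n_fc"]), kd=groups["kd"], fc=groups["fc"],
        criteria_lab_coupling=d.get("criteria_lab_coupling") or {},
        seed=int(d.get("seed", 0)),
    )
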