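"""Confusion accounting, stratified reports and the exact tests."""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from kdtriage import (
    ConfusionSummary,
    fisher_exact,
    mann_whitney_u,
    median_ratio_report,
    stratified_report,
    summarize,
)
from kdtriage.datasets import load_sign_tables, load_taiwan_confusion
from kdtriage.evaluate import render_pct
from kdtriage.forest import ClassificationResult
from kdtriage.lda import FC, INDETERMINATE, KD
from kdtriage.records import CohortTable, Diagnosis, ValidationError

from conftest import make_record


def results_from(calls):
    return [ClassificationResult(f"r{i}", c, "STEP1", 0.0)
            for i, c in enumerate(calls)]


def truth_from(labels):
    return {f"r{i}": t for i, t in enumerate(labels)}


class TestSummarize:
    def test_published_confusion_reproduces_headline_metrics(self):
        cs = load_taiwan_confusion()
        assert cs.sensitivity == Fraction(379, 418)
        assert cs.specificity == Fraction(223, 259)
        assert cs.ppv == Fraction(379, 409)
        assert cs.npv == Fraction(223, 247)
        assert render_pct(cs.sensitivity) == "90.7"
        assert render_pct(cs.specificity) == "86.1"
        assert render_pct(cs.ppv) == "92.7"
        assert render_pct(cs.npv) == "90.3"

    def test_perfect_classifier(self):
        truth = truth_from([KD] * 5 + [FC] * 5)
        res = results_from([KD] * 5 + [FC] * 5)
        cs = summarize(truth, res)
        for m in ("sensitivity", "specificity", "ppv", "npv"):
            assert getattr(cs, m) == 1
        for m in ("indeterminate_rate_kd", "indeterminate_rate_fc",
                  "misclassified_rate_kd", "misclassified_rate_fc"):
            assert getattr(cs, m) == 0

    def test_counting_oracle_on_random_cohort(self, rng):
        truth_labels = [KD if rng.random() < 0.5 else FC for _ in range(30)]
        calls = [(KD, FC, INDETERMINATE)[rng.integers(3)] for _ in range(30)]
        cs = summarize(truth_from(truth_labels), results_from(calls))
        # oracle: loop and count
        def count(t, c):
            return sum(1 for tt, cc in zip(truth_labels, calls)
                       if tt == t and cc == c)
        for t in (KD, FC):
            for c in (KD, FC, INDETERMINATE):
                assert cs.n(t, c) == count(t, c)
        n_kd = truth_labels.count(KD)
        if n_kd:
            assert cs.sensitivity == Fraction(count(KD, KD), n_kd)

    def test_permutation_invariance(self, rng):
        truth_labels = [KD] * 10 + [FC] * 10
        calls = [(KD, FC, INDETERMINATE)[rng.integers(3)] for _ in range(20)]
        cs1 = summarize(truth_from(truth_labels), results_from(calls))
        perm = rng.permutation(20)
        res = results_from(calls)
        cs2 = summarize(truth_from(truth_labels), [res[i] for i in perm])
        assert cs1.counts == cs2.counts

    def test_metric_sum_identity(self, rng):
        """sensitivity + KD indeterminate rate + KD misclassification rate = 1
        exactly, in rational arithmetic."""
        for _ in range(20):
            truth_labels = [KD if rng.random() < 0.6 else FC for _ in range(25)]
            if KD not in truth_labels or FC not in truth_labels:
                continue
            calls = [(KD, FC, INDETERMINATE)[rng.integers(3)] for _ in range(25)]
            cs = summarize(truth_from(truth_labels), results_from(calls))
            assert (cs.sensitivity + cs.indeterminate_rate_kd
                    + cs.misclassified_rate_kd) == 1
            assert (cs.specificity + cs.indeterminate_rate_fc
                    + cs.misclassified_rate_fc) == 1

    def test_id_mismatch_errors(self):
        with pytest.raises(ValidationError):
            summarize({"a": KD}, [ClassificationResult("b", KD, "STEP1", 0.0)])

    def test_zero_denominator_is_none_not_zero(self):
        cs = ConfusionSummary({(KD, KD): 3})
        assert cs.specificity is None
        assert cs.npv is None
        assert cs.to_dict()["specificity_pct"] is None


class TestStratifiedReport:
    def make_cohort_results(self):
        recs, calls, truth = [], [], {}
        spec = [
            ("i1", 0.5, KD, KD), ("i2", 0.8, KD, FC),
            ("o1", 2.0, KD, KD), ("o2", 3.0, FC, FC), ("o3", 1.0, FC, KD),
        ]
        for rid, age, t, c in spec:
            recs.append(make_record(rid, age_years=age,
                                    diagnosis=Diagnosis(t)))
            calls.append(ClassificationResult(rid, c, "STEP1", 0.0))
            truth[rid] = t
        return CohortTable(recs), truth, calls

    def test_age_strata(self):
        cohort, truth, calls = self.make_cohort_results()
        rep = stratified_report(cohort, truth, calls, "age")
        assert set(rep.strata) == {"<1 year", ">=1 year"}
        assert rep.strata["<1 year"].sensitivity == Fraction(1, 2)

    def test_single_stratum_equals_summarize(self):
        cohort, truth, calls = self.make_cohort_results()
        rep = stratified_report(cohort, truth, calls, "illness_days")
        assert set(rep.strata) == {"<8 days"}
        assert rep.strata["<8 days"].counts == summarize(truth, calls).counts

    def test_published_age_fixture(self):
        """Infant stratum: 140 of 157 KD called correctly -> 89.2%."""
        from kdtriage.datasets import load_age_outcomes
        df = load_age_outcomes()
        infants = df[df.stratum == "<1 year"].iloc[0]
        frac = Fraction(int(infants.correct), int(infants.total))
        assert render_pct(frac) == "89.2"
        assert int(infants.correct + infants.misclassified
                   + infants.indeterminate) == int(infants.total)

    def test_published_criteria_fixture(self):
        """3-criteria KD stratum sensitivity is 16/36 = 44.4%."""
        from kdtriage.datasets import load_criteria_outcomes
        df = load_criteria_outcomes()
        row = df[(df.group == "KD") & (df.stratum == "3")].iloc[0]
        assert render_pct(Fraction(int(row.correct), int(row.total))) == "44.4"

    def test_unknown_stratifier_errors(self):
        cohort, truth, calls = self.make_cohort_results()
        with pytest.raises(ValidationError):
            stratified_report(cohort, truth, calls, "weight")


def oracle_fisher(table):
    """Exhaustive hypergeometric enumeration, minimum-likelihood two-sided."""
    a, b = table[0]
    c, d = table[1]
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, c1 - (c + d)), min(r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for aa in range(lo, hi + 1):
        p = hypergeom.pmf(aa, n, r1, c1)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


class TestFisherExact:
    def test_uniform_table_p1(self):
        assert fisher_exact([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_published_cervical_le2_row_is_1(self):
        # cervical lymphadenopathy in the <=2-criteria stratum: 3/14 vs 42/158
        assert fisher_exact([[3, 11], [42, 116]]) == pytest.approx(1.0, abs=5e-4)

    @given(st.lists(st.integers(0, 30), min_size=4, max_size=4)
           .filter(lambda v: 0 < sum(v) <= 60))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_enumeration_oracle(self, cells):
        table = [[cells[0], cells[1]], [cells[2], cells[3]]]
        assert fisher_exact(table) == pytest.approx(oracle_fisher(table),
                                                    rel=1e-7, abs=1e-12)

    def test_negative_entries_error(self):
        with pytest.raises(ValidationError):
            fisher_exact([[1, -1], [2, 3]])

    def test_printed_sign_table_pvalues(self, capsys):
        """Exemplar printed p-values reproduce exactly under the
        minimum-likelihood convention; deviating rows are reported."""
        df = load_sign_tables()
        deviations = []
        for _, row in df.iterrows():
            table = [[row.kd_pos, row.kd_total - row.kd_pos],
                     [row.fc_pos, row.fc_total - row.fc_pos]]
            p = fisher_exact(table)
            printed = str(row.printed_p)
            if printed.startswith("<"):
                assert p < float(printed[1:])
            else:
                target = float(printed)
                decimals = len(printed.split(".")[1]) if "." in printed else 0
                if abs(round(p, decimals) - target) > 10 ** -decimals / 2:
                    deviations.append((row.stratum, row.sign, printed, round(p, 3)))
        # exemplar rows must match exactly at printed precision
        assert round(fisher_exact([[3, 11], [42, 116]]), 2) == 1.0
        assert round(fisher_exact([[353, 15], [40, 2]]), 3) == 0.689
        assert round(fisher_exact([[357, 11], [37, 5]]), 3) == 0.017
        if deviations:
            print("printed p-values deviating from the minimum-likelihood "
                  "two-sided convention:", deviations)


def oracle_mannwhitney(a, b):
    """Permutation enumeration of U over all label assignments."""
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    ranks = np.argsort(np.argsort(pooled)) + 1.0  # no ties assumed
    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - na * (na + 1) / 2
    u_obs = u_of(range(na))
    nm = na * (len(b))
    stat_obs = min(u_obs, nm - u_obs)
    hits = total = 0
    for idx in combinations(range(n), na):
        u = u_of(idx)
        total += 1
        if min(u, nm - u) <= stat_obs + 1e-9:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_identical_samples(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.u == pytest.approx(4.5)
        assert res.pvalue == pytest.approx(1.0, abs=0.05)
        assert res.method == "asymptotic"  # ties force the approximation

    def test_fully_separated_minimal_p(self):
        res = mann_whitney_u([1.0, 2.0], [10.0, 11.0])
        assert res.u in (0.0, 4.0)
        assert res.method == "exact"
        # most extreme of C(4,2)=6 orderings -> two-sided p = 2/6
        assert res.pvalue == pytest.approx(2 / 6)

    def test_exact_branch_matches_permutation_oracle(self, rng):
        for _ in range(10):
            a = rng.normal(0, 1, 5)
            b = rng.normal(0.8, 1, 6)
            res = mann_whitney_u(a, b)
            assert res.method == "exact"
            assert res.pvalue == pytest.approx(oracle_mannwhitney(a, b))

    def test_asymptotic_near_exact_at_boundary(self, rng):
        """At n_a + n_b = 20 without ties the normal approximation sits within
        0.01 absolute p of the exact computation."""
        from scipy.stats import mannwhitneyu
        for _ in range(10):
            a = rng.normal(0, 1, 10)
            b = rng.normal(0.5, 1, 10)
            exact = mannwhitneyu(a, b, alternative="two-sided", method="exact")
            approx = mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic", use_continuity=True)
            assert abs(exact.pvalue - approx.pvalue) < 0.01

    def test_empty_sample_errors(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])


class TestMedianRatios:
    def make_cohort(self, kd_vals, fc_vals, analyte="crp", illness=5):
        recs = []
        for i, v in enumerate(kd_vals):
            recs.append(make_record(f"kd{i}", illness_days=illness,
                                    **{analyte: v}))
        for i, v in enumerate(fc_vals):
            recs.append(make_record(f"fc{i}", diagnosis=Diagnosis.FC,
                                    illness_days=illness, **{analyte: v}))
        return CohortTable(recs)

    def test_identical_distributions_ratio_1(self):
        vals = [10.0, 20.0, 30.0]
        rep = median_ratio_report(self.make_cohort(vals, vals), ["crp"])
        by_bin = {e.bin: e for e in rep}
        assert by_bin["<8 days"].ratio == pytest.approx(1.0)
        assert by_bin["8-10 days"].ratio is None  # empty bin flagged

    def test_zero_fc_median_flagged_undefined(self):
        rep = median_ratio_report(
            self.make_cohort([5.0, 6.0], [0.0, 0.0]), ["crp"])
        entry = [e for e in rep if e.bin == "<8 days"][0]
        assert entry.ratio is None
        assert entry.fc_median == 0.0

    def test_hand_computed_medians(self):
        rep = median_ratio_report(
            self.make_cohort([10.0, 40.0, 90.0], [5.0, 10.0, 15.0]), ["crp"])
        entry = [e for e in rep if e.bin == "<8 days"][0]
        assert entry.kd_median == 40.0
        assert entry.fc_median == 10.0
        assert entry.ratio == pytest.approx(4.0)
        assert entry.pvalue is not None
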