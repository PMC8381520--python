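"""Reference selection, margins, Wald difference test, and the five-way classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kneebench.benchmark import (
    BenchmarkConfig,
    Category,
    MarginPair,
    ReferenceSelectionError,
    classify,
    difference_test,
    eligible_comparators,
    margins_from_reference,
    run_benchmark,
    select_reference,
)
from kneebench.registry import ConstructKey, Registry
from kneebench.survival import NetFailureEstimate
from conftest import make_records


def _estimate(label, failure, n, t=3.0, var=1e-6):
    key = ConstructKey(label, "cemented", "fixed", "CR")
    return NetFailureEstimate(
        construct=key, t=t, failure=failure, variance=var,
        n_at_risk=n, ci_low=failure, ci_high=failure,
    )


class TestSelectReference:
    def test_threshold_excludes_small_cohorts(self):
        ests = [
            _estimate("A", 0.012, 3201),
            _estimate("B", 0.010, 800),
            _estimate("C", 0.015, 2000),
        ]
        assert select_reference(ests).brand == "A"

    def test_tie_broken_by_larger_risk_set(self):
        ests = [_estimate("A", 0.012, 1500), _estimate("B", 0.012, 2500)]
        assert select_reference(ests).brand == "B"

    def test_tie_broken_lexicographically_last(self):
        ests = [_estimate("B", 0.012, 1500), _estimate("A", 0.012, 1500)]
        assert select_reference(ests).brand == "A"

    def test_error_when_none_qualify(self):
        with pytest.raises(ReferenceSelectionError, match="1000"):
            select_reference([_estimate("A", 0.01, 999)])


class TestEligibleComparators:
    def test_reference_excluded(self):
        ests = [_estimate(f"C{i:02d}", 0.02, 600) for i in range(25)]
        ref = select_reference(ests, min_at_risk=500)
        comps = eligible_comparators(ests, ref)
        assert len(comps) == 24
        assert ref not in {c.construct for c in comps}

    def test_below_threshold_excluded(self):
        ests = [_estimate("A", 0.01, 2000), _estimate("B", 0.02, 499)]
        assert eligible_comparators(ests, ests[0].construct) == []

    def test_only_reference_qualifying_gives_empty(self):
        ests = [_estimate("A", 0.01, 2000)]
        assert eligible_comparators(ests, ests[0].construct) == []


class TestMargins:
    @pytest.mark.parametrize(
        "f_ref,m20,m100",
        [(0.0122, 0.00244, 0.0122), (0.0258, 0.00516, 0.0258)],
    )
    def test_relative_risk_margins(self, f_ref, m20, m100):
        margins = margins_from_reference(f_ref)
        assert margins.m20 == pytest.approx(m20, abs=1e-12)
        assert margins.m100 == pytest.approx(m100, abs=1e-12)
        assert not margins.degenerate

    def test_zero_reference_is_degenerate(self):
        margins = margins_from_reference(0.0)
        assert margins.m20 == margins.m100 == 0.0
        assert margins.degenerate


class TestDifferenceTest:
    def test_identity_comparison(self):
        e = _estimate("A", 0.05, 1000, var=1e-4)
        diff, se, lo, hi, z, p = difference_test(e, e)
        assert diff == 0.0
        assert z == 0.0
        assert p == pytest.approx(1.0)
        assert lo <= 0.0 <= hi

    def test_hand_worked_example(self):
        comp = _estimate("C", 0.05, 1000, var=0.01**2)
        ref = _estimate("R", 0.02, 3000, var=0.005**2)
        diff, se, lo, hi, z, p = difference_test(comp, ref)
        assert diff == pytest.approx(0.03, abs=1e-15)
        assert se == pytest.approx(0.011180, abs=1e-6)
        assert lo == pytest.approx(0.008087, abs=1e-5)
        assert hi == pytest.approx(0.051913, abs=1e-5)
        assert z == pytest.approx(2.6833, abs=1e-4)
        assert p == pytest.approx(2 * (1 - 0.9963468), abs=1e-4)

    def test_degenerate_no_event_case(self):
        a = _estimate("A", 0.0, 1000, var=0.0)
        b = _estimate("B", 0.0, 1000, var=0.0)
        assert difference_test(a, b) == (0.0, 0.0, 0.0, 0.0, 0.0, 1.0)

    def test_zero_se_nonzero_diff_rejected(self):
        a = _estimate("A", 0.1, 1000, var=0.0)
        b = _estimate("B", 0.0, 1000, var=0.0)
        with pytest.raises(ValueError, match="degenerate"):
            difference_test(a, b)

    def test_mismatched_timepoints_rejected(self):
        with pytest.raises(ValueError, match="time points"):
            difference_test(_estimate("A", 0.1, 100, t=3.0), _estimate("B", 0.1, 100, t=5.0))


MARGINS = MarginPair(m20=0.00244, m100=0.0122)


class TestClassify:
    @pytest.mark.parametrize(
        "ci,expected",
        [
            ((0.015, 0.030), Category.INFERIOR_100),
            ((-0.001, 0.002), Category.NONINFERIOR_20),
            ((0.003, 0.040), Category.INFERIOR_20),
            ((0.001, 0.020), Category.INCONCLUSIVE),
            ((0.001, 0.010), Category.NONINFERIOR_100),
        ],
    )
    def test_hand_worked_bands(self, ci, expected):
        assert classify(*ci, MARGINS) is expected

    def test_narrow_ci_between_margins_is_inferior_20(self):
        # inferiority takes precedence over noninferiority at 100%
        assert classify(0.004, 0.010, MARGINS) is Category.INFERIOR_20

    def test_equality_falls_through_to_weaker_band(self):
        assert classify(MARGINS.m100, 0.05, MARGINS) is Category.INFERIOR_20
        assert classify(MARGINS.m20, 0.05, MARGINS) is Category.INCONCLUSIVE

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            classify(0.1, 0.0, MARGINS)

    @settings(max_examples=500, deadline=None, derandomize=True)
    @given(
        a=st.floats(-0.2, 0.2),
        b=st.floats(-0.2, 0.2),
        f_ref=st.floats(0.001, 0.2),
    )
    def test_exhaustive_and_consistent(self, a, b, f_ref):
        lo, hi = min(a, b), max(a, b)
        margins = margins_from_reference(f_ref)
        cat = classify(lo, hi, margins)
        assert cat in Category
        if cat is Category.INFERIOR_100:
            assert lo > margins.m20
        if cat is Category.NONINFERIOR_20:
            assert hi < margins.m100


def _two_construct_registry(rng, n_ref=2500, n_comp=1500, lam_ref=0.004, lam_comp=0.004):
    key_ref = ConstructKey("Ref", "cemented", "fixed", "CR")
    key_comp = ConstructKey("Comp", "cemented", "fixed", "PS")
    records = []
    for key, n, lam in ((key_ref, n_ref, lam_ref), (key_comp, n_comp, lam_comp)):
        rev = rng.exponential(1 / lam, n) if lam > 0 else np.full(n, np.inf)
        admin = rng.uniform(11.0, 21.0, n)
        obs = np.minimum(rev, admin)
        statuses = np.where(rev <= admin, "revision", "censored")
        records.extend(make_records(list(zip(obs, statuses)), key))
    return Registry(records=records)


class TestRunBenchmark:
    def test_forced_reference_when_only_one_qualifies(self):
        rng = np.random.default_rng(3)
        reg = _two_construct_registry(rng, n_ref=2000, n_comp=800)
        reports = run_benchmark(reg, timepoints=[3.0, 10.0])
        assert len(reports) == 2
        for report in reports:
            assert report.reference.brand == "Ref"
            assert [r.construct.brand for r in report.rows] == ["Comp"]

    def test_three_fold_failure_flagged_inferior(self):
        rng = np.random.default_rng(11)
        reg = _two_construct_registry(
            rng, n_ref=3000, n_comp=1200, lam_ref=0.002, lam_comp=0.006
        )
        (report,) = run_benchmark(reg, timepoints=[10.0])
        assert report.rows[0].category in (Category.INFERIOR_20, Category.INFERIOR_100)

    def test_unqualified_timepoint_omitted(self):
        recs = make_records([(4.0, "censored")] * 1200)
        reports = run_benchmark(Registry(records=recs), timepoints=[3.0, 10.0])
        assert [r.t for r in reports] == [3.0]

    def test_gender_strata_get_own_reference(self):
        rng = np.random.default_rng(5)
        reg = _two_construct_registry(rng, n_ref=4000, n_comp=3000)
        reports = run_benchmark(reg, timepoints=[3.0], stratify_by="gender")
        assert {r.stratum for r in reports} <= {"F", "M"}
        for report in reports:
            assert report.reference_estimate.n_at_risk >= 1000

    def test_empty_registry_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            run_benchmark(Registry(records=[]))

    def test_config_from_mapping_rejects_unknown_keys(self):
        with pytest.raises(ValueError, match="unknown config key"):
            BenchmarkConfig.from_mapping({"margins": [0.2]})

    def test_rows_sorted_by_difference(self):
        rng = np.random.default_rng(17)
        key_a = ConstructKey("Aaa", "cemented", "fixed", "CR")
        key_b = ConstructKey("Bbb", "cemented", "fixed", "CR")
        key_c = ConstructKey("Ccc", "cemented", "fixed", "CR")
        records = []
        for key, lam in ((key_a, 0.002), (key_b, 0.008), (key_c, 0.004)):
            rev = rng.exponential(1 / lam, 1500)
            admin = rng.uniform(11.0, 21.0, 1500)
            statuses = np.where(rev <= admin, "revision", "censored")
            records.extend(make_records(list(zip(np.minimum(rev, admin), statuses)), key))
        (report,) = run_benchmark(Registry(records=records), timepoints=[10.0])
        diffs = [r.diff for r in report.rows]
        assert diffs == sorted(diffs)
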