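import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest

from clinotext.evaluate import (cohort_flow, concordance_index,
                                flag_discrepancies, km_estimate, ps_metrics,
                                scatter_table)
from clinotext.temporal import SurvivalRecord


def ps_table(values):
    return pd.DataFrame({"patient_id": [f"P{i}" for i in range(len(values))], "score": values})


def surv_table(times, events, prefix="P"):
    return pd.DataFrame({
        "patient_id": [f"{prefix}{i}" for i in range(len(times))],
        "time_months": times,
        "event": events,
    })


class TestPSMetrics:
    def test_perfect_agreement(self):
        truth = ps_table([0, 1, 2, 1, 0, 1, 2, 0, 1, 1])
        _, report = ps_metrics(truth, truth)
        assert report.weighted_f1 == pytest.approx(100.0)
        assert all(v["f1"] == pytest.approx(100.0) for v in report.per_class.values())

    def test_hand_computed_two_class_example(self):
        # truth (0,0,1,1) vs predicted (0,1,1,1): one 0 mislabelled as 1
        truth = ps_table([0, 0, 1, 1])
        pred = ps_table([0, 1, 1, 1])
        matrix, report = ps_metrics(pred, truth)
        assert matrix.counts.tolist() == [[1, 1], [0, 2]]
        c0, c1 = report.per_class[0], report.per_class[1]
        assert c0["precision"] == pytest.approx(100.0)
        assert c0["recall"] == pytest.approx(50.0)
        assert c0["f1"] == pytest.approx(66.7, abs=0.05)
        assert c1["precision"] == pytest.approx(66.7, abs=0.05)
        assert c1["recall"] == pytest.approx(100.0)
        assert c1["f1"] == pytest.approx(80.0)
        assert report.weighted_f1 == pytest.approx(73.3, abs=0.05)

    def test_disjoint_patient_sets_error(self):
        truth = ps_table([0, 1])
        pred = ps_table([0, 1]).assign(patient_id=["X0", "X1"])
        with pytest.raises(ValueError, match="overlap"):
            ps_metrics(pred, truth)

    def test_zero_predicted_positives_warns_precision_zero(self):
        truth = ps_table([0, 1, 1])
        pred = ps_table([1, 1, 1])
        with pytest.warns(UserWarning, match="precision"):
            _, report = ps_metrics(pred, truth)
        assert report.per_class[0]["precision"] == 0.0

    def test_matches_sklearn_on_random_labels(self):
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(5)
        truth = ps_table(rng.integers(0, 4, size=60))
        pred = ps_table(rng.integers(0, 4, size=60))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, report = ps_metrics(pred, truth)
            p, r, f, s = precision_recall_fscore_support(
                truth["score"], pred["score"], labels=sorted(report.per_class), zero_division=0
            )
        for i, cls in enumerate(sorted(report.per_class)):
            assert report.per_class[cls]["precision"] == pytest.approx(100 * p[i])
            assert report.per_class[cls]["recall"] == pytest.approx(100 * r[i])
            assert report.per_class[cls]["f1"] == pytest.approx(100 * f[i])
        expected_weighted = 100 * np.average(f, weights=s)
        assert report.weighted_f1 == pytest.approx(expected_weighted)

    def test_weighted_f1_is_support_weighted_mean(self):
        truth = ps_table([0, 0, 1, 2, 2, 2])
        pred = ps_table([0, 1, 1, 2, 2, 0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, report = ps_metrics(pred, truth)
        total = sum(v["support"] for v in report.per_class.values())
        recomputed = sum(v["support"] / total * v["f1"] for v in report.per_class.values())
        assert report.weighted_f1 == pytest.approx(recomputed)


class TestKaplanMeier:
    def test_all_events_odd_n(self):
        km = km_estimate(surv_table([1, 2, 3, 4, 5], [True] * 5))
        assert km.median == pytest.approx(3.0)
        steps = dict(zip(km.times, km.survival))
        assert steps[1.0] == pytest.approx(0.8)
        assert steps[5.0] == pytest.approx(0.0)

    def test_all_censored_median_undefined(self):
        km = km_estimate(surv_table([1, 2, 3], [False] * 3))
        assert km.median is None
        assert km.median_ci == (None, None)
        assert all(s == pytest.approx(1.0) for s in km.survival)

    def test_hand_computed_product_limit_with_censoring(self):
        # times 1, 2+, 3, 4, 5+, 6 (events at 1, 3, 4, 6):
        #   S(1)=5/6, S(3)=5/6*3/4=0.625, S(4)=0.625*2/3=0.41667, S(6)=0
        km = km_estimate(surv_table([1, 2, 3, 4, 5, 6],
                                    [True, False, True, True, False, True]))
        steps = dict(zip(km.times, km.survival))
        assert steps[1.0] == pytest.approx(5 / 6)
        assert steps[3.0] == pytest.approx(0.625)
        assert steps[4.0] == pytest.approx(5 / 12)
        assert steps[6.0] == pytest.approx(0.0)
        assert km.median == pytest.approx(4.0)  # first time S <= 0.5

    def test_no_censoring_reduces_to_one_minus_ecdf(self):
        rng = np.random.default_rng(11)
        times = np.round(rng.exponential(8.0, size=40), 3)
        km = km_estimate(surv_table(times, [True] * 40))
        for t, s in zip(km.times, km.survival):
            if t == 0:
                continue
            assert s == pytest.approx(np.mean(times > t))

    def test_accepts_survival_records(self):
        records = [SurvivalRecord("A", 1.0, True), SurvivalRecord("B", 2.0, False)]
        assert km_estimate(records).n == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(surv_table([], []))


def brute_force_c(tm, ref):
    """Independent pair enumeration straight from the definition."""
    merged = tm.merge(ref, on="patient_id", suffixes=("_tm", "_ref"))
    conc = disc = tied = 0
    for a, b in itertools.combinations(merged.itertuples(index=False), 2):
        if a.time_months_ref == b.time_months_ref:
            continue
        short, long_ = (a, b) if a.time_months_ref < b.time_months_ref else (b, a)
        if not short.event_ref:
            continue
        if short.time_months_tm < long_.time_months_tm:
            conc += 1
        elif short.time_months_tm > long_.time_months_tm:
            disc += 1
        else:
            tied += 1
    total = conc + disc + tied
    return (conc + 0.5 * tied) / total if total else None


class TestConcordance:
    def test_identity_is_one(self):
        ref = surv_table([1, 2, 3, 4], [True] * 4)
        assert concordance_index(ref, ref).c == pytest.approx(1.0)

    def test_full_reversal_is_zero(self):
        ref = surv_table([1, 2, 3], [True] * 3)
        tm = surv_table([3, 2, 1], [True] * 3)
        assert concordance_index(tm, ref).c == pytest.approx(0.0)

    def test_matches_brute_force_on_random_censored_tables(self):
        rng = np.random.default_rng(3)
        ref = surv_table(rng.exponential(8, 30).round(2), rng.random(30) > 0.3)
        tm = surv_table((rng.exponential(8, 30)).round(2), rng.random(30) > 0.3)
        result = concordance_index(tm, ref)
        assert result.c == pytest.approx(brute_force_c(tm, ref))
        assert result.comparable == result.concordant + result.discordant + result.tied

    def test_matches_lifelines_when_all_events(self):
        from lifelines.utils import concordance_index as ll_c

        rng = np.random.default_rng(9)
        ref = surv_table(rng.exponential(8, 25).round(2), [True] * 25)
        tm = surv_table(rng.exponential(8, 25).round(2), [True] * 25)
        ours = concordance_index(tm, ref).c
        # lifelines scores predictions where larger predicted value means
        # longer survival -- same orientation as TM times
        theirs = ll_c(ref["time_months"], tm["time_months"], ref["event"])
        assert ours == pytest.approx(theirs)

    def test_invariant_under_monotone_transform_of_tm_times(self):
        rng = np.random.default_rng(4)
        ref = surv_table(rng.exponential(8, 20).round(2), rng.random(20) > 0.2)
        tm = surv_table(rng.exponential(8, 20).round(2), [True] * 20)
        c1 = concordance_index(tm, ref).c
        tm2 = tm.assign(time_months=np.log1p(tm["time_months"]) * 7 + 2)
        assert concordance_index(tm2, ref).c == pytest.approx(c1)

    def test_swapping_orientation_maps_c_to_one_minus_c(self):
        rng = np.random.default_rng(6)
        ref = surv_table(rng.exponential(8, 15).round(3), [True] * 15)
        tm = surv_table(rng.exponential(8, 15).round(3), [True] * 15)
        res = concordance_index(tm, ref)
        assert res.tied == 0
        flipped = tm.assign(time_months=-tm["time_months"])
        assert concordance_index(flipped, ref).c == pytest.approx(1 - res.c)

    def test_too_few_comparable_pairs_warns(self):
        ref = surv_table([1, 2], [False, False])
        with pytest.warns(UserWarning, match="comparable"):
            res = concordance_index(ref, ref)
        assert res.c is None


class TestDiscrepancies:
    def test_threshold_cases(self):
        ref = surv_table([3.1, 2.0, 4.0], [True] * 3)
        tm = surv_table([9.0, 10.0, 1.0], [True] * 3)
        flags = {f.patient_id: f for f in flag_discrepancies(tm, ref)}
        assert not flags["P0"].flagged  # ratio 2.9
        assert flags["P1"].flagged  # ratio 5.0
        assert flags["P2"].flagged  # ratio 0.25
        assert flags["P1"].ratio == pytest.approx(5.0)

    def test_sorted_by_log_ratio_magnitude(self):
        ref = surv_table([1.0, 1.0, 1.0], [True] * 3)
        tm = surv_table([2.0, 8.0, 0.5], [True] * 3)
        ordered = [f.patient_id for f in flag_discrepancies(tm, ref)]
        assert ordered == ["P1", "P0", "P2"] or ordered == ["P1", "P2", "P0"]
        assert ordered[0] == "P1"

    def test_zero_reference_time_flagged_for_review(self):
        ref = surv_table([0.0], [False])
        tm = surv_table([1.0], [True])
        flags = flag_discrepancies(tm, ref)
        assert flags[0].flagged and math.isnan(flags[0].ratio)


class TestCohortFlow:
    def test_counts_partition_cohort(self):
        statuses = {
            "tm": {f"P{i}": "resolved" for i in range(8)}
            | {"P8": "unresolved", "P9": "no_follow_up"},
            "reference": {f"P{i}": "resolved" for i in range(10)},
        }
        flow = cohort_flow(statuses)
        tm_row = flow.set_index("arm").loc["tm"]
        assert tm_row["total"] == 10
        assert tm_row["resolved"] + tm_row["unresolved"] + tm_row["no_follow_up"] + tm_row["unmatched"] == 10

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="categories"):
            cohort_flow({"tm": {"P0": "lost"}})

    def test_scatter_one_point_per_doubly_resolved_patient(self):
        ref = surv_table([1, 2, 3], [True] * 3)
        tm = surv_table([1, 2], [True] * 2)
        assert len(scatter_table(tm, ref)) == 2
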