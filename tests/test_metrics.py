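"""Agreement framework: temporal, event, kappa, AUC, ICC, AED support."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_event_list
from oracles import brute_event, brute_temporal

from neoseiz.io import SeizureEvent, SeizureEventList
from neoseiz.metrics import (
    AEDRecord,
    BinaryTrack,
    ContingencyCounts,
    aed_support,
    binarize,
    classify_babies,
    detection_by_duration,
    event_agreement,
    events_from_track,
    icc,
    kappa_indices,
    roc_auc,
    summary_stats,
    temporal_agreement,
)


def evlist(pairs, duration=3600.0):
    return SeizureEventList([SeizureEvent(a, b) for a, b in pairs], duration)


@pytest.fixture(scope="module")
def fig2_pair():
    """Annotation pair reconstructing the canonical worked example:
    temporal sensitivity and specificity both 75.0 %, event sensitivity
    66.7 %, one false detection in one hour."""
    ref = evlist([(0, 200), (1000, 1100), (2000, 2100)])
    test = evlist([(0, 600), (1000, 1300), (3000, 3200)])
    return ref, test


class TestBinarize:
    def test_single_event_ones(self):
        track = binarize(evlist([(0, 200)]))
        assert track.values.sum() == 200
        assert len(track.values) == 3600

    def test_empty_all_zero(self):
        assert binarize(evlist([])).values.sum() == 0

    def test_fractional_event_touches_both_edge_seconds(self):
        track = binarize(evlist([(10.4, 12.3)], duration=20))
        assert list(np.flatnonzero(track.values)) == [10, 11, 12]

    def test_track_event_roundtrip_idempotent(self):
        evs = evlist([(10, 70), (100.0, 130.0)], duration=200)
        track = binarize(evs)
        again = binarize(events_from_track(track))
        assert np.array_equal(track.values, again.values)


class TestTemporal:
    def test_worked_example(self, fig2_pair):
        ref, test = fig2_pair
        counts, tm = temporal_agreement(binarize(ref), binarize(test))
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (300, 2400, 800, 100)
        assert tm.sensitivity == pytest.approx(75.0)
        assert tm.specificity == pytest.approx(75.0)

    def test_identical_tracks(self):
        t = binarize(evlist([(5, 50)], 100))
        _, tm = temporal_agreement(t, t)
        assert tm.sensitivity == 100.0 and tm.specificity == 100.0

    def test_allzero_reference_sensitivity_undefined(self):
        ref = binarize(evlist([], 100))
        test = binarize(evlist([(0, 10)], 100))
        _, tm = temporal_agreement(ref, test)
        assert tm.sensitivity is None
        assert tm.specificity == 90.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            temporal_agreement(binarize(evlist([], 100)), binarize(evlist([], 99)))


class TestKappa:
    def test_perfect_agreement(self):
        k = kappa_indices(ContingencyCounts(tp=50, tn=50, fp=0, fn=0))
        assert k.kappa == pytest.approx(1.0)
        assert k.bias_index == 0.0

    def test_worked_counts(self):
        k = kappa_indices(ContingencyCounts(tp=300, fp=800, fn=100, tn=2400))
        assert k.kappa == pytest.approx(0.283, abs=5e-4)
        assert k.prevalence_index == pytest.approx(0.583, abs=5e-4)
        assert k.bias_index == pytest.approx(0.194, abs=5e-4)

    def test_single_class_undefined(self):
        k = kappa_indices(ContingencyCounts(tp=0, fp=0, fn=0, tn=100))
        assert k.kappa is None

    def test_kappa_at_most_one_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            tp, tn, fp, fn = rng.integers(0, 50, 4)
            if tp + tn + fp + fn == 0:
                continue
            k = kappa_indices(ContingencyCounts(int(tp), int(tn), int(fp), int(fn)))
            if k.kappa is not None:
                assert k.kappa <= 1.0 + 1e-12


class TestEventBased:
    def test_worked_example(self, fig2_pair):
        ref, test = fig2_pair
        em = event_agreement(ref, test)
        assert em.sdr == pytest.approx(66.7, abs=0.05)
        assert em.fd_per_h == pytest.approx(1.0)

    def test_self_agreement(self, fig2_pair):
        ref, _ = fig2_pair
        em = event_agreement(ref, ref)
        assert em.sdr == 100.0 and em.fd_per_h == 0.0

    def test_empty_test(self, fig2_pair):
        ref, _ = fig2_pair
        em = event_agreement(ref, evlist([]))
        assert em.sdr == 0.0 and em.fd_per_h == 0.0

    def test_no_reference_events_sdr_undefined(self):
        em = event_agreement(evlist([]), evlist([(0, 20)]))
        assert em.sdr is None
        assert em.fd_per_h == 1.0


class TestBruteForceEquivalence:
    def test_200_random_annotation_pairs_exact(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            duration = float(rng.integers(600, 7200))
            ref = random_event_list(rng, duration)
            test = random_event_list(rng, duration)
            counts, _ = temporal_agreement(binarize(ref), binarize(test))
            assert (counts.tp, counts.tn, counts.fp, counts.fn) == brute_temporal(
                ref, test, duration
            )
            em = event_agreement(ref, test)
            detected, false_det = brute_event(ref, test, duration)
            assert em.n_detected == detected
            assert em.n_false_detections == false_det

    def test_conservation_and_burden_identity(self):
        rng = np.random.default_rng(321)
        for _ in range(50):
            duration = float(rng.integers(600, 7200))
            ref = random_event_list(rng, duration)
            test = random_event_list(rng, duration)
            counts, _ = temporal_agreement(binarize(ref), binarize(test))
            assert counts.n == int(duration)
            # expert burden x 60 equals TP+FN on the 1 Hz grid
            assert counts.tp + counts.fn == binarize(ref).values.sum()


class TestROC:
    def test_perfectly_ordered_probabilities(self):
        ref = binarize(evlist([(0, 100)], 200))
        trace = np.where(np.arange(200) < 100, 0.9, 0.1)
        auc, curve = roc_auc(trace, ref)
        assert auc == 1.0
        assert len(curve) == 9

    def test_label_independent_probabilities_near_half(self):
        rng = np.random.default_rng(6)
        ref = binarize(evlist([(0, 1800)], 3600))
        auc, _ = roc_auc(rng.uniform(0, 1, 3600), ref)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_rank_and_trapezoid_agree_on_smooth_trace(self):
        rng = np.random.default_rng(15)
        ref = binarize(evlist([(600, 1200), (2000, 2600)], 3600))
        base = np.clip(rng.normal(0.25, 0.1, 3600), 0, 1)
        base[600:1200] = np.clip(rng.normal(0.75, 0.1, 600), 0, 1)
        base[2000:2600] = np.clip(rng.normal(0.75, 0.1, 600), 0, 1)
        auc, curve = roc_auc(base, ref)
        assert auc == pytest.approx(curve.attrs["trapezoid_auc"], abs=0.05)

    def test_single_class_undefined(self):
        ref = binarize(evlist([], 100))
        auc, _ = roc_auc(np.linspace(0, 1, 100), ref)
        assert auc is None


class TestDurationProfile:
    def test_all_90s_seizures_detected(self):
        ref = evlist([(0, 90), (500, 590), (1000, 1090)])
        prof = detection_by_duration(ref, ref)
        row = prof[(prof.bin_lo_min == 1.0)].iloc[0]
        assert row.sdr == 100.0
        empty = prof[prof.bin_lo_min == 5.0].iloc[0]
        assert np.isnan(empty.sdr)

    def test_short_seizures_missed(self):
        ref = evlist([(0, 30), (500, 590)])
        test = evlist([(500, 590)])
        prof = detection_by_duration(ref, test)
        assert prof[prof.bin_lo_min == 0.0].iloc[0].sdr == 0.0
        assert prof[prof.bin_lo_min == 1.0].iloc[0].sdr == 100.0

    def test_histogram_conserves_events(self):
        rng = np.random.default_rng(2)
        ref = random_event_list(rng, 7200.0)
        prof = detection_by_duration(ref, evlist([], 7200.0))
        assert prof.n_events.sum() == len(ref)


class TestSummaryStats:
    def test_two_event_hand_example(self):
        evs = evlist([(0, 60), (7200, 7380)], duration=8000)
        s = summary_stats(evs, start_age_h=10.0)
        assert s.seizure_number == 2
        assert s.seizure_burden_min == pytest.approx(4.0)
        assert s.seizure_onset_h == pytest.approx(10.0)
        assert s.seizure_period_h == pytest.approx(2.05)
        assert s.mean_duration_s == 120.0 and s.median_duration_s == 120.0

    def test_single_event_period(self):
        s = summary_stats(evlist([(100, 280)]), 0.0)
        assert s.seizure_period_h == pytest.approx(180 / 3600)

    def test_empty(self):
        s = summary_stats(evlist([]))
        assert s.seizure_number == 0 and s.seizure_burden_min == 0.0
        assert s.seizure_onset_h is None and s.mean_duration_s is None


class TestICC:
    def test_identical_vectors(self):
        assert icc([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_independent_noise_low(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 10, 30)
        assert icc(a, b) < 0.2

    def test_matches_anova_mean_squares_oracle(self):
        a = [3.1, 5.2, 9.9, 1.0, 7.4]
        b = [2.8, 5.9, 9.1, 1.7, 8.0]
        x = np.array([a, b], dtype=float).T
        n, k = x.shape
        gm, rm, cm = x.mean(), x.mean(axis=1), x.mean(axis=0)
        msr = k * np.sum((rm - gm) ** 2) / (n - 1)
        msc = n * np.sum((cm - gm) ** 2) / (k - 1)
        mse = np.sum((x - rm[:, None] - cm[None, :] + gm) ** 2) / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (msc - mse) / n)
        assert icc(a, b) == pytest.approx(expected, abs=1e-10)

    def test_undefined_pairs_dropped_and_min_n(self):
        with pytest.raises(ValueError, match=">= 3"):
            icc([1.0, 2.0, None, None], [1.0, 2.0, 3.0, 4.0])


class TestBabyClassification:
    def test_identification_rules(self):
        cohort = {
            "sz_detected": (evlist([(0, 60)]), evlist([(10, 30)])),
            "sz_missed": (evlist([(0, 60)]), evlist([])),
            "ns_clean": (evlist([]), evlist([])),
            "ns_false": (evlist([]), evlist([(5, 25)])),
        }
        tab = classify_babies(cohort).set_index("record")
        assert bool(tab.loc["sz_detected", "identified"])
        assert not bool(tab.loc["sz_missed", "identified"])
        assert bool(tab.loc["ns_clean", "identified"])
        assert not bool(tab.loc["ns_false", "identified"])
        assert tab.seizure_baby.sum() == 2


class TestAEDSupport:
    def test_concurrency_window(self):
        ref = evlist([(0, 600)], duration=30000)  # ends 10 min in
        aed = AEDRecord(times_h=[(600 + 30 * 60) / 3600.0])  # 30 min later
        tab = aed_support(aed, ref, evlist([], 30000))
        assert bool(tab.concurrent.iloc[0])

    def test_nonconcurrent_beyond_90min(self):
        ref = evlist([(0, 600)], duration=30000)
        aed = AEDRecord(times_h=[(600 + 100 * 60) / 3600.0])
        tab = aed_support(aed, ref, evlist([], 30000))
        assert not bool(tab.concurrent.iloc[0])

    def test_boundary_touch_is_concurrent(self):
        ref = evlist([(0, 600)], duration=30000)
        aed = AEDRecord(times_h=[(600 + 90 * 60) / 3600.0])  # exactly 90 min
        tab = aed_support(aed, ref, evlist([], 30000))
        assert bool(tab.concurrent.iloc[0])

    def test_dose_outside_recording_excluded(self):
        ref = evlist([(0, 600)], duration=3600)
        aed = AEDRecord(times_h=[5.0])  # 5 h postnatal, record is 1 h from 0
        tab = aed_support(aed, ref, evlist([], 3600), start_age_h=0.0)
        assert len(tab) == 0
        assert tab.attrs["excluded_doses_h"] == [5.0]
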