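"""Clinical splitting, alarm streams, and event-based metrics."""

import numpy as np
import pytest

from seizalign import (LabeledWindow, WindowSet, clinical_split,
                       event_metrics, score_stream, window_auc)
from seizalign.labeling import EXCLUDED, INTERICTAL, PREICTAL


def toy_window_set(patient_id, n_seizures, pre_per_seizure=4, n_inter=20,
                   n_samples=64):
    """Hand-built WindowSet: seizure k's preictal block starts at
    k*1000 s, interictal windows fill the gaps."""
    rng = np.random.default_rng(hash(patient_id) % 2 ** 31)
    windows, intervals = [], []
    t = 0.0
    for k in range(n_seizures):
        base = 1000.0 * (k + 1)
        intervals.append((base - 5.0 * pre_per_seizure, base, PREICTAL))
        intervals.append((base, base + 100.0, EXCLUDED))
        for i in range(pre_per_seizure):
            windows.append(LabeledWindow(
                data=rng.standard_normal((1, n_samples)), label=1,
                patient_id=patient_id,
                t_start_s=base - 5.0 * (pre_per_seizure - i),
                seizure_index=k))
    for i in range(n_inter):
        windows.append(LabeledWindow(
            data=rng.standard_normal((1, n_samples)), label=0,
            patient_id=patient_id, t_start_s=5.0 * i + 0.5))
    windows.sort(key=lambda w: w.t_start_s)
    return WindowSet(windows=windows, rate=12.8, patient_id=patient_id,
                     intervals=intervals)


@pytest.fixture
def cohort():
    return {p: toy_window_set(p, n_seizures=4) for p in ("a", "b", "c")}


class TestClinicalSplit:
    def test_target_with_four_seizures_gives_three_test_seizures(self, cohort):
        plan = clinical_split(cohort, "a")
        tws = cohort["a"]
        test_seiz = {tws.windows[i].seizure_index
                     for _, i in plan.test_windows
                     if tws.windows[i].seizure_index is not None}
        assert len(test_seiz) == 3
        assert plan.included_target_seizure == 0      # chronologically first

    def test_no_leakage_and_no_foreign_test_windows(self, cohort):
        plan = clinical_split(cohort, "b")
        pool = set(plan.train_windows) | set(plan.val_windows)
        assert not pool & set(plan.test_windows)
        assert all(pid == "b" for pid, _ in plan.test_windows)

    def test_matched_interictal_count_equals_preictal(self, cohort):
        plan = clinical_split(cohort, "a")
        tws = cohort["a"]
        target_pool = [i for pid, i in
                       list(plan.train_windows) + list(plan.val_windows)
                       if pid == "a"]
        pre = [i for i in target_pool if tws.windows[i].label == 1]
        inter = [i for i in target_pool if tws.windows[i].label == 0]
        assert len(pre) == len(inter) == 4

    def test_fold_sizes_are_80_20(self, cohort):
        plan = clinical_split(cohort, "a")
        for k in range(5):
            tr, val = plan.fold(k)
            total = len(tr) + len(val)
            assert len(val) == pytest.approx(total / 5, abs=1)

    def test_reproducible_from_seed(self, cohort):
        p1 = clinical_split(cohort, "a", seed=3)
        p2 = clinical_split(cohort, "a", seed=3)
        assert p1.fold_assignments == p2.fold_assignments

    def test_single_patient_cohort_warns(self, caplog):
        coh = {"solo": toy_window_set("solo", n_seizures=2)}
        with caplog.at_level("WARNING"):
            plan = clinical_split(coh, "solo")
        assert "single-patient" in caplog.text
        assert plan.test_windows

    def test_too_few_seizures_rejected(self):
        coh = {"x": toy_window_set("x", n_seizures=1),
               "y": toy_window_set("y", n_seizures=4)}
        with pytest.raises(ValueError, match=">= 2"):
            clinical_split(coh, "x")

    def test_seizure_choice_by_index(self, cohort):
        plan = clinical_split(cohort, "a", seizure_choice=2)
        assert plan.included_target_seizure == 2


class TestScoreStream:
    def test_merge_within_refractory(self):
        alarms = score_stream([0.0, 5.0, 10.0], [1, 1, 1],
                              refractory_s=1800.0)
        assert alarms == [0.0]

    def test_no_positives_empty(self):
        assert score_stream([0.0, 5.0], [0, 0]) == []

    def test_boundary_spacing_two_alarms(self):
        alarms = score_stream([0.0, 2000.0], [1, 1], refractory_s=1800.0)
        assert alarms == [0.0, 2000.0]

    def test_strict_mode_every_window(self):
        alarms = score_stream([0.0, 5.0, 10.0], [1, 0, 1], refractory_s=0.0)
        assert alarms == [0.0, 10.0]

    def test_unordered_input_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            score_stream([5.0, 0.0], [1, 1])


class TestEventMetrics:
    def test_handcrafted_stream_exact(self):
        """4 seizures, alarms in 2 preictal horizons, 3 false alarms over
        10 interictal hours -> sensitivity 0.5, FPR 0.3/h."""
        pre = [(1800, 3600), (7200, 9000), (12600, 14400), (18000, 19800)]
        alarms = [2000.0, 8000.0,            # hits in seizures 1 and 2
                  100.0, 5000.0, 11000.0]    # false alarms
        rep = event_metrics(alarms, pre, interictal_hours=10.0)
        assert rep.sensitivity == 0.5
        assert rep.fpr_per_h == pytest.approx(0.3)
        assert rep.n_test_seizures == 4

    def test_alarm_latency_measured_from_onset(self):
        rep = event_metrics([2000.0], [(1800, 3600)], interictal_hours=1.0)
        assert rep.latencies_s == [1600.0]

    def test_zero_interictal_hours_fpr_missing(self):
        rep = event_metrics([], [(0, 10)], interictal_hours=0.0)
        assert rep.fpr_per_h is None

    def test_perfect_scores_auc_one(self, rng):
        scores = np.r_[rng.uniform(1, 2, 50), rng.uniform(-2, -1, 50)]
        labels = np.r_[np.ones(50), np.zeros(50)].astype(int)
        rep = event_metrics([], [], interictal_hours=1.0,
                            scores=scores, labels=labels)
        assert rep.auc == 1.0

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(20):
            scores = rng.standard_normal(2000)
            labels = np.r_[np.ones(1000), np.zeros(1000)].astype(int)
            aucs.append(window_auc(scores, labels))
        assert all(0.45 < a < 0.55 for a in aucs)

    def test_rank_auc_equals_pairwise_brute_force(self, rng):
        scores = np.round(rng.standard_normal(300), 1)    # induce ties
        labels = rng.integers(0, 2, 300)
        if labels.sum() in (0, 300):
            labels[0] = 1 - labels[0]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        brute = wins / (len(pos) * len(neg))
        assert window_auc(scores, labels) == pytest.approx(brute, abs=1e-12)


class TestLoocvStructure:
    def test_rows_and_average(self, cohort):
        from seizalign import AaeParams, StftConfig, loocv_sweep
        stft_cfg = StftConfig(frame_len=32, hop=16, standardize=True)
        params = AaeParams(latent_dim=4, encoder_widths=(8,),
                           disc_widths=(4,), epochs=2, batch_per_domain=4,
                           seed=0, lambdas=(0.01, 0.5, 0.5))
        df = loocv_sweep(cohort, stft_cfg, params, seed=0)
        assert list(df["target"]) == ["a", "b", "c", "Avg."]
        avg = df[df.target == "Avg."].iloc[0]
        per = df[df.target != "Avg."]
        assert avg["auc"] == pytest.approx(per["auc"].mean())

    def test_reproducible(self, cohort):
        from seizalign import AaeParams, StftConfig, loocv_sweep
        stft_cfg = StftConfig(frame_len=32, hop=16)
        params = AaeParams(latent_dim=4, encoder_widths=(8,),
                           disc_widths=(4,), epochs=2, batch_per_domain=4,
                           seed=0, lambdas=(0.01, 0.5, 0.5))
        df1 = loocv_sweep(cohort, stft_cfg, params, seed=0)
        df2 = loocv_sweep(cohort, stft_cfg, params, seed=0)
        assert df1.equals(df2)
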