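"""Confusion metrics, threshold/window optimization and cross-validation."""

import numpy as np
import pytest

from mandown.errors import DegenerateLabelsError, MandownError, UndefinedRateError
from mandown.training_eval import (
    ConfusionCounts,
    confusion_metrics,
    kfold_cv,
    optimize_threshold,
    optimize_window,
    scenario_confusion,
    train_detector_bank,
    train_down_threshold,
)


class TestConfusionMetrics:
    @pytest.mark.parametrize("tp,fp,p,n,pd,pfa,mcc,acc", [
        # physical-test worked examples: (counts) -> printed rates
        (17, 0, 24, 92, 0.708, 0.0, 0.811, 0.940),
        (18, 0, 24, 92, 0.750, 0.0, 0.839, 0.948),
        (25, 2, 37, 92, 0.676, 0.022, 0.727, 0.891),
        (30, 2, 37, 92, 0.811, 0.022, 0.826, 0.930),
    ])
    def test_worked_examples_to_three_decimals(self, tp, fp, p, n,
                                               pd, pfa, mcc, acc):
        c = ConfusionCounts(tp=tp, fp=fp, tn=n - fp, fn=p - tp)
        got_pd, got_pfa, got_acc, got_mcc = confusion_metrics(c)
        assert round(got_pd, 3) == pd
        assert round(got_pfa, 3) == pfa
        assert round(got_mcc, 3) == mcc
        assert round(got_acc, 3) == acc

    def test_perfect_classifier(self):
        c = ConfusionCounts(tp=10, fp=0, tn=20, fn=0)
        assert confusion_metrics(c) == (1.0, 0.0, 1.0, 1.0)

    def test_accuracy_one_iff_no_errors(self):
        assert ConfusionCounts(5, 0, 5, 0).accuracy == 1.0
        assert ConfusionCounts(5, 1, 4, 0).accuracy < 1.0

    def test_mcc_zero_on_any_zero_denominator_factor(self):
        assert ConfusionCounts(tp=0, fp=0, tn=5, fn=5).mcc == 0.0
        assert ConfusionCounts(tp=5, fp=5, tn=0, fn=0).mcc == 0.0

    def test_undefined_rates_raise(self):
        with pytest.raises(UndefinedRateError):
            _ = ConfusionCounts(tp=0, fp=1, tn=1, fn=0).pd
        with pytest.raises(UndefinedRateError):
            _ = ConfusionCounts(tp=1, fp=0, tn=0, fn=1).pfa

    def test_mcc_is_pearson_of_binary_vectors(self, rng):
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(0, 20, size=4)
            c = ConfusionCounts(int(tp), int(fp), int(tn), int(fn))
            v = np.r_[np.ones(tp), np.ones(fp), np.zeros(tn), np.zeros(fn)]
            y = np.r_[np.ones(tp), np.zeros(fp), np.zeros(tn), np.ones(fn)]
            if v.std() == 0 or y.std() == 0:
                assert c.mcc == 0.0
            else:
                assert c.mcc == pytest.approx(np.corrcoef(v, y)[0, 1],
                                              abs=1e-12)

    def test_mcc_bounds(self, rng):
        for _ in range(100):
            tp, fp, tn, fn = (int(v) for v in rng.integers(0, 30, 4))
            if tp + fp + tn + fn == 0:
                continue
            assert -1.0 <= ConfusionCounts(tp, fp, tn, fn).mcc <= 1.0


class TestScenarioConfusion:
    def test_all_correct(self):
        c = scenario_confusion([True] * 5 + [False] * 5,
                               [True] * 5 + [False] * 5)
        assert (c.tp, c.tn, c.fp, c.fn) == (5, 5, 0, 0)

    def test_inverted_labels_anticorrelate(self):
        c = scenario_confusion([True] * 5 + [False] * 5,
                               [False] * 5 + [True] * 5)
        assert c.mcc == -1.0

    def test_keyed_verdicts_align_by_id(self):
        c = scenario_confusion({"a": True, "b": False},
                               {"b": False, "a": True})
        assert (c.tp, c.tn) == (1, 1)

    def test_id_mismatch_rejected(self):
        with pytest.raises(MandownError, match="ids do not match"):
            scenario_confusion({"a": True}, {"b": True})

    def test_permutation_null_mcc_near_zero(self, rng):
        reps, n = 10_000, 20
        total = 0.0
        for _ in range(reps):
            v = rng.random(n) < 0.5
            y = rng.random(n) < 0.5
            total += scenario_confusion(v, y).mcc
        se = 1.0 / np.sqrt((n - 1) * reps)
        assert abs(total / reps) < 3 * se + 1e-3


class TestOptimizeThreshold:
    def test_separable_classes(self):
        scores = np.array([0.1, 0.2, 0.15, 0.8, 0.9, 0.85])
        labels = np.array([False, False, False, True, True, True])
        gamma, mcc = optimize_threshold(scores, labels)
        assert mcc == 1.0
        assert 0.2 < gamma < 0.8

    def test_matches_exhaustive_fine_grid(self, rng):
        for _ in range(30):
            n = int(rng.integers(8, 30))
            scores = rng.random(n)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            gamma, mcc = optimize_threshold(scores, labels)
            fine = np.linspace(scores.min() - 0.1, scores.max() + 0.1, 2000)
            best = max(scenario_confusion(scores > g, labels).mcc
                       for g in fine)
            assert mcc == pytest.approx(best, abs=1e-12)

    def test_invariant_to_duplicating_recordings(self, rng):
        scores = rng.random(12)
        labels = np.arange(12) < 5
        g1, m1 = optimize_threshold(scores, labels)
        g2, m2 = optimize_threshold(np.r_[scores, scores],
                                    np.r_[labels, labels])
        assert g1 == g2 and m1 == pytest.approx(m2, abs=1e-12)

    def test_shuffled_labels_yield_low_mcc(self):
        total = 0.0
        reps = 20
        for seed in range(reps):
            r = np.random.default_rng(seed)
            scores = r.random(200)
            labels = r.permutation(np.arange(200) < 100)
            _, mcc = optimize_threshold(scores, labels)
            total += mcc
        assert total / reps < 0.25

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            optimize_threshold([0.1, 0.2], [True, True])


class TestDownThreshold:
    def test_quantile_rule_meets_pd_target(self, rng):
        peaks = rng.uniform(1.2, 1.6, 100)
        gamma = train_down_threshold(peaks, pd_target=0.99)
        assert np.mean(peaks > gamma) >= 0.99

    def test_small_sample_detects_everything(self):
        peaks = [1.3, 1.4, 1.5]
        gamma = train_down_threshold(peaks)
        assert all(p > gamma for p in peaks)


class TestTrainingAndCv:
    def test_training_is_deterministic(self, small_corpus):
        recs, _ = small_corpus
        b1, _ = train_detector_bank(recs)
        b2, _ = train_detector_bank(recs)
        assert b1.to_dict() == b2.to_dict()

    def test_cv_same_seed_same_result(self, small_corpus):
        recs, _ = small_corpus
        r1 = kfold_cv(recs, k=3, seed=5)
        r2 = kfold_cv(recs, k=3, seed=5)
        assert r1.per_fold.equals(r2.per_fold)

    def test_cv_duplicated_recordings_zero_sd(self):
        """Duplicating every recording across folds makes all folds train
        and test on identical material, so across-fold SD collapses."""
        from mandown.synthetic_data import ScenarioSpec, generate

        sources = [
            generate(ScenarioSpec("fall_forward", post_fall="lie",
                                  seed=s, fs=100.0)) for s in (1, 2)
        ] + [generate(ScenarioSpec("walk", seed=s, fs=100.0)) for s in (3, 4)]
        recs = []
        for j, src in enumerate(sources):
            for copy_i in range(3):
                r = src.copy()
                # one stratum per source: each fold holds exactly one copy
                r.label = f"{src.label}#{j}"
                r.rec_id = f"r{j}_{copy_i}"
                recs.append(r)
        result = kfold_cv(recs, k=3, seed=0)
        sd_cols = [c for c in result.summary.columns if c.endswith("_sd")]
        assert np.allclose(result.summary.loc["MDS", sd_cols].astype(float),
                           0.0)

    def test_cv_detects_mds_on_small_corpus(self, small_corpus):
        recs, _ = small_corpus
        # at this miniature scale (8 training positives per fold) the
        # fitted models are coarse; the full-scale behaviour is exercised
        # by the acceptance suite
        result = kfold_cv(recs, k=3, seed=11)
        assert result.mean("MDS", "pd") >= 0.7
        assert result.mean("MDS", "pfa") <= 0.1

    def test_optimize_window_single_candidate(self, small_corpus):
        recs, _ = small_corpus
        tau, mcc = optimize_window(recs, "D", 0, [4500.0])
        assert tau == 4500.0
        assert -1.0 <= mcc <= 1.0

    def test_optimize_window_matches_exhaustive_loop(self, small_corpus):
        recs, _ = small_corpus
        candidates = [2000.0, 4500.0]
        tau, mcc = optimize_window(recs, "D", 0, candidates)
        per_tau = {}
        for c in candidates:
            _, m = optimize_window(recs, "D", 0, [c])
            per_tau[c] = m
        best = max(per_tau.values())
        assert mcc == pytest.approx(best, abs=1e-12)
        assert per_tau[tau] == pytest.approx(best, abs=1e-12)
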