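"""Fold construction, metric panel, confusion and time-resolved accuracy."""

import numpy as np
import pandas as pd
import pytest

from moztrack.evaluation import (
    LeakageError,
    assert_trial_disjoint,
    compute_metrics,
    confusion_normalized,
    generate_folds,
    grid_search,
    mean_confusion,
    summarize_metric_panels,
    time_resolved_accuracy,
)
from oracles import naive_metric_panel


def meta_frame(spec):
    """spec: list of (strain, net, count)."""
    rows = []
    for strain, net, count in spec:
        for i in range(count):
            rows.append(
                {
                    "trial_id": f"{strain}_{net}{i}",
                    "net_type": net,
                    "strain": strain,
                    "resistance": "IS" if strain in ("Kisumu", "NGousso") else "IR",
                }
            )
    return pd.DataFrame(rows)


class TestGenerateFolds:
    def test_single_possible_combination_caps_folds(self):
        meta = meta_frame([(s, "UT", 1) for s in ("Kisumu", "NGousso", "VK7", "Banfora")]
                          + [(s, "OL", 2) for s in ("Kisumu", "NGousso", "VK7", "Banfora")])
        folds = generate_folds(meta, n_folds=5, n_train=0, n_test=12, per_strain=True)
        assert len(folds) == 1

    def test_combinatorial_count_of_balanced_test_sets(self):
        # per strain: 1 UT of 1, 2 OL of 3 -> 3 ways each -> 3^4 = 81 sets
        meta = meta_frame([(s, "UT", 1) for s in ("Kisumu", "NGousso", "VK7", "Banfora")]
                          + [(s, "OL", 3) for s in ("Kisumu", "NGousso", "VK7", "Banfora")])
        folds = generate_folds(meta, n_folds=81, n_train=0, n_test=12, per_strain=True)
        assert len(folds) == 81
        assert len({f.test_trials for f in folds}) == 81

    def test_surplus_ut_slots_dropped_to_n_test(self):
        meta = meta_frame([(s, "UT", 2) for s in ("Kisumu", "NGousso", "VK7", "Banfora")]
                          + [(s, "OL", 3) for s in ("Kisumu", "NGousso", "VK7", "Banfora")])
        folds = generate_folds(meta, n_folds=10, n_train=8, n_test=9, per_strain=True)
        for f in folds:
            assert len(f.test_trials) == 9
            ol = [t for t in f.test_trials if "_OL" in t]
            assert len(ol) == 8  # all OL slots kept, UT shed

    def test_train_test_disjoint_and_two_class(self):
        meta = meta_frame([("Kisumu", "UT", 4), ("VK7", "UT", 4),
                           ("Kisumu", "OL", 4), ("VK7", "OL", 4)])
        folds = generate_folds(meta, n_folds=20, n_train=12, n_test=4,
                               per_strain=False, test_n_ut=2, test_n_ol=2)
        for f in folds:
            assert not set(f.train_trials) & set(f.test_trials)

    def test_unsatisfiable_composition_names_cell(self):
        meta = meta_frame([("Kisumu", "UT", 1), ("Kisumu", "OL", 1)])
        with pytest.raises(ValueError, match="Kisumu"):
            generate_folds(meta, per_strain=True, test_ol_per_strain=2)

    def test_reproducible_under_seed(self):
        meta = meta_frame([("Kisumu", "UT", 4), ("VK7", "OL", 4),
                           ("NGousso", "UT", 2), ("Banfora", "OL", 2)])
        a = generate_folds(meta, n_folds=5, n_train=6, n_test=2, seed=3,
                           per_strain=False, test_n_ut=1, test_n_ol=1)
        b = generate_folds(meta, n_folds=5, n_train=6, n_test=2, seed=3,
                           per_strain=False, test_n_ut=1, test_n_ol=1)
        assert [f.test_trials for f in a] == [f.test_trials for f in b]


class TestMetrics:
    def test_closed_form_balanced_accuracy(self):
        y_true = np.array(["OL"] * 10 + ["UT"] * 10)
        y_call = np.array(["OL"] * 8 + ["UT"] * 2 + ["UT"] * 9 + ["OL"] * 1)
        scores = np.where(y_call == "OL", 0.9, 0.1)
        panel = compute_metrics(y_true, y_call, scores)
        assert panel["balanced_accuracy"] == pytest.approx(0.85)

    def test_perfect_predictions(self):
        y = np.array(["OL", "UT", "OL", "UT"])
        scores = np.array([1.0, 0.0, 1.0, 0.0])
        panel = compute_metrics(y, y, scores)
        assert panel["log_loss"] == pytest.approx(0.0, abs=1e-12)
        for k in ("mcc", "cohen_kappa", "roc_auc", "pr_auc_OL", "pr_auc_UT"):
            assert panel[k] == pytest.approx(1.0)

    def test_degenerate_all_positive_predictor(self):
        y_true = np.array(["OL"] * 5 + ["UT"] * 15)
        y_call = np.array(["OL"] * 20)
        panel = compute_metrics(y_true, y_call, np.full(20, 0.8))
        assert panel["recall_OL"] == 1.0
        assert panel["balanced_accuracy"] == pytest.approx(0.5)

    def test_matches_naive_panel(self, rng):
        for _ in range(30):
            n = 40
            y_true = np.where(rng.random(n) < 0.4, "OL", "UT")
            if len(set(y_true)) < 2:
                continue
            y_call = np.where(rng.random(n) < 0.5, "OL", "UT")
            scores = rng.uniform(0.02, 0.98, n)
            panel = compute_metrics(y_true, y_call, scores)
            ref = naive_metric_panel(list(y_true), list(y_call), list(scores))
            for k, v in ref.items():
                assert panel[k] == pytest.approx(v, rel=1e-9, abs=1e-12), k

    def test_summary_mean_min_max(self):
        panels = [{"m": 0.2}, {"m": 0.8}, {"m": 0.5}]
        s = summarize_metric_panels(panels)
        assert s.loc["m", "mean"] == pytest.approx(0.5)
        assert s.loc["m", "min"] == pytest.approx(0.2)
        assert s.loc["m", "max"] == pytest.approx(0.8)


class TestConfusion:
    def test_perfect_classifier_is_identity(self):
        y = ["UT", "OL", "UT", "OL"]
        conf = confusion_normalized(y, y)
        np.testing.assert_allclose(conf.to_numpy(), np.eye(2))

    def test_rows_sum_to_one(self, rng):
        y_true = np.where(rng.random(100) < 0.3, "OL", "UT")
        y_call = np.where(rng.random(100) < 0.6, "OL", "UT")
        conf = confusion_normalized(y_true, y_call)
        np.testing.assert_allclose(conf.sum(axis=1), 1.0)

    def test_coin_flip_rows_near_half(self, rng):
        n = 4000
        y_true = np.repeat(["UT", "OL"], n // 2)
        y_call = np.where(rng.random(n) < 0.5, "OL", "UT")
        conf = confusion_normalized(y_true, y_call)
        assert np.abs(conf.to_numpy() - 0.5).max() < 3 * np.sqrt(0.25 / (n / 2))

    def test_fold_averaging(self):
        a = confusion_normalized(["UT", "OL"], ["UT", "OL"])
        b = confusion_normalized(["UT", "OL"], ["OL", "UT"])
        m = mean_confusion([a, b])
        np.testing.assert_allclose(m.to_numpy(), 0.5)


class TestTimeResolved:
    def preds(self, starts, correct, strain="Kisumu"):
        starts = np.asarray(starts, dtype=float)
        y = np.where(np.asarray(correct), "OL", "UT")
        return pd.DataFrame(
            {
                "start_s": starts,
                "net_type": ["OL"] * len(starts),
                "track_call": y,
                "strain": [strain] * len(starts),
            }
        )

    def test_half_open_bins(self):
        out = time_resolved_accuracy([self.preds([304.9], [True])], 300.0, 1200.0)
        bins = out["bins"]
        assert bins.loc[bins["bin_start_s"] == 300.0, "n_tracks"].iloc[0] == 1
        assert bins.loc[bins["bin_start_s"] == 0.0, "n_tracks"].iloc[0] == 0

    def test_all_correct_gives_unit_accuracy(self):
        out = time_resolved_accuracy(
            [self.preds([10, 400, 700], [True, True, True])], 300.0, 900.0
        )
        got = out["bins"]["mean_accuracy"].dropna()
        np.testing.assert_allclose(got, 1.0)

    def test_empty_bins_reported_missing_not_zero(self):
        out = time_resolved_accuracy([self.preds([10.0], [False])], 300.0, 1200.0)
        bins = out["bins"].set_index("bin_start_s")
        assert bins.loc[0.0, "mean_accuracy"] == 0.0
        assert np.isnan(bins.loc[600.0, "mean_accuracy"])
        assert bins.loc[600.0, "n_tracks"] == 0

    def test_before_after_panel(self):
        out = time_resolved_accuracy(
            [self.preds([100, 200, 2000], [True, False, True])], 300.0, 3600.0
        )
        ba = out["before_after"].set_index("period")
        assert ba.loc["before_30min", "mean_accuracy"] == pytest.approx(0.5)
        assert ba.loc["after_30min", "mean_accuracy"] == pytest.approx(1.0)


class TestLeakageGuards:
    def test_overlap_raises(self):
        with pytest.raises(LeakageError, match="T1"):
            assert_trial_disjoint(["T1", "T2"], ["T1"], "unit")

    def test_disjoint_passes(self):
        assert_trial_disjoint(["T1"], ["T2"], "unit")


class TestGridSearch:
    def test_single_point_grid_returns_it(self, rng):
        from moztrack.synthio import contrast_study, study_metadata, study_tracks

        study = contrast_study(n_per_arm=4, seed=4, tracks_per_trial=5)
        tracks, meta = study_tracks(study), study_metadata(study)
        best, table = grid_search(
            tracks, meta, [7.5], [7.0], seed=0, n_folds=2,
            strategy="comprehensive",
        )
        assert best["window_s"] == 7.5 and best["overlap_s"] == 7.0
        assert len(table) == 1
        assert np.isfinite(best["balanced_accuracy"])

    def test_invalid_overlap_points_skipped(self, rng):
        from moztrack.synthio import contrast_study, study_metadata, study_tracks

        study = contrast_study(n_per_arm=4, seed=4, tracks_per_trial=5)
        tracks, meta = study_tracks(study), study_metadata(study)
        best, table = grid_search(
            tracks, meta, [7.5], [7.0, 8.0], seed=0, n_folds=2,
            strategy="comprehensive",
        )
        assert len(table) == 1  # overlap 8.0 > window skipped
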