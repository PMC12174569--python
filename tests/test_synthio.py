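"""Simulator contracts: determinism, censoring, containment, behaviour knobs."""

import numpy as np
import pytest

from moztrack import synthio
from moztrack.features import kinematic_series, zero_crossings
from moztrack.synthio import (
    OL_PARAMS,
    UT_PARAMS,
    BehaviourParams,
    GapLaw,
    TrialSpec,
    contrast_study,
    drop_samples,
    inject_gaps,
    simulate_study,
    simulate_track,
    simulate_trial,
    study_metadata,
    study_tracks,
)

ARENA = (1200.0, 1000.0)


def quiet_params(**kw):
    base = dict(
        mean_speed=400.0, speed_sd=50.0, turn_concentration=4.0,
        reversal_rate=0.0, pause_prob=0.0, variability=0.0,
        speed_variability=0.0, saccade_prob=0.0,
    )
    base.update(kw)
    return BehaviourParams(**base)


class TestBehaviourParams:
    @pytest.mark.parametrize(
        "kw",
        [
            {"mean_speed": -1.0},
            {"mean_speed": float("nan")},
            {"speed_sd": -5.0},
            {"turn_concentration": -0.1},
            {"reversal_rate": float("inf")},
            {"pause_prob": 1.5},
            {"variability": -1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            quiet_params(**kw)

    def test_jitter_is_deterministic_and_validated(self):
        p = quiet_params(variability=0.4)
        a = p.jitter(np.random.default_rng(7))
        b = p.jitter(np.random.default_rng(7))
        assert a == b
        assert a.variability == 0.0


class TestSimulateTrack:
    def test_noise_free_limit_is_perfectly_straight(self):
        p = quiet_params(turn_concentration=float("inf"), speed_sd=0.0, mean_speed=100.0)
        tr = simulate_track(p, 2.0, 50.0, (10_000.0, 10_000.0), seed=3)
        steps = np.hypot(np.diff(tr.x), np.diff(tr.y))
        net = np.hypot(tr.x[-1] - tr.x[0], tr.y[-1] - tr.y[0])
        assert net / steps.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_speed_means_zero_path(self):
        p = quiet_params(mean_speed=0.0, speed_sd=0.0)
        tr = simulate_track(p, 1.0, 50.0, ARENA, seed=1)
        assert np.hypot(np.diff(tr.x), np.diff(tr.y)).sum() == 0.0

    def test_higher_concentration_means_smaller_angle_changes(self):
        means = {}
        for kappa in (1.0, 10.0):
            vals = []
            for seed in range(120):
                tr = simulate_track(quiet_params(turn_concentration=kappa), 4.0,
                                    50.0, ARENA, seed=seed)
                ks = kinematic_series(tr.x, tr.y, tr.real, 50.0)
                vals.append(ks.angle_change.mean())
            means[kappa] = np.mean(vals)
        assert means[10.0] < means[1.0]

    def test_reversal_rate_increases_vx_sign_changes(self):
        # one-sided Monte-Carlo comparison over >= 100 tracks per rate
        def crossings_per_second(rate, seed):
            tr = simulate_track(quiet_params(reversal_rate=rate), 4.0, 50.0,
                                ARENA, seed=seed)
            ks = kinematic_series(tr.x, tr.y, tr.real, 50.0)
            return zero_crossings(ks.vx, signed=True, mask=ks.valid_v) / 4.0

        low = [crossings_per_second(0.5, s) for s in range(120)]
        high = [crossings_per_second(5.0, s + 1000) for s in range(120)]
        from scipy.stats import mannwhitneyu

        p = mannwhitneyu(high, low, alternative="greater").pvalue
        assert p < 0.01

    def test_arena_containment(self):
        tr = simulate_track(OL_PARAMS, 30.0, 50.0, (100.0, 80.0), seed=11)
        assert tr.x.min() >= 0 and tr.x.max() <= 100.0
        assert tr.y.min() >= 0 and tr.y.max() <= 80.0

    def test_determinism(self):
        a = simulate_track(UT_PARAMS, 5.0, 50.0, ARENA, seed=42)
        b = simulate_track(UT_PARAMS, 5.0, 50.0, ARENA, seed=42)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)

    def test_pause_frames_have_zero_displacement(self):
        p = quiet_params(pause_prob=0.3, pause_mean_frames=4.0)
        tr = simulate_track(p, 20.0, 50.0, ARENA, seed=5)
        steps = np.hypot(np.diff(tr.x), np.diff(tr.y))
        frac = np.mean(steps == 0.0)
        assert 0.15 < frac < 0.45


class TestInjectGaps:
    def test_zero_dropout_is_identity(self):
        tr = simulate_track(UT_PARAMS, 2.0, 50.0, ARENA, seed=0)
        assert inject_gaps(tr, GapLaw(0.0, 3), seed=1) is tr

    def test_forced_run_removal(self):
        tr = simulate_track(UT_PARAMS, 2.0, 50.0, ARENA, seed=0)  # 101 samples
        out = drop_samples(tr, np.arange(10, 15))
        assert out.n_samples == 96
        gap_pos = np.where(np.diff(out.frames) == 6)[0]
        assert list(out.frames[gap_pos]) == [9]

    def test_endpoints_never_removed_and_monotone(self):
        tr = simulate_track(UT_PARAMS, 10.0, 50.0, ARENA, seed=2)
        out = inject_gaps(tr, GapLaw(0.4, 5), seed=3)
        assert out.frames[0] == tr.frames[0] and out.frames[-1] == tr.frames[-1]
        assert np.all(np.diff(out.frames) > 0)

    def test_removed_fraction_matches_nominal_rate(self):
        tr = simulate_track(UT_PARAMS, 200.0, 50.0, ARENA, seed=4)  # 10001 samples
        out = inject_gaps(tr, GapLaw(0.1, 3), seed=5)
        removed = 1.0 - out.n_samples / tr.n_samples
        n = tr.n_samples
        half_width = 2.576 * np.sqrt(0.1 * 0.9 / n)
        assert abs(removed - 0.1) < half_width

    def test_invalid_gap_law_rejected(self):
        with pytest.raises(ValueError):
            GapLaw(1.0, 3)
        with pytest.raises(ValueError):
            GapLaw(0.1, 0)


class TestSimulateTrial:
    def spec(self, **kw):
        base = dict(trial_id="T", net_type="OL", strain="Kisumu", resistance="IS",
                    n_mosquitoes=25, duration_s=3600.0, tracks_per_mosquito=1.0,
                    seed=9)
        base.update(kw)
        return TrialSpec(**base)

    def test_mortality_cutoff_censors_starts(self):
        spec = self.spec(mortality_cutoff_s=1800.0, duration_s=7200.0)
        tracks = simulate_trial(spec, UT_PARAMS, OL_PARAMS)
        assert all(t.t[0] <= 1800.0 for t in tracks)
        assert all(t.t[-1] <= 1800.0 + 1e-9 for t in tracks)

    def test_one_track_per_mosquito_without_censoring(self):
        spec = self.spec(net_type="UT", resistance="IR", mortality_cutoff_s=None)
        tracks = simulate_trial(spec, UT_PARAMS, OL_PARAMS)
        assert len(tracks) == 25
        assert len({t.track_id for t in tracks}) == 25

    def test_determinism(self):
        spec = self.spec()
        a = simulate_trial(spec, UT_PARAMS, OL_PARAMS)
        b = simulate_trial(spec, UT_PARAMS, OL_PARAMS)
        assert len(a) == len(b)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.x, tb.x)
            assert np.array_equal(ta.frames, tb.frames)

    def test_cutoff_beyond_duration_rejected(self):
        with pytest.raises(ValueError):
            self.spec(mortality_cutoff_s=7200.0, duration_s=3600.0)

    def test_min_track_duration_at_least_one_second(self):
        spec = self.spec(n_mosquitoes=40)
        tracks = simulate_trial(spec, UT_PARAMS, OL_PARAMS)
        assert all(t.duration_s >= 1.0 - 1e-9 for t in tracks)


class TestSimulateStudy:
    def test_trial_counts_match_study_design(self):
        study = simulate_study(17, 23, seed=0, n_mosquitoes=1, duration_s=60.0)
        assert len(study) == 40
        meta = study_metadata(study)
        assert (meta["net_type"] == "UT").sum() == 17
        assert (meta["net_type"] == "OL").sum() == 23

    def test_two_trial_study_labels(self):
        study = simulate_study(1, 1, seed=0, n_mosquitoes=1, duration_s=60.0)
        meta = study_metadata(study)
        assert sorted(meta["net_type"]) == ["OL", "UT"]
        assert set(meta["resistance"]) <= {"IS", "IR"}

    def test_reproducible_under_master_seed(self):
        a = simulate_study(2, 2, seed=5, n_mosquitoes=2, duration_s=120.0)
        b = simulate_study(2, 2, seed=5, n_mosquitoes=2, duration_s=120.0)
        for (sa, tra), (sb, trb) in zip(a, b):
            assert sa == sb
            for x, y in zip(tra, trb):
                assert np.array_equal(x.x, y.x)

    def test_balance_check_rejects_missing_cell(self):
        with pytest.raises(ValueError, match="condition cell"):
            simulate_study(1, 1, strain_plan=["Kisumu"], seed=0,
                           require_balance=True, n_mosquitoes=1, duration_s=60.0)

    def test_is_ol_trials_are_censored(self):
        study = contrast_study(n_per_arm=4, seed=3)
        for spec, tracks in study:
            if spec.net_type == "OL" and spec.resistance == "IS":
                assert spec.mortality_cutoff_s == 1800.0
                assert all(t.t[0] <= 1800.0 for t in tracks)
            else:
                assert spec.mortality_cutoff_s is None

    def test_study_tracks_flattens(self):
        study = simulate_study(1, 1, seed=1, n_mosquitoes=2, duration_s=120.0)
        assert len(study_tracks(study)) == sum(len(tr) for _, tr in study)
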