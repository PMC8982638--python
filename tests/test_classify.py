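"""Feature computation, windowing, training, prediction and cross-validation."""

import numpy as np
import pandas as pd
import pytest

import mbassay as mb
from mbassay.classify import _binary_median_smooth, _end_minus_start
from mbassay.labels import UNANNOTATED, LabelSeries
from mbassay.tracking import ArenaGeometry, empty_track


def make_track(xy, fps=25.0):
    t = empty_track(len(xy), fps)
    t["x_px"] = [p[0] for p in xy]
    t["y_px"] = [p[1] for p in xy]
    t["major_px"] = 20.0
    t["minor_px"] = 10.0
    t["theta_rad"] = 0.0
    t["valid"] = True
    return t


ARENA = ArenaGeometry.from_rect(266, 425)


class TestFrameFeatures:
    def test_stationary_track_zero_speed(self):
        feats = mb.compute_frame_features(make_track([(50, 50)] * 10), ARENA)
        assert np.allclose(feats.speed_px_s, 0.0)

    def test_straight_line_speed(self):
        xy = [(10 + 10 * i, 50) for i in range(20)]
        feats = mb.compute_frame_features(make_track(xy), ARENA)
        assert np.allclose(feats.speed_px_s, 250.0)  # 10 px/frame at 25 fps

    def test_speed_matches_finite_difference_oracle(self, rng):
        xy = list(zip(50 + rng.normal(0, 5, 30), 60 + rng.normal(0, 5, 30)))
        track = make_track(xy)
        feats = mb.compute_frame_features(track, ARENA)
        x = track.x_px.to_numpy()
        y = track.y_px.to_numpy()
        want = np.hypot(np.gradient(x), np.gradient(y)) * 25.0
        assert np.allclose(feats.speed_px_s, want)

    def test_wall_and_corner_distances(self):
        feats = mb.compute_frame_features(make_track([(10, 20)] * 5), ARENA)
        assert np.allclose(feats.dist_to_nearest_wall_px, 10.0)
        assert np.allclose(feats.dist_to_nearest_corner_px, np.hypot(10, 20))

    def test_pixel_change_absent_without_frames(self):
        feats = mb.compute_frame_features(make_track([(50, 50)] * 10), ARENA)
        assert feats.local_pixel_change.isna().all()

    def test_all_invalid_track_rejected(self):
        t = make_track([(0, 0)] * 5)
        t["valid"] = False
        with pytest.raises(ValueError):
            mb.compute_frame_features(t, ARENA)


class TestWindowize:
    def test_constant_feature(self):
        f = pd.DataFrame({"a": np.full(50, 3.0)})
        w = mb.windowize(f, window_radii_frames=(2, 6))
        for r in (2, 6):
            assert np.allclose(w[f"a_r{r}_mean"], 3.0)
            assert np.allclose(w[f"a_r{r}_std"], 0.0)
            assert np.allclose(w[f"a_r{r}_end_minus_start"], 0.0)

    def test_edge_truncation(self):
        f = pd.DataFrame({"a": np.arange(10, dtype=float)})
        w = mb.windowize(f, window_radii_frames=(2,))
        # frame 0 averages frames {0, 1, 2} only
        assert w["a_r2_mean"].iloc[0] == pytest.approx(1.0)
        assert w["a_r2_end_minus_start"].iloc[0] == pytest.approx(2.0)

    def test_matches_sliding_window_brute_force(self, rng):
        vals = rng.normal(0, 1, 40)
        f = pd.DataFrame({"a": vals})
        w = mb.windowize(f, window_radii_frames=(3,))
        for i in range(40):
            lo, hi = max(i - 3, 0), min(i + 3, 39) + 1
            win = vals[lo:hi]
            assert w["a_r3_mean"].iloc[i] == pytest.approx(win.mean())
            assert w["a_r3_std"].iloc[i] == pytest.approx(win.std())
            assert w["a_r3_min"].iloc[i] == pytest.approx(win.min())
            assert w["a_r3_max"].iloc[i] == pytest.approx(win.max())
            assert w["a_r3_end_minus_start"].iloc[i] == pytest.approx(win[-1] - win[0])

    def test_column_count(self):
        f = pd.DataFrame({"a": np.zeros(10), "b": np.zeros(10)})
        w = mb.windowize(f)
        assert w.shape[1] == 2 * 3 * 5

    def test_radius_zero_rejected(self):
        with pytest.raises(ValueError):
            mb.windowize(pd.DataFrame({"a": [1.0]}), window_radii_frames=(0,))


@pytest.fixture(scope="module")
def separable():
    spec = mb.SessionSpec(duration_s=40, fps=25, n_bouts=3,
                          bout_duration_s_mean=4, bout_duration_s_sd=1, seed=2)
    _, truth = mb.make_trajectory(spec)
    wf = mb.windowize(mb.make_feature_table(truth.labels, 10.0, seed=2))
    return wf, truth.labels


class TestTrainPredict:
    def test_separable_training_accuracy_100(self, separable):
        wf, labels = separable
        model = mb.train_classifier(wf, labels, seed=0)
        pred = mb.predict_frames(model, wf, smooth_radius_frames=0)
        assert np.array_equal(pred.mask, labels.mask)

    def test_same_seed_identical_predictions(self, separable):
        wf, labels = separable
        p1 = mb.predict_frames(mb.train_classifier(wf, labels, seed=3), wf)
        p2 = mb.predict_frames(mb.train_classifier(wf, labels, seed=3), wf)
        assert np.array_equal(p1.score, p2.score)

    def test_single_class_rejected(self, separable):
        wf, _ = separable
        with pytest.raises(ValueError):
            mb.train_classifier(wf, LabelSeries(label=np.zeros(len(wf), np.int8)))

    def test_unannotated_frames_excluded(self, separable):
        wf, labels = separable
        lab = labels.label.copy()
        lab[::2] = UNANNOTATED
        model = mb.train_classifier(wf, LabelSeries(label=lab), seed=0)
        pred = mb.predict_frames(model, wf, smooth_radius_frames=0)
        assert np.mean(pred.mask == labels.mask) > 0.99

    def test_serialization_roundtrip(self, separable, tmp_path):
        wf, labels = separable
        model = mb.train_classifier(wf, labels, seed=1)
        path = tmp_path / "model.joblib"
        model.save(path)
        loaded = mb.BuryingClassifier.load(path)
        assert np.array_equal(loaded.decision_scores(wf), model.decision_scores(wf))

    def test_column_mismatch_rejected(self, separable):
        wf, labels = separable
        model = mb.train_classifier(wf, labels, seed=0)
        with pytest.raises(ValueError):
            model.decision_scores(wf.iloc[:, :5])


class TestMedianSmoothing:
    def test_radius_zero_is_identity(self, rng):
        raw = rng.random(100) < 0.5
        assert np.array_equal(_binary_median_smooth(raw, 0), raw)

    def test_isolated_positive_removed(self):
        raw = np.zeros(20, bool)
        raw[10] = True
        assert not _binary_median_smooth(raw, 2).any()

    def test_matches_sliding_median_oracle(self, rng):
        raw = rng.random(200) < 0.5
        for radius in (1, 2, 4):
            got = _binary_median_smooth(raw, radius)
            for i in range(200):
                lo, hi = max(i - radius, 0), min(i + radius, 199) + 1
                n_pos = raw[lo:hi].sum()
                size = hi - lo
                if 2 * n_pos > size:
                    assert got[i]
                elif 2 * n_pos < size:
                    assert not got[i]
                else:
                    assert got[i] == raw[i]

    def test_end_minus_start_helper(self):
        v = np.array([1.0, 5.0, 2.0])
        assert list(_end_minus_start(v, 1)) == [4.0, 1.0, -3.0]


class TestCrossValidate:
    def test_quadrants_sum_to_annotated(self):
        spec = mb.SessionSpec(duration_s=60, fps=25, n_bouts=4,
                              bout_duration_s_mean=4, bout_duration_s_sd=1, seed=3)
        _, truth = mb.make_trajectory(spec)
        wf = mb.windowize(mb.make_feature_table(truth.labels, 3.0, seed=3))
        rep = mb.cross_validate(wf, truth.labels, k=4, seed=0, n_rounds=30)
        assert rep.tp + rep.fn + rep.tn + rep.fp == rep.n_frames_annotated
        assert 0 <= rep.acc_burying <= 1 and 0 <= rep.acc_nonburying <= 1

    def test_strong_separation_high_accuracy(self):
        spec = mb.SessionSpec(duration_s=60, fps=25, n_bouts=4,
                              bout_duration_s_mean=4, bout_duration_s_sd=1, seed=4)
        _, truth = mb.make_trajectory(spec)
        wf = mb.windowize(mb.make_feature_table(truth.labels, 10.0, seed=4))
        rep = mb.cross_validate(wf, truth.labels, k=5, seed=0, n_rounds=30)
        assert rep.acc_burying > 0.95 and rep.acc_nonburying > 0.95

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            mb.cross_validate(pd.DataFrame({"a": [1.0, 2.0]}),
                              LabelSeries(label=np.array([1, 0], np.int8)), k=1)


def test_cv_accuracy_monotone_in_separation():
    """Median CV accuracy never decreases as class separation grows."""
    seps = [0.5, 1.5, 3.0]
    medians = []
    for sep in seps:
        accs = []
        for seed in range(3):
            spec = mb.SessionSpec(duration_s=48, fps=25, n_bouts=3,
                                  bout_duration_s_mean=4, bout_duration_s_sd=1, seed=seed)
            _, truth = mb.make_trajectory(spec)
            wf = mb.windowize(mb.make_feature_table(truth.labels, sep, seed=seed))
            rep = mb.cross_validate(wf, truth.labels, k=3, seed=0, n_rounds=30)
            accs.append(0.5 * (rep.acc_burying + rep.acc_nonburying))
        medians.append(np.median(accs))
    assert medians[0] <= medians[1] + 0.02 and medians[1] <= medians[2] + 0.02
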