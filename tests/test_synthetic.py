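"""Generator contracts: determinism, confinement, and ground-truth fidelity."""

import numpy as np
import pytest
from scipy.stats import norm

import mbassay as mb
from mbassay.synthetic import _chord_offset


class TestTrajectory:
    def test_frame_count_is_duration_times_fps(self):
        spec = mb.SessionSpec(duration_s=60, fps=25, n_bouts=0, seed=1)
        track, _ = mb.make_trajectory(spec)
        assert len(track) == 1500

    def test_no_bouts_means_all_negative_labels(self):
        spec = mb.SessionSpec(duration_s=30, fps=25, n_bouts=0, seed=3)
        _, truth = mb.make_trajectory(spec)
        assert not truth.labels.mask.any()
        assert len(truth.bouts) == 0

    def test_same_seed_reproduces_track_exactly(self):
        spec = mb.SessionSpec(duration_s=30, fps=25, n_bouts=2, seed=7)
        t1, g1 = mb.make_trajectory(spec)
        t2, g2 = mb.make_trajectory(mb.SessionSpec(duration_s=30, fps=25, n_bouts=2, seed=7))
        assert t1.equals(t2)
        assert np.array_equal(g1.labels.label, g2.labels.label)

    def test_trajectory_confined_to_arena(self, short_session):
        spec, track, _ = short_session
        assert (track.x_px >= 0).all() and (track.x_px <= spec.arena_w_px).all()
        assert (track.y_px >= 0).all() and (track.y_px <= spec.arena_h_px).all()

    def test_bouts_are_exactly_the_label_runs(self, short_session):
        _, _, truth = short_session
        reseg = mb.segment_bouts(truth.labels, truth.bouts.fps, min_bout_s=0.0)
        assert reseg == truth.bouts

    def test_bout_frames_are_slow(self, short_session):
        spec, track, truth = short_session
        v = np.hypot(np.diff(track.x_px), np.diff(track.y_px)) * spec.fps
        mask = truth.labels.mask[1:]
        # interior bout frames obey the 20%-of-mean speed cap
        assert np.median(v[mask]) < np.median(v[~mask])

    def test_rejects_bad_spec(self):
        with pytest.raises(ValueError):
            mb.SessionSpec(duration_s=0)
        with pytest.raises(ValueError):
            mb.SessionSpec(fps=-1)
        with pytest.raises(ValueError):
            mb.SessionSpec(corner_bias=1.5)


class TestRenderFrames:
    def test_frame_count_and_determinism(self, rendered_session):
        spec, track, _, stack = rendered_session
        assert stack.shape[0] == len(track)
        again = mb.render_frames(track, spec, noise_sd=0.0, seed=5)
        assert np.array_equal(stack, again)

    def test_single_dark_region_at_ground_truth_centroid(self, rendered_session):
        spec, track, _, stack = rendered_session
        frame = stack[0]
        dark = frame < 100
        from scipy import ndimage

        labeled, n = ndimage.label(dark)
        assert n == 1
        # pixel-mass centroid oracle
        ys, xs = np.nonzero(dark)
        assert abs(xs.mean() - track.x_px.iloc[0]) <= 0.5
        assert abs(ys.mean() - track.y_px.iloc[0]) <= 0.5

    def test_rejects_oversized_ellipse(self, rendered_session):
        spec, track, _, _ = rendered_session
        bad = track.copy()
        bad["major_px"] = spec.arena_w_px * 2
        with pytest.raises(ValueError):
            mb.render_frames(bad, spec)


class TestMarbleImage:
    def test_zero_coverage_shows_full_disks(self):
        img, truth = mb.make_marble_image(5, [0.0] * 5, seed=2)
        for vis, full in zip(truth.per_marble_visible_px, truth.per_marble_full_px):
            assert vis == full

    def test_full_coverage_hides_marble(self):
        img, truth = mb.make_marble_image(1, [1.0], seed=2)
        assert truth.per_marble_visible_px[0] == 0

    def test_half_coverage_within_two_percent(self):
        img, truth = mb.make_marble_image(1, [0.5], seed=4)
        frac = truth.per_marble_visible_px[0] / truth.per_marble_full_px[0]
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_chord_offset_closed_form(self):
        # segment area fraction acos(d) - d sqrt(1-d^2) over pi, checked at d=0
        assert _chord_offset(0.5) == pytest.approx(0.0, abs=1e-9)
        assert _chord_offset(0.0) == 1.0
        assert _chord_offset(1.0) == -1.0

    def test_rejects_bad_coverage(self):
        with pytest.raises(ValueError):
            mb.make_marble_image(2, [0.5, 1.5])


class TestObserverLabels:
    def test_zero_rates_identity(self, short_session):
        _, _, truth = short_session
        obs = mb.make_observer_labels(truth.labels, 0.0, 0.0, seed=1)
        assert np.array_equal(obs.label, truth.labels.label)

    def test_unit_rates_complement(self, short_session):
        _, _, truth = short_session
        obs = mb.make_observer_labels(truth.labels, 1.0, 1.0, seed=1)
        assert np.array_equal(obs.mask, ~truth.labels.mask)

    def test_flip_rates_within_binomial_error(self):
        spec = mb.SessionSpec(duration_s=400, fps=25, n_bouts=10, seed=9)
        _, truth = mb.make_trajectory(spec)
        miss, fa = 0.1, 0.05
        obs = mb.make_observer_labels(truth.labels, miss, fa, seed=3)
        pos = truth.labels.mask
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        miss_hat = np.mean(~obs.mask[pos])
        fa_hat = np.mean(obs.mask[~pos])
        assert abs(miss_hat - miss) <= 3 * np.sqrt(miss * (1 - miss) / n_pos)
        assert abs(fa_hat - fa) <= 3 * np.sqrt(fa * (1 - fa) / n_neg)


class TestFeatureTable:
    def test_zero_separation_equal_means(self, short_session):
        _, _, truth = short_session
        X = mb.make_feature_table(truth.labels, 0.0, seed=1)
        pos, neg = truth.labels.mask, ~truth.labels.mask
        diff = X.loc[pos, "f0"].mean() - X.loc[neg, "f0"].mean()
        se = np.sqrt(1 / pos.sum() + 1 / neg.sum())
        assert abs(diff) < 4 * se

    def test_large_separation_linearly_separable(self, short_session):
        _, _, truth = short_session
        X = mb.make_feature_table(truth.labels, 10.0, noise_sd=1.0, seed=1)
        pred = X["f0"].to_numpy() > 5.0
        assert np.array_equal(pred, truth.labels.mask)

    def test_unit_separation_bayes_accuracy(self):
        spec = mb.SessionSpec(duration_s=600, fps=25, n_bouts=18, bout_duration_s_mean=15,
                              bout_duration_s_sd=2.0, seed=6)
        _, truth = mb.make_trajectory(spec)
        X = mb.make_feature_table(truth.labels, 1.0, seed=2)
        pred = X["f0"].to_numpy() > 0.5  # optimal threshold at the midpoint
        acc = np.mean(pred == truth.labels.mask)
        expected = norm.cdf(0.5)  # closed-form Gaussian overlap
        assert acc == pytest.approx(expected, abs=0.02)
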