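import numpy as np
import pandas as pd
import pytest

from sociotouch import behavior as beh


def make_traces(n=600, fps=120.0, labels=None, **kw):
    time = np.arange(n) / fps
    if labels is None:
        labels = {"m_1": np.tile([10.0, 20.0], (n, 1))}
    return beh.PoseTraces(time=time, labels=labels, **kw)


def square_eye(n, side=2.0, center=(0.0, 0.0)):
    cx, cy = center
    h = side / 2
    corners = [(-h, -h), (h, -h), (h, h), (-h, h)]
    return {
        f"eye_{i+1}": np.tile([cx + dx, cy + dy], (n, 1))
        for i, (dx, dy) in enumerate(corners)
    }


class TestMotionEnergy:
    def test_static_marker_zero(self):
        t = make_traces()
        assert np.all(beh.label_motion_energy(t, "m_1") == 0)

    def test_two_frame_step(self):
        xy = np.zeros((10, 2))
        xy[:, 0] = 3.0 * (np.arange(10) // 2)  # step 3 px every 2 frames
        t = make_traces(10, labels={"m_1": xy})
        e = beh.label_motion_energy(t, "m_1")
        assert np.allclose(e[2:], 3.0)

    def test_unknown_label_raises(self):
        with pytest.raises(KeyError):
            beh.label_motion_energy(make_traces(), "nope")

    def test_excluded_frames_masked_not_interpolated(self):
        t = make_traces(10)
        mask = np.zeros(10, bool)
        mask[4] = True
        t = beh.exclude_frames(t, mask)
        e = beh.label_motion_energy(t, "m_1")
        assert np.isnan(e[4]) and np.isnan(e[6])  # frame and its 2-ahead use

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        xy = rng.normal(0, 1, (50, 2))
        t1 = make_traces(50, labels={"m_1": xy})
        t2 = make_traces(50, labels={"m_1": xy + [100.0, -40.0]})
        assert np.allclose(
            beh.label_motion_energy(t1, "m_1")[2:], beh.label_motion_energy(t2, "m_1")[2:]
        )


class TestEyeArea:
    def test_unit_square(self):
        t = make_traces(5, labels=square_eye(5, side=2.0))
        assert np.allclose(beh.eye_area_trace(t), 4.0)

    def test_scaling_homogeneity(self):
        t1 = make_traces(5, labels=square_eye(5, side=2.0))
        t2 = make_traces(5, labels=square_eye(5, side=4.0))
        assert np.allclose(beh.eye_area_trace(t2), 4 * beh.eye_area_trace(t1))

    def test_rotation_invariance(self):
        n = 5
        sq = square_eye(n)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rot = {k: v @ R.T for k, v in sq.items()}
        a1 = beh.eye_area_trace(make_traces(n, labels=sq))
        a2 = beh.eye_area_trace(make_traces(n, labels=rot))
        assert np.allclose(a1, a2)

    def test_too_few_labels(self):
        t = make_traces(5, labels={"eye_1": np.zeros((5, 2)), "eye_2": np.ones((5, 2))})
        with pytest.raises(ValueError):
            beh.eye_area_trace(t)


class TestSaccades:
    def _pupil(self, x):
        n = len(x)
        return {
            f"pupil_{i}": np.column_stack([x, np.zeros(n)]) + off
            for i, off in enumerate([(0, 1), (0, -1), (1, 0), (-1, 0)], start=1)
        }

    def test_slow_drift_no_events(self):
        x = np.linspace(0, 5, 600)  # 1 px/s at 120 fps
        t = make_traces(600, labels=self._pupil(x))
        assert len(beh.detect_saccades(t, velocity_threshold=100)) == 0

    def test_fast_positive_jump_is_temporal(self):
        x = np.zeros(200)
        x[100:] = 8.0
        t = make_traces(200, labels=self._pupil(x))
        ev = beh.detect_saccades(t, velocity_threshold=100)
        assert len(ev) == 1 and ev.direction.iloc[0] == "temporal"

    def test_pure_y_motion_ignored(self):
        n = 200
        y = np.zeros(n)
        y[100:] = 50.0
        labels = {
            f"pupil_{i}": np.column_stack([np.zeros(n), y]) for i in range(1, 5)
        }
        t = make_traces(n, labels=labels)
        assert len(beh.detect_saccades(t, velocity_threshold=100)) == 0


class TestAFEBouts:
    time = np.arange(1200) / 120.0

    def test_subthreshold_no_bouts(self):
        f = np.zeros_like(self.time)
        out = beh.detect_afe_bouts(f, self.time, "whisker_protraction", 1.0)
        assert len(out) == 0

    def test_single_planted_bout(self):
        f = np.zeros_like(self.time)
        f[(self.time >= 2) & (self.time < 4)] = 2.0
        out = beh.detect_afe_bouts(f, self.time, "whisker_protraction", 1.0, 0.5, 0.25)
        assert len(out) == 1
        assert out.duration.iloc[0] == pytest.approx(2.0, abs=0.02)

    def test_close_epochs_merged(self):
        f = np.zeros_like(self.time)
        f[(self.time >= 2) & (self.time < 3)] = 2.0
        f[(self.time >= 3.1) & (self.time < 4)] = 2.0  # 0.1 s gap < 0.25 s
        out = beh.detect_afe_bouts(f, self.time, "whisker_protraction", 1.0)
        assert len(out) == 1

    def test_short_epochs_discarded(self):
        f = np.zeros_like(self.time)
        f[(self.time >= 2) & (self.time < 2.2)] = 2.0
        out = beh.detect_afe_bouts(f, self.time, "whisker_protraction", 1.0, 0.5)
        assert len(out) == 0

    def test_orbital_uses_below_threshold(self):
        area = np.full_like(self.time, 100.0)
        area[(self.time >= 1) & (self.time < 3)] = 50.0
        out = beh.detect_afe_bouts(area, self.time, "orbital_tightening", 70.0)
        assert len(out) == 1

    def test_masked_gap_splits_only_if_long(self):
        f = np.zeros_like(self.time)
        f[(self.time >= 2) & (self.time < 5)] = 2.0
        short = f.copy()
        short[(self.time >= 3) & (self.time < 3.1)] = np.nan  # gap < merge_gap
        assert len(beh.detect_afe_bouts(short, self.time, "whisker_protraction", 1.0)) == 1
        long = f.copy()
        long[(self.time >= 3) & (self.time < 3.5)] = np.nan  # gap >= merge_gap
        assert len(beh.detect_afe_bouts(long, self.time, "whisker_protraction", 1.0)) == 2


class TestAvoidance:
    time = np.arange(600) / 120.0

    def _frac(self, motion, direction):
        return beh.running_avoidance_fraction(motion, direction, self.time, (0, 5))

    def test_all_backward(self):
        assert self._frac(np.ones(600), -np.ones(600)) == 1.0

    def test_no_backward(self):
        assert self._frac(np.ones(600), np.ones(600)) == 0.0

    def test_half_backward(self):
        d = np.ones(600)
        d[:300] = -1
        assert self._frac(np.ones(600), d) == pytest.approx(0.5)

    def test_never_running_is_missing(self):
        assert np.isnan(self._frac(np.zeros(600), np.ones(600)))


class TestExcludeFrames:
    def test_empty_mask_identity(self):
        t = make_traces(10)
        out = beh.exclude_frames(t, np.zeros(10, bool))
        assert np.array_equal(out.exclusion_mask, t.exclusion_mask)

    def test_all_masked_features_missing(self):
        t = make_traces(10, labels=square_eye(10))
        out = beh.exclude_frames(t, np.ones(10, bool))
        assert np.all(np.isnan(beh.eye_area_trace(out)))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            beh.exclude_frames(make_traces(10), np.zeros(9, bool))

    def test_masks_or_combined(self):
        t = make_traces(10)
        m1 = np.zeros(10, bool); m1[2] = True
        m2 = np.zeros(10, bool); m2[7] = True
        out = beh.exclude_frames(beh.exclude_frames(t, m1), m2)
        assert out.exclusion_mask[2] and out.exclusion_mask[7]


class TestPlantedEventRecovery:
    def test_detectors_recover_planted_events(self, behavior_session):
        from sociotouch import pipeline

        session, truth = behavior_session
        traces = session.behavior
        events = truth["events"]
        thr = pipeline.afe_thresholds(traces)
        w = pipeline.whisker_protraction_feature(traces)
        area = beh.eye_area_trace(traces)
        for kind, feature in (("whisker_protraction", w), ("orbital_tightening", area)):
            planted = events[events.kind == kind]
            bouts = beh.detect_afe_bouts(feature, traces.time, kind, thr[kind])
            hits = sum(
                ((bouts.t_start < p.t_stop) & (bouts.t_stop > p.t_start)).any()
                for _, p in planted.iterrows()
            )
            assert hits >= 0.95 * len(planted)
        planted_s = events[events.kind == "saccade"]
        detected = beh.detect_saccades(traces, velocity_threshold=240.0)
        assert len(detected) >= 0.95 * len(planted_s)
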