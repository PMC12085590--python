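import numpy as np
import pytest

from sociotouch import decoding, synth
from sociotouch.timeline import TrialWindow


def gain_session(ratio, n_units=10, seed=3):
    cfg = synth.SyntheticConfig(
        n_units={"vS1": n_units, "tSTR": 0, "BLA": 0},
        archetype_proportions={"sustained_excited": 1.0},
        frac_social_pref=1.0,
        frac_object_pref=0.0,
        context_gain_ratio=ratio,
        rng_seed=seed,
    )
    return synth.generate_session(cfg, include_behavior=False)[0]


def neural_features(session, choice="forced"):
    trials = session.trial_windows(choice=choice)
    return decoding.make_feature_matrix(
        "neural", session.spikes_by_unit(), trials, window=(0, 5)
    )


class TestFeatureMatrix:
    def test_averaged_window_shape(self, small_neural_session):
        session, _ = small_neural_session
        X, labels, names = neural_features(session)
        assert X.shape == (24, 8) and len(labels) == 24 and len(names) == 8

    def test_binned_neural_shape(self, small_neural_session):
        session, _ = small_neural_session
        trials = session.trial_windows(choice="forced")
        X, _, _ = decoding.make_feature_matrix(
            "neural", session.spikes_by_unit(), trials, window=(-1, 2), bin_width=0.05
        )
        assert X.shape == (24, 8 * 60)

    def test_behavior_feature_columns(self):
        trials = [TrialWindow(i, "social", "forced", 10.0 + 10 * i) for i in range(4)]
        t = np.arange(0, 60, 1 / 120)
        feats = {f"lab{i}": np.ones_like(t) for i in range(23)}
        X, _, names = decoding.make_feature_matrix(
            "behavior_all_labels", trials=trials, window=(0, 3), bin_width=0.1,
            behavior_features=feats, behavior_time=t,
        )
        assert X.shape == (4, 23 * 30)

    def test_empty_trials_rejected(self):
        with pytest.raises(ValueError):
            decoding.make_feature_matrix("neural", {}, [])

    def test_unknown_source_rejected(self, small_neural_session):
        session, _ = small_neural_session
        with pytest.raises(ValueError):
            decoding.make_feature_matrix(
                "voltage", session.spikes_by_unit(), session.trial_windows()
            )


class TestDecodeContext:
    def test_planted_gain_highly_decodable(self):
        session = gain_session(5.0)
        X, labels, _ = neural_features(session)
        res = decoding.decode_context(X, labels, n_iterations=30, seed=0)
        assert res.accuracy_mean >= 0.9

    def test_permuted_labels_at_chance(self, rng):
        session = gain_session(5.0)
        X, labels, _ = neural_features(session)
        res = decoding.decode_context(X, rng.permutation(labels), n_iterations=30, seed=0)
        band = 1.96 * np.sqrt(0.25 / len(labels))
        assert abs(res.accuracy_mean - 0.5) <= band + 0.05

    def test_constant_feature_uninformative(self, rng):
        X = np.ones((80, 1))
        labels = np.array(["social", "object"] * 40)
        res = decoding.decode_context(X, labels, n_iterations=20, seed=0)
        assert 0.3 <= res.accuracy_mean <= 0.7

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            decoding.decode_context(np.ones((10, 2)), np.array(["social"] * 10))

    def test_unit_subsampling(self):
        session = gain_session(5.0)
        X, labels, _ = neural_features(session)
        res = decoding.decode_context(X, labels, n_iterations=10, n_units=3, seed=0)
        assert res.n_units == 3 and res.accuracy_mean > 0.5

    def test_estimator_interface(self):
        session = gain_session(5.0)
        X, labels, _ = neural_features(session)
        dec = decoding.ContextDecoder(n_iterations=5, random_state=0).fit(X, labels)
        assert set(dec.predict(X)) <= {"social", "object"}
        assert dec.get_params()["n_iterations"] == 5


class TestTimecourse:
    def test_gain_confined_to_stim_period(self):
        session = gain_session(6.0, n_units=8)
        trials = session.trial_windows(choice="forced")
        centers, results = decoding.decode_timecourse(
            session.spikes_by_unit(), trials, window=(-1, 2), bin_width=0.5,
            n_units=8, n_iterations=15, seed=0,
        )
        assert len(centers) == 6 and len(results) == 6
        pre = [r.accuracy_mean for c, r in zip(centers, results) if c < 0]
        post = [r.accuracy_mean for c, r in zip(centers, results) if c > 0.5]
        assert max(pre) < 0.75  # baseline bins near chance
        assert min(post) > 0.8  # stim bins carry the context signal


class TestShuffleControls:
    def setup_method(self):
        session = gain_session(5.0)
        self.X, self.labels, _ = neural_features(session)

    def test_all_modes_destroy_information(self):
        base = decoding.decode_context(self.X, self.labels, n_iterations=20, seed=0)
        for mode in ("test_labels", "partial_80pct", "time_shuffle_neural"):
            res = decoding.shuffle_controls(
                self.X, self.labels, mode, n_iterations=20, seed=0
            )
            assert res.accuracy_mean < base.accuracy_mean

    def test_zero_fraction_partial_equals_unshuffled(self):
        base = decoding.decode_context(self.X, self.labels, n_iterations=10, seed=7)
        res = decoding.shuffle_controls(
            self.X, self.labels, "partial_80pct", shuffle_fraction=0.0,
            n_iterations=10, seed=0,
        )
        assert abs(res.accuracy_mean - base.accuracy_mean) < 0.1

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            decoding.shuffle_controls(self.X, self.labels, "bogus")

    def test_time_shuffle_collapses_to_chance(self):
        res = decoding.shuffle_controls(
            self.X, self.labels, "time_shuffle_neural", n_iterations=20, seed=0
        )
        assert abs(res.accuracy_mean - 0.5) < 0.15


class TestDriftExclusion:
    def test_rules(self):
        b1 = {1: np.array([5.0, 6.0, 7.0]), 2: np.array([5.0, 6.0, 7.0]),
              3: np.array([5.0, 6.0, 7.0]), 4: np.array([4.0])}
        mu, sd = 6.0, 1.0
        b2 = {1: mu + 2 * sd, 2: mu, 3: mu + 1.5 * sd, 4: 100.0}
        kept, report = decoding.exclude_baseline_drift([1, 2, 3, 4], b1, b2)
        assert 1 not in kept                       # beyond 1.5 SD -> excluded
        assert 2 in kept                           # unchanged -> kept
        assert 3 in kept                           # exactly 1.5 SD -> kept (strict >)
        assert 4 in kept and "sd-undefined" in report[4]


class TestLocomotion:
    def test_uninformative_locomotion_preserves_accuracy(self, rng):
        session = gain_session(5.0)
        X, labels, _ = neural_features(session)
        loco = rng.normal(0, 1, (len(labels), 3))  # unrelated to context
        aug = decoding.decode_with_locomotion(X, loco, labels, n_iterations=15, seed=0)
        neural = decoding.decode_context(X, labels, n_iterations=15, seed=0)
        assert abs(aug.accuracy_mean - neural.accuracy_mean) < 0.1

    def test_shuffling_neural_removes_neural_signal(self, rng):
        session = gain_session(5.0)
        X, labels, _ = neural_features(session)
        loco = rng.normal(0, 1, (len(labels), 1))
        res = decoding.decode_with_locomotion(
            X, loco, labels, shuffle_neural=True, n_iterations=15, seed=0
        )
        assert abs(res.accuracy_mean - 0.5) < 0.15

    def test_locomotion_only_signal_survives_neural_shuffle(self, rng):
        labels = np.array(["social"] * 40 + ["object"] * 40)
        X = rng.normal(0, 1, (80, 5))  # uninformative neural features
        loco = np.where(labels == "social", 2.0, -2.0)[:, None] + rng.normal(0, 0.3, (80, 1))
        res = decoding.decode_with_locomotion(
            X, loco, labels, shuffle_neural=True, n_iterations=15, seed=0
        )
        assert res.accuracy_mean > 0.8
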