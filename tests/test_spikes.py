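import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sociotouch import spikes
from sociotouch.timeline import TrialWindow


def meta(uid=0, isi=0.05, amp=0.05, med=80.0, p2t=500.0, depth=300.0):
    return spikes.UnitMeta(
        unit_id=uid, depth=depth, peak_to_trough=p2t,
        isi_violation=isi, amplitude_cutoff=amp, median_amplitude=med,
    )


class TestQC:
    @pytest.mark.parametrize(
        "isi,amp,med,kept,reason",
        [
            (0.12, 0.05, 80, False, "isi_violation"),
            (0.05, 0.05, 60, True, None),
            (0.05, 0.15, 80, False, "amplitude_cutoff"),
            (0.05, 0.05, 40, False, "median_amplitude"),
            (0.10, 0.05, 80, False, "isi_violation"),  # boundary: strict <
            (0.05, 0.05, 50, False, "median_amplitude"),  # boundary: strict >
        ],
    )
    def test_threshold_rules(self, isi, amp, med, kept, reason):
        kept_units, rejected = spikes.qc_filter_units([meta(isi=isi, amp=amp, med=med)])
        assert bool(kept_units) is kept
        if not kept:
            assert reason in rejected[0]

    def test_empty_list(self):
        kept, rejected = spikes.qc_filter_units([])
        assert kept == [] and rejected == {}

    def test_missing_metric_rejected_with_reason(self):
        u = spikes.UnitMeta(unit_id=3, depth=0, isi_violation=0.01,
                            amplitude_cutoff=0.01, median_amplitude=None)
        kept, rejected = spikes.qc_filter_units([u])
        assert not kept and rejected[3] == ["missing:median_amplitude"]

    @settings(max_examples=40, derandomize=True)
    @given(
        isi=st.floats(0, 0.3), amp=st.floats(0, 0.3), med=st.floats(0, 150),
        d_isi=st.floats(0, 0.2), d_amp=st.floats(0, 0.2), d_med=st.floats(0, 50),
    )
    def test_relaxing_thresholds_is_monotone(self, isi, amp, med, d_isi, d_amp, d_med):
        u = meta(isi=isi, amp=amp, med=med)
        strict, _ = spikes.qc_filter_units([u], thresholds=(0.10, 0.10, 50))
        loose, _ = spikes.qc_filter_units(
            [u], thresholds=(0.10 + d_isi, 0.10 + d_amp, 50 - d_med)
        )
        if strict:
            assert loose


class TestUnitTypes:
    @pytest.mark.parametrize("p2t,expected", [(450, "RS"), (300, "other"), (400, "RS")])
    def test_rs_boundary_inclusive(self, p2t, expected):
        assert spikes.classify_unit_types([meta(p2t=p2t)])[0] == expected

    def test_missing_waveform_raises(self):
        u = spikes.UnitMeta(unit_id=0, depth=0)
        with pytest.raises(ValueError):
            spikes.classify_unit_types([u])


class TestRegions:
    BOUNDS = {"vS1": (0, 1000), "tSTR": (1000, 2000), "BLA": (3000, 4000)}

    @pytest.mark.parametrize(
        "depth,expected",
        [(500, "vS1"), (1000, "tSTR"), (2500, "unassigned"), (4000, "unassigned")],
    )
    def test_half_open_membership(self, depth, expected):
        assert spikes.assign_regions_by_depth([meta(depth=depth)], self.BOUNDS)[0] == expected

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            spikes.assign_regions_by_depth(
                [meta()], {"vS1": (0, 1200), "tSTR": (1000, 2000)}
            )


class TestBinning:
    def test_conservation(self):
        train = np.sort(np.random.default_rng(1).uniform(0, 1, 10))
        _, rates = spikes.bin_firing_rates(train, 0.05, 0, 1)
        assert rates.sum() * 0.05 == pytest.approx(10)

    def test_empty_train(self):
        _, rates = spikes.bin_firing_rates([], 0.05, 0, 1)
        assert np.all(rates == 0)

    def test_edge_spike_goes_to_later_bin(self):
        centers, rates = spikes.bin_firing_rates([0.05], 0.05, 0, 0.2)
        hot = np.flatnonzero(rates)
        assert centers[hot[0]] == pytest.approx(0.075)


class TestSmoothing:
    def test_constant_unchanged(self):
        out = spikes.smooth_rates(np.full(40, 4.0), 0.25, 0.05)
        assert np.allclose(out, 4.0)

    def test_impulse_spread(self):
        x = np.zeros(41)
        x[20] = 1.0
        out = spikes.smooth_rates(x, 0.25, 0.05)
        assert np.allclose(out[18:23], 0.2)
        assert out.sum() == pytest.approx(1.0)

    def test_single_bin_window_is_identity(self):
        x = np.arange(10, dtype=float)
        assert np.allclose(spikes.smooth_rates(x, 0.05, 0.05), x)

    def test_subbin_window_rejected(self):
        with pytest.raises(ValueError):
            spikes.smooth_rates(np.ones(5), 0.01, 0.05)


def _trial(i, t):
    return TrialWindow(i, "social", "forced", t)


class TestAlignment:
    def test_single_trial_average_is_trial(self):
        times, rates = spikes.bin_firing_rates(
            np.arange(0.025, 30, 0.2), 0.05, 0, 30
        )
        rel, per, avg, dropped = spikes.trial_align_psth(times, rates, [_trial(0, 10)])
        assert per.shape == (1, 180)
        assert np.allclose(avg, per[0]) and not dropped
        assert rel[0] == pytest.approx(-1.975) and rel[-1] == pytest.approx(6.975)

    def test_identical_trials_average(self):
        times, rates = spikes.bin_firing_rates(np.arange(0.025, 60, 0.1), 0.05, 0, 60)
        rel, per, avg, _ = spikes.trial_align_psth(times, rates, [_trial(0, 10), _trial(1, 30)])
        assert np.allclose(avg, per[0])

    def test_out_of_range_trial_dropped(self):
        times, rates = spikes.bin_firing_rates([1.0], 0.05, 0, 12)
        _, per, _, dropped = spikes.trial_align_psth(times, rates, [_trial(7, 10)])
        assert dropped == [7] and per.shape[0] == 0

    def test_pipeline_linearity(self):
        rng = np.random.default_rng(2)
        a = np.sort(rng.uniform(0, 40, 200))
        b = np.sort(rng.uniform(0, 40, 150))
        trials = [_trial(0, 10), _trial(1, 25)]

        def run(train):
            t, r = spikes.bin_firing_rates(train, 0.05, 0, 40)
            sm = spikes.smooth_rates(r, 0.25, 0.05)
            return spikes.trial_align_psth(t, sm, trials)[2]

        combined = run(np.sort(np.concatenate([a, b])))
        assert np.allclose(combined, run(a) + run(b), atol=1e-9)


class TestZScore:
    def test_constant_trace_zeroed_after_centering(self):
        t = np.arange(-2, 7, 0.05) + 0.025
        psth = np.full_like(t, 3.0)
        psth[t >= 0] = 5.0
        z, flagged = spikes.zscore_to_isi(psth, t, (-2, 0))
        assert flagged  # flat baseline has zero SD
        assert np.allclose(z[t < 0], 0.0)

    def test_hand_arithmetic(self):
        t = np.array([-1.5, -0.5, 0.5])
        psth = np.array([1.0, 3.0, 5.0])  # baseline mean 2, sd 1
        z, flagged = spikes.zscore_to_isi(psth, t, (-2, 0))
        assert not flagged and z[2] == pytest.approx(3.0)

    def test_bad_window_rejected(self):
        t = np.arange(-2, 7, 0.05)
        with pytest.raises(ValueError):
            spikes.zscore_to_isi(np.ones_like(t), t, (1, 2))
        with pytest.raises(ValueError):
            spikes.zscore_to_isi(np.ones_like(t), t, (-0.01, 0.0))


class TestWindowRates:
    def test_counts_and_rate(self):
        train = np.array([10.1, 10.2, 14.9, 15.0, 20.0])
        rates = spikes.window_rates(train, [_trial(0, 10)], (0, 5))
        assert rates[0] == pytest.approx(3 / 5)  # half-open [10, 15)
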