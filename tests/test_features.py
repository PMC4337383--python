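import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snbdecode import (
    BaselineStats,
    ConfigError,
    DataError,
    SynthConfig,
    Trial,
    active_channel_series,
    activation_probability_map,
    bin_spike_counts,
    binarize_trial,
    binary_tensor,
    count_tensor,
    entropy_bin_edges,
    generate_session,
    intertrial_baseline,
    population_rate_series,
)
from snbdecode.session import IntertrialSegment, Session


def _trial(spikes=None, span=(-500.0, 1500.0)):
    return Trial(
        trial_id=0,
        cue_stimulus=1,
        trial_start=span[0],
        trial_end=span[1],
        cue_onset=0.0,
        cue_offset=150.0,
        spikes=spikes or {},
    )


class TestSpikeCountVectors:
    def test_two_second_trial_gives_20_bins(self):
        counts, edges = bin_spike_counts(_trial(), bin_ms=100.0)
        assert counts.shape == (20, 60)
        assert edges[0] == -500.0 and edges[-1] == 1500.0

    def test_silent_trial_all_zero_except_ground(self):
        counts, _ = bin_spike_counts(_trial())
        assert np.all(counts[:, :59] == 0)
        assert np.all(counts[:, 59] == 1)

    def test_counts_match_direct_interval_recount(self, rng):
        spikes = {
            ch: np.sort(rng.uniform(-500, 1500, size=rng.integers(0, 40)))
            for ch in range(1, 60)
        }
        spikes = {ch: t for ch, t in spikes.items() if t.size}
        trial = _trial(spikes)
        counts, edges = bin_spike_counts(trial, bin_ms=100.0)
        for b in range(len(edges) - 1):
            for ch in range(1, 60):
                t = trial.channel_spikes(ch)
                expect = np.sum((t >= edges[b]) & (t < edges[b + 1]))
                assert counts[b, ch - 1] == expect

    def test_spike_conservation(self, single_session):
        session, _ = single_session
        X, edges = count_tensor(session.trials)
        for trial, counts in zip(session.trials, X):
            in_span = trial.count_in_window(edges[0], edges[-1])
            assert counts[:, :59].sum() == in_span

    def test_boundary_spike_belongs_to_later_bin(self):
        counts, _ = bin_spike_counts(_trial({1: [100.0]}), bin_ms=100.0)
        assert counts[6, 0] == 1 and counts[5, 0] == 0  # bin [100, 200)

    def test_trailing_partial_bin_dropped(self):
        counts, edges = bin_spike_counts(_trial(span=(-500.0, 1550.0)), bin_ms=100.0)
        assert counts.shape[0] == 20 and edges[-1] == 1500.0

    def test_invalid_bin_width_rejected(self):
        with pytest.raises(ConfigError):
            bin_spike_counts(_trial(), bin_ms=0.0)


class TestEntropyBinGrid:
    def test_first_bin_is_550_ms_then_250(self):
        edges = entropy_bin_edges((-500.0, 1500.0))
        assert edges[0] == -500.0 and edges[1] == 50.0
        assert np.allclose(np.diff(edges)[1:], 250.0)
        assert edges[-1] <= 1500.0


class TestBaseline:
    def test_silent_segments_give_zero_stats(self):
        session = Session(
            protocol="single",
            trials=[_trial()],
            intertrial_segments=[IntertrialSegment(0.0, 1000.0)],
        )
        bl = intertrial_baseline(session)
        assert np.all(bl.mean_hz == 0) and np.all(bl.sd_hz == 0)
        assert bl.n_windows == 4

    def test_single_window_flagged_degenerate(self):
        session = Session(
            protocol="single",
            trials=[_trial()],
            intertrial_segments=[IntertrialSegment(0.0, 250.0)],
        )
        bl = intertrial_baseline(session)
        assert bl.degenerate and np.all(bl.sd_hz == 0)

    def test_missing_segments_is_an_error(self):
        session = Session(protocol="single", trials=[_trial()])
        with pytest.raises(DataError, match="inter-trial"):
            intertrial_baseline(session)

    def test_homogeneous_poisson_rate_recovered(self):
        rate = 2.0
        cfg = SynthConfig(
            protocol="single",
            n_stimuli=2,
            trials_per_stimulus=30,
            baseline_rate=rate,
            evoked_rate_gain=0.0,
            snb_prob={"pre_cue": 0.0, "cue": 0.0},
            seed=17,
        )
        session, _ = generate_session(cfg)
        bl = intertrial_baseline(session)
        total_s = bl.n_windows * 0.25 * 59
        se = np.sqrt(rate / total_s)
        assert abs(bl.mean_hz.mean() - rate) < 3 * se


class TestBinarization:
    def test_silent_trial_only_ground_bit(self):
        bl = BaselineStats(np.zeros(59), np.zeros(59), 4, False)
        bits, _ = binarize_trial(_trial(), bl)
        assert np.all(bits[:, :59] == 0) and np.all(bits[:, 59] == 1)

    def test_degenerate_sd_any_activity_counts(self):
        bl = BaselineStats(np.zeros(59), np.zeros(59), 1, True)
        bits, _ = binarize_trial(_trial({5: [100.0]}), bl)
        assert bits[1, 4] == 1  # bin [50, 300)

    def test_activation_requires_exceeding_3sd(self):
        # unit 1 baseline 1 Hz +/- 1 Hz -> threshold 4 Hz; one spike in a
        # 250 ms bin is 4 Hz exactly: strict inequality, stays inactive
        mean = np.zeros(59)
        sd = np.zeros(59)
        mean[0], sd[0] = 1.0, 1.0
        bl = BaselineStats(mean, sd, 10, False)
        bits, _ = binarize_trial(_trial({1: [100.0]}), bl)
        assert bits[1, 0] == 0
        bits2, _ = binarize_trial(_trial({1: [100.0, 120.0]}), bl)  # 8 Hz
        assert bits2[1, 0] == 1

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_binarization_monotone_in_spikes(self, seed):
        """Adding spikes never deactivates a unit."""
        r = np.random.default_rng(seed)
        base = np.sort(r.uniform(-500, 1500, size=10))
        extra = np.sort(np.concatenate([base, r.uniform(-500, 1500, size=5)]))
        bl = BaselineStats(r.uniform(0, 1, 59), r.uniform(0, 1, 59), 8, False)
        b1, _ = binarize_trial(_trial({3: base}), bl)
        b2, _ = binarize_trial(_trial({3: extra}), bl)
        assert np.all(b2 >= b1)


class TestPopulationSeries:
    def test_silent_trials_zero_rate(self):
        rate, _ = population_rate_series([_trial(), _trial()])
        assert np.all(rate == 0)

    def test_poisson_rate_scales_with_units(self):
        lam = 1.0
        cfg = SynthConfig(
            protocol="single",
            n_stimuli=2,
            trials_per_stimulus=25,
            baseline_rate=lam,
            evoked_rate_gain=0.0,
            snb_prob={"pre_cue": 0.0, "cue": 0.0},
            seed=23,
        )
        session, _ = generate_session(cfg)
        rate, edges = population_rate_series(session.trials)
        total_s = len(session) * (edges[-1] - edges[0]) / 1000.0
        se = np.sqrt(59 * lam / total_s)
        assert abs(rate.mean() - 59 * lam) < 3 * se

    def test_singleton_trial_set_is_own_profile(self):
        t = _trial({1: [10.0, 20.0]})
        rate, edges = population_rate_series([t], bin_ms=250.0)
        b = np.searchsorted(edges, 10.0, "right") - 1
        assert rate[b] == 2 / 0.25

    def test_active_channel_count_consistent_with_probability_map(self, single_session):
        session, _ = single_session
        bl = intertrial_baseline(session)
        B, _ = binary_tensor(session.trials, bl)
        pmap = activation_probability_map(B)
        counts = active_channel_series(B)
        np.testing.assert_allclose(pmap.sum(axis=1), counts)
        assert np.all((pmap >= 0) & (pmap <= 1))
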