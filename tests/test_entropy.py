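import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from snbdecode import (
    DataError,
    SynthConfig,
    binary_tensor,
    entropy_series,
    equalized_entropy_comparison,
    equivalent_stimuli,
    generate_session,
    intertrial_baseline,
    pattern_entropy,
    shannon_bits,
    standardize_and_correlate,
)


def _patterns_from_tallies(tallies, d=60):
    """N binary vectors realizing the given identical-pattern tallies."""
    rows = []
    for i, n in enumerate(tallies):
        v = np.zeros(d, dtype=int)
        v[: i + 1] = 1
        rows.extend([v] * n)
    return np.array(rows)


class TestPatternEntropy:
    def test_all_distinct_vectors_reach_upper_limit(self):
        H, equiv = pattern_entropy(np.eye(46, 60, dtype=int))
        assert equiv == pytest.approx(46.0)
        assert H == pytest.approx(np.log2(46))

    def test_identical_vectors_zero_entropy(self):
        H, equiv = pattern_entropy(np.ones((30, 60), dtype=int))
        assert H == 0.0 and equiv == 1.0

    def test_tallies_2_1_1_give_1_5_bits(self):
        # frequencies (0.5, 0.25, 0.25): H = 1.5 bits directly
        H, equiv = pattern_entropy(_patterns_from_tallies([2, 1, 1]))
        assert H == pytest.approx(1.5)
        assert equiv == pytest.approx(2.0**1.5)

    def test_empty_bin_rejected(self):
        with pytest.raises(DataError):
            pattern_entropy(np.empty((0, 60)))

    def test_matches_shannon_oracle_on_random_tallies(self, rng):
        """Plug-in formula equals the Shannon entropy of the empirical
        frequencies for 1,000 random tally vectors."""
        for _ in range(1000):
            k = rng.integers(1, 12)
            tallies = rng.integers(1, 30, size=k)
            expect = stats.entropy(tallies / tallies.sum(), base=2)
            assert abs(shannon_bits(tallies) - expect) < 1e-12

    @given(st.lists(st.integers(1, 50), min_size=1, max_size=10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_entropy_bounds(self, tallies):
        H = shannon_bits(np.array(tallies))
        N = sum(tallies)
        assert -1e-12 <= H <= np.log2(N) + 1e-12
        assert 1.0 - 1e-9 <= 2.0**H <= N + 1e-9


class TestEquivalentStimuli:
    def test_worked_value(self):
        assert equivalent_stimuli(0.9) == 1.87

    @pytest.mark.parametrize("H,expect", [(0.0, 1.0), (1.0, 2.0), (2.0, 4.0)])
    def test_exact_powers(self, H, expect):
        assert equivalent_stimuli(H) == expect

    def test_monotone_in_entropy(self):
        hs = np.linspace(0, 5, 40)
        vals = [equivalent_stimuli(h) for h in hs]
        assert np.all(np.diff(vals) >= 0)


class TestEntropySeries:
    def test_stimulus_raises_entropy_over_prestimulus(self):
        """The control pattern: pre-stimulus bins are dominated by the null
        response; stochastic evoked recruitment diversifies patterns."""
        cfg = SynthConfig(
            protocol="single",
            n_stimuli=4,
            trials_per_stimulus=20,
            snb_prob={"pre_cue": 0.0, "cue": 0.0},
            seed=31,
        )
        session, _ = generate_session(cfg)
        baseline = intertrial_baseline(session)
        B, edges = binary_tensor(session.trials, baseline)
        series = entropy_series(B, bin_edges=edges)
        assert series.H_bits[1] > series.H_bits[0]
        assert np.all(series.normalized <= 1.0 + 1e-9)


class TestEqualizedComparison:
    def test_identical_groups_zero_width_band(self):
        B = np.tile(np.eye(10, 60)[:, None, :], (1, 3, 1))
        cmp = equalized_entropy_comparison(B, B.copy(), n_resamples=20, seed=0)
        np.testing.assert_allclose(cmp.band_low, cmp.band_high)
        np.testing.assert_allclose(cmp.resampled_mean, cmp.small.H_bits)

    def test_stereotyped_large_group_always_zero(self):
        large = np.ones((40, 2, 60))
        small = np.tile(np.eye(8, 60)[:, None, :], (1, 2, 1))
        cmp = equalized_entropy_comparison(large, small, n_resamples=30, seed=1)
        assert np.all(cmp.resampled_mean == 0)
        assert cmp.n_equalized == 8

    def test_band_covers_honest_subsamples(self, rng):
        """The 99th-percentile band contains the entropy of a fresh honest
        subsample in almost every draw."""
        large = (rng.uniform(size=(60, 1, 60)) < 0.4).astype(int)
        small = (rng.uniform(size=(15, 1, 60)) < 0.4).astype(int)
        cmp = equalized_entropy_comparison(large, small, n_resamples=300, seed=2)
        inside = 0
        draws = 200
        for _ in range(draws):
            idx = rng.choice(60, size=15, replace=False)
            H, _ = pattern_entropy(large[idx][:, 0, :])
            inside += cmp.band_low[0] - 1e-12 <= H <= cmp.band_high[0] + 1e-12
        assert inside / draws >= 0.95

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            equalized_entropy_comparison(np.empty((0, 2, 60)), np.ones((3, 2, 60)))


class TestStandardizedCorrelation:
    def test_linear_relation_survives_zscoring(self, rng):
        rows = []
        for net in range(3):
            x = rng.normal(size=10) * (net + 1) + net
            rows.append(pd.DataFrame({"network": net, "bin": range(10), "x": x, "y": 2 * x + 1}))
        res = standardize_and_correlate(pd.concat(rows))
        assert res[0].r == pytest.approx(1.0)
        assert res[0].n == 30

    def test_independent_noise_gives_small_r(self, rng):
        rows = []
        for net in range(4):
            rows.append(
                pd.DataFrame(
                    {"network": net, "bin": range(50),
                     "x": rng.normal(size=50), "y": rng.normal(size=50)}
                )
            )
        res = standardize_and_correlate(pd.concat(rows))
        assert abs(res[0].r) < 0.2

    def test_matches_textbook_pearson_on_pooled_zscores(self):
        panel = pd.DataFrame(
            {
                "network": [0, 0, 0, 1, 1, 1],
                "bin": [0, 1, 2, 0, 1, 2],
                "x": [1.0, 2.0, 4.0, 10.0, 11.0, 15.0],
                "y": [0.5, 0.4, 0.9, 3.0, 1.0, 2.0],
            }
        )
        res = standardize_and_correlate(panel)
        zs = []
        for _, g in panel.groupby("network"):
            zx = (g["x"] - g["x"].mean()) / g["x"].std(ddof=1)
            zy = (g["y"] - g["y"].mean()) / g["y"].std(ddof=1)
            zs.append(np.stack([zx, zy]))
        z = np.concatenate(zs, axis=1)
        r_expect, p_expect = stats.pearsonr(z[0], z[1])
        assert res[0].r == pytest.approx(r_expect)
        assert res[0].p == pytest.approx(p_expect)

    def test_zero_variance_network_flagged_and_excluded(self, rng):
        a = pd.DataFrame({"network": 0, "bin": range(5),
                          "x": np.ones(5), "y": rng.normal(size=5)})
        b = pd.DataFrame({"network": 1, "bin": range(5),
                          "x": rng.normal(size=5), "y": rng.normal(size=5)})
        res = standardize_and_correlate(pd.concat([a, b]))
        assert res[0].flagged_networks == (0,)
        assert res[0].n == 5
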