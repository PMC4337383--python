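"""Pattern entropy of binary network activity vectors and pooled
standardized correlations.

For a bin holding N binary vectors grouped into identical-pattern classes
with tallies n_i, the plug-in entropy is

    H(x) = log2 N - (1/N) * sum_i n_i log2 n_i        [bits]

which equals the Shannon entropy of the empirical pattern frequencies
n_i / N.  Entropy is reported alongside its *equivalent number* 2^H — the
count of equally likely patterns carrying the same entropy (so 46
all-distinct vectors give equivalent number 46, and a fully stereotyped
bin gives 1).

Comparisons between trial groups of unequal size equalize trial counts by
subsampling the larger group (without replacement) to the smaller group's
size, 300 times by default, reporting the per-bin mean and the
99th-percentile extremes of the resampled values as a band; the smaller
group's entropy is computed directly.

When variables (mean firing rate, active channels, normalized entropy) are
compared across networks, each variable is first z-scored within its
network and the pooled Pearson correlation r is computed over all
(bin, network) points with a two-sided t-test p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError


def shannon_bits(tallies: np.ndarray) -> float:
    """Plug-in Shannon entropy (bits) of a tally vector.

    Shared kernel for pattern entropy and cluster stimulus-label entropy.
    """
    n = np.asarray(tallies, dtype=float)
    n = n[n > 0]
    if n.size == 0:
        raise DataError("entropy of an empty tally is undefined")
    N = n.sum()
    return float(np.log2(N) - (n * np.log2(n)).sum() / N)


def pattern_tallies(patterns: np.ndarray) -> np.ndarray:
    """Counts of identical rows of a ``(N, d)`` binary-pattern array."""
    patterns = np.asarray(patterns)
    if patterns.ndim != 2 or patterns.shape[0] == 0:
        raise DataError("patterns must be a non-empty (N, d) array")
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    return counts


def pattern_entropy(patterns: np.ndarray) -> tuple[float, float]:
    """Entropy (bits) and equivalent number 2^H of one bin's vectors."""
    H = shannon_bits(pattern_tallies(patterns))
    N = patterns.shape[0]
    if not (-1e-9 <= H <= np.log2(N) + 1e-9):
        raise DataError("entropy outside [0, log2 N]")  # pragma: no cover
    return H, float(2.0**H)


def equivalent_stimuli(H_bits: float) -> float:
    """Equivalent number of equally likely outcomes for an entropy,
    rounded to two decimals for reporting (0.9 bits -> 1.87)."""
    if H_bits < 0:
        raise DataError("entropy must be >= 0")
    return round(float(2.0**H_bits), 2)


@dataclass
class EntropySeries:
    """Per-bin pattern entropy of one trial group."""

    H_bits: np.ndarray
    equivalent_number: np.ndarray
    n_trials: int
    bin_edges: np.ndarray | None = None

    @property
    def normalized(self) -> np.ndarray:
        """H / log2 N: entropy as a fraction of the trial-count ceiling."""
        if self.n_trials < 2:
            return np.zeros_like(self.H_bits)
        return self.H_bits / np.log2(self.n_trials)

    def to_dict(self) -> dict:
        d = {
            "H_bits": self.H_bits.tolist(),
            "equivalent_number": self.equivalent_number.tolist(),
            "n_trials": self.n_trials,
        }
        if self.bin_edges is not None:
            d["bin_edges_ms"] = np.asarray(self.bin_edges).tolist()
        return d


def entropy_series(binary: np.ndarray, bin_edges: np.ndarray | None = None) -> EntropySeries:
    """Per-bin entropy of a ``(n_trials, n_bins, 60)`` binary tensor."""
    binary = np.asarray(binary)
    if binary.ndim != 3 or binary.shape[0] == 0:
        raise DataError("binary tensor must be non-empty (n_trials, n_bins, d)")
    H = np.array([pattern_entropy(binary[:, b, :])[0] for b in range(binary.shape[1])])
    return EntropySeries(H_bits=H, equivalent_number=2.0**H,
                         n_trials=binary.shape[0], bin_edges=bin_edges)


@dataclass
class EqualizedEntropyComparison:
    """Trial-count-equalized entropy of a large vs a small trial group."""

    small: EntropySeries          # computed directly
    resampled_mean: np.ndarray    # per-bin mean over resamples of the large group
    band_low: np.ndarray
    band_high: np.ndarray
    n_resamples: int
    n_equalized: int              # trials per resample (= small group size)

    def to_dict(self) -> dict:
        return {
            "small": self.small.to_dict(),
            "resampled_mean": self.resampled_mean.tolist(),
            "band_low": self.band_low.tolist(),
            "band_high": self.band_high.tolist(),
            "n_resamples": self.n_resamples,
            "n_equalized": self.n_equalized,
        }


def equalized_entropy_comparison(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_resamples: int = 300,
    seed: int | None = None,
    band_percentiles: tuple[float, float] = (0.5, 99.5),
    bin_edges: np.ndarray | None = None,
) -> EqualizedEntropyComparison:
    """Compare two binary tensors with equalized trial counts.

    The larger group (auto-detected) is subsampled without replacement to
    the smaller group's size ``n_resamples`` times; the smaller group's
    entropy is computed directly.
    """
    a, b = np.asarray(group_a), np.asarray(group_b)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise DataError("both trial groups must be non-empty")
    if a.shape[1:] != b.shape[1:]:
        raise DataError("groups must share the bin grid")
    large, small = (a, b) if a.shape[0] >= b.shape[0] else (b, a)
    rng = np.random.default_rng(seed)
    k = small.shape[0]
    n_bins = small.shape[1]
    H = np.empty((n_resamples, n_bins))
    for r in range(n_resamples):
        idx = rng.choice(large.shape[0], size=k, replace=False)
        sub = large[idx]
        H[r] = [pattern_entropy(sub[:, bb, :])[0] for bb in range(n_bins)]
    lo, hi = band_percentiles
    return EqualizedEntropyComparison(
        small=entropy_series(small, bin_edges=bin_edges),
        resampled_mean=H.mean(axis=0),
        band_low=np.percentile(H, lo, axis=0),
        band_high=np.percentile(H, hi, axis=0),
        n_resamples=n_resamples,
        n_equalized=k,
    )


@dataclass
class CorrelationResult:
    var_x: str
    var_y: str
    r: float
    p: float
    n: int
    flagged_networks: tuple = ()

    def to_dict(self) -> dict:
        return {
            "pair": [self.var_x, self.var_y],
            "r": self.r,
            "p": self.p,
            "n": self.n,
            "flagged_networks": list(self.flagged_networks),
        }


def standardize_and_correlate(
    panel: pd.DataFrame,
    variables: list[str] | None = None,
    network_col: str = "network",
) -> list[CorrelationResult]:
    """Within-network z-scoring followed by pooled Pearson correlations.

    ``panel`` holds one row per (network, bin) with one column per
    variable.  A variable with zero variance within some network is flagged
    and that network is excluded from pairs involving it.
    """
    if network_col not in panel.columns:
        raise DataError(f"panel lacks a {network_col!r} column")
    if variables is None:
        variables = [c for c in panel.columns if c not in (network_col, "bin")]
    if len(variables) < 2:
        raise DataError("need at least two variables to correlate")

    results = []
    for vx, vy in combinations(variables, 2):
        xs, ys, flagged = [], [], []
        for net, grp in panel.groupby(network_col, sort=True):
            x = grp[vx].to_numpy(float)
            y = grp[vy].to_numpy(float)
            if len(x) < 2 or x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
                flagged.append(net)
                continue
            xs.append((x - x.mean()) / x.std(ddof=1))
            ys.append((y - y.mean()) / y.std(ddof=1))
        if not xs:
            raise DataError(f"no network with variance in both {vx!r} and {vy!r}")
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        if len(x) < 3:
            raise DataError("fewer than 3 pooled points")
        r, p = stats.pearsonr(x, y)
        results.append(
            CorrelationResult(vx, vy, float(r), float(p), len(x), tuple(flagged))
        )
    return results
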