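"""Population features: spike-count vectors, binary activity vectors,
firing-rate and active-channel time series.

Spike-count vectors are 60-dimensional: one count per electrode (channels
1..59) in a 100 ms bin plus the ground element fixed at 1.  Binary network
activity vectors use 250 ms bins, the first of which spans -500 to +50 ms
peristimulus (550 ms); a unit's bit is 1 when its firing rate in the bin
strictly exceeds its inter-trial baseline mean plus three baseline standard
deviations, and the ground bit is always 1.

Bins are half-open ``[a, b)``: a spike at an exact boundary belongs to the
later bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError
from .session import GROUND_CHANNEL, N_CHANNELS, Session, Trial

FIRST_BINARY_BIN_MS = 550.0
BINARY_BIN_MS = 250.0


def bin_edges(span: tuple[float, float], bin_ms: float) -> np.ndarray:
    """Uniform half-open bin edges covering ``span``; a trailing partial
    bin is dropped."""
    if bin_ms <= 0:
        raise ConfigError("bin_ms must be positive")
    a, b = span
    n = int(np.floor((b - a) / bin_ms + 1e-9))
    if n < 1:
        raise ConfigError(f"span {span} shorter than one {bin_ms} ms bin")
    return a + bin_ms * np.arange(n + 1)


def entropy_bin_edges(span: tuple[float, float]) -> np.ndarray:
    """Edges of the binary-vector series: a 550 ms first bin anchored at
    -500 ms peristimulus, then 250 ms bins ([-500,50), [50,300), ...)."""
    a, b = span
    first_end = a + FIRST_BINARY_BIN_MS
    if first_end > b:
        raise ConfigError("span shorter than the 550 ms first bin")
    edges = [a, first_end]
    while edges[-1] + BINARY_BIN_MS <= b + 1e-9:
        edges.append(edges[-1] + BINARY_BIN_MS)
    return np.asarray(edges)


def _counts_in_bins(trial: Trial, edges: np.ndarray) -> np.ndarray:
    """(n_bins, 60) electrode counts; ground element fixed at 1."""
    n_bins = len(edges) - 1
    out = np.zeros((n_bins, N_CHANNELS), dtype=int)
    for ch, times in trial.spikes.items():
        idx = np.searchsorted(times, edges, side="left")
        out[:, ch - 1] = np.diff(idx)
    out[:, GROUND_CHANNEL - 1] = 1
    return out


def bin_spike_counts(
    trial: Trial, bin_ms: float = 100.0, span: tuple[float, float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin 60-dim spike-count vectors for one trial.

    Returns ``(counts, edges)`` where ``counts`` is ``(n_bins, 60)`` with
    the ground element = 1 in every bin.  The default span is the whole
    trial, truncated to whole bins.
    """
    span = span or (trial.trial_start, trial.trial_end)
    edges = bin_edges(span, bin_ms)
    return _counts_in_bins(trial, edges), edges


def count_tensor(
    trials: list[Trial], bin_ms: float = 100.0, span: tuple[float, float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked count vectors ``(n_trials, n_bins, 60)`` on a common grid.

    Without an explicit span, the intersection of all trial spans is used so
    every trial covers every bin.
    """
    if not trials:
        raise DataError("no trials")
    if span is None:
        span = (max(t.trial_start for t in trials), min(t.trial_end for t in trials))
    edges = bin_edges(span, bin_ms)
    X = np.stack([_counts_in_bins(t, edges) for t in trials])
    return X, edges


@dataclass
class BaselineStats:
    """Per-unit mean and SD of firing rate (Hz) in inter-trial windows."""

    mean_hz: np.ndarray  # (59,)
    sd_hz: np.ndarray  # (59,)
    n_windows: int
    degenerate: bool  # fewer than 2 windows: SD is identically 0

    @property
    def threshold_hz(self) -> np.ndarray:
        return self.mean_hz + 3.0 * self.sd_hz


def intertrial_baseline(session: Session, bin_ms: float = BINARY_BIN_MS) -> BaselineStats:
    """Baseline firing statistics from non-overlapping windows tiling the
    inter-trial segments (window width matches the analysis bin)."""
    if not session.intertrial_segments:
        raise DataError(
            "no inter-trial segments: record gaps between trials or supply "
            "an explicit BaselineStats"
        )
    rates = []  # one (59,) rate vector per window
    for seg in session.intertrial_segments:
        n_win = int(np.floor(seg.duration_ms / bin_ms + 1e-9))
        if n_win == 0:
            continue
        edges = seg.start_ms + bin_ms * np.arange(n_win + 1)
        counts = np.zeros((n_win, N_CHANNELS - 1))
        for ch, times in seg.spikes.items():
            idx = np.searchsorted(times, edges, side="left")
            counts[:, ch - 1] = np.diff(idx)
        rates.append(counts / (bin_ms / 1000.0))
    if not rates:
        raise DataError("inter-trial segments shorter than one baseline window")
    r = np.concatenate(rates)
    degenerate = r.shape[0] < 2
    sd = np.zeros(N_CHANNELS - 1) if degenerate else r.std(axis=0, ddof=1)
    return BaselineStats(
        mean_hz=r.mean(axis=0), sd_hz=sd, n_windows=r.shape[0], degenerate=degenerate
    )


def binarize_trial(
    trial: Trial, baseline: BaselineStats, edges: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Binary activity vectors ``(n_bins, 60)`` for one trial.

    Bit j is 1 iff unit j's rate in the bin strictly exceeds baseline mean
    + 3 SD (with SD = 0 this degenerates to "any activity above the mean
    counts").  The ground bit is always 1.
    """
    if edges is None:
        edges = entropy_bin_edges((trial.trial_start, trial.trial_end))
    counts = _counts_in_bins(trial, edges)
    widths_s = np.diff(edges) / 1000.0
    rates = counts[:, : N_CHANNELS - 1] / widths_s[:, None]
    bits = np.zeros_like(counts)
    bits[:, : N_CHANNELS - 1] = (rates > baseline.threshold_hz[None, :]).astype(int)
    bits[:, GROUND_CHANNEL - 1] = 1
    return bits, edges


def binary_tensor(
    trials: list[Trial], baseline: BaselineStats, span: tuple[float, float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked binary vectors ``(n_trials, n_bins, 60)`` on a common grid."""
    if not trials:
        raise DataError("no trials")
    if span is None:
        span = (max(t.trial_start for t in trials), min(t.trial_end for t in trials))
    edges = entropy_bin_edges(span)
    B = np.stack([binarize_trial(t, baseline, edges)[0] for t in trials])
    return B, edges


def population_rate_series(trials: list[Trial], bin_ms: float = BINARY_BIN_MS,
                           edges: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Mean over trials of the pooled spike rate per bin, in spikes/s."""
    if not trials:
        raise DataError("no trials")
    if edges is None:
        span = (max(t.trial_start for t in trials), min(t.trial_end for t in trials))
        edges = bin_edges(span, bin_ms)
    widths_s = np.diff(edges) / 1000.0
    pooled = np.zeros(len(edges) - 1)
    for t in trials:
        counts = _counts_in_bins(t, edges)
        pooled += counts[:, : N_CHANNELS - 1].sum(axis=1)
    return pooled / len(trials) / widths_s, edges


def active_channel_series(binary: np.ndarray) -> np.ndarray:
    """Per-bin mean number of active electrodes (ground excluded) over
    trials; input is ``(n_trials, n_bins, 60)``."""
    return binary[:, :, : N_CHANNELS - 1].sum(axis=2).mean(axis=0)


def activation_probability_map(binary: np.ndarray) -> np.ndarray:
    """Per-bin per-unit probability of being active, ``(n_bins, 59)``
    (the 8x8 activation maps, ground excluded)."""
    return binary[:, :, : N_CHANNELS - 1].mean(axis=0)
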