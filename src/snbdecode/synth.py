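"""Synthetic MEA sessions with stimulus-evoked responses and injected bursts.

The generator emulates the statistical structure of optogenetically driven
cultured-network recordings: 59 electrode units firing as inhomogeneous
Poisson processes, random-dot stimuli on a 10x10 grid (18-22 dots each),
stimulus-specific recruitment through per-unit receptive fields, an
exponentially decaying reverberation of the evoked response after stimulus
offset, cue-dependent multiplicative adaptation of probe responses across a
silent 1 s delay (hidden memory), and spontaneous synchronized network
bursts (SNBs) that drive a fixed core of units at high rate while
recruiting the remaining units stochastically.

A single scalar ``excitability`` scales both the within-burst firing rate
and the recruitment probability, giving the generator a handle on the
saturation regime: past ``excitability * snb_recruit_prob >= 1`` every
burst recruits every unit and burst patterns become identical.

Bursts destroy stimulus information the way the analysis expects to see it
destroyed: a burst at or before a stimulus replaces that stimulus's evoked
recruitment profile with the stimulus-averaged profile (activity without
identity), and any burst before the probe erases the cue-specific
adaptation, so the probe response is drawn cue-independently.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .session import (
    IntertrialSegment,
    Protocol,
    Session,
    SNBClass,
    TIME_DECIMALS,
    Trial,
    TrialAnnotation,
)

_PHASES = ("pre_cue", "cue", "delay", "probe")


def default_snb_prob(protocol: str = "sequential") -> dict[str, float]:
    # spontaneous bursts interrupt ~1-5% of trials; raise for testing
    phases = ("pre_cue", "cue") if protocol == "single" else _PHASES
    return {phase: 0.01 for phase in phases}


@dataclass
class SynthConfig:
    """Parameters of the synthetic session.

    Rates are Hz per unit, durations and windows are ms.  ``snb_prob`` maps
    trial phase to the probability that a burst is injected there (at most
    one burst per trial); for the single-stimulus protocol only ``pre_cue``
    and ``cue`` apply.
    """

    protocol: str = "single"
    n_stimuli: int = 4
    trials_per_stimulus: int = 160
    n_units: int = 59
    baseline_rate: float = 0.02

    # stimuli and receptive fields
    grid_shape: tuple[int, int] = (10, 10)
    dots_range: tuple[int, int] = (18, 22)
    n_responsive_units: int = 16
    rf_size: int = 4
    evoked_rate_gain: float = 3.5  # Hz per dot overlapping a unit's field
    receptive_fields: list[np.ndarray] | None = None

    # trial timing (peristimulus ms; cue onset = 0)
    pre_window: float = 500.0
    stimulus_duration: float = 150.0
    delay_duration: float = 1050.0  # sequential only (cue offset -> probe onset)
    post_window: float | None = None  # after last stimulus offset; default per protocol
    reverberation_tau: float = 200.0
    intertrial_gap: float = 1000.0

    # hidden memory: per (cue, unit) multiplicative gain on probe responses;
    # by default each unit is either depressed or facilitated by a given
    # cue (drawn equiprobably), so the cue leaves a recruitment-pattern
    # signature in the probe response at an unchanged mean rate
    adaptation_factors: tuple[float, float] = (0.15, 1.85)
    adaptation_matrix: np.ndarray | None = None

    # synchronized network bursts
    snb_prob: dict[str, float] | None = None
    n_core_units: int = 15
    snb_unit_rate: float = 60.0  # Hz per participating unit at excitability 1
    snb_recruit_prob: float = 0.3
    excitability: float = 1.0
    snb_duration: float = 300.0
    delay_snb_gap_range: tuple[float, float] = (100.0, 300.0)

    seed: int = 0

    def __post_init__(self) -> None:
        if self.protocol not in ("single", "sequential"):
            raise ConfigError(f"unknown protocol {self.protocol!r}")
        if self.n_stimuli < 1 or self.trials_per_stimulus < 0:
            raise ConfigError("n_stimuli >= 1 and trials_per_stimulus >= 0 required")
        if self.baseline_rate < 0 or self.evoked_rate_gain < 0 or self.snb_unit_rate < 0:
            raise ConfigError("rates must be >= 0")
        if self.excitability < 0:
            raise ConfigError("excitability must be >= 0")
        lo, hi = self.dots_range
        if not (1 <= lo <= hi <= self.grid_shape[0] * self.grid_shape[1]):
            raise ConfigError("invalid dots_range")
        if self.snb_prob is None:
            self.snb_prob = default_snb_prob(self.protocol)
        for phase, p in self.snb_prob.items():
            if phase not in _PHASES:
                raise ConfigError(f"unknown SNB phase {phase!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigError("SNB probabilities must lie in [0, 1]")
        if self.protocol == "single":
            for phase in ("delay", "probe"):
                if self.snb_prob.get(phase, 0.0) > 0:
                    raise ConfigError(f"{phase} SNBs require the sequential protocol")
        if not 0.0 <= self.snb_recruit_prob <= 1.0:
            raise ConfigError("snb_recruit_prob must lie in [0, 1]")
        if self.adaptation_matrix is not None:
            m = np.asarray(self.adaptation_matrix, float)
            if m.shape != (self.n_stimuli, self.n_units) or np.any(m <= 0):
                raise ConfigError("adaptation_matrix must be (n_stimuli, n_units) and > 0")
            self.adaptation_matrix = m

    @property
    def trial_span(self) -> tuple[float, float]:
        """Peristimulus extent of one trial, ``[trial_start, trial_end)``."""
        if self.post_window is not None:
            post = self.post_window
        else:
            # defaults give a 2.0 s single trial and a 2.6 s sequential trial
            post = 1350.0 if self.protocol == "single" else 750.0
        if self.protocol == "single":
            end = self.stimulus_duration + post
        else:
            end = self.stimulus_duration + self.delay_duration + self.stimulus_duration + post
        return (-self.pre_window, end)


def generate_dot_stimuli(
    n_stimuli: int,
    seed: int | np.random.Generator = 0,
    grid_shape: tuple[int, int] = (10, 10),
    dots_range: tuple[int, int] = (18, 22),
) -> np.ndarray:
    """Random-dot patterns: boolean ``(n_stimuli, rows, cols)`` arrays.

    Each pattern lights 18-22 (inclusive) randomly positioned cells of the
    grid; patterns within one call are pairwise distinct.
    """
    if n_stimuli < 1:
        raise ConfigError("n_stimuli >= 1 required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_cells = grid_shape[0] * grid_shape[1]
    patterns: list[np.ndarray] = []
    seen: set[bytes] = set()
    while len(patterns) < n_stimuli:
        n_dots = int(rng.integers(dots_range[0], dots_range[1] + 1))
        cells = rng.choice(n_cells, size=n_dots, replace=False)
        flat = np.zeros(n_cells, dtype=bool)
        flat[cells] = True
        if flat.tobytes() in seen:
            continue
        seen.add(flat.tobytes())
        patterns.append(flat.reshape(grid_shape))
    return np.stack(patterns)


def _generate_receptive_fields(cfg: SynthConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Flat grid-cell index sets per unit; non-responsive units get empty sets."""
    n_cells = cfg.grid_shape[0] * cfg.grid_shape[1]
    fields: list[np.ndarray] = [np.empty(0, dtype=int) for _ in range(cfg.n_units)]
    responsive = rng.choice(cfg.n_units, size=min(cfg.n_responsive_units, cfg.n_units), replace=False)
    for u in responsive:
        fields[int(u)] = np.sort(rng.choice(n_cells, size=cfg.rf_size, replace=False))
    return fields


def _overlaps(fields: list[np.ndarray], patterns: np.ndarray) -> np.ndarray:
    """``(n_patterns, n_units)`` dot counts inside each unit's field."""
    flat = patterns.reshape(patterns.shape[0], -1)
    out = np.zeros((patterns.shape[0], len(fields)))
    for u, cells in enumerate(fields):
        if cells.size:
            out[:, u] = flat[:, cells].sum(axis=1)
    return out


def _poisson_homogeneous(
    rng: np.random.Generator, rate_hz: float, start: float, stop: float
) -> np.ndarray:
    if rate_hz <= 0 or stop <= start:
        return np.empty(0)
    n = rng.poisson(rate_hz * (stop - start) / 1000.0)
    return rng.uniform(start, stop, size=n)

def _poisson_exp_decay(
    rng: np.random.Generator, rate0_hz: float, onset: float, tau: float, stop: float
) -> np.ndarray:
    """Spikes under intensity ``rate0 * exp(-(t - onset)/tau)`` on [onset, stop)."""
    if rate0_hz <= 0 or stop <= onset or tau <= 0:
        return np.empty(0)
    span = stop - onset
    mass = rate0_hz * tau / 1000.0 * (1.0 - np.exp(-span / tau))
    n = rng.poisson(mass)
    if n == 0:
        return np.empty(0)
    # inverse CDF of the exponential density truncated to [0, span)
    u = rng.uniform(0.0, 1.0, size=n)
    t = -tau * np.log1p(-u * (1.0 - np.exp(-span / tau)))
    return onset + t


def _draw_snb_phase(cfg: SynthConfig, rng: np.random.Generator) -> str | None:
    """At most one burst per trial; phases drawn by their configured mass."""
    u = rng.uniform()
    acc = 0.0
    for phase in _PHASES:
        acc += cfg.snb_prob.get(phase, 0.0)
        if u < acc:
            return phase
    return None


def _snb_window(cfg: SynthConfig, phase: str, rng: np.random.Generator) -> tuple[float, float]:
    """Burst window for a phase, peristimulus ms.

    * pre_cue: burst ends at or before cue onset
    * cue: burst overlaps cue onset ("prior to or coincident with" the cue)
    * delay: burst ends 100-300 ms before the probe (the characteristic
      pre-probe pause of delay bursts)
    * probe: burst immediately precedes or coincides with the probe
    """
    d = cfg.snb_duration
    start_trial, _ = cfg.trial_span
    if phase == "pre_cue":
        lo, hi = start_trial, -d
    elif phase == "cue":
        lo, hi = -d, 0.0
    elif phase == "delay":
        probe_onset = cfg.stimulus_duration + cfg.delay_duration
        g0, g1 = cfg.delay_snb_gap_range
        lo, hi = probe_onset - d - g1, probe_onset - d - g0
    elif phase == "probe":
        probe_onset = cfg.stimulus_duration + cfg.delay_duration
        lo, hi = probe_onset - d, probe_onset
    else:  # pragma: no cover
        raise ConfigError(f"unknown phase {phase}")
    if hi < lo:
        raise ConfigError(f"trial too short for a {phase}-phase burst of {d} ms")
    start = rng.uniform(lo, hi)
    return start, start + d


def generate_session(config: SynthConfig) -> tuple[Session, list[TrialAnnotation]]:
    """Generate a session plus ground-truth annotations for every trial.

    The ground truth records the injected burst phase (mapped onto the
    segmentation classes) or, absent a burst, whether realized spiking in
    the final 200 ms of the delay makes a sequential trial ineligible as a
    control.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    sequential = cfg.protocol == "sequential"

    n_patterns = cfg.n_stimuli + (1 if sequential else 0)
    patterns = generate_dot_stimuli(n_patterns, rng, cfg.grid_shape, cfg.dots_range)
    probe_pattern_idx = cfg.n_stimuli if sequential else None

    fields = (
        cfg.receptive_fields
        if cfg.receptive_fields is not None
        else _generate_receptive_fields(cfg, rng)
    )
    if len(fields) != cfg.n_units:
        raise ConfigError("receptive_fields must list one cell set per unit")
    overlaps = _overlaps(fields, patterns)  # (n_patterns, n_units)
    mean_cue_overlap = overlaps[: cfg.n_stimuli].mean(axis=0)

    if sequential:
        if cfg.adaptation_matrix is not None:
            adapt = cfg.adaptation_matrix
        else:
            lo, hi = cfg.adaptation_factors
            adapt = np.where(
                rng.uniform(size=(cfg.n_stimuli, cfg.n_units)) < 0.5, lo, hi
            )
        adapt_mean = adapt.mean(axis=0)

    core_units = np.sort(rng.choice(cfg.n_units, size=cfg.n_core_units, replace=False))
    recruit_p = min(1.0, cfg.excitability * cfg.snb_recruit_prob)
    burst_rate = cfg.excitability * cfg.snb_unit_rate

    # balanced pseudorandom stimulus order
    labels = np.repeat(np.arange(1, cfg.n_stimuli + 1), cfg.trials_per_stimulus)
    labels = rng.permutation(labels)

    start, end = cfg.trial_span
    span = end - start
    cue_on, cue_off = 0.0, cfg.stimulus_duration
    if sequential:
        probe_on = cue_off + cfg.delay_duration
        probe_off = probe_on + cfg.stimulus_duration

    trials: list[Trial] = []
    segments: list[IntertrialSegment] = []
    truth: list[TrialAnnotation] = []
    cursor = 0.0

    for trial_id, label in enumerate(labels):
        # inter-trial gap before each trial carries pure baseline activity
        gap_spikes = {}
        for u in range(cfg.n_units):
            ts = _poisson_homogeneous(rng, cfg.baseline_rate, cursor, cursor + cfg.intertrial_gap)
            if ts.size:
                gap_spikes[u + 1] = np.round(np.sort(ts), TIME_DECIMALS)
        segments.append(
            IntertrialSegment(start_ms=cursor, end_ms=cursor + cfg.intertrial_gap, spikes=gap_spikes)
        )
        cursor += cfg.intertrial_gap
        t0 = cursor - start  # absolute time of cue onset

        phase = _draw_snb_phase(cfg, rng)
        snb_window = _snb_window(cfg, phase, rng) if phase is not None else None
        burst_before_cue = phase in ("pre_cue", "cue")

        # evoked recruitment profiles (Hz per unit); any burst erases the
        # cue-specific adaptation of the probe response
        cue_overlap = mean_cue_overlap if burst_before_cue else overlaps[label - 1]
        cue_rate = cfg.evoked_rate_gain * cue_overlap
        if sequential:
            factor = adapt_mean if phase is not None else adapt[label - 1]
            probe_rate = cfg.evoked_rate_gain * overlaps[probe_pattern_idx] * factor

        if phase is not None:
            member = np.zeros(cfg.n_units, dtype=bool)
            member[core_units] = True
            member |= rng.uniform(size=cfg.n_units) < recruit_p

        spikes: dict[int, np.ndarray] = {}
        for u in range(cfg.n_units):
            parts = [_poisson_homogeneous(rng, cfg.baseline_rate, start, end)]
            if cue_rate[u] > 0:
                parts.append(_poisson_homogeneous(rng, cue_rate[u], cue_on, cue_off))
                parts.append(
                    _poisson_exp_decay(rng, cue_rate[u], cue_off, cfg.reverberation_tau, end)
                )
            if sequential and probe_rate[u] > 0:
                parts.append(_poisson_homogeneous(rng, probe_rate[u], probe_on, probe_off))
                parts.append(
                    _poisson_exp_decay(rng, probe_rate[u], probe_off, cfg.reverberation_tau, end)
                )
            if phase is not None and member[u]:
                a, b = snb_window
                parts.append(_poisson_homogeneous(rng, burst_rate, max(a, start), min(b, end)))
            ts = np.concatenate(parts)
            ts = ts[(ts >= start) & (ts < end)]
            if ts.size:
                spikes[u + 1] = np.round(np.sort(ts), TIME_DECIMALS)

        kwargs = dict(
            trial_id=trial_id,
            cue_stimulus=int(label),
            trial_start=start,
            trial_end=end,
            cue_onset=cue_on,
            cue_offset=cue_off,
            spikes=spikes,
            t0_ms=t0,
        )
        if sequential:
            kwargs.update(
                probe_stimulus=int(probe_pattern_idx + 1),
                probe_onset=probe_on,
                probe_offset=probe_off,
            )
        trial = Trial(**kwargs)
        trials.append(trial)

        if phase is None:
            cls = SNBClass.CONTROL
            if sequential and trial.count_in_window(probe_on - 200.0, probe_on) > 0:
                cls = SNBClass.EXCLUDED_DELAY_ACTIVITY
            truth.append(TrialAnnotation(trial_id, cls))
        else:
            cls = {
                "pre_cue": SNBClass.SNB_CUE,
                "cue": SNBClass.SNB_CUE,
                "delay": SNBClass.SNB_DELAY,
                "probe": SNBClass.SNB_PROBE,
            }[phase]
            if not sequential:
                cls = SNBClass.SNB_SINGLE
            count = trial.count_in_window(*snb_window)
            truth.append(TrialAnnotation(trial_id, cls, count, snb_window))

        cursor += span

    session = Session(
        protocol=Protocol(cfg.protocol),
        trials=trials,
        intertrial_segments=segments,
        stimulus_set=tuple(range(1, cfg.n_stimuli + 1)),
    )
    return session, truth


def with_overrides(cfg: SynthConfig, **kwargs) -> SynthConfig:
    """Copy of ``cfg`` with fields replaced (convenience for sweeps)."""
    return replace(cfg, **kwargs)
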