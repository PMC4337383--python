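"""Rule-based detection of synchronized network bursts (SNBs) per trial.

Single-stimulus protocol: a trial contains an SNB when strictly more than
``single_snb_min_spikes`` pooled spikes fall in the first
``single_snb_window_ms`` of the trial (the window starts at ``trial_start``,
i.e. 500 ms before the stimulus under the default peristimulus layout).

Sequential protocol, evaluated in temporal precedence (first match wins):

1. *cue* burst: pooled count in the first ``cue_window_ms`` of the trial is
   at least ``half_mean_fraction`` times the session mean spikes per trial;
2. *delay* burst: pooled count between cue offset and probe onset reaches
   the same half-mean threshold AND the spike-free pause immediately before
   the probe (gap from the last delay spike to probe onset) lies within
   ``delay_pause_range``;
3. *probe* burst: at least ``probe_min_spikes`` pooled spikes in a 300 ms
   window anchored 100 ms before probe onset;
4. otherwise the trial is a control unless any spike falls in the final
   ``control_quiet_ms`` of the delay, in which case it is flagged
   ``excluded_delay_activity`` (ineligible as a hidden-memory control).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError
from .session import Protocol, Session, SNBClass, Trial, TrialAnnotation


@dataclass
class SegmentationParams:
    single_snb_min_spikes: int = 20
    single_snb_window_ms: float = 590.0
    cue_window_ms: float = 590.0
    half_mean_fraction: float = 0.5
    probe_min_spikes: int = 20
    # probe window relative to probe onset; 300 ms anchored 100 ms early
    probe_window: tuple[float, float] = (-100.0, 200.0)
    delay_pause_range: tuple[float, float] = (100.0, 300.0)
    control_quiet_ms: float = 200.0

    def __post_init__(self) -> None:
        if self.single_snb_min_spikes <= 0 or self.probe_min_spikes <= 0:
            raise ConfigError("spike-count thresholds must be positive")
        if self.single_snb_window_ms <= 0 or self.cue_window_ms <= 0:
            raise ConfigError("windows must be positive")
        if self.probe_window[1] <= self.probe_window[0]:
            raise ConfigError("probe window must be positive")
        lo, hi = self.delay_pause_range
        if not 0 <= lo <= hi:
            raise ConfigError("invalid delay pause range")


def detect_snb_single(trial: Trial, params: SegmentationParams | None = None) -> bool:
    """True iff pooled spikes in the first window strictly exceed the threshold."""
    params = params or SegmentationParams()
    a = trial.trial_start
    count = trial.count_in_window(a, a + params.single_snb_window_ms)
    return count > params.single_snb_min_spikes


def mean_spikes_per_trial(session: Session) -> float:
    """Arithmetic mean of the pooled spike count per trial over all trials."""
    if not session.trials:
        raise DataError("cannot take the mean of an empty session")
    return float(np.mean([t.total_spikes() for t in session.trials]))


def classify_sequential_trial(
    trial: Trial, session_mean: float, params: SegmentationParams | None = None
) -> TrialAnnotation:
    """Assign exactly one burst class to a sequential-protocol trial."""
    params = params or SegmentationParams()
    if not trial.has_probe:
        raise DataError(f"trial {trial.trial_id}: sequential classification requires probe events")
    threshold = params.half_mean_fraction * session_mean

    # 1. cue-phase burst (>= threshold; the rule fires "whenever half the
    #    mean ... occurred")
    a = trial.trial_start
    cue_window = (a, a + params.cue_window_ms)
    cue_count = trial.count_in_window(*cue_window)
    if cue_count >= threshold:
        return TrialAnnotation(trial.trial_id, SNBClass.SNB_CUE, cue_count, cue_window)

    # 2. delay-phase burst: half-mean count between cue and probe plus a
    #    spike-free pause of 100-300 ms immediately before the probe
    delay_window = (trial.cue_offset, trial.probe_onset)
    delay_count = trial.count_in_window(*delay_window)
    if delay_count >= threshold:
        last = -np.inf
        for times in trial.spikes.values():
            i = np.searchsorted(times, trial.probe_onset, "left")
            if i > 0:
                last = max(last, times[i - 1])
        pause = trial.probe_onset - last
        lo, hi = params.delay_pause_range
        if lo <= pause <= hi:
            return TrialAnnotation(trial.trial_id, SNBClass.SNB_DELAY, delay_count, delay_window)

    # 3. probe-phase burst
    pw = (trial.probe_onset + params.probe_window[0], trial.probe_onset + params.probe_window[1])
    probe_count = trial.count_in_window(*pw)
    if probe_count >= params.probe_min_spikes:
        return TrialAnnotation(trial.trial_id, SNBClass.SNB_PROBE, probe_count, pw)

    # 4. control, unless the final stretch of the delay is not silent
    quiet = (trial.probe_onset - params.control_quiet_ms, trial.probe_onset)
    quiet_count = trial.count_in_window(*quiet)
    if quiet_count > 0:
        return TrialAnnotation(
            trial.trial_id, SNBClass.EXCLUDED_DELAY_ACTIVITY, quiet_count, quiet
        )
    return TrialAnnotation(trial.trial_id, SNBClass.CONTROL)


def annotate_session(
    session: Session, params: SegmentationParams | None = None
) -> list[TrialAnnotation]:
    """Classify every trial of a session with the protocol's rules."""
    params = params or SegmentationParams()
    if session.protocol is Protocol.SINGLE:
        out = []
        for t in session.trials:
            if detect_snb_single(t, params):
                a = t.trial_start
                w = (a, a + params.single_snb_window_ms)
                out.append(
                    TrialAnnotation(t.trial_id, SNBClass.SNB_SINGLE, t.count_in_window(*w), w)
                )
            else:
                out.append(TrialAnnotation(t.trial_id, SNBClass.CONTROL))
        return out
    mean = mean_spikes_per_trial(session)
    return [classify_sequential_trial(t, mean, params) for t in session.trials]


def agreement(a: list[TrialAnnotation], b: list[TrialAnnotation]) -> float:
    """Fraction of trials on which two annotation lists assign the same class."""
    if len(a) != len(b):
        raise DataError("annotation lists cover different trial sets")
    by_id = {ann.trial_id: ann.snb_class for ann in b}
    hits = sum(1 for ann in a if by_id.get(ann.trial_id) == ann.snb_class)
    return hits / len(a) if a else 1.0
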