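"""Trial-aligned multielectrode spike data and its plain-text on-disk format.

A recording session consists of trials recorded from a 60-channel MEA
(channels 1..59 are electrodes, channel 60 is the ground and never carries
spikes).  Internally every trial lives on a *peristimulus clock*: time zero
is the onset of the (cue) stimulus, so windows such as "the first 590 ms of
the trial" translate to ``[trial_start, trial_start + 590)`` with
``trial_start`` typically at -500 ms.  On disk, times are absolute session
milliseconds; each trial records the absolute time of its cue onset
(``t0_ms``) so the two clocks convert exactly.

All windows throughout the package are half-open ``[a, b)``.

On-disk format
--------------
* spike events: CSV with header ``trial_id,channel,time_ms`` (absolute ms,
  ``.`` decimal, three decimals i.e. microsecond resolution).  Inter-trial
  spikes carry ``trial_id = -1``.
* session metadata: JSON declaring the protocol, stimulus labels, channel
  count and absolute event times per trial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

N_CHANNELS = 60
GROUND_CHANNEL = 60
ELECTRODE_CHANNELS = tuple(range(1, 60))

#: fixed on-disk time resolution (ms decimals); 1e-3 ms = 1 us
TIME_DECIMALS = 3


class Protocol(str, Enum):
    SINGLE = "single"
    SEQUENTIAL = "sequential"


class SNBClass(str, Enum):
    """Trial classes assigned by burst segmentation (or generator truth)."""

    CONTROL = "control"
    SNB_SINGLE = "snb_single"
    SNB_CUE = "snb_cue"
    SNB_DELAY = "snb_delay"
    SNB_PROBE = "snb_probe"
    EXCLUDED_DELAY_ACTIVITY = "excluded_delay_activity"


def _as_spike_dict(spikes) -> dict[int, np.ndarray]:
    out: dict[int, np.ndarray] = {}
    for ch, times in (spikes or {}).items():
        ch = int(ch)
        arr = np.asarray(times, dtype=float)
        out[ch] = arr
    return out


@dataclass
class Trial:
    """One trial on the peristimulus clock (cue onset = 0 ms).

    ``spikes`` maps electrode channel (1..59) to a sorted array of spike
    times in ms.  ``t0_ms`` is the absolute session time of cue onset.
    """

    trial_id: int
    cue_stimulus: int
    trial_start: float
    trial_end: float
    cue_onset: float = 0.0
    cue_offset: float = 0.0
    probe_stimulus: int | None = None
    probe_onset: float | None = None
    probe_offset: float | None = None
    spikes: dict[int, np.ndarray] = field(default_factory=dict)
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        self.spikes = _as_spike_dict(self.spikes)
        self.validate()

    def validate(self) -> None:
        if not (self.trial_start <= self.cue_onset < self.cue_offset <= self.trial_end):
            raise DataError(
                f"trial {self.trial_id}: event times out of order "
                f"(start={self.trial_start}, cue=[{self.cue_onset},{self.cue_offset}), "
                f"end={self.trial_end})"
            )
        if (self.probe_onset is None) != (self.probe_offset is None):
            raise DataError(f"trial {self.trial_id}: probe onset/offset must both be set")
        if self.probe_onset is not None:
            if not (self.cue_offset < self.probe_onset < self.probe_offset <= self.trial_end):
                raise DataError(f"trial {self.trial_id}: probe events out of order")
        for ch, times in self.spikes.items():
            if ch == GROUND_CHANNEL:
                raise DataError(
                    f"trial {self.trial_id}: ground channel {GROUND_CHANNEL} carries no spikes"
                )
            if not (1 <= ch < GROUND_CHANNEL):
                raise DataError(f"trial {self.trial_id}: unknown channel {ch}")
            if times.size:
                if np.any(np.diff(times) < 0):
                    raise DataError(f"trial {self.trial_id}: channel {ch} spikes not sorted")
                if times[0] < self.trial_start or times[-1] >= self.trial_end:
                    raise DataError(
                        f"trial {self.trial_id}: channel {ch} spike outside "
                        f"[{self.trial_start}, {self.trial_end})"
                    )

    @property
    def has_probe(self) -> bool:
        return self.probe_onset is not None

    def channel_spikes(self, channel: int) -> np.ndarray:
        return self.spikes.get(channel, np.empty(0))

    def count_in_window(self, start: float, stop: float, channel: int | None = None) -> int:
        """Spike count in peristimulus window ``[start, stop)``.

        Pooled across electrodes when ``channel`` is None.
        """
        if channel is not None:
            t = self.channel_spikes(channel)
            return int(np.searchsorted(t, stop, "left") - np.searchsorted(t, start, "left"))
        return sum(
            int(np.searchsorted(t, stop, "left") - np.searchsorted(t, start, "left"))
            for t in self.spikes.values()
        )

    def total_spikes(self) -> int:
        return sum(int(t.size) for t in self.spikes.values())


@dataclass
class IntertrialSegment:
    """Spikes recorded between trials, on the absolute session clock."""

    start_ms: float
    end_ms: float
    spikes: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spikes = _as_spike_dict(self.spikes)
        if self.end_ms <= self.start_ms:
            raise DataError("inter-trial segment must have positive duration")

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms

    def total_spikes(self) -> int:
        return sum(int(t.size) for t in self.spikes.values())


@dataclass
class TrialAnnotation:
    """One burst class per trial, with the evidence that triggered the rule."""

    trial_id: int
    snb_class: SNBClass
    evidence_count: int = 0
    evidence_window: tuple[float, float] | None = None

    def to_row(self) -> dict:
        w = self.evidence_window
        return {
            "trial_id": self.trial_id,
            "snb_class": self.snb_class.value,
            "evidence_count": self.evidence_count,
            "evidence_start_ms": "" if w is None else w[0],
            "evidence_end_ms": "" if w is None else w[1],
        }


@dataclass
class Session:
    """An ordered collection of trials sharing one protocol and stimulus set."""

    protocol: Protocol
    trials: list[Trial]
    intertrial_segments: list[IntertrialSegment] = field(default_factory=list)
    stimulus_set: tuple[int, ...] = ()
    n_channels: int = N_CHANNELS

    def __post_init__(self) -> None:
        self.protocol = Protocol(self.protocol)
        if not self.stimulus_set and self.trials:
            self.stimulus_set = tuple(sorted({t.cue_stimulus for t in self.trials}))
        for t in self.trials:
            if self.protocol is Protocol.SEQUENTIAL and not t.has_probe:
                raise DataError(f"trial {t.trial_id}: sequential protocol requires probe events")
            if self.protocol is Protocol.SINGLE and t.has_probe:
                raise DataError(f"trial {t.trial_id}: single protocol forbids probe events")

    def __len__(self) -> int:
        return len(self.trials)

    def cue_labels(self) -> np.ndarray:
        return np.array([t.cue_stimulus for t in self.trials], dtype=int)

    def total_spikes(self) -> int:
        return sum(t.total_spikes() for t in self.trials) + sum(
            s.total_spikes() for s in self.intertrial_segments
        )


# ---------------------------------------------------------------------------
# plain-text reader / writer
# ---------------------------------------------------------------------------


def _trial_meta(trial: Trial) -> dict:
    d = {
        "trial_id": trial.trial_id,
        "cue_stimulus": trial.cue_stimulus,
        "t0_ms": trial.t0_ms,
        "trial_start_ms": trial.t0_ms + trial.trial_start,
        "trial_end_ms": trial.t0_ms + trial.trial_end,
        "cue_onset_ms": trial.t0_ms + trial.cue_onset,
        "cue_offset_ms": trial.t0_ms + trial.cue_offset,
    }
    if trial.has_probe:
        d["probe_stimulus"] = trial.probe_stimulus
        d["probe_onset_ms"] = trial.t0_ms + trial.probe_onset
        d["probe_offset_ms"] = trial.t0_ms + trial.probe_offset
    return d


def write_session(session: Session, spike_csv, metadata_json) -> None:
    """Write a session as the CSV + JSON pair.

    Output is deterministic (trials in order, spikes sorted by time then
    channel) and ``read_session`` inverts it exactly at the stored 1 us
    time resolution.
    """
    meta = {
        "protocol": session.protocol.value,
        "n_channels": session.n_channels,
        "stimulus_set": list(session.stimulus_set),
        "trials": [_trial_meta(t) for t in session.trials],
        "intertrial_segments": [
            {"start_ms": s.start_ms, "end_ms": s.end_ms} for s in session.intertrial_segments
        ],
    }
    rows: list[tuple[int, int, float]] = []
    for trial in session.trials:
        trial.validate()
        for ch, times in trial.spikes.items():
            rows.extend((trial.trial_id, ch, trial.t0_ms + t) for t in times)
    for seg in session.intertrial_segments:
        for ch, times in seg.spikes.items():
            rows.extend((-1, ch, t) for t in times)
    rows.sort(key=lambda r: (r[2], r[1], r[0]))
    df = pd.DataFrame(rows, columns=["trial_id", "channel", "time_ms"])
    df.to_csv(spike_csv, index=False, float_format=f"%.{TIME_DECIMALS}f")
    Path(metadata_json).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_session(spike_csv, metadata_json) -> Session:
    """Read the CSV + JSON pair back into a :class:`Session`.

    Spikes are assigned to trials and inter-trial segments by time; a spike
    falling outside every declared segment, or on an invalid channel, is a
    format error.
    """
    meta = json.loads(Path(metadata_json).read_text())
    protocol = Protocol(meta["protocol"])
    trial_meta = meta["trials"]
    seg_meta = meta.get("intertrial_segments", [])

    trial_spikes: list[dict[int, list[float]]] = [dict() for _ in trial_meta]
    seg_spikes: list[dict[int, list[float]]] = [dict() for _ in seg_meta]

    trial_bounds = [(tm["trial_start_ms"], tm["trial_end_ms"]) for tm in trial_meta]
    seg_bounds = [(sm["start_ms"], sm["end_ms"]) for sm in seg_meta]

    df = pd.read_csv(spike_csv)
    expected = ["trial_id", "channel", "time_ms"]
    if list(df.columns) != expected:
        raise FormatError(f"spike table must have columns {expected}, got {list(df.columns)}")

    channels = df["channel"].to_numpy(int)
    times = df["time_ms"].to_numpy(float)
    bad = (channels < 1) | (channels >= GROUND_CHANNEL)
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        row = df.iloc[i]
        if channels[i] == GROUND_CHANNEL:
            raise FormatError(f"ground channel {GROUND_CHANNEL} carries no spikes: row {dict(row)}")
        raise FormatError(f"unknown channel index {channels[i]}: row {dict(row)}")

    # one sorted interval list over trials and inter-trial segments
    intervals = [(a, b, ("trial", i)) for i, (a, b) in enumerate(trial_bounds)]
    intervals += [(a, b, ("segment", i)) for i, (a, b) in enumerate(seg_bounds)]
    intervals.sort()
    starts = np.array([iv[0] for iv in intervals]) if intervals else np.empty(0)
    ends = np.array([iv[1] for iv in intervals]) if intervals else np.empty(0)
    if times.size:
        pos = np.searchsorted(starts, times, side="right") - 1
        outside = (pos < 0) | (times >= ends[np.clip(pos, 0, None)])
        if np.any(outside):
            i = int(np.flatnonzero(outside)[0])
            raise FormatError(f"spike outside any declared segment: row {dict(df.iloc[i])}")
        for i in range(times.size):
            kind, idx = intervals[pos[i]][2]
            target = trial_spikes if kind == "trial" else seg_spikes
            target[idx].setdefault(int(channels[i]), []).append(times[i])

    trials = []
    for tm, spk in zip(trial_meta, trial_spikes):
        t0 = float(tm["t0_ms"])
        rel = {
            ch: np.round(np.sort(np.asarray(ts, float)) - t0, TIME_DECIMALS)
            for ch, ts in spk.items()
        }
        kwargs = dict(
            trial_id=int(tm["trial_id"]),
            cue_stimulus=int(tm["cue_stimulus"]),
            trial_start=tm["trial_start_ms"] - t0,
            trial_end=tm["trial_end_ms"] - t0,
            cue_onset=tm["cue_onset_ms"] - t0,
            cue_offset=tm["cue_offset_ms"] - t0,
            spikes=rel,
            t0_ms=t0,
        )
        if "probe_onset_ms" in tm:
            kwargs.update(
                probe_stimulus=int(tm["probe_stimulus"]),
                probe_onset=tm["probe_onset_ms"] - t0,
                probe_offset=tm["probe_offset_ms"] - t0,
            )
        trials.append(Trial(**kwargs))

    segments = [
        IntertrialSegment(
            start_ms=sm["start_ms"],
            end_ms=sm["end_ms"],
            spikes={ch: np.sort(np.asarray(ts, float)) for ch, ts in spk.items()},
        )
        for sm, spk in zip(seg_meta, seg_spikes)
    ]
    return Session(
        protocol=protocol,
        trials=trials,
        intertrial_segments=segments,
        stimulus_set=tuple(meta.get("stimulus_set", ())),
        n_channels=int(meta.get("n_channels", N_CHANNELS)),
    )


def write_annotations(annotations: list[TrialAnnotation], path) -> None:
    pd.DataFrame([a.to_row() for a in annotations]).to_csv(path, index=False)


def read_annotations(path) -> list[TrialAnnotation]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        window = None
        if row.evidence_start_ms == row.evidence_start_ms:  # not NaN
            window = (float(row.evidence_start_ms), float(row.evidence_end_ms))
        out.append(
            TrialAnnotation(
                trial_id=int(row.trial_id),
                snb_class=SNBClass(row.snb_class),
                evidence_count=int(row.evidence_count),
                evidence_window=window,
            )
        )
    return out
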