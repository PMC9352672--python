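"""Event-processing layer: metric detectors, combinators, controller.

Behaviour is represented as *events* — half-open time intervals
[onset, offset) carrying a kind (power, entropy, perch, bout, contact,
syllable, sequence, directed_song, motif, video) and a source. Simple events
come from hysteresis thresholding of per-frame audio metrics or from perch
sensors; complex events are built by temporal logic over simpler streams:

    bout          = power AND entropy
    contact       = front_perch(bird 1) AND front_perch(bird 2)
    directed_song = bout AND contact

The closed-loop stimulus controller advances a looping video playlist
whenever a timeout elapses with no motif event, keeping a singing male
engaged with novel virtual females.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .audio import AudioSignal

__all__ = [
    "Event",
    "HysteresisParams",
    "SequenceEvent",
    "power_metric",
    "spectral_flatness",
    "entropy_metric",
    "frame_metrics",
    "hysteresis_events",
    "combine_and",
    "assemble_sequences",
    "stimulus_controller",
    "perch_occupancy",
    "write_events_jsonl",
    "read_events_jsonl",
]


@dataclass(frozen=True)
class Event:
    kind: str
    onset: float
    offset: float
    source_id: str = ""
    payload: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class HysteresisParams:
    """Two thresholds: ON requires crossing above on_threshold, OFF below
    off_threshold. on_threshold >= off_threshold so the band suppresses
    chatter when the metric hovers near the noise level."""

    on_threshold: float
    off_threshold: float
    metric: str = "power"

    def __post_init__(self) -> None:
        if self.on_threshold < self.off_threshold:
            raise ValueError("on_threshold must be >= off_threshold")


@dataclass(frozen=True)
class SequenceEvent:
    onset: float
    offset: float
    bird_id: str
    labels: tuple[str, ...]
    emitted_at: float


def power_metric(frame: np.ndarray) -> float:
    """Mean squared sample value of one frame."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size == 0:
        raise ValueError("empty frame")
    return float(np.mean(frame ** 2))


def spectral_flatness(magnitudes: np.ndarray) -> float:
    """Geometric mean / arithmetic mean of a magnitude spectrum (Wiener
    entropy): ~0 for a pure tone, 1 for a perfectly flat spectrum."""
    m = np.asarray(magnitudes, dtype=np.float64)
    am = m.mean()
    if am == 0:
        return 0.0
    if np.any(m == 0):
        return 0.0
    gm = np.exp(np.mean(np.log(m)))
    return float(gm / am)


def entropy_metric(frame: np.ndarray) -> float:
    """Spectral flatness of the frame's magnitude spectrum."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size == 0:
        raise ValueError("empty frame")
    return spectral_flatness(np.abs(np.fft.rfft(frame)))


def frame_metrics(signal: AudioSignal, frame_size: int = 1024,
                  hop: int = 512) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame (times, power, entropy) over a signal.

    Frame times are the frame centres in seconds. ~21 ms frames at 48 kHz
    suit call/syllable timescales.
    """
    s = signal.samples
    n_frames = max(0, 1 + (s.size - frame_size) // hop)
    times = np.empty(n_frames)
    power = np.empty(n_frames)
    entropy = np.empty(n_frames)
    for i in range(n_frames):
        fr = s[i * hop:i * hop + frame_size]
        times[i] = signal.time_of(i * hop + frame_size // 2)
        power[i] = power_metric(fr)
        entropy[i] = entropy_metric(fr)
    return times, power, entropy


def hysteresis_events(times: Sequence[float], values: Sequence[float],
                      params: HysteresisParams, source_id: str = "",
                      horizon: float | None = None) -> list[Event]:
    """Threshold a metric stream with hysteresis into ON intervals.

    The detector turns ON at the first sample strictly above on_threshold
    and OFF at the first subsequent sample strictly below off_threshold;
    values inside the band never toggle the state, which suppresses switch
    bouncing. An interval still open at the end of the stream is closed at
    ``horizon`` (default: last timestamp) and flagged in its payload.
    """
    events: list[Event] = []
    on_at: float | None = None
    for t, v in zip(times, values):
        if on_at is None:
            if v > params.on_threshold:
                on_at = float(t)
        else:
            if v < params.off_threshold:
                events.append(Event(params.metric, on_at, float(t), source_id))
                on_at = None
    if on_at is not None:
        end = float(horizon) if horizon is not None else float(times[-1])
        events.append(Event(params.metric, on_at, end, source_id,
                            {"truncated": True}))
    return events


def _check_stream(evts: Sequence[Event]) -> None:
    for a, b in zip(evts, evts[1:]):
        if b.onset < a.offset:
            raise ValueError("event stream is overlapping or unordered")


def combine_and(a: Sequence[Event], b: Sequence[Event], kind: str,
                source_id: str = "") -> list[Event]:
    """Interval intersection of two event streams (both active simultaneously).

    Inputs must each be time-ordered and non-overlapping. Used for
    bout = power AND entropy, contact = front(bird1) AND front(bird2),
    directed_song = bout AND contact.
    """
    _check_stream(a)
    _check_stream(b)
    out: list[Event] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i].onset, b[j].onset)
        hi = min(a[i].offset, b[j].offset)
        if lo < hi:
            out.append(Event(kind, lo, hi, source_id))
        if a[i].offset <= b[j].offset:
            i += 1
        else:
            j += 1
    return out


def assemble_sequences(syllables: Sequence[Event], gap_window: float = 0.5,
                       emit_delay: float = 3.0) -> list[SequenceEvent]:
    """Chain syllable events into sequences by inter-syllable gap.

    A syllable whose onset falls strictly within ``gap_window`` seconds of
    the previous offset extends the current sequence; otherwise it opens a
    new one. Each sequence is emitted once the gap window has elapsed after
    its last syllable (``emitted_at = offset + gap_window``, always within
    ``emit_delay`` of the sequence end).
    """
    out: list[SequenceEvent] = []
    cur: list[Event] = []

    def close() -> None:
        if cur:
            out.append(SequenceEvent(
                onset=cur[0].onset, offset=cur[-1].offset,
                bird_id=cur[0].source_id,
                labels=tuple(e.payload.get("label", "") for e in cur),
                emitted_at=min(cur[-1].offset + gap_window,
                               cur[-1].offset + emit_delay)))

    for ev in syllables:
        if cur and ev.onset - cur[-1].offset < gap_window:
            cur.append(ev)
        else:
            close()
            cur = [ev]
    close()
    return out


def stimulus_controller(motif_events: Sequence[Event], n_videos: int,
                        timeout: float = 180.0, start: float = 0.0,
                        horizon: float | None = None) -> list[Event]:
    """Closed-loop video switching driven by motif detections.

    A timer of ``timeout`` seconds is reset by every motif event (and by
    every video change). Whenever the timer expires the next video in the
    cyclic playlist is displayed. With no motifs at all, changes fall at
    start + timeout, start + 2*timeout, ... up to and including the horizon.
    Returned events are instantaneous video-change events whose payload
    holds the new video index.
    """
    if n_videos < 1:
        raise ValueError("need at least one video")
    if horizon is None:
        horizon = max((e.onset for e in motif_events), default=start)
    changes: list[Event] = []
    video = 0
    last_reset = start
    onsets = sorted(e.onset for e in motif_events)
    for t in list(onsets) + [None]:
        boundary = horizon if t is None else t
        while last_reset + timeout <= boundary:
            last_reset += timeout
            video = (video + 1) % n_videos
            changes.append(Event("video", last_reset, last_reset,
                                 payload={"video": video}))
        if t is not None:
            last_reset = t
    return changes


def perch_occupancy(perch_events: Sequence[Event],
                    horizon: float) -> dict[str, float]:
    """Proportion of [0, horizon) spent in each perch state.

    Events must be non-overlapping; uncovered time is attributed to
    ``"other"``. Each event's payload carries its state under "state" (or
    the event's kind is used). Proportions sum to 1.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    evts = sorted(perch_events, key=lambda e: e.onset)
    _check_stream(evts)
    totals: dict[str, float] = {}
    covered = 0.0
    for e in evts:
        lo, hi = max(0.0, e.onset), min(horizon, e.offset)
        if hi <= lo:
            continue
        state = e.payload.get("state", e.kind)
        totals[state] = totals.get(state, 0.0) + (hi - lo)
        covered += hi - lo
    if covered < horizon - 1e-12:
        totals["other"] = totals.get("other", 0.0) + (horizon - covered)
    return {k: v / horizon for k, v in totals.items()}


def write_events_jsonl(path, events: Iterable[Event]) -> None:
    with open(path, "w") as fh:
        for e in events:
            fh.write(json.dumps({"kind": e.kind, "onset": e.onset,
                                 "offset": e.offset, "source_id": e.source_id,
                                 "payload": e.payload}) + "\n")


def read_events_jsonl(path) -> list[Event]:
    out = []
    for line in Path(path).read_text().splitlines():
        if line.strip():
            d = json.loads(line)
            out.append(Event(d["kind"], d["onset"], d["offset"],
                             d.get("source_id", ""), d.get("payload", {})))
    return out
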