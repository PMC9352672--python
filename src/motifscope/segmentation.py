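"""Two-threshold amplitude segmentation of song syllables.

A candidate syllable is triggered when the absolute sample value exceeds the
on-threshold. From the trigger, the onset is found by searching backwards for
the last index whose trailing peak-to-peak amplitude over a window of ``w``
samples falls below the off-threshold, and the offset by searching forwards
for the first index whose leading window does. Candidates outside the
expected syllable duration band (30-300 ms for zebra finches) are discarded.

Both an offline (whole-buffer) and an online (chunked) implementation are
provided; they are guaranteed to produce identical segments on identical
audio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .audio import AudioSignal

__all__ = [
    "SegmentationParams",
    "Segment",
    "detect_trigger",
    "segment_signal",
    "segment_stream",
    "StreamSegmenter",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds and duration band for amplitude segmentation.

    ``t_on`` applies to the absolute sample value; ``t_off`` applies to the
    peak-to-peak amplitude over ``w`` samples. The two are independent
    parameters even though the defaults coincide.
    """

    t_on: float = 0.5
    t_off: float = 0.5
    w: int = 325
    min_dur: float = 0.030
    max_dur: float = 0.300

    def __post_init__(self) -> None:
        if self.t_on <= 0 or self.t_off <= 0:
            raise ValueError("thresholds must be positive")
        if self.w < 1:
            raise ValueError("window length w must be >= 1")
        if not 0 < self.min_dur < self.max_dur:
            raise ValueError("need 0 < min_dur < max_dur")


@dataclass(frozen=True)
class Segment:
    """A detected span of sound, half-open in sample indices [onset, offset)."""

    onset: int
    offset: int
    samples: np.ndarray
    sample_rate: float
    source_id: str = ""
    start_time: float = 0.0
    truncated: bool = False

    @property
    def onset_s(self) -> float:
        return self.start_time + self.onset / self.sample_rate

    @property
    def offset_s(self) -> float:
        return self.start_time + self.offset / self.sample_rate

    @property
    def duration(self) -> float:
        return (self.offset - self.onset) / self.sample_rate


class _Candidate(NamedTuple):
    i_on: int
    onset: int
    offset: int
    truncated: bool


def _window_ptp(s: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Peak-to-peak over trailing [i-w, i] and leading [i, i+w] windows.

    Windows are clipped at the buffer edges (``mode='nearest'`` replicates
    the edge sample, which leaves max/min over the clipped window unchanged).
    """
    size = w + 1
    back_origin = (size - 1) // 2  # shifts the window to end at index i

    def trailing_ptp(x: np.ndarray) -> np.ndarray:
        return (maximum_filter1d(x, size, mode="nearest", origin=back_origin)
                - minimum_filter1d(x, size, mode="nearest", origin=back_origin))

    back = trailing_ptp(s)
    fwd = trailing_ptp(s[::-1])[::-1]  # leading window = trailing on reversal
    # Backward (onset) windows are clipped at the buffer start: a file opens
    # in silence and the stream's earlier history is unavailable. Forward
    # (offset) windows must be complete — at the end of the data the future
    # is unknown, so an offset cannot be declared there; the candidate is
    # closed at the boundary and flagged instead.
    if s.size > w:
        fwd[s.size - w:] = np.inf
    else:
        fwd[:] = np.inf
    return back, fwd


def _scan(s: np.ndarray, p: SegmentationParams) -> list[_Candidate]:
    """Sequential left-to-right scan emitting unfiltered segment candidates.

    After each candidate, scanning resumes at offset + 1 so one syllable can
    never produce two overlapping segments.
    """
    n = s.size
    if n == 0:
        return []
    back_ptp, fwd_ptp = _window_ptp(s, p.w)
    idx = np.arange(n)
    prev_quiet = np.maximum.accumulate(np.where(back_ptp < p.t_off, idx, -1))
    nq = np.where(fwd_ptp < p.t_off, idx, n)
    next_quiet = np.minimum.accumulate(nq[::-1])[::-1]
    triggers = np.flatnonzero(np.abs(s) > p.t_on)

    out: list[_Candidate] = []
    pos = 0
    ti = 0
    while ti < triggers.size:
        ti = np.searchsorted(triggers, pos)
        if ti >= triggers.size:
            break
        i_on = int(triggers[ti])
        onset = int(prev_quiet[i_on])
        truncated = False
        if onset < 0:
            onset, truncated = 0, True
        offset = int(next_quiet[i_on])
        if offset >= n:
            offset, truncated = n, True
        out.append(_Candidate(i_on, onset, offset, truncated))
        pos = offset + 1
    return out


def detect_trigger(signal: AudioSignal, params: SegmentationParams) -> list[int]:
    """Indices where |s_i| crosses the on-threshold outside emitted segments.

    One trigger is reported per candidate segment (the sample that initiated
    its back/forward search), including candidates later removed by the
    duration filter.
    """
    return [c.i_on for c in _scan(signal.samples, params)]


def _build(signal: AudioSignal, cands: Iterable[_Candidate],
           p: SegmentationParams) -> list[Segment]:
    segs = []
    for c in cands:
        dur = (c.offset - c.onset) / signal.sample_rate
        if p.min_dur <= dur <= p.max_dur:
            segs.append(Segment(
                onset=c.onset, offset=c.offset,
                samples=signal.samples[c.onset:c.offset].copy(),
                sample_rate=signal.sample_rate,
                source_id=signal.source_id,
                start_time=signal.start_time,
                truncated=c.truncated,
            ))
    return segs


def segment_signal(signal: AudioSignal,
                   params: SegmentationParams | None = None) -> list[Segment]:
    """Offline segmentation of a whole buffer.

    Returns time-ordered, non-overlapping segments whose durations lie in
    [min_dur, max_dur]. Candidates whose onset or offset search ran into the
    buffer boundary are truncated there and flagged.
    """
    p = params or SegmentationParams()
    return _build(signal, _scan(signal.samples, p), p)


class StreamSegmenter:
    """Online segmentation over contiguous chunks.

    Emits exactly the segments the offline algorithm would produce on the
    concatenated audio: a candidate is released only once its forward quiet
    window lies fully inside the received data, which makes it final. Call
    :meth:`flush` after the last chunk to release any boundary-truncated
    candidate.
    """

    def __init__(self, params: SegmentationParams | None = None) -> None:
        self.params = params or SegmentationParams()
        self._buf: np.ndarray | None = None
        self._meta: AudioSignal | None = None
        self._emitted = 0

    def _signal(self) -> AudioSignal:
        assert self._meta is not None and self._buf is not None
        return AudioSignal(self._buf, self._meta.sample_rate,
                           self._meta.start_time, self._meta.source_id)

    def process(self, chunk: AudioSignal) -> list[Segment]:
        if len(chunk) == 0 and self._buf is None:
            return []
        if self._buf is None:
            self._meta = chunk
            self._buf = np.asarray(chunk.samples, dtype=np.float64)
        else:
            assert self._meta is not None
            if chunk.sample_rate != self._meta.sample_rate:
                raise ValueError("sample_rate changed mid-stream")
            if chunk.start_time != 0.0:
                expected = self._meta.start_time + self._buf.size / self._meta.sample_rate
                if abs(chunk.start_time - expected) > 0.5 / self._meta.sample_rate:
                    raise ValueError(
                        f"discontiguous chunk: starts at {chunk.start_time:.6f}s, "
                        f"expected {expected:.6f}s")
            self._buf = np.concatenate([self._buf, chunk.samples])
        return self._release(final=False)

    def _release(self, final: bool) -> list[Segment]:
        assert self._buf is not None
        cands = _scan(self._buf, self.params)
        if not final:
            # Final iff the leading quiet window [offset, offset+w] is complete.
            safe = []
            for c in cands:
                if c.offset + self.params.w < self._buf.size and not c.truncated:
                    safe.append(c)
                else:
                    break
            cands = safe
        new = cands[self._emitted:]
        self._emitted = len(cands)
        return _build(self._signal(), new, self.params)

    def flush(self) -> list[Segment]:
        if self._buf is None:
            return []
        return self._release(final=True)


def segment_stream(chunks: Iterable[AudioSignal],
                   params: SegmentationParams | None = None) -> Iterator[Segment]:
    """Incremental segmentation of contiguous chunks (see :class:`StreamSegmenter`)."""
    seg = StreamSegmenter(params)
    for chunk in chunks:
        yield from seg.process(chunk)
    yield from seg.flush()
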