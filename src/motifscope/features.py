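"""Compressed-spectrogram syllable features.

Each segment is turned into a fixed-length feature vector by (1) a magnitude
STFT whose window exactly fits the shortest admissible syllable, (2) cropping
to the zebra-finch audible band 200 Hz - 8 kHz, (3) cropping/zero-padding the
time axis to a fixed number of columns spanning the longest admissible
syllable, and (4) summing the spectrogram over time and over frequency and
normalizing each profile to unit mass. At the defaults (48 kHz, 30-300 ms,
512 time bins) this yields 234 frequency bins + 512 time bins = a
746-dimensional vector.

Naming note: ``F_t`` is the sum OVER time, i.e. a frequency profile, and
``F_f`` the sum over frequency, i.e. a time profile — the subscript names the
summation axis, not the remaining one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window, stft

from .segmentation import Segment

__all__ = [
    "SpectrogramParams",
    "SegmentSpectrogram",
    "SyllableFeatures",
    "derive_stft_params",
    "compute_spectrogram",
    "extract_features",
    "featurize_segment",
]


@dataclass(frozen=True)
class SpectrogramParams:
    fft_size: int = 1440
    stride: int = 25
    f_low: float = 200.0
    f_high: float = 8000.0
    max_time_bins: int = 512
    window: str = "boxcar"  # bare STFT; "hann" available

    def __post_init__(self) -> None:
        if self.fft_size < 1 or self.stride < 1 or self.max_time_bins < 1:
            raise ValueError("fft_size, stride and max_time_bins must be >= 1")
        if not 0 <= self.f_low < self.f_high:
            raise ValueError("need 0 <= f_low < f_high")

    def freq_bins(self, sample_rate: float) -> np.ndarray:
        """Indices of FFT bins retained by the band crop.

        A bin is kept iff its centre frequency lies in [f_low, f_high).
        The half-open interval reproduces 234 bins at 48 kHz / FFT 1440.
        """
        if self.f_high > sample_rate / 2:
            raise ValueError("f_high exceeds Nyquist")
        freqs = np.arange(self.fft_size // 2 + 1) * sample_rate / self.fft_size
        return np.flatnonzero((freqs >= self.f_low) & (freqs < self.f_high))


@dataclass(frozen=True)
class SegmentSpectrogram:
    """Band-cropped magnitude spectrogram, n_freq_bins x max_time_bins."""

    magnitudes: np.ndarray
    freq_bin_hz: float
    n_frames: int  # columns actually computed from audio (rest are zero pad)
    params: SpectrogramParams


@dataclass(frozen=True)
class SyllableFeatures:
    """Unit-sum frequency profile F_t, time profile F_f, and concatenation F."""

    F_t: np.ndarray
    F_f: np.ndarray

    @property
    def F(self) -> np.ndarray:
        return np.concatenate([self.F_t, self.F_f])

    def __len__(self) -> int:
        return self.F_t.size + self.F_f.size


def derive_stft_params(min_dur: float, max_dur: float, sample_rate: float,
                       target_time_bins: int = 512, **kwargs) -> SpectrogramParams:
    """Derive FFT size and stride from the syllable duration band.

    The FFT window is the largest that fits the shortest syllable
    (``floor(min_dur * sample_rate)``); the stride then spreads the longest
    syllable over ``target_time_bins`` columns:
    ``round((max_dur * sample_rate - fft_size) / target_time_bins)``.

    At (30 ms, 300 ms, 48 kHz, 512) this gives fft_size=1440, stride=25.
    """
    if not 0 < min_dur < max_dur:
        raise ValueError("need 0 < min_dur < max_dur")
    if target_time_bins < 1:
        raise ValueError("target_time_bins must be >= 1")
    fft_size = int(np.floor(min_dur * sample_rate))
    stride = round((max_dur * sample_rate - fft_size) / target_time_bins)
    if stride < 1:
        raise ValueError(
            f"derived stride {stride} < 1: target_time_bins={target_time_bins} "
            "exceeds the number of available frames")
    return SpectrogramParams(fft_size=fft_size, stride=stride,
                             max_time_bins=target_time_bins, **kwargs)


def compute_spectrogram(segment: Segment,
                        params: SpectrogramParams | None = None) -> SegmentSpectrogram:
    """Magnitude STFT of a segment, band-cropped and fixed to max_time_bins columns.

    Frames are fully contained in the (possibly zero-padded) segment: a
    minimum-length segment yields exactly one computed frame. Columns beyond
    the available frames are zero; frames beyond max_time_bins are dropped.
    """
    p = params or SpectrogramParams()
    x = np.asarray(segment.samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot compute spectrogram of an empty segment")
    if x.size < p.fft_size:
        x = np.pad(x, (0, p.fft_size - x.size))
    _, _, Z = stft(x, fs=segment.sample_rate, window=get_window(p.window, p.fft_size),
                   nperseg=p.fft_size, noverlap=p.fft_size - p.stride,
                   boundary=None, padded=False, scaling="spectrum")
    mag = np.abs(Z)
    keep = p.freq_bins(segment.sample_rate)
    mag = mag[keep]
    n_frames = min(mag.shape[1], p.max_time_bins)
    out = np.zeros((keep.size, p.max_time_bins))
    out[:, :n_frames] = mag[:, :n_frames]
    return SegmentSpectrogram(out, segment.sample_rate / p.fft_size, n_frames, p)


def extract_features(spec: SegmentSpectrogram) -> SyllableFeatures:
    """Sum the spectrogram over time and frequency; normalize each to unit sum."""
    F_t = spec.magnitudes.sum(axis=1)  # over time -> frequency profile
    F_f = spec.magnitudes.sum(axis=0)  # over frequency -> time profile
    st, sf = F_t.sum(), F_f.sum()
    if st == 0 or sf == 0:
        raise ValueError("all-zero spectrogram: features undefined; discard segment")
    return SyllableFeatures(F_t / st, F_f / sf)


def featurize_segment(segment: Segment,
                      params: SpectrogramParams | None = None) -> SyllableFeatures:
    """Segment -> spectrogram -> features in one call."""
    return extract_features(compute_spectrogram(segment, params))
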