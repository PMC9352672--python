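"""Audio containers and WAV I/O.

Audio is carried as a mono float array normalized to [-1, 1], the form the
segmentation thresholds are defined on. WAV files are read through
:mod:`scipy.io.wavfile`; integer PCM is rescaled to float on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.io import wavfile

__all__ = ["AudioSignal", "read_wav", "write_wav"]


@dataclass(frozen=True)
class AudioSignal:
    """A mono audio buffer with a sample rate and a time origin.

    Parameters
    ----------
    samples
        1-D float array. After :meth:`normalized`, all values lie in [-1, 1].
    sample_rate
        Sampling frequency in Hz.
    start_time
        Time (seconds) of sample 0, used when stitching streamed chunks.
    source_id
        Identifier of the bird / channel this buffer came from.
    """

    samples: np.ndarray
    sample_rate: float = 48000.0
    start_time: float = 0.0
    source_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=np.float64).ravel()
        )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def time_of(self, index: int) -> float:
        """Absolute time in seconds of a sample index."""
        return self.start_time + index / self.sample_rate

    def normalized(self) -> "AudioSignal":
        """Peak-normalize to [-1, 1]. A silent buffer is returned unchanged."""
        peak = np.max(np.abs(self.samples)) if self.samples.size else 0.0
        if peak == 0.0:
            return self
        return replace(self, samples=self.samples / peak)


def read_wav(path, channel: int = 0, normalize: bool = True,
             source_id: str | None = None) -> AudioSignal:
    """Read a WAV file into an :class:`AudioSignal`.

    Integer PCM is scaled by the type's full range; multi-channel files are
    reduced to the requested ``channel``.
    """
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[:, channel]
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        data = data.astype(np.float64) / max(abs(info.min), info.max)
    else:
        data = data.astype(np.float64)
    sig = AudioSignal(data, float(rate),
                      source_id=source_id if source_id is not None else str(path))
    return sig.normalized() if normalize else sig


def write_wav(path, signal: AudioSignal) -> None:
    """Write an :class:`AudioSignal` as 16-bit PCM."""
    clipped = np.clip(signal.samples, -1.0, 1.0)
    wavfile.write(path, int(signal.sample_rate),
                  (clipped * 32767).astype(np.int16))
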