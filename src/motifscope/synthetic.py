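"""Synthetic zebra-finch-like song and event fixtures with known ground truth.

Real song recordings are not redistributable, so every module is exercised
on generated audio that mimics the coarse structure of zebra finch song:
30-300 ms syllables (harmonic stacks with fundamentals of 400-1000 Hz,
linear frequency sweeps, noise bursts), introductory notes, a stereotyped
motif repeated several times per bout, sub-500 ms gaps within bouts and
longer silences between them, plus a low Gaussian noise floor. The acoustic
model is deliberately minimal — sinusoid sums, not vocal production — which
is sufficient for syllable types to form separable clusters in feature
space but does not reproduce natural within-type variability.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .audio import AudioSignal
from .events import Event

__all__ = [
    "SyllableSpec",
    "SongSpec",
    "render_syllable",
    "render_song",
    "render_syllable_dataset",
    "generate_label_sequences",
    "render_event_streams",
    "default_motif",
]

RAMP_S = 0.005  # cosine on/off ramp


@dataclass(frozen=True)
class SyllableSpec:
    """One syllable type: harmonic stack, frequency sweep, or noise burst."""

    kind: str = "harmonic_stack"
    label: str = "A"
    ff: float = 600.0
    n_harmonics: int = 4
    f_start: float = 2000.0
    f_end: float = 6000.0
    duration: float = 0.1
    amplitude: float = 0.9

    def __post_init__(self) -> None:
        if self.kind not in ("harmonic_stack", "sweep", "noise_burst"):
            raise ValueError(f"unknown syllable kind {self.kind!r}")
        if not 0 <= self.amplitude <= 1:
            raise ValueError("amplitude must be in [0, 1]")


def default_motif() -> list[SyllableSpec]:
    """A four-syllable motif of distinct types (plus see SongSpec.intro)."""
    return [
        SyllableSpec("harmonic_stack", "A", ff=450, n_harmonics=6, duration=0.12),
        SyllableSpec("sweep", "B", f_start=6000, f_end=2000, duration=0.08),
        SyllableSpec("harmonic_stack", "C", ff=850, n_harmonics=4, duration=0.15),
        SyllableSpec("noise_burst", "D", duration=0.06),
    ]


@dataclass(frozen=True)
class SongSpec:
    """Layout of a synthetic song recording."""

    motif: tuple[SyllableSpec, ...] = field(
        default_factory=lambda: tuple(default_motif()))
    intro: SyllableSpec = SyllableSpec("harmonic_stack", "i", ff=550,
                                       n_harmonics=3, duration=0.045,
                                       amplitude=0.7)
    n_intro: int = 2
    repeats_per_bout: int = 3
    n_bouts: int = 3
    gap: float = 0.08        # within-bout inter-syllable gap, < 0.5 s
    bout_gap: float = 1.0    # between-bout silence, > 0.5 s
    noise_floor: float = 0.0  # RMS of additive Gaussian noise
    label_noise: float = 0.0  # probability of substituting a random syllable
    ff_jitter: float = 0.0    # per-rendition pitch jitter (relative sd)
    dur_jitter: float = 0.0   # per-rendition duration jitter (relative sd)
    timbre_jitter: float = 0.0  # per-rendition harmonic/envelope jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.gap < 0.5 < self.bout_gap:
            raise ValueError("need gap < 0.5 s < bout_gap")


def render_syllable(spec: SyllableSpec, sample_rate: float = 48000.0,
                    rng: np.random.Generator | None = None,
                    timbre_jitter: float = 0.0) -> np.ndarray:
    """Waveform of one syllable with 5 ms cosine on/off ramps.

    Harmonic stacks sum n_harmonics sinusoids at k*ff with 1/k amplitudes;
    sweeps are a single linear chirp; noise bursts are white Gaussian noise.
    ``timbre_jitter`` is the log-normal sd of per-rendition multiplicative
    jitter on each harmonic's amplitude (and on the sweep's envelope tilt),
    emulating the many-dimensional rendition-to-rendition variability of
    real vocalizations.
    """
    n = int(round(spec.duration * sample_rate))
    t = np.arange(n) / sample_rate
    if spec.kind == "harmonic_stack":
        if spec.ff * spec.n_harmonics >= sample_rate / 2:
            raise ValueError("highest harmonic at or above Nyquist")
        weights = 1.0 / np.arange(1, spec.n_harmonics + 1)
        if timbre_jitter > 0 and rng is not None:
            weights = weights * np.exp(rng.normal(0, timbre_jitter, weights.size))
        y = sum(w * np.sin(2 * np.pi * k * spec.ff * t)
                for k, w in enumerate(weights, start=1))
    elif spec.kind == "sweep":
        # instantaneous frequency: linear ramp plus a jittered sinusoidal bend
        frac = t / spec.duration
        freq = spec.f_start + (spec.f_end - spec.f_start) * frac
        if timbre_jitter > 0 and rng is not None and n > 1:
            bend = rng.normal(0, timbre_jitter) * 0.15 * abs(spec.f_end - spec.f_start)
            freq = freq + bend * np.sin(np.pi * frac)
        phase = 2 * np.pi * np.cumsum(freq) / sample_rate
        y = np.sin(phase)
        if timbre_jitter > 0 and rng is not None and n > 1:
            tilt = rng.normal(0, timbre_jitter)
            y = y * np.exp(tilt * (frac - 0.5))
    else:  # noise_burst: band-limited noise, band edges jittered per rendition
        rng = rng or np.random.default_rng(0)
        lo, hi = 2000.0, 7000.0
        if timbre_jitter > 0:
            lo *= np.exp(rng.normal(0, 0.3 * timbre_jitter))
            hi *= np.exp(rng.normal(0, 0.3 * timbre_jitter))
        spectrum = np.fft.rfft(rng.standard_normal(n))
        f = np.fft.rfftfreq(n, 1 / sample_rate)
        spectrum[(f < lo) | (f > min(hi, sample_rate / 2))] = 0
        y = np.fft.irfft(spectrum, n)
    peak = np.max(np.abs(y)) if n else 1.0
    if peak > 0:
        y = y / peak * spec.amplitude
    ramp_n = min(int(RAMP_S * sample_rate), n // 2)
    if ramp_n > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        y[:ramp_n] *= ramp
        y[-ramp_n:] *= ramp[::-1]
    return y


def render_song(spec: SongSpec,
                sample_rate: float = 48000.0) -> tuple[AudioSignal, pd.DataFrame]:
    """Render a full recording and its ground-truth syllable table.

    Each bout is ``n_intro`` introductory notes followed by
    ``repeats_per_bout`` motif repetitions; bouts are separated by
    ``bout_gap`` and the recording is padded by ``bout_gap`` at both ends.
    With ``label_noise`` > 0, each planted syllable may be substituted by a
    random one from the repertoire (the truth table records what was
    actually sung). Returns the signal and a DataFrame with columns
    onset_sample, offset_sample, onset_s, offset_s, label.
    """
    rng = np.random.default_rng(spec.seed)
    repertoire = list(spec.motif) + [spec.intro]
    plan: list[SyllableSpec] = []
    bout_breaks: list[int] = []  # index into plan where each bout starts
    for _ in range(spec.n_bouts):
        bout_breaks.append(len(plan))
        plan.extend([spec.intro] * spec.n_intro)
        for _ in range(spec.repeats_per_bout):
            plan.extend(spec.motif)

    pieces: list[np.ndarray] = []
    rows = []
    cursor = int(round(spec.bout_gap * sample_rate))
    pieces.append(np.zeros(cursor))
    bout_set = set(bout_breaks)
    for i, syl in enumerate(plan):
        if i in bout_set and i > 0:
            gap_n = int(round(spec.bout_gap * sample_rate))
        elif i > 0:
            gap_n = int(round(spec.gap * sample_rate))
        else:
            gap_n = 0
        if gap_n:
            pieces.append(np.zeros(gap_n))
            cursor += gap_n
        if spec.label_noise > 0 and rng.random() < spec.label_noise:
            syl = repertoire[rng.integers(len(repertoire))]
        if spec.ff_jitter > 0 or spec.dur_jitter > 0:
            pitch = 1 + rng.normal(0, spec.ff_jitter) if spec.ff_jitter else 1.0
            dur = float(np.clip(
                syl.duration * (1 + rng.normal(0, spec.dur_jitter)), 0.03, 0.3)
            ) if spec.dur_jitter else syl.duration
            syl = replace(syl, duration=dur, ff=syl.ff * pitch,
                          f_start=syl.f_start * pitch, f_end=syl.f_end * pitch)
        y = render_syllable(syl, sample_rate, rng,
                            timbre_jitter=spec.timbre_jitter)
        pieces.append(y)
        rows.append({"onset_sample": cursor, "offset_sample": cursor + y.size,
                     "onset_s": cursor / sample_rate,
                     "offset_s": (cursor + y.size) / sample_rate,
                     "label": syl.label})
        cursor += y.size
    pieces.append(np.zeros(int(round(spec.bout_gap * sample_rate))))
    samples = np.concatenate(pieces)
    if spec.noise_floor > 0:
        samples = samples + rng.normal(0, spec.noise_floor, samples.size)
        samples = np.clip(samples, -1, 1)
    return AudioSignal(samples, sample_rate, source_id="synthetic"), pd.DataFrame(rows)


def render_syllable_dataset(specs: list[SyllableSpec] | None = None,
                            n_per_type: int = 1000, seed: int = 0,
                            sample_rate: float = 48000.0,
                            ff_jitter: float = 0.01,
                            dur_jitter: float = 0.02,
                            timbre_jitter: float = 0.3,
                            noise_floor: float = 0.005
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Feature vectors for jittered renditions of each syllable type.

    Emulates a per-bird training set at desk scale: each rendition perturbs
    the fundamental (or sweep endpoints) and the duration by Gaussian
    relative jitters (sd ``ff_jitter`` and ``dur_jitter``; durations clipped
    to the 30-300 ms band), adds a noise floor, and featurizes the result.
    The default jitters are of the order of rendition-to-rendition
    variability of stereotyped zebra finch song (duration and
    fundamental-frequency CVs of a few percent at most); Gaussian jitter
    gives each type a density mode in feature space, as repeated stereotyped
    renditions do. Returns (features, labels) where features is
    (n_types * n_per_type) x 746 at the default spectrogram parameters.
    """
    from .features import featurize_segment
    from .segmentation import Segment

    specs = specs if specs is not None else default_motif() + [
        SyllableSpec("harmonic_stack", "E", ff=650, n_harmonics=2, duration=0.2)]
    rng = np.random.default_rng(seed)
    feats, labels = [], []
    for s in specs:
        for _ in range(n_per_type):
            dur = float(np.clip(s.duration * (1 + rng.normal(0, dur_jitter)),
                                0.03, 0.3))
            pitch = 1 + rng.normal(0, ff_jitter)  # whole-syllable pitch shift
            jittered = replace(s, duration=dur, ff=s.ff * pitch,
                               f_start=s.f_start * pitch, f_end=s.f_end * pitch)
            y = render_syllable(jittered, sample_rate, rng,
                                timbre_jitter=timbre_jitter)
            if noise_floor > 0:
                y = y + rng.normal(0, noise_floor, y.size)
            seg = Segment(0, y.size, y, sample_rate, source_id=s.label)
            feats.append(featurize_segment(seg).F)
            labels.append(s.label)
    return np.asarray(feats), np.asarray(labels)


def generate_label_sequences(cycle, n_sequences: int = 200, seed: int = 0,
                             repeats=(2, 5), n_intro=(0, 4),
                             label_noise: float = 0.1,
                             alphabet=None) -> list[list[str]]:
    """Bout-like label sequences built on a planted motif cycle.

    Each sequence is a run of introductory notes followed by several full
    motif repetitions; every token is independently replaced by a random
    alphabet label with probability ``label_noise``.
    """
    cycle = list(cycle)
    alphabet = list(alphabet) if alphabet is not None else cycle + ["i"]
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_sequences):
        seq = ["i"] * int(rng.integers(n_intro[0], n_intro[1] + 1))
        seq += cycle * int(rng.integers(repeats[0], repeats[1] + 1))
        seq = [alphabet[rng.integers(len(alphabet))]
               if rng.random() < label_noise else t for t in seq]
        out.append(seq)
    return out


def render_event_streams(scenario: dict) -> dict:
    """Event fixtures with known intersections and timing statistics.

    ``scenario`` keys (all optional):
      perch: {bird_id: [(state, onset, offset), ...]} -> perch Events
      playbacks: list of playback onsets (s)
      call_delay_mode / call_delay_sd: own-call delay distribution (s)
      motif_onsets: list of motif detection times (s)
      seed: RNG seed for the call delays

    Returns {"perch": {...}, "playbacks": [...], "calls": [...],
    "motifs": [...], "meta": {...}} with the planted parameters recorded in
    ``meta``.
    """
    rng = np.random.default_rng(scenario.get("seed", 0))
    out: dict = {"meta": {}}
    perch = {}
    for bird, sched in scenario.get("perch", {}).items():
        perch[bird] = [Event("perch", t0, t1, bird, {"state": state})
                       for state, t0, t1 in sched]
    out["perch"] = perch
    playbacks = list(scenario.get("playbacks", []))
    out["playbacks"] = playbacks
    mode = scenario.get("call_delay_mode", 0.29)
    sd = scenario.get("call_delay_sd", 0.05)
    calls = []
    for p in playbacks:
        dt = -1.0
        while not 0 < dt <= 2.0:
            dt = rng.normal(mode, sd)
        calls.append(p + dt)
    out["calls"] = sorted(calls)
    out["meta"]["call_delay_mode"] = mode
    out["meta"]["call_delay_sd"] = sd
    out["motifs"] = [Event("motif", t, t) for t in scenario.get("motif_onsets", [])]
    return out
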