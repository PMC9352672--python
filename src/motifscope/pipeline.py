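"""Offline training pipeline and online detection pipeline.

Training: segment -> featurize -> t-SNE embed -> behaviour map -> label the
training syllables by their map region -> assemble label sequences ->
transition matrix -> motif cycle + substrings. Detection: streamed
segmentation -> post-embedding classification -> sequence assembly -> motif
events, reusing a persisted model.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from . import behaviour_map as bm
from .audio import AudioSignal
from .events import Event, SequenceEvent, assemble_sequences
from .features import SpectrogramParams, featurize_segment
from .motif import (Motif, TransitionModel, build_transitions, detect_motifs,
                    find_motif, motif_substrings, save_motif)
from .segmentation import Segment, SegmentationParams, segment_signal, segment_stream

log = logging.getLogger("motifscope")

__all__ = ["PipelineConfig", "TrainResult", "run_train_pipeline",
           "run_detect_pipeline", "segments_to_sequences"]


@dataclass(frozen=True)
class PipelineConfig:
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    spectrogram: SpectrogramParams = field(default_factory=SpectrogramParams)
    perplexity: float = 30.0
    seed: int = 0
    # "auto" scales the map smoothing with the embedding extent (see
    # build_behaviour_map); the production-scale value is 15 embedding units.
    kernel_bandwidth: float | str = "auto"
    min_peak_distance: float | str = "auto"
    grid_size: int = 1000
    gap_window: float = 0.5
    emit_delay: float = 3.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "segmentation" in d:
            d["segmentation"] = SegmentationParams(**d["segmentation"])
        if "spectrogram" in d:
            d["spectrogram"] = SpectrogramParams(**d["spectrogram"])
        return cls(**d)

    @property
    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class TrainResult:
    model: bm.EmbeddingModel
    bmap: bm.BehaviourMap
    transitions: TransitionModel
    motif: Motif
    segments: list[Segment]
    labels: list[str]


def segments_to_sequences(segments: Iterable[Segment], labels: Iterable[str],
                          gap_window: float = 0.5,
                          emit_delay: float = 3.0) -> list[SequenceEvent]:
    """Wrap labelled segments as syllable events and chain them by gap."""
    evts = [Event("syllable", s.onset_s, s.offset_s, s.source_id,
                  {"label": lab})
            for s, lab in zip(segments, labels)]
    evts.sort(key=lambda e: e.onset)
    return assemble_sequences(evts, gap_window, emit_delay)


def run_train_pipeline(signals: Iterable[AudioSignal],
                       config: PipelineConfig | None = None,
                       out_dir=None) -> TrainResult:
    """Full unsupervised training on one or more recordings of one bird."""
    cfg = config or PipelineConfig()
    segments: list[Segment] = []
    for sig in signals:
        segments.extend(segment_signal(sig, cfg.segmentation))
    log.info("segmentation: %d segments kept", len(segments))
    if not segments:
        raise ValueError("training stage 'segment': no segments detected")

    features = np.array([featurize_segment(s, cfg.spectrogram).F
                         for s in segments])
    model = bm.train_embedding(features, cfg.perplexity, cfg.seed)
    bmap = bm.build_behaviour_map(model, cfg.kernel_bandwidth,
                                  cfg.min_peak_distance, cfg.grid_size)
    log.info("behaviour map: %d regions", bmap.n_regions)

    labels = [bmap.region_at(xy) or bm.UNCLASSIFIED
              for xy in model.training_embedding]
    seqs = segments_to_sequences(segments, labels, cfg.gap_window, cfg.emit_delay)
    transitions = build_transitions([s.labels for s in seqs])
    motif = motif_substrings(find_motif(transitions), [s.labels for s in seqs])
    log.info("motif: %s", "".join(motif.cycle))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bm.save_model(out, model, bmap)
        save_motif(out / "motif.json", transitions, motif)
        (out / "config.json").write_text(json.dumps(
            {"config": cfg.to_dict(), "config_hash": cfg.hash,
             "n_segments": len(segments), "n_regions": bmap.n_regions,
             "motif": list(motif.cycle)}, indent=2))
    return TrainResult(model, bmap, transitions, motif, segments, labels)


def run_detect_pipeline(chunks: Iterable[AudioSignal],
                        model: bm.EmbeddingModel, bmap: bm.BehaviourMap,
                        motif: Motif,
                        config: PipelineConfig | None = None,
                        bird_id: str = "") -> dict:
    """Streamed detection: syllable, sequence and motif event streams."""
    cfg = config or PipelineConfig()
    syllables: list[Event] = []
    n_unclassified = 0
    for seg in segment_stream(chunks, cfg.segmentation):
        z = featurize_segment(seg, cfg.spectrogram).F
        if z.size != model.training_features.shape[1]:
            raise ValueError(
                f"feature dimension {z.size} does not match model "
                f"{model.training_features.shape[1]}")
        c = bm.classify(z, model, bmap)
        if c.label == bm.UNCLASSIFIED:
            n_unclassified += 1
        syllables.append(Event(
            "syllable", seg.onset_s, seg.offset_s, bird_id or seg.source_id,
            {"label": c.label, "certainty": c.certainty, "latency": c.latency,
             "x": None if c.point is None else float(c.point[0]),
             "y": None if c.point is None else float(c.point[1])}))
    log.info("detection: %d syllables, %d unclassified",
             len(syllables), n_unclassified)
    sequences = assemble_sequences(syllables, cfg.gap_window, cfg.emit_delay)
    motif_events = []
    for s in sequences:
        ev = detect_motifs([l for l in s.labels if l != bm.UNCLASSIFIED],
                           motif, onset=s.onset, bird_id=s.bird_id)
        if ev is not None:
            motif_events.append(ev)
    return {"syllables": syllables, "sequences": sequences,
            "motifs": motif_events, "n_unclassified": n_unclassified}
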