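"""Motif discovery from syllable-label transition statistics.

Zebra finch song repeats a stereotyped syllable sequence (the motif) many
times per bout, so motif transitions dominate the first-order transition
matrix and the motif shows up as a cycle: start at the globally most
frequent transition and greedily follow each label's most frequent outgoing
transition until a label repeats — the repeated suffix is the motif. Dead
ends (labels with no outgoing transitions, e.g. terminal introductory-note
regions) are escaped by backtracking to the previous label's next-best arc.

Because birds sing variations of the full motif, detection in live sequences
screens for the motif's most common substrings rather than exact repeats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TransitionModel",
    "Motif",
    "MotifEvent",
    "build_transitions",
    "find_motif",
    "motif_substrings",
    "detect_motifs",
    "count_nonoverlapping",
    "save_motif",
    "load_motif",
]


@dataclass(frozen=True)
class TransitionModel:
    """First-order transition counts and row-normalized probabilities."""

    labels: tuple[str, ...]
    counts: np.ndarray  # (k, k) ints, counts[a][b] = a -> b

    @property
    def probabilities(self) -> np.ndarray:
        rows = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(rows > 0, self.counts / np.where(rows > 0, rows, 1), 0.0)
        return p

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class Motif:
    """A discovered motif cycle plus its most common substrings in training data."""

    cycle: tuple[str, ...]
    substrings: tuple[tuple[str, ...], ...] = ()


@dataclass(frozen=True)
class MotifEvent:
    onset: float
    bird_id: str
    motif: tuple[str, ...]
    occurrences: int


def build_transitions(sequences: Iterable[Sequence[str]],
                      exclude: Sequence[str] = ("UNCLASSIFIED",)) -> TransitionModel:
    """Count adjacent ordered label pairs within each sequence.

    Pairs never span sequence boundaries; tokens in ``exclude`` are dropped
    before pairing.
    """
    seqs = [[t for t in seq if t not in exclude] for seq in sequences]
    seqs = [s for s in seqs if s]
    if not seqs:
        raise ValueError("no sequences (after excluding unclassified tokens)")
    labels = tuple(sorted({t for s in seqs for t in s}))
    li = {l: i for i, l in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for s in seqs:
        for a, b in zip(s, s[1:]):
            counts[li[a], li[b]] += 1
    return TransitionModel(labels, counts)


def _canonical_rotation(cycle: tuple[str, ...]) -> tuple[str, ...]:
    rots = [cycle[i:] + cycle[:i] for i in range(len(cycle))]
    return min(rots)


def find_motif(model: TransitionModel) -> Motif:
    """Extract the dominant cycle of the transition matrix.

    Start at the arc with the globally maximal count; repeatedly append the
    current label's most frequent next label (ties broken lexicographically);
    stop at the first revisit — the revisited suffix is the cycle. A label
    with no outgoing transitions is a dead end, resolved by depth-first
    backtracking over each predecessor's next-best arcs. The cycle is
    canonicalized to its lexicographically smallest rotation.
    """
    counts = model.counts
    if counts.sum() == 0:
        raise ValueError("transition model has no transitions")
    k = len(model.labels)

    def ranked_next(i: int) -> list[int]:
        row = counts[i]
        order = sorted(range(k), key=lambda j: (-row[j], model.labels[j]))
        return [j for j in order if row[j] > 0]

    a, b = (int(i) for i in np.unravel_index(int(np.argmax(counts)),
                                             counts.shape))

    # DFS over next-best choices; the global-max arc (a, b) is tried first,
    # then a's remaining arcs if every continuation through b dead-ends.
    path: list[int] = [a]
    choice_stack: list[list[int]] = [[b] + [j for j in ranked_next(a) if j != b]]
    while True:
        if path[-1] in path[:-1]:
            i = path.index(path[-1])
            cycle = tuple(model.labels[j] for j in path[i:-1])
            return Motif(_canonical_rotation(cycle))
        options = choice_stack[-1]
        if options:
            nxt = options.pop(0)
            path.append(nxt)
            choice_stack.append(ranked_next(nxt))
        else:
            # dead end: backtrack to the previous node's next-best arc
            path.pop()
            choice_stack.pop()
            if not path or not choice_stack:
                raise ValueError(
                    "no cycle reachable from the dominant transition; "
                    f"exhausted path {[model.labels[j] for j in path]}")


def count_nonoverlapping(seq: Sequence[str], sub: Sequence[str]) -> int:
    """Leftmost-greedy non-overlapping occurrence count of ``sub`` in ``seq``."""
    sub = tuple(sub)
    n, m = len(seq), len(sub)
    if m == 0 or m > n:
        return 0
    count = i = 0
    while i <= n - m:
        if tuple(seq[i:i + m]) == sub:
            count += 1
            i += m
        else:
            i += 1
    return count


def motif_substrings(motif: Motif, sequences: Iterable[Sequence[str]],
                     min_length: int = 2, top: int = 10) -> Motif:
    """Rank the cyclic substrings of the motif by occurrence in training data.

    Candidates are contiguous runs of the cyclically extended cycle with
    length from ``min_length`` up to the cycle length (a single-label cycle
    is extended to a ``min_length`` run, since one letter alone is not
    evidence of a motif). The ``top`` most frequent, by non-overlapping
    count over the training sequences, are retained; ties prefer longer
    substrings, then lexicographic order.
    """
    cyc = motif.cycle
    L = len(cyc)
    max_len = max(L, min_length)
    ext = cyc * (max_len // L + 2)
    cands = {tuple(ext[i:i + m])
             for m in range(min_length, max_len + 1)
             for i in range(L)}
    seqs = [list(s) for s in sequences]
    scored = [(sub, sum(count_nonoverlapping(s, sub) for s in seqs))
              for sub in cands]
    scored.sort(key=lambda t: (-t[1], -len(t[0]), t[0]))
    return Motif(cyc, tuple(sub for sub, _ in scored[:top]))


def detect_motifs(sequence: Sequence[str], motif: Motif,
                  onset: float = 0.0, bird_id: str = "") -> MotifEvent | None:
    """Screen one sequence for the motif's substrings.

    If any retained substring occurs, emit one event carrying the most
    frequent substring in *this* sequence (ties broken by retained rank) and
    its non-overlapping occurrence count; otherwise None.
    """
    if not motif.substrings:
        raise ValueError("motif has no ranked substrings; run motif_substrings first")
    best: tuple[str, ...] | None = None
    best_count = 0
    for sub in motif.substrings:
        c = count_nonoverlapping(sequence, sub)
        if c > best_count:
            best, best_count = sub, c
    if best is None:
        return None
    return MotifEvent(onset=onset, bird_id=bird_id, motif=best,
                      occurrences=best_count)


def save_motif(path, model: TransitionModel, motif: Motif) -> None:
    doc = {
        "labels": list(model.labels),
        "counts": model.counts.tolist(),
        "cycle": list(motif.cycle),
        "substrings": [list(s) for s in motif.substrings],
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_motif(path) -> tuple[TransitionModel, Motif]:
    doc = json.loads(Path(path).read_text())
    model = TransitionModel(tuple(doc["labels"]),
                            np.asarray(doc["counts"], dtype=np.int64))
    motif = Motif(tuple(doc["cycle"]),
                  tuple(tuple(s) for s in doc["substrings"]))
    return model, motif
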