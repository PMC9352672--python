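"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive each quantity from its definition with the
simplest possible machinery (per-index scans, dense boolean time grids,
exhaustive enumeration) and share no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------- segmentation

def ptp_back(s: np.ndarray, i: int, w: int) -> float:
    """Peak-to-peak of the trailing window [i-w, i], clipped at the start."""
    win = s[max(0, i - w):i + 1]
    return float(win.max() - win.min())


def ptp_fwd(s: np.ndarray, i: int, w: int) -> float:
    """Peak-to-peak of the leading window [i, i+w]; incomplete windows at
    the end of the buffer can never qualify as quiet."""
    if i + w + 1 > s.size:
        return float("inf")
    win = s[i:i + w + 1]
    return float(win.max() - win.min())


def segment_scan_oracle(s: np.ndarray, t_on: float, t_off: float,
                        w: int) -> list[tuple[int, int, int, bool]]:
    """Literal sequential evaluation of the two-threshold scheme.

    Returns (trigger, onset, offset, truncated) tuples before duration
    filtering. Window peak-to-peak values are evaluated per index from
    their definition (vectorized with a sliding window for speed, but
    through different machinery than the implementation's rank filters).
    """
    n = s.size
    if n == 0:
        return []
    # per-index trailing/leading window ptp, computed exhaustively
    back = np.array([ptp_back(s, i, w) for i in range(n)]) if n <= 2000 else None
    fwd = np.array([ptp_fwd(s, i, w) for i in range(n)]) if n <= 2000 else None
    if back is None:
        from numpy.lib.stride_tricks import sliding_window_view
        sw = sliding_window_view(s, w + 1)
        interior = sw.max(axis=1) - sw.min(axis=1)
        back = np.empty(n)
        back[w:] = interior
        back[:w] = [ptp_back(s, i, w) for i in range(w)]
        fwd = np.empty(n)
        fwd[:n - w] = interior
        fwd[n - w:] = [ptp_fwd(s, i, w) for i in range(n - w, n)]
    out = []
    pos = 0
    while True:
        trig = None
        for i in range(pos, n):
            if abs(s[i]) > t_on:
                trig = i
                break
        if trig is None:
            break
        onset, trunc = 0, True
        for i in range(trig, -1, -1):
            if back[i] < t_off:
                onset, trunc = i, False
                break
        offset = n
        for i in range(trig, n):
            if fwd[i] < t_off:
                offset = i
                break
        truncated = trunc or offset == n
        out.append((trig, onset, offset, truncated))
        pos = offset + 1
    return out


def segments_oracle(s: np.ndarray, t_on: float, t_off: float, w: int,
                    min_dur: float, max_dur: float,
                    sample_rate: float) -> list[tuple[int, int]]:
    """Duration-filtered (onset, offset) pairs from the literal scan."""
    out = []
    for _, onset, offset, _ in segment_scan_oracle(s, t_on, t_off, w):
        dur = (offset - onset) / sample_rate
        if min_dur <= dur <= max_dur:
            out.append((onset, offset))
    return out


# ---------------------------------------------------------------------- events

def interval_and_oracle(a: list[tuple[float, float]],
                        b: list[tuple[float, float]],
                        horizon: float, dt: float = 1e-3
                        ) -> list[tuple[float, float]]:
    """Dense boolean AND of two interval sets on a millisecond grid."""
    t = np.arange(0.0, horizon, dt)
    act_a = np.zeros(t.size, dtype=bool)
    act_b = np.zeros(t.size, dtype=bool)
    for lo, hi in a:
        act_a[(t >= lo) & (t < hi)] = True
    for lo, hi in b:
        act_b[(t >= lo) & (t < hi)] = True
    both = act_a & act_b
    out = []
    i = 0
    while i < both.size:
        if both[i]:
            j = i
            while j < both.size and both[j]:
                j += 1
            out.append((t[i], t[j - 1] + dt))
            i = j
        else:
            i += 1
    return out


def controller_sim_oracle(motif_times: list[float], n_videos: int,
                          timeout: float, horizon: float,
                          dt: float = 1.0) -> list[tuple[float, int]]:
    """Discrete-time replay of the video-switch logic at 1 s resolution."""
    changes = []
    video = 0
    last_reset = 0.0
    motifs = sorted(motif_times)
    mi = 0
    t = dt
    while t <= horizon + 1e-9:
        while mi < len(motifs) and motifs[mi] <= t:
            if motifs[mi] > last_reset:
                last_reset = motifs[mi]
            mi += 1
        if t - last_reset >= timeout:
            video = (video + 1) % n_videos
            changes.append((t, video))
            last_reset = t
        t += dt
    return changes


def gap_partition_oracle(intervals: list[tuple[float, float]],
                         gap: float) -> list[list[int]]:
    """Group interval indices whenever the inter-interval gap is < gap."""
    groups: list[list[int]] = []
    for i, (on, off) in enumerate(intervals):
        if groups and on - intervals[groups[-1][-1]][1] < gap:
            groups[-1].append(i)
        else:
            groups.append([i])
    return groups


# ----------------------------------------------------------------------- motif

def best_cycle_oracle(labels: tuple[str, ...], counts: np.ndarray):
    """Enumerate all simple cycles; pick the one with maximal minimum arc count.

    Ties broken by total arc count, then lexicographic rotation. Uses
    networkx only for the enumeration.
    """
    import networkx as nx
    G = nx.DiGraph()
    k = len(labels)
    for i in range(k):
        for j in range(k):
            if counts[i][j] > 0:
                G.add_edge(i, j)
    best = None
    for cyc in nx.simple_cycles(G):
        arcs = [counts[a][b] for a, b in zip(cyc, cyc[1:] + cyc[:1])]
        rots = [tuple(cyc[i:] + cyc[:i]) for i in range(len(cyc))]
        key = (min(arcs), sum(arcs), min(tuple(labels[i] for i in r) for r in rots))
        if best is None or key > best[0]:
            best = (key, min(tuple(labels[i] for i in r) for r in rots))
    return None if best is None else best[1]


def count_substring_oracle(seq: list[str], sub: list[str]) -> int:
    """Leftmost-greedy non-overlapping count by repeated string find."""
    s = "\x00".join(seq) + "\x00"
    p = "\x00".join(sub) + "\x00"
    count = 0
    pos = 0
    while True:
        i = s.find(p, pos)
        if i < 0:
            return count
        count += 1
        pos = i + len(p)
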