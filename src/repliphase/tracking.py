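"""Frame-to-frame nucleus linking by optimal (Hungarian) assignment.

Objects are linked between consecutive frames by minimizing total
Euclidean centroid displacement, with a gating distance ``max_disp``:
pairs farther apart than the gate are forbidden, and every unmatched
object contributes ``max_disp`` to the objective (the standard
dummy-node reduction, which keeps the assignment square). Tracks are
maximal chains of such links — no gap closing, no division handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .segment import LabelVolume

_FORBIDDEN = 1e12  # sentinel for gated-out pairs


@dataclass
class Assignment:
    pairs: list[tuple[int, int]]       # (index in frame t, index in frame t+1)
    unmatched_a: list[int]
    unmatched_b: list[int]
    total_cost: float                  # matched distances + max_disp per unmatched


def link_frames(objects_a: np.ndarray, objects_b: np.ndarray,
                max_disp: float) -> Assignment:
    """Optimal gated matching between two centroid sets (physical units).

    Minimizes ``sum(matched distances) + max_disp × n_unmatched`` subject
    to every matched pair being within ``max_disp``.
    """
    if max_disp < 0:
        raise ValueError("max_disp must be >= 0")
    a = np.atleast_2d(np.asarray(objects_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(objects_b, dtype=np.float64))
    n, m = (a.shape[0] if a.size else 0), (b.shape[0] if b.size else 0)
    if n == 0 or m == 0:
        return Assignment(pairs=[], unmatched_a=list(range(n)),
                          unmatched_b=list(range(m)),
                          total_cost=max_disp * (n + m))
    dist = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    # Square (n+m) matrix: real pairs top-left (gated), dummy diagonals at
    # max_disp for unmatched rows/columns, zero block bottom-right.
    cost = np.full((n + m, n + m), _FORBIDDEN)
    gated = np.where(dist <= max_disp, dist, _FORBIDDEN)
    cost[:n, :m] = gated
    cost[:n, m:] = _FORBIDDEN
    cost[n:, :m] = _FORBIDDEN
    np.fill_diagonal(cost[:n, m:], max_disp)
    np.fill_diagonal(cost[n:, :m], max_disp)
    cost[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    pairs, un_a, un_b = [], [], []
    for r, c in zip(rows, cols):
        if r < n and c < m:
            if dist[r, c] <= max_disp:
                pairs.append((int(r), int(c)))
            else:  # only reachable in degenerate all-forbidden cases
                un_a.append(int(r))
                un_b.append(int(c))
        elif r < n:
            un_a.append(int(r))
        elif c < m:
            un_b.append(int(c))
    pairs.sort()
    total = sum(dist[r, c] for r, c in pairs) + max_disp * (len(un_a) + len(un_b))
    return Assignment(pairs=pairs, unmatched_a=sorted(un_a),
                      unmatched_b=sorted(un_b), total_cost=float(total))


@dataclass
class NucleusTrack:
    """One tracked object: contiguous frames, per-frame centroid (µm) and
    label, and per-channel mean intensities filled in by the trace stage."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    centroids: list[np.ndarray] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)
    intensities: dict[int, list[float]] = field(default_factory=dict)  # channel -> per-frame means

    def append(self, frame: int, centroid: np.ndarray, label: int) -> None:
        if self.frames and frame != self.frames[-1] + 1:
            raise ValueError("track frames must be contiguous")
        self.frames.append(frame)
        self.centroids.append(np.asarray(centroid, dtype=np.float64))
        self.labels.append(int(label))

    def __len__(self) -> int:
        return len(self.frames)


def build_tracks(label_volumes: list[LabelVolume], max_disp: float) -> list[NucleusTrack]:
    """Chain frame-to-frame assignments into tracks.

    An unmatched object starts a new track; a track whose object finds no
    match terminates. Every object belongs to exactly one track.
    """
    if not label_volumes:
        raise ValueError("need at least one frame of labels")
    centroids = [lv.centroids_um() for lv in label_volumes]
    tracks: list[NucleusTrack] = []
    next_id = 0
    # active[i] = track currently ending at object i of the previous frame
    active: dict[int, NucleusTrack] = {}
    for i in range(centroids[0].shape[0]):
        tr = NucleusTrack(track_id=next_id)
        tr.append(0, centroids[0][i], i + 1)
        tracks.append(tr)
        active[i] = tr
        next_id += 1
    for t in range(1, len(label_volumes)):
        prev, cur = centroids[t - 1], centroids[t]
        assign = link_frames(prev, cur, max_disp)
        new_active: dict[int, NucleusTrack] = {}
        for r, c in assign.pairs:
            tr = active[r]
            tr.append(t, cur[c], c + 1)
            new_active[c] = tr
        for c in assign.unmatched_b:
            tr = NucleusTrack(track_id=next_id)
            tr.append(t, cur[c], c + 1)
            tracks.append(tr)
            new_active[c] = tr
            next_id += 1
        active = new_active
    return tracks


def tracks_to_table(tracks: list[NucleusTrack]) -> pd.DataFrame:
    """Serialize tracks to a long table (track_id, frame, label, z/y/x µm)."""
    rows = []
    for tr in tracks:
        for f, c, lab in zip(tr.frames, tr.centroids, tr.labels):
            row = {"track_id": tr.track_id, "frame": f, "label": lab}
            for name, v in zip(("z", "y", "x")[-len(c):], c):
                row[name] = v
            rows.append(row)
    return pd.DataFrame(rows)


def tracks_from_table(df: pd.DataFrame) -> list[NucleusTrack]:
    """Inverse of :func:`tracks_to_table`."""
    coord_cols = [c for c in ("z", "y", "x") if c in df.columns]
    tracks = []
    for tid, grp in df.sort_values(["track_id", "frame"]).groupby("track_id"):
        tr = NucleusTrack(track_id=int(tid))
        for _, row in grp.iterrows():
            tr.append(int(row["frame"]), row[coord_cols].to_numpy(dtype=float),
                      int(row["label"]))
        tracks.append(tr)
    return tracks
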