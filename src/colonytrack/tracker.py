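"""Frame-to-frame tracking with mitosis-aware lineage construction.

Nucleus instances are linked across consecutive frames by a gated
linear-sum assignment whose cost mixes centroid distance and overlap;
an unmatched track coasts for a configurable number of grace frames
before being declared lost, and unmatched tracks whose pixels largely
fall inside a matched object are flagged as merge events rather than
losses.  Mitosis events (from the 4-class classifier or from truth)
pre-empt the assignment: the mother track is closed at the division
frame and two daughter tracks are opened at the seed positions, giving
the lineage forest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import linear_sum_assignment

from .mitosis import MitosisEvent

_BIG = 1e9


@dataclass(frozen=True)
class TrackerConfig:
    """Linking parameters.

    max_link_distance : assignment gate in pixels (default 15).
    grace_frames : frames an unmatched track may coast before it is lost.
    w_dist, w_overlap : weights of the distance term (scaled by the gate)
        and the 1-IoU term; with the defaults both terms lie in [0, 1].
    min_track_frames : default span filter (5 frames = 10 min at 2-min
        acquisition) applied by ``filter_tracks``.
    """

    max_link_distance: float = 15.0
    grace_frames: int = 5
    w_dist: float = 1.0
    w_overlap: float = 1.0
    min_track_frames: int = 5

    def __post_init__(self) -> None:
        if self.max_link_distance <= 0:
            raise ValueError("max_link_distance must be positive")
        if min(self.grace_frames, self.w_dist, self.w_overlap) < 0:
            raise ValueError("weights and grace_frames must be non-negative")


@dataclass
class _Obj:
    """One instance in one frame."""

    label: int
    centroid: np.ndarray
    pixels: frozenset
    area: int


@dataclass
class Track:
    """Identity chain of one cell across frames."""

    id: int
    entries: dict[int, tuple[float, float]] = field(default_factory=dict)
    labels: dict[int, int] = field(default_factory=dict)
    areas: dict[int, int] = field(default_factory=dict)
    parent_id: int | None = None
    merged_into: int | None = None
    lost: bool = False

    @property
    def birth_frame(self) -> int:
        return min(self.entries)

    @property
    def death_frame(self) -> int:
        return max(self.entries)

    @property
    def n_frames(self) -> int:
        return len(self.entries)

    def positions(self) -> dict[int, tuple[float, float]]:
        return dict(self.entries)


class Lineage:
    """Directed forest over track ids; edges mark mother -> daughter."""

    def __init__(self) -> None:
        self.graph = nx.DiGraph()
        self._tracks: dict[int, Track] = {}

    def add_track(self, track: Track) -> None:
        self._tracks[track.id] = track
        self.graph.add_node(track.id)

    def add_division(self, mother: int, d1: int, d2: int, t_div: int) -> None:
        self.graph.add_edge(mother, d1, t_div=t_div)
        self.graph.add_edge(mother, d2, t_div=t_div)

    def parent_of(self, tid: int) -> int | None:
        preds = list(self.graph.predecessors(tid))
        return preds[0] if preds else None

    def children_of(self, tid: int) -> list[int]:
        return sorted(self.graph.successors(tid))

    def division_frame_of(self, tid: int) -> int | None:
        """Frame at which this track divides (None if it never does)."""
        for _, _, d in self.graph.out_edges(tid, data=True):
            return d["t_div"]
        return None

    def birth_frame_of(self, tid: int) -> int:
        return self._tracks[tid].birth_frame

    def complete_generations(self) -> list[int]:
        """Tracks born at a division that divide again (full cell cycles)."""
        return sorted(
            tid
            for tid in self.graph.nodes
            if self.parent_of(tid) is not None
            and self.division_frame_of(tid) is not None
        )

    def roots(self) -> list[int]:
        return sorted(
            t for t in self.graph.nodes if self.parent_of(t) is None
        )

    def to_newick(self) -> str:
        """Newick-like text export of the forest (frame spans as lengths)."""

        def clause(tid: int) -> str:
            kids = self.children_of(tid)
            span = self._tracks[tid].n_frames if tid in self._tracks else 0
            me = f"{tid}:{span}"
            if not kids:
                return me
            return "(" + ",".join(clause(k) for k in kids) + ")" + me

        return ";".join(clause(r) for r in self.roots()) + ";"

    def edge_list(self) -> list[tuple[int, int, int]]:
        return [
            (u, v, d["t_div"]) for u, v, d in self.graph.edges(data=True)
        ]


def _extract_objects(instances: np.ndarray) -> list[_Obj]:
    instances = np.asarray(instances)
    ids = np.unique(instances[instances > 0])
    objs = []
    if ids.size:
        coms = ndi.center_of_mass(instances > 0, instances, ids)
        for lab, com in zip(ids, coms):
            idx = np.flatnonzero(instances.ravel() == lab)
            objs.append(
                _Obj(
                    int(lab),
                    np.asarray(com, dtype=float),
                    frozenset(idx.tolist()),
                    int(idx.size),
                )
            )
    return objs


def link_cost(
    prev: _Obj, nxt: _Obj, config: TrackerConfig
) -> float | None:
    """Pair cost, or None when outside the distance gate."""
    d = float(np.linalg.norm(prev.centroid - nxt.centroid))
    if d > config.max_link_distance:
        return None
    inter = len(prev.pixels & nxt.pixels)
    union = len(prev.pixels | nxt.pixels)
    iou = inter / union if union else 0.0
    return config.w_dist * (d / config.max_link_distance) + config.w_overlap * (
        1.0 - iou
    )


def assignment_pairs(
    prev_objs: Sequence[_Obj],
    next_objs: Sequence[_Obj],
    config: TrackerConfig = TrackerConfig(),
) -> list[tuple[int, int]]:
    """Gated optimal assignment between two object lists (index pairs)."""
    np_, nn = len(prev_objs), len(next_objs)
    cost = np.full((np_, nn), _BIG)
    for i, p in enumerate(prev_objs):
        for j, q in enumerate(next_objs):
            c = link_cost(p, q, config)
            if c is not None:
                cost[i, j] = c
    if cost.size == 0:
        return []
    ri, ci = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(ri, ci) if cost[i, j] < _BIG]


class Tracker:
    """Stateful frame-by-frame tracker."""

    def __init__(self, config: TrackerConfig = TrackerConfig()) -> None:
        self.config = config
        self.tracks: dict[int, Track] = {}
        self.lineage = Lineage()
        self._active: dict[int, _Obj] = {}  # track id -> last seen object
        self._last_seen: dict[int, int] = {}
        self._next_id = 1
        self._frame = -1

    # -- helpers ----------------------------------------------------------
    def _open(self, obj: _Obj, frame: int, parent: int | None = None) -> int:
        tid = self._next_id
        self._next_id += 1
        tr = Track(tid, parent_id=parent)
        self.tracks[tid] = tr
        self.lineage.add_track(tr)
        self._record(tid, obj, frame)
        return tid

    def _record(self, tid: int, obj: _Obj, frame: int) -> None:
        tr = self.tracks[tid]
        tr.entries[frame] = (float(obj.centroid[0]), float(obj.centroid[1]))
        tr.labels[frame] = obj.label
        tr.areas[frame] = obj.area
        self._active[tid] = obj
        self._last_seen[tid] = frame

    def _close(self, tid: int, lost: bool = True) -> None:
        self.tracks[tid].lost = lost
        self._active.pop(tid, None)
        self._last_seen.pop(tid, None)

    # -- main step --------------------------------------------------------
    def step(
        self,
        instances: np.ndarray,
        events: Sequence[MitosisEvent] = (),
    ) -> None:
        """Advance one frame: lineage first, then gated assignment."""
        self._frame += 1
        t = self._frame
        cfg = self.config
        objs = _extract_objects(instances)
        consumed: set[int] = set()  # indices of objs claimed by lineage

        # --- divisions occurring at this frame
        for ev in sorted(events, key=lambda e: e.position):
            mother_tid = self._nearest_active(ev.position)
            daughter_idx = self._claim_daughters(ev, objs, consumed)
            if daughter_idx is None:
                continue
            i1, i2 = daughter_idx
            parent = None
            if mother_tid is not None:
                self._close(mother_tid, lost=False)
                parent = mother_tid
            d1 = self._open(objs[i1], t, parent)
            d2 = self._open(objs[i2], t, parent)
            consumed.update((i1, i2))
            if parent is not None:
                self.lineage.add_division(parent, d1, d2, t)

        # --- gated assignment for everything else
        free_idx = [i for i in range(len(objs)) if i not in consumed]
        active_ids = sorted(self._active)
        pairs = assignment_pairs(
            [self._active[tid] for tid in active_ids],
            [objs[i] for i in free_idx],
            cfg,
        )
        matched_tracks = set()
        matched_obj = set()
        for pi, qi in pairs:
            tid = active_ids[pi]
            self._record(tid, objs[free_idx[qi]], t)
            matched_tracks.add(tid)
            matched_obj.add(free_idx[qi])

        # --- unmatched tracks: merge check, then coasting / loss
        matched_pixels = [
            (free_idx[qi], objs[free_idx[qi]]) for _, qi in pairs
        ]
        for tid in active_ids:
            if tid in matched_tracks:
                continue
            prev = self._active[tid]
            merged = None
            for oi, obj in matched_pixels:
                ov = len(prev.pixels & obj.pixels)
                if prev.area and ov / prev.area > 0.5:
                    merged = oi
                    break
            if merged is not None:
                winner = next(
                    (
                        t2
                        for t2 in matched_tracks
                        if self.tracks[t2].labels.get(t) == objs[merged].label
                    ),
                    None,
                )
                self.tracks[tid].merged_into = winner
                self._close(tid, lost=False)
            elif t - self._last_seen[tid] >= cfg.grace_frames:
                self._close(tid, lost=True)
            # else: keep coasting

        # --- unmatched objects open new tracks (deterministic order)
        leftovers = sorted(
            (i for i in free_idx if i not in matched_obj),
            key=lambda i: (objs[i].centroid[0], objs[i].centroid[1]),
        )
        for i in leftovers:
            self._open(objs[i], t)

    def _nearest_active(self, position) -> int | None:
        best, best_d = None, self.config.max_link_distance
        for tid in sorted(self._active):
            d = math.hypot(
                self._active[tid].centroid[0] - position[0],
                self._active[tid].centroid[1] - position[1],
            )
            if d <= best_d:
                best, best_d = tid, d
        return best

    def _claim_daughters(self, ev, objs, consumed):
        """Nearest distinct instances to the two seeds, within the gate."""
        picks = []
        taken = set(consumed)
        for seed in ev.daughter_seeds:
            best, best_d = None, self.config.max_link_distance
            for i, o in enumerate(objs):
                if i in taken:
                    continue
                d = math.hypot(o.centroid[0] - seed[0], o.centroid[1] - seed[1])
                if d <= best_d:
                    best, best_d = i, d
            if best is None:
                return None
            picks.append(best)
            taken.add(best)
        return tuple(picks)


def track_cells(
    instance_series: Sequence[np.ndarray],
    events: Sequence[MitosisEvent] = (),
    config: TrackerConfig = TrackerConfig(),
) -> tuple[dict[int, Track], Lineage]:
    """Track a whole instance-mask series, with optional mitosis events."""
    by_frame: dict[int, list[MitosisEvent]] = {}
    for e in events:
        by_frame.setdefault(e.t_div, []).append(e)
    tk = Tracker(config)
    for t, inst in enumerate(instance_series):
        tk.step(inst, by_frame.get(t, ()))
    return tk.tracks, tk.lineage


def link_frames(
    instances_t: np.ndarray,
    instances_t1: np.ndarray,
    config: TrackerConfig = TrackerConfig(),
) -> list[tuple[int, int]]:
    """Optimal gated links between the labels of two consecutive frames.

    Returns (label_at_t, label_at_t1) pairs — the single-step linking
    primitive used inside the tracker.
    """
    a = _extract_objects(instances_t)
    b = _extract_objects(instances_t1)
    return [
        (a[i].label, b[j].label) for i, j in assignment_pairs(a, b, config)
    ]


def filter_tracks(
    tracks: Mapping[int, Track], min_track_frames: int | None = None,
    config: TrackerConfig = TrackerConfig(),
) -> dict[int, Track]:
    """Drop tracks identified in fewer than ``min_track_frames`` frames.

    Short-lived tracks are overwhelmingly spurious detections; removing
    them (default: anything under 5 frames, i.e. 10 min) brings
    per-frame counts close to the true cell count.
    """
    n = config.min_track_frames if min_track_frames is None else min_track_frames
    return {tid: tr for tid, tr in tracks.items() if tr.n_frames >= n}


def counts_per_frame(
    tracks: Mapping[int, Track], n_frames: int
) -> np.ndarray:
    """Cells per frame, counting only frames where a track was matched."""
    counts = np.zeros(n_frames, dtype=int)
    for tr in tracks.values():
        for f in tr.entries:
            if 0 <= f < n_frames:
                counts[f] += 1
    return counts


def tracks_to_table(tracks: Mapping[int, Track]) -> "pandas.DataFrame":
    """Long-format track table (track_id, frame, row, col, area, parent_id, flags)."""
    import pandas as pd

    rows = []
    for tid in sorted(tracks):
        tr = tracks[tid]
        flags = "merged" if tr.merged_into is not None else (
            "lost" if tr.lost else ""
        )
        for f in sorted(tr.entries):
            r, c = tr.entries[f]
            rows.append(
                {
                    "track_id": tid,
                    "frame": f,
                    "row": r,
                    "col": c,
                    "area": tr.areas.get(f, 0),
                    "parent_id": tr.parent_id if tr.parent_id is not None else -1,
                    "flags": flags,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["track_id", "frame", "row", "col", "area", "parent_id", "flags"],
    )
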