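"""Mitosis events from 4-class spatiotemporal masks.

A division shows up in a 4-class mask stack as a connected blob of
mitotic (class 2) and daughter (class 3) voxels in (rows, cols, time).
``extract_events`` labels those blobs in 3-D, filters out small or
short-lived ones, resolves each survivor's division time and seeds two
daughter positions for the tracker.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import regionprops

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EventFilter:
    """Spurious-event filter.

    A candidate 3-D component must have a voxel volume strictly larger
    than ``min_volume`` and span at least ``min_persistence`` frames.
    Defaults (300, 10) suit raw classifier output, whose mitotic blobs
    bleed beyond the annotation windows.  Strictly windowed annotation
    masks confine each event to frames_before + frames_after frames, so
    use :meth:`for_windows` there.
    """

    min_volume: int = 300
    min_persistence: int = 10

    def __post_init__(self) -> None:
        if self.min_volume < 1 or self.min_persistence < 1:
            raise ValueError("filter thresholds must be positive")

    @classmethod
    def for_windows(cls, windows) -> "EventFilter":
        """Filter consistent with strictly windowed class masks."""
        span = windows.frames_before + windows.frames_after
        return cls(min_volume=300, min_persistence=min(10, span))


@dataclass
class MitosisEvent:
    """One filtered division: position, time and daughter seed points."""

    position: tuple[float, float]
    t_div: int
    daughter_seeds: tuple[tuple[float, float], tuple[float, float]]
    component_id: int = 0

    @property
    def as_xyt(self) -> tuple[float, float, int]:
        return (self.position[0], self.position[1], self.t_div)


_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
_STRUCT_2D = np.ones((3, 3), dtype=bool)  # 8-connectivity


def extract_events(
    classmask: np.ndarray,
    event_filter: EventFilter = EventFilter(),
) -> list[MitosisEvent]:
    """Find filtered mitosis events in a (t, rows, cols) 4-class stack.

    Class-2 and class-3 voxels are merged and connected-component labeled
    in 3-D with 26-connectivity.  Components failing the volume or
    persistence filter are discarded; each survivor yields one event with
    a resolved division time and two daughter seeds.
    """
    classmask = np.asarray(classmask)
    if classmask.ndim != 3:
        raise ValueError("classmask must be (t, rows, cols)")
    merged = (classmask == 2) | (classmask == 3)
    labels, n = ndi.label(merged, structure=_STRUCT_3D)
    events: list[MitosisEvent] = []
    for comp_id in range(1, n + 1):
        comp = labels == comp_id
        volume = int(comp.sum())
        frames = np.flatnonzero(comp.any(axis=(1, 2)))
        persistence = int(frames[-1] - frames[0] + 1)
        if volume <= event_filter.min_volume:
            continue
        if persistence < event_filter.min_persistence:
            continue
        t_div = resolve_division_time(comp, classmask)
        pos = _component_position(comp, classmask, t_div)
        seeds = seed_daughters(comp, classmask, t_div, pos)
        events.append(MitosisEvent(pos, t_div, seeds, comp_id))
    return events


def resolve_division_time(
    component: np.ndarray, classmask: np.ndarray
) -> int:
    """Division time of one 3-D component.

    t_div is the first frame at which the component's class-3 region
    splits into two 2-D (8-connected) objects; if no split is ever seen,
    the frame at which the class-2 area is largest.  Ties resolve to the
    earliest frame.
    """
    frames = np.flatnonzero(component.any(axis=(1, 2)))
    for t in frames:
        d3 = component[t] & (classmask[t] == 3)
        if d3.any():
            _, n = ndi.label(d3, structure=_STRUCT_2D)
            if n >= 2:
                return int(t)
    # no observed split: fall back to peak class-2 area
    best_t, best_area = int(frames[0]), -1
    for t in frames:
        area = int((component[t] & (classmask[t] == 2)).sum())
        if area > best_area:
            best_t, best_area = int(t), area
    return best_t


def _component_position(
    component: np.ndarray, classmask: np.ndarray, t_div: int
) -> tuple[float, float]:
    """Event position: centroid of the component's plane at t_div."""
    plane = component[t_div]
    if not plane.any():  # pragma: no cover - t_div always within component
        plane = component.any(axis=0)
    r, c = ndi.center_of_mass(plane)
    return (float(r), float(c))


def seed_daughters(
    component: np.ndarray,
    classmask: np.ndarray,
    t_div: int,
    position: tuple[float, float] | None = None,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Two daughter seed points at the division frame.

    If two (or more) class-3 objects exist at t_div, the seeds are the
    centroids of the two largest.  Otherwise the mother region's shape is
    used: seeds sit at plus/minus half the major-axis length from its
    centroid along its orientation.  A degenerate (single-pixel) mother
    yields two coincident seeds with a logged warning.
    """
    d3 = component[t_div] & (classmask[t_div] == 3)
    lab, n = ndi.label(d3, structure=_STRUCT_2D)
    if n >= 2:
        sizes = ndi.sum_labels(d3, lab, index=range(1, n + 1))
        top2 = np.argsort(sizes)[::-1][:2] + 1
        coms = ndi.center_of_mass(d3, lab, top2)
        return (
            (float(coms[0][0]), float(coms[0][1])),
            (float(coms[1][0]), float(coms[1][1])),
        )
    # single (or no) daughter object: use the mother region's major axis
    mother = component[t_div]
    props = regionprops(mother.astype(np.uint8))[0]
    r0, c0 = props.centroid
    half = props.axis_major_length / 2.0
    if half < 0.5:
        log.warning("degenerate mother region at frame %d: coincident seeds", t_div)
        return ((float(r0), float(c0)), (float(r0), float(c0)))
    theta = props.orientation  # angle of major axis vs row axis
    dr = -half * math.cos(theta)
    dc = -half * math.sin(theta)
    return (
        (float(r0 + dr), float(c0 + dc)),
        (float(r0 - dr), float(c0 - dc)),
    )


def events_to_table(events: list[MitosisEvent]) -> "pandas.DataFrame":
    """Tabulate events (CSV-ready)."""
    import pandas as pd

    rows = []
    for i, e in enumerate(events):
        (s1r, s1c), (s2r, s2c) = e.daughter_seeds
        rows.append(
            {
                "event_id": i,
                "row": e.position[0],
                "col": e.position[1],
                "t_div": e.t_div,
                "seed1_row": s1r,
                "seed1_col": s1c,
                "seed2_row": s2r,
                "seed2_col": s2c,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id", "row", "col", "t_div",
            "seed1_row", "seed1_col", "seed2_row", "seed2_col",
        ],
    )
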