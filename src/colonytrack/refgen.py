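"""Automated annotation from fluorescence nuclear reporters.

Manual labeling cannot keep up with time-lapses containing tens of
thousands of nuclei per frame, so reference objects are generated
automatically from the fluorescence channel: a band-pass filter and
threshold find the nuclei, FogBank-style separation splits touching
ones, and a second, finer band-pass finds the condensed DNA of cells
about to divide.  A small assignment step then links each condensing
mother to its two daughters in the next frame, and the result is written
out as a 4-class mask (0 background, 1 nucleus, 2 mitotic nucleus,
3 daughter) with fixed temporal windows: class 2 for the 5 frames before
a division and class 3 for the 3 frames after.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import linear_sum_assignment
from skimage.filters import difference_of_gaussians, threshold_otsu

from . import imgio
from .fogbank import FogbankParams, separate_objects
from .imgio import TimeLapse
from .simdata import DivisionEvent

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandpassParams:
    """Difference-of-Gaussians band-pass plus threshold.

    Two presets are used: :func:`nucleus_preset` passes whole-nucleus
    scale structure, :func:`condensed_preset` the smaller, brighter
    condensed-DNA puncta.  ``threshold_mode`` is "otsu" (automatic) or
    "fixed" (use ``threshold_value``, the empirically-determined option).
    """

    low_sigma: float
    high_sigma: float
    threshold_mode: str = "otsu"
    threshold_value: float | None = None

    def __post_init__(self) -> None:
        if not self.low_sigma < self.high_sigma:
            raise ValueError("low_sigma must be < high_sigma")
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ValueError("threshold_mode must be 'otsu' or 'fixed'")
        if self.threshold_mode == "fixed" and self.threshold_value is None:
            raise ValueError("fixed mode requires threshold_value")

    @classmethod
    def nucleus_preset(cls) -> "BandpassParams":
        return cls(low_sigma=2.0, high_sigma=12.0)

    @classmethod
    def condensed_preset(cls) -> "BandpassParams":
        return cls(low_sigma=1.0, high_sigma=4.0)


@dataclass(frozen=True)
class AnnotationWindows:
    """Temporal windows for mitotic / daughter labels around a division."""

    frames_before: int = 5
    frames_after: int = 3

    def __post_init__(self) -> None:
        if self.frames_before < 1 or self.frames_after < 1:
            raise ValueError("windows must be >= 1 frame")


def bandpass_response(frame: np.ndarray, bp: BandpassParams) -> np.ndarray:
    return difference_of_gaussians(
        np.asarray(frame, dtype=float), bp.low_sigma, bp.high_sigma
    )


def _threshold(resp: np.ndarray, bp: BandpassParams) -> np.ndarray:
    if bp.threshold_mode == "fixed":
        return resp > bp.threshold_value
    vmin, vmax = float(resp.min()), float(resp.max())
    if vmax - vmin < 1e-12:
        return np.zeros(resp.shape, dtype=bool)
    return resp > threshold_otsu(resp)


def segment_nuclei(
    fluor_frame: np.ndarray,
    bp: BandpassParams | None = None,
    fog: FogbankParams = FogbankParams(),
) -> np.ndarray:
    """Instance-segment nuclei in one fluorescence frame.

    Pipeline: band-pass -> threshold -> FogBank separation -> per-object
    binary erosion by a radius-1 disk.  An all-background result is a
    valid empty mask.
    """
    bp = bp or BandpassParams.nucleus_preset()
    resp = bandpass_response(fluor_frame, bp)
    mask = _threshold(resp, bp)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    # the response itself is the descent surface: nucleus centers peak,
    # contacts form saddles, so touching nuclei separate cleanly
    labels = separate_objects(mask, intensity=resp, params=fog)
    # final erosion: shrink each object by 1 px, keeping objects that
    # would vanish entirely
    eroded_fg = ndi.binary_erosion(labels > 0, structure=np.ones((3, 3)))
    out = np.where(eroded_fg, labels, 0).astype(np.int32)
    for lab in np.unique(labels[labels > 0]):
        if not (out == lab).any():
            out[labels == lab] = lab
    return out


def detect_condensed(
    fluor_frame: np.ndarray,
    instances: np.ndarray,
    bp_condensed: BandpassParams | None = None,
    min_area_fraction: float = 0.10,
) -> set[int]:
    """Flag instances whose condensed-DNA band-pass response is large.

    An instance is a class-2 (mitotic) candidate iff the thresholded
    condensed-scale response covers at least ``min_area_fraction`` of the
    instance's area.
    """
    bp_condensed = bp_condensed or BandpassParams.condensed_preset()
    resp = bandpass_response(fluor_frame, bp_condensed)
    fg = instances > 0
    if not fg.any():
        return set()
    ids = np.unique(instances[fg])
    if bp_condensed.threshold_mode == "fixed":
        thr = float(bp_condensed.threshold_value)
    else:
        # every nucleus rim excites the fine band-pass, so the per-
        # instance peak response of ordinary nuclei sets a stable
        # per-frame baseline; condensed cores stand far above it
        peaks = ndi.labeled_comprehension(
            resp, instances, ids, np.max, float, 0.0
        )
        thr = 1.6 * float(np.median(peaks))
    hot = resp > thr
    flagged = set()
    for lab in ids:
        cell = instances == lab
        need = max(2.0, min_area_fraction * cell.sum())
        if hot[cell].sum() >= need:
            flagged.add(int(lab))
    return flagged


def _centroids(instances: np.ndarray) -> dict[int, np.ndarray]:
    ids = np.unique(instances[instances > 0])
    if ids.size == 0:
        return {}
    coms = ndi.center_of_mass(instances > 0, instances, ids)
    return {int(l): np.asarray(c) for l, c in zip(ids, coms)}


def link_daughters(
    instance_series: Sequence[np.ndarray],
    flagged_series: Sequence[set[int]],
    max_distance: float = 15.0,
    dedup_frames: int = 6,
) -> list[DivisionEvent]:
    """Turn per-frame condensation flags into division events.

    Every object at frame t0 enters a linear-sum assignment against the
    objects at t0+1 on centroid distance (pairs beyond ``max_distance``
    forbidden); each flagged (condensing) object is *duplicated* so it may
    claim two successors.  A division is recorded iff the two copies map
    to two distinct objects at t0+1.  Event positions are the mother
    centroid; the event frame is t0+1, when the daughters first exist.
    """
    if len(instance_series) != len(flagged_series):
        raise ValueError("series lengths differ")
    events: list[DivisionEvent] = []
    big = 1e9
    for t0 in range(len(instance_series) - 1):
        inst0, inst1 = instance_series[t0], instance_series[t0 + 1]
        flags = flagged_series[t0]
        c0 = _centroids(inst0)
        c1 = _centroids(inst1)
        if not c0 or not c1:
            continue
        rows: list[tuple[int, int]] = []  # (object id, copy index)
        for lab in sorted(c0):
            rows.append((lab, 0))
            if lab in flags:
                rows.append((lab, 1))
        cols = sorted(c1)
        nr, nc = len(rows), len(cols)
        # square augmentation: every row/col may instead go unmatched at a
        # cost of the gate distance, so a duplicate claims a second object
        # only when that is genuinely cheaper than leaving it unmatched
        size = nr + nc
        cost = np.full((size, size), big)
        for i, (lab, _) in enumerate(rows):
            for j, lab1 in enumerate(cols):
                d = float(np.linalg.norm(c0[lab] - c1[lab1]))
                if d <= max_distance:
                    cost[i, j] = d
        for i in range(nr):
            cost[i, nc + i] = max_distance
        for j in range(nc):
            cost[nr + j, j] = max_distance
        cost[nr:, nc:] = 0.0
        ri, ci = linear_sum_assignment(cost)
        claimed: dict[int, list[int]] = {}
        for i, j in zip(ri, ci):
            if i >= nr or j >= nc or cost[i, j] >= big:
                continue
            lab = rows[i][0]
            claimed.setdefault(lab, []).append(cols[j])
        for lab in sorted(flags):
            kids = claimed.get(lab, [])
            if len(kids) == 2 and kids[0] != kids[1]:
                events.append(
                    DivisionEvent(
                        mother_id=int(lab),
                        daughter_ids=(int(kids[0]), int(kids[1])),
                        frame=t0 + 1,
                        row=float(c0[lab][0]),
                        col=float(c0[lab][1]),
                    )
                )
    # a condensing nucleus can split transiently a few frames before the
    # definitive separation; the division completes at the *last* split,
    # so nearby earlier events are premature duplicates
    keep = []
    for i, e in enumerate(events):
        premature = any(
            0 < e2.frame - e.frame <= dedup_frames
            and math.hypot(e2.row - e.row, e2.col - e.col) <= max_distance
            for e2 in events
        )
        if not premature:
            keep.append(e)
    return keep


def _chain_object(
    instance_series: Sequence[np.ndarray],
    start_frame: int,
    start_label: int,
    frames: Sequence[int],
    max_distance: float = 15.0,
) -> dict[int, int]:
    """Follow one object across ``frames`` by nearest-centroid chaining.

    Returns {frame: label}.  ``frames`` must be sorted and may extend
    forward or backward from ``start_frame``.
    """
    out = {start_frame: start_label}
    cents = _centroids(instance_series[start_frame])
    if start_label not in cents:
        return {}
    pos = cents[start_label]
    forward = [f for f in frames if f > start_frame]
    backward = [f for f in frames if f < start_frame][::-1]
    for seq in (forward, backward):
        cur = pos
        for f in seq:
            if not (0 <= f < len(instance_series)):
                break
            cf = _centroids(instance_series[f])
            if not cf:
                break
            lab, d = min(
                ((l, np.linalg.norm(c - cur)) for l, c in cf.items()),
                key=lambda x: x[1],
            )
            if d > max_distance:
                break
            out[f] = lab
            cur = cf[lab]
    return out


def build_class_masks(
    instance_series: Sequence[np.ndarray],
    events: Sequence[DivisionEvent],
    windows: AnnotationWindows = AnnotationWindows(),
) -> np.ndarray:
    """4-class mask stack from instances plus division events.

    The mother's pixels become class 2 in the ``frames_before`` frames
    preceding the division; each daughter's pixels become class 3 in the
    ``frames_after`` frames from the division on.  All other nucleus
    pixels are class 1.  Overlapping windows at one pixel: the later
    event wins.  Events whose windows run off the stack are clipped with
    a logged warning.
    """
    n = len(instance_series)
    shape = instance_series[0].shape
    out = np.zeros((n,) + shape, dtype=np.uint8)
    for t in range(n):
        out[t][instance_series[t] > 0] = 1
    for e in sorted(events, key=lambda e: e.frame):
        t_div = e.frame
        lo = t_div - windows.frames_before
        hi = t_div + windows.frames_after - 1
        if lo < 0 or hi > n - 1:
            log.warning(
                "division at frame %d: window [%d, %d] clipped to stack",
                t_div, lo, hi,
            )
        mother_frames = [f for f in range(max(0, lo), t_div) if f < n]
        chain = _chain_object(
            instance_series, t_div - 1, e.mother_id, mother_frames
        ) if t_div - 1 >= 0 else {}
        for f, lab in chain.items():
            out[f][instance_series[f] == lab] = 2
        for did in e.daughter_ids:
            d_frames = [f for f in range(t_div, min(n, t_div + windows.frames_after))]
            if not d_frames:
                continue
            chain = _chain_object(instance_series, t_div, did, d_frames)
            for f, lab in chain.items():
                out[f][instance_series[f] == lab] = 3
    return out


def annotate_timelapse(
    fluor: TimeLapse,
    bp: BandpassParams | None = None,
    bp_condensed: BandpassParams | None = None,
    fog: FogbankParams = FogbankParams(),
    windows: AnnotationWindows = AnnotationWindows(),
):
    """Full annotation chain on a fluorescence stack.

    Returns ``(instance_series, events, class_mask_stack)``: per-frame
    instance masks, linked division events, and the (t, rows, cols)
    4-class stack.
    """
    instances = [segment_nuclei(f, bp, fog) for f in fluor.frames]
    flags = [
        detect_condensed(f, inst, bp_condensed)
        for f, inst in zip(fluor.frames, instances)
    ]
    events = link_daughters(instances, flags)
    classmask = build_class_masks(instances, events, windows)
    return instances, events, classmask


def make_training_tiles(
    phase: TimeLapse,
    classmask: np.ndarray,
    mode: str = "2d",
    tile_2d: tuple[int, int] = (256, 256),
    tile_3d: tuple[int, int, int] = (256, 256, 16),
    normalize: bool = True,
):
    """Cut matched image/label tile pairs for classifier training.

    2D mode: per-frame 256x256 pairs with binary labels (nucleus vs
    background).  3D mode: 256x256x16 spatiotemporal pairs (frames last)
    keeping all four classes; random 128x128x16 crops are drawn from
    these at training time.  Frames are z-score normalized first, the
    same transform inference applies.
    """
    classmask = np.asarray(classmask)
    stack = phase.as_array()
    if normalize:
        stack = np.stack([imgio.zscore_normalize(f) for f in stack])
    if classmask.shape != stack.shape:
        raise ValueError("phase stack and class mask shapes differ")
    pairs = []
    if mode == "2d":
        for t in range(stack.shape[0]):
            img_tiles, _ = imgio.tile_image(stack[t], tile_2d)
            lab_tiles, _ = imgio.tile_image(classmask[t], tile_2d)
            for it, lt in zip(img_tiles, lab_tiles):
                pairs.append((it, (lt > 0).astype(np.uint8)))
    elif mode == "3d":
        if stack.shape[0] < tile_3d[2]:
            raise ValueError(
                f"3D mode needs >= {tile_3d[2]} frames, got {stack.shape[0]}"
            )
        vol = np.moveaxis(stack, 0, -1)  # (rows, cols, frames)
        lab = np.moveaxis(classmask, 0, -1)
        img_tiles, layout = imgio.tile_image(vol, tile_3d)
        lab_tiles, _ = imgio.tile_image(lab, tile_3d)
        pairs = list(zip(img_tiles, lab_tiles))
    else:
        raise ValueError("mode must be '2d' or '3d'")
    return pairs
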