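"""Assignment-based evaluation and single-cell dynamics statistics.

Two families live here.  The first scores a *test* result against a
*reference* by solving a gated linear-sum-assignment problem: object
detection per frame (``match_objects`` / ``detection_scores``), mitosis
events in (x, y, t) (``match_mitoses``), and track identity
(``linkage_error_rate``).  The second turns tracks and lineages into
biology: interdivision times, doubling-time estimates from raw counts or
from counted mitoses, windowed mitosis rates, per-cell mean squared
displacement, and profiles of any per-cell metric versus distance from
the colony edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import linear_sum_assignment

from .imgio import Calibration

_BIG = 1e9  # cost assigned to gated-out pairs


@dataclass(frozen=True)
class MatchConfig:
    """Gates for assignment-based matching.

    max_distance : spatial gate in pixels (default 15).
    max_time_offset : temporal gate in frames, used only when matching
        mitosis events (default 6).
    """

    max_distance: float = 15.0
    max_time_offset: int = 6

    def __post_init__(self) -> None:
        if self.max_distance <= 0 or self.max_time_offset <= 0:
            raise ValueError("gates must be positive")


@dataclass
class MatchResult:
    """Outcome of one gated assignment.

    tp : matched pairs; fp : unmatched test objects ("additional");
    fn : unmatched reference objects ("missing"); pairs : list of
    (reference_id, test_id) for the matches.
    """

    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int]] = field(default_factory=list)


@dataclass(frozen=True)
class ScoreReport:
    """Detection scores derived from a MatchResult."""

    f1: float
    fraction_additional: float
    fraction_missing: float


def _region_props(instances: np.ndarray):
    """Centroids and pixel-index sets per label of an instance mask."""
    instances = np.asarray(instances)
    ids = np.unique(instances[instances > 0])
    centroids = {}
    pixels = {}
    if ids.size:
        coms = ndi.center_of_mass(instances > 0, instances, ids)
        for i, lab in enumerate(ids):
            centroids[int(lab)] = np.asarray(coms[i], dtype=float)
        flat = instances.ravel()
        order = np.argsort(flat, kind="stable")
        sorted_vals = flat[order]
        for lab in ids:
            lo = np.searchsorted(sorted_vals, lab, "left")
            hi = np.searchsorted(sorted_vals, lab, "right")
            pixels[int(lab)] = frozenset(order[lo:hi].tolist())
    return [int(i) for i in ids], centroids, pixels


def pair_cost(
    d: float, iou: float, max_distance: float, w_dist: float = 1.0,
    w_overlap: float = 1.0,
) -> float:
    """Normalized matching cost: w_dist*(d/gate) + w_overlap*(1 - IoU)."""
    return w_dist * (d / max_distance) + w_overlap * (1.0 - iou)


def gated_assignment(cost: np.ndarray, allowed: np.ndarray):
    """Optimal assignment on a gated cost matrix.

    Gated-out pairs get a prohibitive cost; any assignment landing on one
    is discarded afterwards.  Returns the list of (row, col) kept pairs.
    """
    if cost.size == 0:
        return []
    work = np.where(allowed, cost, _BIG)
    rows, cols = linear_sum_assignment(work)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if allowed[r, c]]


def match_objects(
    reference: np.ndarray,
    test: np.ndarray,
    config: MatchConfig = MatchConfig(),
) -> MatchResult:
    """Match test instances to reference instances within one frame.

    Cost combines centroid distance (scaled by the gate) and 1 - IoU;
    pairs farther apart than ``max_distance`` are forbidden.  Leftover
    test objects are counted FP ("additional"), leftover reference
    objects FN ("missing").
    """
    reference = np.asarray(reference)
    test = np.asarray(test)
    if reference.shape != test.shape:
        raise ValueError("reference and test masks must share a shape")
    rids, rcent, rpix = _region_props(reference)
    tids, tcent, tpix = _region_props(test)
    nr, nt = len(rids), len(tids)
    cost = np.zeros((nr, nt))
    allowed = np.zeros((nr, nt), dtype=bool)
    for i, ri in enumerate(rids):
        for j, tj in enumerate(tids):
            d = float(np.linalg.norm(rcent[ri] - tcent[tj]))
            if d > config.max_distance:
                continue
            inter = len(rpix[ri] & tpix[tj])
            union = len(rpix[ri] | tpix[tj])
            iou = inter / union if union else 0.0
            cost[i, j] = pair_cost(d, iou, config.max_distance)
            allowed[i, j] = True
    kept = gated_assignment(cost, allowed)
    pairs = [(rids[i], tids[j]) for i, j in kept]
    return MatchResult(
        tp=len(pairs), fp=nt - len(pairs), fn=nr - len(pairs), pairs=pairs
    )


def detection_scores(
    match: MatchResult | int,
    fp: int | None = None,
    fn: int | None = None,
    reference_count: int | None = None,
) -> ScoreReport:
    """Detection F1 and additional/missing fractions.

    F1 = 2*TP / (2*TP + FN + FP).  The additional and missing fractions
    are FP and FN normalized by the reference object count (TP + FN when
    not given explicitly).  Raises when TP = FP = FN = 0 (F1 undefined).
    """
    if isinstance(match, MatchResult):
        tp, fp_, fn_ = match.tp, match.fp, match.fn
        if fp is not None and reference_count is None:
            reference_count = fp  # detection_scores(match, ref_count) call form
    else:
        tp, fp_, fn_ = int(match), int(fp), int(fn)
    denom = 2 * tp + fn_ + fp_
    if denom == 0:
        raise ValueError("F1 undefined: no objects in reference or test")
    ref = reference_count if reference_count is not None else tp + fn_
    if ref <= 0:
        raise ValueError("reference count must be positive")
    return ScoreReport(
        f1=2 * tp / denom,
        fraction_additional=fp_ / ref,
        fraction_missing=fn_ / ref,
    )


def match_mitoses(
    reference_events: Sequence[tuple[float, float, int]],
    test_events: Sequence[tuple[float, float, int]],
    config: MatchConfig = MatchConfig(),
) -> MatchResult:
    """Match mitosis events (row, col, t) under spatial and temporal gates.

    Assignment cost is the spatial distance; a pair is admissible only if
    it is within ``max_distance`` pixels and ``max_time_offset`` frames.
    """
    nr, nt = len(reference_events), len(test_events)
    cost = np.zeros((nr, nt))
    allowed = np.zeros((nr, nt), dtype=bool)
    for i, (r0, c0, t0) in enumerate(reference_events):
        for j, (r1, c1, t1) in enumerate(test_events):
            d = math.hypot(r0 - r1, c0 - c1)
            if d <= config.max_distance and abs(t0 - t1) <= config.max_time_offset:
                cost[i, j] = d
                allowed[i, j] = True
    kept = gated_assignment(cost, allowed)
    return MatchResult(
        tp=len(kept), fp=nt - len(kept), fn=nr - len(kept), pairs=kept
    )


# ---------------------------------------------------------------------------
# tracking evaluation

def linkage_error_rate(
    reference_tracks: Mapping[int, Mapping[int, tuple[float, float]]],
    test_tracks: Mapping[int, Mapping[int, tuple[float, float]]],
    config: MatchConfig = MatchConfig(),
) -> dict[int, float]:
    """Per-reference-track linkage error rate.

    Tracks are mappings ``track_id -> {frame: (row, col)}``.  In every
    frame, reference positions are paired to test positions by gated
    centroid-distance assignment.  A linkage error is a frame at which the
    paired test id changes while the reference id persists; the rate is
    that count divided by the track's length in frames.  Frames where the
    reference object has no paired test object are skipped.
    """
    frames = sorted(
        {f for tr in reference_tracks.values() for f in tr}
        | {f for tr in test_tracks.values() for f in tr}
    )
    # per frame: reference id -> test id
    paired: dict[int, dict[int, int]] = {}
    for f in frames:
        rids = [tid for tid, tr in reference_tracks.items() if f in tr]
        tids = [tid for tid, tr in test_tracks.items() if f in tr]
        cost = np.zeros((len(rids), len(tids)))
        allowed = np.zeros_like(cost, dtype=bool)
        for i, ri in enumerate(rids):
            p = reference_tracks[ri][f]
            for j, tj in enumerate(tids):
                q = test_tracks[tj][f]
                d = math.hypot(p[0] - q[0], p[1] - q[1])
                if d <= config.max_distance:
                    cost[i, j] = d
                    allowed[i, j] = True
        kept = gated_assignment(cost, allowed)
        paired[f] = {rids[i]: tids[j] for i, j in kept}
    rates: dict[int, float] = {}
    for rid, tr in reference_tracks.items():
        fs = sorted(tr)
        errors = 0
        last_tid = None
        for f in fs:
            tid = paired.get(f, {}).get(rid)
            if tid is None:
                continue
            if last_tid is not None and tid != last_tid:
                errors += 1
            last_tid = tid
        rates[rid] = errors / len(fs) if fs else 0.0
    return rates


def track_lengths(
    tracks: Mapping[int, Mapping[int, tuple[float, float]]]
) -> dict[int, int]:
    """Number of frames each track is continuously identified."""
    return {tid: len(tr) for tid, tr in tracks.items()}


# ---------------------------------------------------------------------------
# division statistics

def interdivision_times(
    lineage,
    calibration: Calibration = Calibration(),
    plausibility_bound_h: float = 9.0,
) -> tuple[list[float], dict[str, int]]:
    """Interdivision times (hours) for complete generations.

    A complete generation is a track born at its mother's division that
    itself divides: the interdivision time is (own division frame - birth
    frame) * frame_interval.  Also reports how many values fall below /
    at-or-above the plausibility bound (default 9 h: shorter cycles are
    likely tracking errors).

    ``lineage`` is anything exposing ``division_frame_of(track_id)`` and
    ``birth_frame_of(track_id)`` plus ``complete_generations()`` — see
    ``tracker.Lineage``.
    """
    hours = []
    for tid in lineage.complete_generations():
        dt_frames = lineage.division_frame_of(tid) - lineage.birth_frame_of(tid)
        hours.append(dt_frames * calibration.frame_interval / 60.0)
    counts = {
        "below_bound": sum(h < plausibility_bound_h for h in hours),
        "at_or_above_bound": sum(h >= plausibility_bound_h for h in hours),
    }
    return hours, counts


def doubling_time_counts(
    counts: Sequence[float],
    calibration: Calibration = Calibration(),
    window_frames: int = 30,
) -> np.ndarray:
    """Doubling time from raw cell counts in sliding windows.

    For each window start t0, DT = ln 2 / (ln(N_t/N_0) / t) with
    N_0 = counts[t0], N_t = counts[t0 + window_frames], and t the window
    span in hours.  Windows with non-growing counts (ratio <= 1) yield
    NaN, the undefined-value marker.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts[: max(1, len(counts) - window_frames)] == 0):
        raise ValueError("N_0 must be positive in every window")
    t_hours = window_frames * calibration.frame_interval / 60.0
    out = np.full(max(0, len(counts) - window_frames), np.nan)
    for i in range(len(out)):
        n0, nt = counts[i], counts[i + window_frames]
        if n0 > 0 and nt > n0:
            out[i] = math.log(2) / (math.log(nt / n0) / t_hours)
    return out


def doubling_time_mitoses(
    counts_at_window_start: Sequence[float],
    mitoses_per_window: Sequence[float],
    window_hours: float,
) -> np.ndarray:
    """Doubling time from counted mitoses per window.

    DT = ln 2 / (ln((N_t0 + #mitoses) / N_t0) / t).  Because every counted
    division adds one cell, N_t0 + #mitoses is the count the population
    would reach without death; comparing this estimator with
    ``doubling_time_counts`` therefore separates division slowdown from
    cell loss.  Windows with zero mitoses yield NaN.
    """
    n0 = np.asarray(counts_at_window_start, dtype=float)
    m = np.asarray(mitoses_per_window, dtype=float)
    if n0.shape != m.shape:
        raise ValueError("window series must align")
    if np.any(n0 == 0):
        raise ValueError("N_0 must be positive")
    out = np.full(n0.shape, np.nan)
    grow = m > 0
    out[grow] = math.log(2) / (
        np.log((n0[grow] + m[grow]) / n0[grow]) / window_hours
    )
    return out


def mitosis_rate(
    event_frames: Sequence[int],
    n_frames: int,
    calibration: Calibration = Calibration(),
    window_minutes: float = 60.0,
    denominator: float | Sequence[float] | None = None,
    smoothing_frames: int = 20,
) -> np.ndarray:
    """Windowed, smoothed mitosis rate series.

    Counts events inside a sliding window of ``window_minutes`` starting
    at every frame, divides by ``denominator`` (a scalar such as the
    initial cell count, or a per-frame series such as the current count),
    then applies a ``smoothing_frames`` moving average.
    """
    window = int(round(window_minutes / calibration.frame_interval))
    ev = np.bincount(
        np.asarray(event_frames, dtype=int), minlength=n_frames
    )[:n_frames].astype(float)
    csum = np.concatenate([[0.0], np.cumsum(ev)])
    n_windows = max(0, n_frames - window + 1)
    raw = csum[window : window + n_windows] - csum[:n_windows]
    if denominator is None:
        denom = np.ones(n_windows)
    else:
        denom = np.asarray(denominator, dtype=float)
        if denom.ndim == 0:
            denom = np.full(n_windows, float(denom))
        else:
            denom = denom[:n_windows]
    rate = raw / denom
    if smoothing_frames > 1 and rate.size:
        kernel = np.ones(smoothing_frames) / smoothing_frames
        rate = np.convolve(rate, kernel, mode="same")
    return rate


# ---------------------------------------------------------------------------
# motility

def msd(
    tracks: Mapping[int, Mapping[int, tuple[float, float]]],
    calibration: Calibration = Calibration(),
    horizon_minutes: float = 60.0,
) -> dict[tuple[int, int], float]:
    """Per-cell, per-start-frame mean squared displacement (μm²).

    MSD(track, t0) = mean over lags Δ in 1..H of |x(t0+Δ) - x(t0)|²,
    H = horizon in frames; converted to μm² via the pixel area.  Start
    frames whose track does not cover the full horizon are skipped.
    """
    horizon = int(round(horizon_minutes / calibration.frame_interval))
    out: dict[tuple[int, int], float] = {}
    for tid, tr in tracks.items():
        frames = sorted(tr)
        fset = set(frames)
        for t0 in frames:
            lags = [t0 + d for d in range(1, horizon + 1)]
            if not all(t in fset for t in lags):
                continue
            p0 = np.asarray(tr[t0], dtype=float)
            sq = [
                float(np.sum((np.asarray(tr[t], dtype=float) - p0) ** 2))
                for t in lags
            ]
            out[(tid, t0)] = float(np.mean(sq)) * calibration.pixel_area
    return out


def colony_mask(
    instances: np.ndarray, closing_radius: int | None = None
) -> np.ndarray:
    """Colony footprint: morphological closing of the nucleus union.

    The closing radius defaults to three times the typical nucleus radius
    (estimated from the median object area), bridging inter-nuclear gaps
    so the colony reads as one region.
    """
    fg = np.asarray(instances) > 0
    if not fg.any():
        return fg
    if closing_radius is None:
        ids, areas = np.unique(
            np.asarray(instances)[fg], return_counts=True
        )
        r_nuc = math.sqrt(float(np.median(areas)) / math.pi)
        closing_radius = max(1, int(round(3 * r_nuc)))
    from skimage.morphology import disk

    return ndi.binary_closing(
        fg, structure=disk(closing_radius), border_value=0
    )


def edge_distances(
    instances: np.ndarray,
    centroids: Mapping[int, tuple[float, float]],
    calibration: Calibration = Calibration(),
    closing_radius: int | None = None,
) -> dict[int, float]:
    """Distance (μm) of each cell centroid from the colony edge."""
    cmask = colony_mask(instances, closing_radius)
    dist = ndi.distance_transform_edt(cmask)
    px = calibration.pixel_size_um
    out = {}
    for cid, (r, c) in centroids.items():
        ri = int(np.clip(round(r), 0, dist.shape[0] - 1))
        ci = int(np.clip(round(c), 0, dist.shape[1] - 1))
        out[cid] = float(dist[ri, ci]) * px
    return out


def edge_distance_profile(
    distances_um: Sequence[float],
    values: Sequence[float],
    bin_width_um: float = 25.0,
) -> "pandas.DataFrame":
    """Bin a per-cell metric by distance from the colony edge.

    Returns a DataFrame with bin centers, mean metric value and cell count
    per bin — the form used for MSD-, mitosis-rate- and cell-fraction-
    versus-edge-distance profiles.
    """
    import pandas as pd

    d = np.asarray(distances_um, dtype=float)
    v = np.asarray(values, dtype=float)
    if d.shape != v.shape:
        raise ValueError("distances and values must align")
    if d.size == 0:
        return pd.DataFrame(columns=["bin_center_um", "mean_value", "n"])
    nbins = int(np.floor(d.max() / bin_width_um)) + 1
    idx = np.minimum((d / bin_width_um).astype(int), nbins - 1)
    rows = []
    for b in range(nbins):
        sel = idx == b
        if not sel.any():
            continue
        rows.append(
            {
                "bin_center_um": (b + 0.5) * bin_width_um,
                "mean_value": float(v[sel].mean()),
                "n": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)
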