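"""Synthetic colony time-lapses with complete ground truth.

The simulator emulates the statistical structure the pipeline assumes for
pluripotent stem-cell colonies imaged every two minutes: elliptical
nuclei packed in a colony cluster, Brownian-like motion that is stronger
at the colony edge than in the interior, and divisions in which the
nucleus brightens with condensed DNA for a few frames before splitting
into two daughters.  It renders a fluorescence channel (bright nuclei on
a dark background, brighter condensed core before division) and a
phase-like channel (a deterministic edge-enhanced, low-contrast
transform of the same scene), and returns the full truth: per-frame
instance masks, 4-class masks (0 background / 1 nucleus / 2 mitotic /
3 daughter), tracks, lineage and division events.

A lightweight birth–death population simulator (``simulate_population``)
shares the same interdivision-time model without rendering images, for
count-based estimator studies at large cell numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
from scipy import ndimage as ndi
from scipy.stats import truncnorm

from .imgio import Calibration, TimeLapse

# rendering levels (arbitrary fluorescence units)
BG_LEVEL = 10.0
NUCLEUS_LEVEL = 100.0
# condensation concentrates the chromatin signal into the core: the extra
# flux scales with nucleus area, so per-pixel core brightness is roughly
# 1.5x the nucleus level regardless of cell size
CONDENSED_FLUX_FACTOR = 0.35


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic time-lapse.

    Interdivision times are drawn from a normal distribution truncated to
    the biologically plausible 9–24 h band; the 15 h default mean matches
    the median cycle length of cultured pluripotent stem cells.  Motility
    is a per-frame Gaussian step whose standard deviation depends on
    whether the cell currently sits near the colony edge.
    """

    n_cells_initial: int = 20
    n_frames: int = 60
    frame_interval_min: float = 2.0
    image_shape: tuple[int, int] = (256, 256)
    # a stem-cell nucleus is ~10 um across; at ~0.64 um pixels that is a
    # semi-axis of 6-9 px
    nucleus_radii: tuple[float, float] = (6.0, 9.0)  # semi-axis range, px
    motility_sigma_edge: float = 0.6  # px / frame
    motility_sigma_interior: float = 0.25
    interdivision_mean_h: float = 15.0
    interdivision_sd_h: float = 3.0
    interdivision_min_h: float = 9.0
    interdivision_max_h: float = 24.0
    condensation_frames_before: int = 5
    daughter_frames_after: int = 3
    noise_sd: float = 0.0
    death_rate_per_frame: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_initial < 1 or self.n_frames < 1:
            raise ValueError("counts must be positive")
        if not (
            self.interdivision_min_h
            <= self.interdivision_mean_h
            <= self.interdivision_max_h
        ):
            raise ValueError("interdivision mean outside plausibility band")
        if self.condensation_frames_before < 1 or self.daughter_frames_after < 1:
            raise ValueError("annotation windows must be >= 1 frame")

    @property
    def calibration(self) -> Calibration:
        return Calibration(frame_interval=self.frame_interval_min)

    def interdivision_distribution(self):
        """Frozen scipy distribution of interdivision times in hours."""
        a = (self.interdivision_min_h - self.interdivision_mean_h) / self.interdivision_sd_h
        b = (self.interdivision_max_h - self.interdivision_mean_h) / self.interdivision_sd_h
        return truncnorm(a, b, loc=self.interdivision_mean_h, scale=self.interdivision_sd_h)


@dataclass
class DivisionEvent:
    """One division: mother's last position and the frame daughters appear."""

    mother_id: int
    daughter_ids: tuple[int, int]
    frame: int  # first frame at which the daughters exist
    row: float
    col: float


@dataclass
class SimulationTruth:
    """Complete ground truth for a simulated time-lapse."""

    instance_masks: list[np.ndarray]  # label = track id
    class_masks: list[np.ndarray]  # values {0,1,2,3}
    tracks: dict[int, dict[int, tuple[float, float]]]
    parents: dict[int, int]  # child track id -> mother track id
    divisions: list[DivisionEvent]
    config: SimulationConfig

    def n_cells(self, frame: int) -> int:
        return sum(1 for tr in self.tracks.values() if frame in tr)

    def counts(self) -> np.ndarray:
        return np.array(
            [self.n_cells(t) for t in range(self.config.n_frames)]
        )

    def completed_interdivision_hours(self) -> list[float]:
        """Lifetimes (h) of tracks born at a division that divide again."""
        div_frame = {e.mother_id: e.frame for e in self.divisions}
        out = []
        for e in self.divisions:
            mid = e.mother_id
            if mid in self.parents and mid in div_frame:
                birth = min(self.tracks[mid])
                out.append(
                    (div_frame[mid] - birth)
                    * self.config.frame_interval_min
                    / 60.0
                )
        return out


@dataclass
class _Cell:
    tid: int
    row: float
    col: float
    a: float  # major semi-axis
    b: float  # minor semi-axis
    theta: float
    birth: int
    t_div: int  # frame at which this cell's daughters appear (may be > n_frames)


def _draw_division_offset(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    hours = float(cfg.interdivision_distribution().rvs(random_state=rng))
    return max(1, int(round(hours * 60.0 / cfg.frame_interval_min)))


def _place_colony(cfg: SimulationConfig, rng: np.random.Generator):
    """Dart-throw non-overlapping positions in a central disk."""
    h, w = cfg.image_shape
    r_max = cfg.nucleus_radii[1]
    sep = 2.0 * r_max + 1.0
    colony_r = sep * math.sqrt(cfg.n_cells_initial / 1.6)
    if 2 * (colony_r + 2 * r_max) > min(h, w):
        raise ValueError(
            f"image {cfg.image_shape} too small for {cfg.n_cells_initial} cells"
        )
    center = np.array([h / 2.0, w / 2.0])
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < cfg.n_cells_initial:
        attempts += 1
        if attempts > 20000:
            raise ValueError("could not place initial cells without overlap")
        rad = colony_r * math.sqrt(rng.uniform())
        ang = rng.uniform(0, 2 * math.pi)
        p = center + rad * np.array([math.sin(ang), math.cos(ang)])
        if all(np.linalg.norm(p - q) >= sep for q in pts):
            pts.append(p)
    return pts, center, colony_r


def _ellipse_mask(shape, row, col, a, b, theta):
    """Boolean mask of a filled rotated ellipse (bounding-box local eval)."""
    h, w = shape
    rmax = max(a, b)
    r0, r1 = int(max(0, row - rmax - 1)), int(min(h, row + rmax + 2))
    c0, c1 = int(max(0, col - rmax - 1)), int(min(w, col + rmax + 2))
    if r0 >= r1 or c0 >= c1:
        return None, None
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr, dc = rr - row, cc - col
    ct, st = math.cos(theta), math.sin(theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    local = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return (slice(r0, r1), slice(c0, c1)), local


def simulate_timelapse(
    config: SimulationConfig,
) -> tuple[TimeLapse, TimeLapse, SimulationTruth]:
    """Simulate a colony and render paired fluorescence / phase-like stacks.

    Returns ``(fluorescence, phase_like, truth)``.  Identical configs
    (including the seed) give bit-identical outputs.
    """
    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)
    cb, da = cfg.condensation_frames_before, cfg.daughter_frames_after

    pts, colony_center, colony_r0 = _place_colony(cfg, rng)
    cells: list[_Cell] = []
    next_tid = 1
    for p in pts:
        a = rng.uniform(*cfg.nucleus_radii)
        b = a * rng.uniform(0.7, 0.95)
        theta = rng.uniform(0, math.pi)
        total = _draw_division_offset(cfg, rng)
        # initial cells are mid-cycle: uniformly random remaining fraction
        remaining = max(1, int(round(total * rng.uniform())))
        cells.append(
            _Cell(next_tid, p[0], p[1], a, b, theta, birth=0, t_div=remaining)
        )
        next_tid += 1

    tracks: dict[int, dict[int, tuple[float, float]]] = {
        c.tid: {} for c in cells
    }
    parents: dict[int, int] = {}
    divisions: list[DivisionEvent] = []
    instance_masks: list[np.ndarray] = []
    condensed_flags: list[dict[int, bool]] = []
    h, w = cfg.image_shape

    for t in range(cfg.n_frames):
        # divisions scheduled for this frame: mother is replaced by daughters
        new_cells: list[_Cell] = []
        survivors: list[_Cell] = []
        for c in cells:
            if c.t_div == t:
                d_a = max(cfg.nucleus_radii[0] * 0.85, c.a * 0.8)
                d_b = d_a * rng.uniform(0.7, 0.95)
                # daughters form at opposite spindle poles, clearly apart
                off = d_a + 2.5
                dr = off * math.cos(c.theta)
                dc = off * math.sin(c.theta)
                kids = []
                for sgn in (+1, -1):
                    kr = min(max(c.row + sgn * dr, d_a + 1), h - d_a - 2)
                    kc = min(max(c.col + sgn * dc, d_a + 1), w - d_a - 2)
                    kid = _Cell(
                        next_tid,
                        kr,
                        kc,
                        d_a,
                        d_b,
                        rng.uniform(0, math.pi),
                        birth=t,
                        t_div=t + _draw_division_offset(cfg, rng),
                    )
                    parents[kid.tid] = c.tid
                    tracks[kid.tid] = {}
                    kids.append(kid)
                    next_tid += 1
                divisions.append(
                    DivisionEvent(
                        c.tid, (kids[0].tid, kids[1].tid), t, c.row, c.col
                    )
                )
                new_cells.extend(kids)
            else:
                survivors.append(c)
        cells = survivors + new_cells

        # random death (apoptosis); default off
        if cfg.death_rate_per_frame > 0 and cells:
            keep = rng.uniform(size=len(cells)) >= cfg.death_rate_per_frame
            cells = [c for c, k in zip(cells, keep) if k]

        # Brownian step; edge cells (outer 30% of the colony radius) move more
        if t > 0 and cells:
            pos = np.array([[c.row, c.col] for c in cells])
            centroid = pos.mean(axis=0)
            rad = np.linalg.norm(pos - centroid, axis=1)
            edge_cut = 0.7 * max(rad.max(), 1.0)
            for c, r in zip(cells, rad):
                sigma = (
                    cfg.motility_sigma_edge
                    if r >= edge_cut
                    else cfg.motility_sigma_interior
                )
                c.row += sigma * rng.standard_normal()
                c.col += sigma * rng.standard_normal()
        # excluded volume: nuclei push each other apart instead of
        # interpenetrating (overlaps stay transient and shallow)
        if cells:
            _relax_overlaps(cells)
            for c in cells:
                c.row = float(np.clip(c.row, c.a + 1, h - c.a - 2))
                c.col = float(np.clip(c.col, c.a + 1, w - c.a - 2))

        inst = np.zeros((h, w), dtype=np.int32)
        cflags: dict[int, bool] = {}
        for c in cells:
            tracks[c.tid][t] = (c.row, c.col)
            box, local = _ellipse_mask((h, w), c.row, c.col, c.a, c.b, c.theta)
            if box is not None:
                region = inst[box]
                region[local] = c.tid
            cflags[c.tid] = t >= c.t_div - cb  # condensing before division
        instance_masks.append(inst)
        condensed_flags.append(cflags)

    class_masks = _build_truth_class_masks(
        instance_masks, tracks, parents, divisions, cb, da
    )

    # rendering -------------------------------------------------------------
    fluor_frames, phase_frames = [], []
    for t in range(cfg.n_frames):
        scene = np.full((h, w), BG_LEVEL)
        inst = instance_masks[t]
        scene[inst > 0] = NUCLEUS_LEVEL
        # condensed-DNA core: inner ellipse of each condensing cell
        cond = condensed_flags[t]
        for tid, flag in cond.items():
            if not flag or t not in tracks[tid]:
                continue
            row, col = tracks[tid][t]
            cell_px = inst == tid
            if not cell_px.any():
                continue
            area = float(cell_px.sum())
            r_core = max(1.5, 0.45 * math.sqrt(area / math.pi))
            box, local = _ellipse_mask((h, w), row, col, r_core, r_core, 0.0)
            if box is not None:
                core_sel = local & (inst[box] == tid)
                n_core = int(core_sel.sum())
                if n_core:
                    extra = CONDENSED_FLUX_FACTOR * NUCLEUS_LEVEL * area / n_core
                    region = scene[box]
                    region[core_sel] += extra
        phase = render_phase_like(scene)
        if cfg.noise_sd > 0:
            scene = scene + rng.normal(0, cfg.noise_sd, scene.shape)
            phase = phase + rng.normal(0, cfg.noise_sd, phase.shape)
        fluor_frames.append(scene)
        phase_frames.append(phase)

    cal = cfg.calibration
    truth = SimulationTruth(
        instance_masks, class_masks, tracks, parents, divisions, cfg
    )
    return (
        TimeLapse(fluor_frames, cal),
        TimeLapse(phase_frames, cal),
        truth,
    )


def _relax_overlaps(cells: list["_Cell"], sweeps: int = 4) -> None:
    """Pairwise soft repulsion: separate overlapping nuclei symmetrically."""
    for _ in range(sweeps):
        moved = False
        for i in range(len(cells)):
            ci = cells[i]
            ri = 0.5 * (ci.a + ci.b)
            for j in range(i + 1, len(cells)):
                cj = cells[j]
                rj = 0.5 * (cj.a + cj.b)
                min_d = 0.95 * (ri + rj)
                dr, dc = cj.row - ci.row, cj.col - ci.col
                d = math.hypot(dr, dc)
                if d >= min_d:
                    continue
                if d < 1e-6:
                    dr, dc, d = 1.0, 0.0, 1.0
                push = 0.5 * (min_d - d)
                ur, uc = dr / d, dc / d
                ci.row -= push * ur
                ci.col -= push * uc
                cj.row += push * ur
                cj.col += push * uc
                moved = True
        if not moved:
            break


def render_phase_like(scene: np.ndarray) -> np.ndarray:
    """Deterministic phase-contrast-like rendering of a fluorescence scene.

    Nuclei appear as faint dark regions with bright edge halos on a mid-
    gray background — enough structure for a pixel classifier to learn,
    without trivially mirroring the fluorescence contrast.
    """
    s = ndi.gaussian_filter(scene.astype(float), 1.2)
    span = max(s.max() - s.min(), 1e-9)
    sn = (s - s.min()) / span
    gr = ndi.sobel(sn, axis=0)
    gc = ndi.sobel(sn, axis=1)
    edges = np.hypot(gr, gc)
    edges = edges / max(edges.max(), 1e-9)
    return 120.0 + 35.0 * edges - 18.0 * sn


def _build_truth_class_masks(
    instance_masks, tracks, parents, divisions, cb, da
) -> list[np.ndarray]:
    n = len(instance_masks)
    masks = []
    mother_window: dict[int, tuple[int, int]] = {}  # tid -> (t0, t1) class-2
    daughter_window: dict[int, tuple[int, int]] = {}
    for e in divisions:
        mother_window[e.mother_id] = (e.frame - cb, e.frame - 1)
        for did in e.daughter_ids:
            daughter_window[did] = (e.frame, e.frame + da - 1)
    for t in range(n):
        inst = instance_masks[t]
        cls = (inst > 0).astype(np.uint8)
        for tid, (t0, t1) in mother_window.items():
            if t0 <= t <= t1:
                cls[inst == tid] = 2
        for tid, (t0, t1) in daughter_window.items():
            if t0 <= t <= t1:
                cls[inst == tid] = 3
        masks.append(cls)
    return masks


# ---------------------------------------------------------------------------
# oracle classifier

def oracle_classifier(
    truth: SimulationTruth,
    flip_rate: float,
    rng_seed: int,
    n_classes: int = 4,
) -> list[np.ndarray]:
    """Per-frame class-probability maps that are right except for flips.

    The argmax of each returned (rows, cols, n_classes) map equals the
    truth class everywhere except at a ``flip_rate`` fraction of pixels,
    chosen reproducibly from ``rng_seed``, where it is a uniformly random
    *other* class.
    """
    if not (0 <= flip_rate < 0.5):
        raise ValueError("flip_rate must be in [0, 0.5)")
    rng = np.random.default_rng(rng_seed)
    maps = []
    for cls in truth.class_masks:
        labels = cls.astype(int).copy()
        if flip_rate > 0:
            flip = rng.uniform(size=labels.shape) < flip_rate
            offsets = rng.integers(1, n_classes, size=labels.shape)
            labels[flip] = (labels[flip] + offsets[flip]) % n_classes
        prob = np.full(labels.shape + (n_classes,), 0.1 / (n_classes - 1))
        for k in range(n_classes):
            prob[labels == k, k] = 0.9
        maps.append(prob)
    return maps


def sweep_fixture(
    n_frames: int = 4,
    image_shape: tuple[int, int] = (200, 200),
    rng_seed: int = 0,
):
    """Mask series for studying object-separation parameters.

    Each frame holds touching pairs of small elliptical nuclei together
    with the two imperfections a thresholded microscopy mask carries:
    background specks (a few pixels, should be discarded) and partial
    nucleus fragments (10-14 px, true objects that an aggressive size
    filter would lose).  Returns (binary masks, reference instance masks).
    """
    rng = np.random.default_rng(rng_seed)
    h, w = image_shape
    masks, refs = [], []
    for _ in range(n_frames):
        ref = np.zeros(image_shape, dtype=np.int32)
        lab = 0
        # touching pairs of nuclei
        for _ in range(8):
            r = rng.uniform(20, h - 20)
            c = rng.uniform(20, w - 30)
            a = rng.uniform(2.4, 3.2)
            for k in range(2):
                lab += 1
                cc = c + k * (2 * a - 0.5)
                box, local = _ellipse_mask(
                    image_shape, r, cc, a, a * 0.85, rng.uniform(0, math.pi)
                )
                if box is not None:
                    region = ref[box]
                    region[local & (region == 0)] = lab
        # partial fragments: true nuclei detected at reduced extent
        for _ in range(4):
            lab += 1
            r, c = rng.uniform(15, h - 15), rng.uniform(15, w - 15)
            box, local = _ellipse_mask(image_shape, r, c, 2.1, 1.7, 0.0)
            if box is not None:
                region = ref[box]
                region[local & (region == 0)] = lab
        mask = ref > 0
        # background specks (not in the reference)
        for _ in range(10):
            r = int(rng.uniform(5, h - 5))
            c = int(rng.uniform(5, w - 5))
            if mask[max(0, r - 5) : r + 5, max(0, c - 5) : c + 5].any():
                continue
            sz = int(rng.integers(5, 9))
            blob = np.zeros(image_shape, dtype=bool)
            blob[r, c] = True
            blob = ndi.binary_dilation(blob, iterations=1)
            extra = np.flatnonzero(
                ndi.binary_dilation(blob) & ~blob
            )
            take = rng.permutation(extra)[: max(0, sz - int(blob.sum()))]
            blob.ravel()[take] = True
            mask |= blob
        masks.append(mask)
        refs.append(ref)
    return masks, refs


# ---------------------------------------------------------------------------
# lightweight population model (no rendering)

@dataclass
class PopulationResult:
    """Counts and events from a birth–death simulation without images."""

    counts: np.ndarray  # cells per frame
    division_frames: list[int]
    death_frames: list[int]
    interdivision_hours: list[float]  # completed generations only
    config: SimulationConfig


def simulate_population(config: SimulationConfig) -> PopulationResult:
    """Birth–death process sharing the image simulator's division model.

    Tracks only division schedules and counts — suitable for studying
    count-based doubling-time and interdivision estimators at cell
    numbers far beyond what image rendering supports.
    """
    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)
    dist = cfg.interdivision_distribution()

    def frames_of(hours: float) -> int:
        return max(1, int(round(hours * 60.0 / cfg.frame_interval_min)))

    # (t_div, birth_frame, born_at_division)
    cells: list[tuple[int, int, bool]] = []
    for _ in range(cfg.n_cells_initial):
        total = frames_of(float(dist.rvs(random_state=rng)))
        remaining = max(1, int(round(total * rng.uniform())))
        cells.append((remaining, 0, False))

    counts = np.zeros(cfg.n_frames, dtype=int)
    division_frames: list[int] = []
    death_frames: list[int] = []
    interdiv: list[float] = []
    for t in range(cfg.n_frames):
        nxt: list[tuple[int, int, bool]] = []
        for t_div, birth, full_gen in cells:
            if t_div == t:
                division_frames.append(t)
                if full_gen:
                    interdiv.append(
                        (t - birth) * cfg.frame_interval_min / 60.0
                    )
                for _ in range(2):
                    off = frames_of(float(dist.rvs(random_state=rng)))
                    nxt.append((t + off, t, True))
            else:
                nxt.append((t_div, birth, full_gen))
        if cfg.death_rate_per_frame > 0 and nxt:
            keep = rng.uniform(size=len(nxt)) >= cfg.death_rate_per_frame
            died = int((~keep).sum())
            death_frames.extend([t] * died)
            nxt = [c for c, k in zip(nxt, keep) if k]
        cells = nxt
        counts[t] = len(cells)
    return PopulationResult(
        counts, division_frames, death_frames, interdiv, cfg
    )
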