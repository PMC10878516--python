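"""Image stack I/O, focus selection, stitching, normalization and tiling.

The pipeline's universal container is :class:`TimeLapse`: an ordered list of
2-D grayscale frames plus a :class:`Calibration` that converts pixels to
micrometres and frame indices to minutes.  Images travel on disk as
multi-page TIFF (16-bit unsigned for intensities, 32-bit unsigned for label
masks); tiling layouts are JSON sidecars.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage as ndi


@dataclass(frozen=True)
class Calibration:
    """Spatial and temporal calibration of an acquisition.

    Parameters
    ----------
    pixel_area : float
        Area covered by one pixel, in square micrometres.  The default of
        0.406 corresponds to a 10x objective on the acquisition system the
        defaults emulate.
    frame_interval : float
        Minutes elapsed between consecutive frames (default 2.0).
    """

    pixel_area: float = 0.406
    frame_interval: float = 2.0

    def __post_init__(self) -> None:
        if self.pixel_area <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_area and frame_interval must be positive")

    @property
    def pixel_size_um(self) -> float:
        """Linear pixel size in micrometres (sqrt of pixel area)."""
        return math.sqrt(self.pixel_area)


@dataclass
class TimeLapse:
    """Ordered grayscale frames with calibration.

    ``frames`` is a list of equally shaped 2-D float arrays; ``z_planes``
    optionally records how many focal planes were acquired per timepoint
    before focus selection collapsed them.
    """

    frames: list[np.ndarray]
    calibration: Calibration = field(default_factory=Calibration)
    z_planes: int | None = None

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("TimeLapse requires at least one frame")
        shape = self.frames[0].shape
        for i, f in enumerate(self.frames):
            f = np.asarray(f)
            if f.ndim != 2:
                raise ValueError(f"frame {i} is not 2-D")
            if f.shape != shape:
                raise ValueError("all frames must share one shape")
            if not np.all(np.isfinite(f)):
                raise ValueError(f"frame {i} contains non-finite values")
            self.frames[i] = f

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    def as_array(self) -> np.ndarray:
        """Stack frames into a (t, rows, cols) array."""
        return np.stack(self.frames, axis=0)


@dataclass
class TileGrid:
    """2-D arrangement of equally shaped field-of-view images.

    ``overlap_fraction`` is the fraction of the linear tile size shared with
    each neighbor (default 0.10, the nominal stage overlap).
    """

    tiles: list[list[np.ndarray]]
    overlap_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_fraction < 0.5):
            raise ValueError("overlap_fraction must be in [0, 0.5)")
        if len(self.tiles) == 0 or any(len(r) == 0 for r in self.tiles):
            raise ValueError("empty tile grid")
        ncols = len(self.tiles[0])
        shape = np.asarray(self.tiles[0][0]).shape
        for r, row in enumerate(self.tiles):
            if len(row) != ncols:
                raise ValueError("ragged tile grid")
            for c, t in enumerate(row):
                if np.asarray(t).shape != shape:
                    raise ValueError(f"tile ({r},{c}) shape mismatch")


# ---------------------------------------------------------------------------
# focus selection

def sharpness(plane: np.ndarray) -> float:
    """Sharpness score of one plane: variance of its Laplacian."""
    return float(np.var(ndi.laplace(np.asarray(plane, dtype=float))))


def select_best_focus(
    z_stack: Sequence[np.ndarray], return_index: bool = False
) -> np.ndarray | tuple[np.ndarray, int]:
    """Pick the sharpest plane from a z-stack.

    Sharpness is the variance of the Laplacian; ties break toward the lower
    plane index.  With ``return_index`` the chosen index is reported too.
    """
    if len(z_stack) == 0:
        raise ValueError("empty z-stack")
    shape = np.asarray(z_stack[0]).shape
    if any(np.asarray(p).shape != shape for p in z_stack):
        raise ValueError("z planes must share one shape")
    scores = [sharpness(p) for p in z_stack]
    idx = int(np.argmax(scores))
    best = np.asarray(z_stack[idx])
    return (best, idx) if return_index else best


# ---------------------------------------------------------------------------
# stitching

def stitch_grid(grid: TileGrid) -> np.ndarray:
    """Compose a tile grid into one mosaic using nominal stage offsets.

    Each tile is placed at its nominal position (step = tile size minus
    overlap); pixels in overlap strips are averaged over all contributing
    tiles.  No registration refinement is performed.
    """
    nrows, ncols = len(grid.tiles), len(grid.tiles[0])
    th, tw = np.asarray(grid.tiles[0][0]).shape
    step_r = int(round(th * (1 - grid.overlap_fraction)))
    step_c = int(round(tw * (1 - grid.overlap_fraction)))
    out_h = step_r * (nrows - 1) + th
    out_w = step_c * (ncols - 1) + tw
    acc = np.zeros((out_h, out_w), dtype=float)
    cnt = np.zeros((out_h, out_w), dtype=float)
    for r in range(nrows):
        for c in range(ncols):
            r0, c0 = r * step_r, c * step_c
            acc[r0 : r0 + th, c0 : c0 + tw] += np.asarray(
                grid.tiles[r][c], dtype=float
            )
            cnt[r0 : r0 + th, c0 : c0 + tw] += 1.0
    return acc / cnt


# ---------------------------------------------------------------------------
# normalization

def zscore_normalize(image: np.ndarray) -> np.ndarray:
    """Z-score normalize an image to zero mean, unit standard deviation."""
    image = np.asarray(image, dtype=float)
    if image.size <= 1:
        raise ValueError("image must have more than one pixel")
    sd = image.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant image (zero variance)")
    return (image - image.mean()) / sd


# ---------------------------------------------------------------------------
# tiling

@dataclass(frozen=True)
class TileLayout:
    """Record of how an array was cut into tiles, enabling exact reassembly."""

    original_shape: tuple[int, ...]
    padded_shape: tuple[int, ...]
    tile_shape: tuple[int, ...]
    grid_shape: tuple[int, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "original_shape": list(self.original_shape),
                "padded_shape": list(self.padded_shape),
                "tile_shape": list(self.tile_shape),
                "grid_shape": list(self.grid_shape),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TileLayout":
        d = json.loads(text)
        return cls(
            tuple(d["original_shape"]),
            tuple(d["padded_shape"]),
            tuple(d["tile_shape"]),
            tuple(d["grid_shape"]),
        )


def tile_image(
    image: np.ndarray,
    tile_shape: Sequence[int],
    pad_mode: str = "reflect",
) -> tuple[list[np.ndarray], TileLayout]:
    """Cut an array into a grid of equally sized tiles.

    The array is padded (reflect by default) up to a multiple of
    ``tile_shape`` in every dimension, then cut without overlap.  Tiles are
    returned in row-major grid order.  ``untile`` inverts the operation
    exactly on the original extent.
    """
    image = np.asarray(image)
    tile_shape = tuple(int(t) for t in tile_shape)
    if len(tile_shape) != image.ndim:
        raise ValueError("tile_shape must match image dimensionality")
    if any(t < 1 for t in tile_shape):
        raise ValueError("tile dims must be >= 1")
    grid = tuple(
        max(1, math.ceil(s / t)) for s, t in zip(image.shape, tile_shape)
    )
    padded_shape = tuple(g * t for g, t in zip(grid, tile_shape))
    pad = [(0, p - s) for p, s in zip(padded_shape, image.shape)]
    if any(p[1] > 0 for p in pad):
        # reflect padding needs size >= 2 along the axis; fall back to edge
        mode = pad_mode
        if pad_mode == "reflect" and any(
            s < 2 and p[1] > 0 for s, p in zip(image.shape, pad)
        ):
            mode = "edge"
        padded = np.pad(image, pad, mode=mode)
    else:
        padded = image
    tiles: list[np.ndarray] = []
    for idx in np.ndindex(*grid):
        sl = tuple(
            slice(i * t, (i + 1) * t) for i, t in zip(idx, tile_shape)
        )
        tiles.append(padded[sl].copy())
    layout = TileLayout(image.shape, padded_shape, tile_shape, grid)
    return tiles, layout


def untile(tiles: Sequence[np.ndarray], layout: TileLayout) -> np.ndarray:
    """Reassemble tiles produced by :func:`tile_image`."""
    expected = int(np.prod(layout.grid_shape))
    if len(tiles) != expected:
        raise ValueError(f"expected {expected} tiles, got {len(tiles)}")
    out = np.empty(layout.padded_shape, dtype=np.asarray(tiles[0]).dtype)
    for tile, idx in zip(tiles, np.ndindex(*layout.grid_shape)):
        sl = tuple(
            slice(i * t, (i + 1) * t)
            for i, t in zip(idx, layout.tile_shape)
        )
        out[sl] = tile
    crop = tuple(slice(0, s) for s in layout.original_shape)
    return out[crop]


# ---------------------------------------------------------------------------
# TIFF I/O

def read_stack(path: str | Path) -> np.ndarray:
    """Read a (multi-page) TIFF into a (t, rows, cols) or (rows, cols) array."""
    return tifffile.imread(str(path))


def read_timelapse(
    path: str | Path, calibration: Calibration | None = None
) -> TimeLapse:
    arr = read_stack(path)
    if arr.ndim == 2:
        arr = arr[None]
    frames = [arr[i].astype(float) for i in range(arr.shape[0])]
    return TimeLapse(frames, calibration or Calibration())


def write_timelapse(path: str | Path, stack: TimeLapse | np.ndarray) -> None:
    """Write frames as 16-bit multi-page TIFF (values clipped to uint16)."""
    arr = stack.as_array() if isinstance(stack, TimeLapse) else np.asarray(stack)
    arr = np.clip(np.rint(arr), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(str(path), arr, photometric="minisblack")


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    """Write a label mask stack as 32-bit unsigned TIFF."""
    arr = np.asarray(labels)
    if arr.min() < 0:
        raise ValueError("label masks must be non-negative")
    tifffile.imwrite(str(path), arr.astype(np.uint32))


def read_labels(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int64)
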