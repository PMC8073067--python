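"""Satellite-conformal grids and raster-to-grid aggregation.

Reflectance maps from the two platforms (UAV orthomosaics at centimetre
resolution, satellite bands at 10/20 m) are brought onto a common lattice of
square cells that is snapped to integer multiples of the cell size in a
planar, metric coordinate system — the same convention the Sentinel-2 pixel
grid uses.  All downstream calibration and monitoring operates on these
per-cell aggregates.

Conventions
-----------
* Coordinates are planar metres; ``y`` decreases down array rows (north-up).
* A cell ``(row, col)`` of a grid with origin ``(x0, y0)`` (top-left) and
  size ``s`` covers the half-open box ``[x0+col*s, x0+(col+1)*s) ×
  [y0-(row+1)*s, y0-row*s)``; a pixel belongs to the cell containing its
  centre, so every pixel belongs to exactly one cell.
* NoData is NaN; cells with no valid pixels, or with a valid-pixel area
  fraction below ``min_coverage``, are flagged invalid.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from typing import Iterable, Sequence

import numpy as np

BANDS = ("green", "red", "red_edge", "nir")
PLATFORMS = ("uav", "satellite")

_SNAP_EPS = 1e-9


@dataclasses.dataclass
class Raster:
    """Single-band, north-up reflectance raster with square pixels.

    ``values`` holds reflectance as a fraction of incoming radiation;
    slight super-unity values (up to 1.5) are tolerated, anything outside
    [0, 1.5] is rejected.  ``origin_x``/``origin_y`` locate the top-left
    corner in planar metres.
    """

    values: np.ndarray
    origin_x: float
    origin_y: float
    pixel_size: float
    band: str
    platform: str
    date: dt.date

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster values must be a non-empty 2-D array")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}")
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1.5):
            raise ValueError("reflectance outside [0, 1.5]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint."""
        n_rows, n_cols = self.values.shape
        return (
            self.origin_x,
            self.origin_y - n_rows * self.pixel_size,
            self.origin_x + n_cols * self.pixel_size,
            self.origin_y,
        )

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Centre coordinates: (xs over columns, ys over rows)."""
        n_rows, n_cols = self.values.shape
        xs = self.origin_x + (np.arange(n_cols) + 0.5) * self.pixel_size
        ys = self.origin_y - (np.arange(n_rows) + 0.5) * self.pixel_size
        return xs, ys


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Lattice of square cells snapped to multiples of the cell size."""

    origin_x: float
    origin_y: float
    cell_size: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")
        for v in (self.origin_x, self.origin_y):
            if abs(v / self.cell_size - round(v / self.cell_size)) > _SNAP_EPS:
                raise ValueError(
                    "grid origin must lie on integer multiples of cell_size"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        s = self.cell_size
        x0 = self.origin_x + col * s
        y1 = self.origin_y - row * s
        return (x0, y1 - s, x0 + s, y1)

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col); may fall outside the grid.

        The half-open convention puts a point on a cell's left/bottom edge
        inside that cell.
        """
        s = self.cell_size
        col = np.floor((np.asarray(x, dtype=float) - self.origin_x) / s).astype(int)
        row = (np.ceil((self.origin_y - np.asarray(y, dtype=float)) / s) - 1).astype(int)
        return row, col


@dataclasses.dataclass
class GridLayer:
    """Per-cell scalar values on a :class:`GridSpec` with a validity mask."""

    grid: GridSpec
    values: np.ndarray
    valid: np.ndarray
    variable: str = ""
    date: dt.date | None = None
    platform: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).copy()
        self.valid = np.asarray(self.valid, dtype=bool).copy()
        if self.values.shape != self.grid.shape or self.valid.shape != self.grid.shape:
            raise ValueError("layer arrays must match the grid shape")
        self.values[~self.valid] = np.nan

    def copy(self) -> "GridLayer":
        return GridLayer(
            self.grid, self.values.copy(), self.valid.copy(),
            self.variable, self.date, self.platform,
        )


@dataclasses.dataclass(frozen=True)
class DatePairing:
    """A UAV/satellite acquisition-date pair within the matching window."""

    uav_date: dt.date
    satellite_date: dt.date
    gap_days: int
    max_gap_days: int = 5

    def __post_init__(self) -> None:
        gap = abs((self.uav_date - self.satellite_date).days)
        if gap != self.gap_days:
            raise ValueError("gap_days inconsistent with the dates")
        if self.gap_days > self.max_gap_days:
            raise ValueError("pairing exceeds the maximum gap")


def build_grid(bounds: Sequence[float], cell_size: float) -> GridSpec:
    """Smallest snapped grid fully covering ``bounds = (xmin, ymin, xmax, ymax)``.

    Cell edges lie on integer multiples of ``cell_size``; the bounds are
    snapped outward.
    """
    if not cell_size > 0:
        raise ValueError("cell_size must be positive")
    xmin, ymin, xmax, ymax = map(float, bounds)
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("bounds are empty or degenerate")
    s = cell_size
    origin_x = math.floor(xmin / s + _SNAP_EPS) * s
    origin_y = math.ceil(ymax / s - _SNAP_EPS) * s
    n_cols = int(math.ceil((xmax - origin_x) / s - _SNAP_EPS))
    n_rows = int(math.ceil((origin_y - ymin) / s - _SNAP_EPS))
    return GridSpec(origin_x, origin_y, s, max(n_cols, 1), max(n_rows, 1))


def aggregate_to_grid(
    raster: Raster, grid: GridSpec, min_coverage: float = 0.5
) -> GridLayer:
    """Average raster pixels into grid cells (pixel-centre membership).

    Each cell's value is the arithmetic mean of all non-NoData pixels whose
    centres fall inside it.  Cells whose valid-pixel area fraction is below
    ``min_coverage`` are flagged invalid.
    """
    if not 0 < min_coverage <= 1:
        raise ValueError("min_coverage must be in (0, 1]")
    xs, ys = raster.pixel_centers()
    _, col = grid.cell_index(xs, np.zeros_like(xs))
    row, _ = grid.cell_index(np.zeros_like(ys), ys)

    in_col = (col >= 0) & (col < grid.n_cols)
    in_row = (row >= 0) & (row < grid.n_rows)
    if not (in_col.any() and in_row.any()):
        raise ValueError("raster does not overlap the grid")

    vals = raster.values[np.ix_(in_row, in_col)]
    rows = row[in_row]
    cols = col[in_col]
    flat = (rows[:, None] * grid.n_cols + cols[None, :]).ravel()
    v = vals.ravel()
    good = np.isfinite(v)
    n_cells = grid.n_rows * grid.n_cols
    counts = np.bincount(flat[good], minlength=n_cells).astype(float)
    sums = np.bincount(flat[good], weights=v[good], minlength=n_cells)

    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    coverage = counts * raster.pixel_size**2 / grid.cell_size**2
    valid = (counts > 0) & (coverage >= min_coverage - 1e-12)
    return GridLayer(
        grid,
        means.reshape(grid.shape),
        valid.reshape(grid.shape),
        variable=f"reflectance_{raster.band}",
        date=raster.date,
        platform=raster.platform,
    )


def exclude_cells(layer: GridLayer, mask: np.ndarray) -> GridLayer:
    """Invalidate the cells flagged ``True`` in ``mask``; values untouched."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != layer.grid.shape:
        raise ValueError("mask shape does not match the grid")
    out = layer.copy()
    out.valid &= ~mask
    out.values[~out.valid] = np.nan
    return out


def _lattice_compatible(a: GridSpec, b: GridSpec) -> bool:
    fine = min(a.cell_size, b.cell_size)
    coarse = max(a.cell_size, b.cell_size)
    ratio = coarse / fine
    if abs(ratio - round(ratio)) > _SNAP_EPS:
        return False
    for v in (a.origin_x - b.origin_x, a.origin_y - b.origin_y):
        if abs(v / fine - round(v / fine)) > _SNAP_EPS:
            return False
    return True


def resample_layer(layer: GridLayer, target: GridSpec) -> GridLayer:
    """Coarsen (mean of valid children) or refine (broadcast) onto ``target``.

    Grids must share the snap lattice with an integer cell-size ratio.
    """
    src = layer.grid
    if not _lattice_compatible(src, target):
        raise ValueError("incompatible grid lattices")

    out_vals = np.full(target.shape, np.nan)
    out_valid = np.zeros(target.shape, dtype=bool)

    if target.cell_size >= src.cell_size:  # coarsen (or same-size shift)
        s = src.cell_size
        xs = src.origin_x + (np.arange(src.n_cols) + 0.5) * s
        ys = src.origin_y - (np.arange(src.n_rows) + 0.5) * s
        _, col = target.cell_index(xs, np.zeros_like(xs))
        row, _ = target.cell_index(np.zeros_like(ys), ys)
        ok_c = (col >= 0) & (col < target.n_cols)
        ok_r = (row >= 0) & (row < target.n_rows)
        flat = (row[ok_r][:, None] * target.n_cols + col[ok_c][None, :]).ravel()
        v = layer.values[np.ix_(ok_r, ok_c)].ravel()
        good = np.isfinite(v) & layer.valid[np.ix_(ok_r, ok_c)].ravel()
        n_cells = target.n_rows * target.n_cols
        counts = np.bincount(flat[good], minlength=n_cells).astype(float)
        sums = np.bincount(flat[good], weights=v[good], minlength=n_cells)
        with np.errstate(invalid="ignore", divide="ignore"):
            out_vals = (sums / counts).reshape(target.shape)
        out_valid = (counts > 0).reshape(target.shape)
    else:  # refine: broadcast parent values to children
        s = target.cell_size
        xs = target.origin_x + (np.arange(target.n_cols) + 0.5) * s
        ys = target.origin_y - (np.arange(target.n_rows) + 0.5) * s
        _, col = src.cell_index(xs, np.zeros_like(xs))
        row, _ = src.cell_index(np.zeros_like(ys), ys)
        ok_c = (col >= 0) & (col < src.n_cols)
        ok_r = (row >= 0) & (row < src.n_rows)
        sub_vals = layer.values[np.ix_(row[ok_r], col[ok_c])]
        sub_valid = layer.valid[np.ix_(row[ok_r], col[ok_c])]
        out_vals[np.ix_(ok_r, ok_c)] = sub_vals
        out_valid[np.ix_(ok_r, ok_c)] = sub_valid

    return GridLayer(
        target, out_vals, out_valid, layer.variable, layer.date, layer.platform
    )


def match_dates(
    uav_dates: Iterable[dt.date],
    satellite_dates: Iterable[dt.date],
    max_gap_days: int = 5,
) -> list[DatePairing]:
    """One-to-one nearest pairing of acquisition dates within the gap window.

    Plant development over a few days is negligible, so acquisitions at most
    ``max_gap_days`` apart are treated as simultaneous.  Candidate pairs are
    taken greedily by increasing gap; ties break toward the earlier UAV date.
    Unmatched dates are silently omitted.
    """
    uav = sorted(set(uav_dates))
    sat = sorted(set(satellite_dates))
    if not uav or not sat:
        raise ValueError("date lists must be non-empty")
    candidates = sorted(
        (abs((u - s).days), u, s)
        for u in uav
        for s in sat
        if abs((u - s).days) <= max_gap_days
    )
    used_u: set[dt.date] = set()
    used_s: set[dt.date] = set()
    pairs: list[DatePairing] = []
    for gap, u, s in candidates:
        if u in used_u or s in used_s:
            continue
        used_u.add(u)
        used_s.add(s)
        pairs.append(DatePairing(u, s, gap, max_gap_days))
    pairs.sort(key=lambda p: p.satellite_date)
    return pairs
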