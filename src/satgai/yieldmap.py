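"""Grid-resolution yield maps from plot polygons and per-plot yields.

Plot-trial yields are known per plot; reflectance aggregates live on the
satellite-conformal grid.  To compare them, each grid cell's yield is the
area-weighted mixture of the yields of the plots intersecting it, with bare
soil (tramlines, margins, anything outside the plots) contributing zero.
Fractions come from exact polygon clipping, not pixel counting, so the
result is deterministic; a fine-rasterisation cross-check lives in the test
suite.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.strtree import STRtree

from .geogrid import GridLayer, GridSpec

BARE = "bare"


@dataclasses.dataclass
class PlotLayout:
    """Plot polygons with ids, and the trial's outer boundary.

    Plot polygons must be valid and pairwise non-overlapping; everything
    inside ``field`` but outside a plot is bare soil.
    """

    plots: dict  # plot_id -> shapely Polygon
    field: object  # shapely Polygon: trial boundary

    def __post_init__(self) -> None:
        for pid, poly in self.plots.items():
            if not poly.is_valid:
                raise ValueError(f"invalid geometry for plot {pid!r}")
        ids = list(self.plots)
        geoms = [self.plots[i] for i in ids]
        tree = STRtree(geoms)
        for i, geom in enumerate(geoms):
            for j in tree.query(geom):
                if j <= i:
                    continue
                inter = geom.intersection(geoms[j]).area
                if inter > 1e-9:
                    raise ValueError(
                        f"plots {ids[i]!r} and {ids[j]!r} overlap (area {inter:.3g})"
                    )

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.field.bounds


@dataclasses.dataclass
class YieldMap:
    """Per-cell grain yield (g/m²) plus the area-fraction table behind it."""

    layer: GridLayer
    fractions: pd.DataFrame  # columns: row, col, plot_id, fraction


def area_fractions(
    layout: PlotLayout, grid: GridSpec, include_field_fraction: bool = True
) -> pd.DataFrame:
    """Exact area fraction of each plot (and bare soil) per grid cell.

    Returns a long table ``row, col, plot_id, fraction``; fractions of a
    cell sum to 1, the remainder after all plots being bare.  When
    ``include_field_fraction`` is set an extra ``field_fraction`` column
    records how much of the cell lies inside the trial boundary, so that
    cells sticking out of the trial can be excluded downstream.
    """
    ids = list(layout.plots)
    geoms = [layout.plots[i] for i in ids]
    tree = STRtree(geoms)
    cell_area = grid.cell_size**2
    rows = []
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            cell = box(*grid.cell_bounds(r, c))
            total = 0.0
            field_frac = (
                cell.intersection(layout.field).area / cell_area
                if include_field_fraction
                else np.nan
            )
            for j in tree.query(cell):
                frac = cell.intersection(geoms[j]).area / cell_area
                if frac > 1e-12:
                    rows.append((r, c, ids[j], frac, field_frac))
                    total += frac
            bare = max(0.0, 1.0 - total)
            if bare > 1e-12 or total == 0.0:
                rows.append((r, c, BARE, bare, field_frac))
    df = pd.DataFrame(
        rows, columns=["row", "col", "plot_id", "fraction", "field_fraction"]
    )
    if not include_field_fraction:
        df = df.drop(columns=["field_fraction"])
    return df


def make_yield_map(
    fractions: pd.DataFrame,
    yields: Mapping[str, float],
    grid: GridSpec,
    min_field_fraction: float = 1.0 - 1e-9,
) -> YieldMap:
    """Combine area fractions with plot yields into a per-cell yield layer.

    Cell yield = Σ fraction × plot yield, bare soil counting as zero.  Cells
    whose trial-boundary coverage falls below ``min_field_fraction`` keep
    their value but are flagged invalid (partially outside the trial).
    """
    referenced = set(fractions["plot_id"]) - {BARE}
    missing = referenced - set(yields)
    if missing:
        raise KeyError(f"missing yield for plots: {sorted(missing)}")
    if any(y < 0 for y in yields.values()):
        raise ValueError("yields must be non-negative")

    values = np.zeros(grid.shape)
    for rec in fractions.itertuples(index=False):
        if rec.plot_id == BARE:
            continue
        values[rec.row, rec.col] += rec.fraction * float(yields[rec.plot_id])

    valid = np.ones(grid.shape, dtype=bool)
    if "field_fraction" in fractions.columns:
        cover = fractions.groupby(["row", "col"])["field_fraction"].first()
        for (r, c), frac in cover.items():
            if np.isfinite(frac) and frac < min_field_fraction:
                valid[r, c] = False

    layer = GridLayer(grid, values, valid, variable="grain_yield_g_m2")
    return YieldMap(layer, fractions)
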