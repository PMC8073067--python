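"""Scenario matrix: temporal × spatial × spectral yield-explanation runs.

Each scenario predicts per-cell GAI from one platform's reflectance under a
combination of options, cumulates absorbed PAR until harvest, and regresses
the per-cell grain yield on it:

* temporal — ``available`` (the platform's full acquisition calendar) or
  ``common`` (only acquisitions with a counterpart on the other platform
  within 5 days);
* spatial — ``res10`` (everything on the 10 m grid; UAV only, since the
  satellite red-edge band is native 20 m), ``res10_re20`` (red edge
  aggregated at 20 m and broadcast to the 10 m grid), or ``res20``
  (everything, including the yield map, on the 20 m grid);
* spectral — the ``nir_re`` simple-ratio model or the multi-ratio ``viquo``
  model.

The full crossing yields 12 UAV and 8 satellite scenarios.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import radiation, vigai, yieldmap
from .geogrid import GridLayer, GridSpec, aggregate_to_grid, build_grid, match_dates, resample_layer

logger = logging.getLogger(__name__)

TEMPORAL_OPTIONS = ("available", "common")
SPATIAL_OPTIONS = ("res10", "res10_re20", "res20")
SPECTRAL_OPTIONS = ("nir_re", "viquo")

_SPECTRAL_BANDS = {
    "nir_re": ("red_edge", "nir"),
    "viquo": ("green", "red", "red_edge", "nir"),
}


@dataclasses.dataclass(frozen=True)
class ScenarioConfig:
    platform: str
    temporal: str
    spatial: str
    spectral: str

    def __post_init__(self) -> None:
        if self.platform not in ("uav", "satellite"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.temporal not in TEMPORAL_OPTIONS:
            raise ValueError(f"unknown temporal option {self.temporal!r}")
        if self.spatial not in SPATIAL_OPTIONS:
            raise ValueError(f"unknown spatial option {self.spatial!r}")
        if self.spectral not in SPECTRAL_OPTIONS:
            raise ValueError(f"unknown spectral option {self.spectral!r}")
        if self.platform == "satellite" and self.spatial == "res10":
            raise ValueError(
                "satellite red edge is native 20 m; use res10_re20 or res20"
            )

    @property
    def label(self) -> str:
        return f"{self.platform}/{self.temporal}/{self.spatial}/{self.spectral}"


def full_crossing(platform: str) -> list[ScenarioConfig]:
    """All scenario combinations of one platform (12 UAV, 8 satellite)."""
    spatial = SPATIAL_OPTIONS if platform == "uav" else ("res10_re20", "res20")
    return [
        ScenarioConfig(platform, t, s, sp)
        for t in TEMPORAL_OPTIONS
        for s in spatial
        for sp in SPECTRAL_OPTIONS
    ]


def select_dates(
    all_dates: Mapping[str, Sequence[dt.date]],
    platform: str,
    temporal: str,
    max_gap_days: int = 5,
    exclude_dates: Sequence[dt.date] = (),
) -> list[dt.date]:
    """Acquisition dates entering a scenario for one platform.

    ``exclude_dates`` drops acquisitions known to be unusable (for example
    satellite dates flagged as date-affected) before the temporal option is
    applied.
    """
    excluded = set(exclude_dates)
    own = sorted(set(all_dates[platform]) - excluded)
    if not own:
        raise ValueError("empty acquisition calendar")
    if temporal == "available":
        return own
    uav = sorted(set(all_dates["uav"]) - excluded)
    sat = sorted(set(all_dates["satellite"]) - excluded)
    if not uav or not sat:
        raise ValueError("no common acquisition dates within the matching window")
    pairs = match_dates(uav, sat, max_gap_days)
    chosen = sorted(
        {p.uav_date if platform == "uav" else p.satellite_date for p in pairs}
    )
    if not chosen:
        raise ValueError("no common acquisition dates within the matching window")
    return chosen


@dataclasses.dataclass
class ScenarioResult:
    config: ScenarioConfig
    slope: float
    intercept: float
    r2: float
    r2_as_printed: float
    n_cells: int
    apar: GridLayer
    dates: list


class StudyBundle:
    """Caches grids, yield maps and per-cell band aggregates of one study.

    ``study`` must expose ``raster(platform, date, band)``, ``dates``,
    ``daily`` (daily weather with weighted PAR), ``layout``, ``yields`` and
    a config with ``field_bounds``, ``season_start``, ``harvest``.
    """

    def __init__(self, study, min_coverage: float = 0.5):
        self.study = study
        self.min_coverage = min_coverage
        bounds = study.config.field_bounds
        self.grids: dict[int, GridSpec] = {
            10: build_grid(bounds, 10.0),
            20: build_grid(bounds, 20.0),
        }
        self.yield_maps: dict[int, yieldmap.YieldMap] = {}
        for size, grid in self.grids.items():
            frac = yieldmap.area_fractions(study.layout, grid)
            self.yield_maps[size] = yieldmap.make_yield_map(
                frac, study.yields, grid
            )
        self._agg_cache: dict = {}

    @property
    def dates(self) -> Mapping[str, Sequence[dt.date]]:
        return self.study.dates

    @property
    def daily(self) -> pd.DataFrame:
        return self.study.daily

    def grid(self, cell_size: int) -> GridSpec:
        return self.grids[cell_size]

    def _aggregate(self, platform: str, date: dt.date, band: str, cell_size: int) -> GridLayer:
        key = (platform, date, band, cell_size)
        if key not in self._agg_cache:
            raster = self.study.raster(platform, date, band)
            self._agg_cache[key] = aggregate_to_grid(
                raster, self.grids[cell_size], self.min_coverage
            )
        return self._agg_cache[key]

    def band_layer(
        self, platform: str, date: dt.date, band: str, spatial: str
    ) -> GridLayer:
        """Per-cell band reflectance under one spatial option."""
        if spatial == "res20":
            return self._aggregate(platform, date, band, 20)
        if spatial == "res10":
            if platform == "satellite" and band == "red_edge":
                raise ValueError("satellite red edge has no native 10 m resolution")
            return self._aggregate(platform, date, band, 10)
        if spatial == "res10_re20":
            if band == "red_edge":
                coarse = self._aggregate(platform, date, band, 20)
                return resample_layer(coarse, self.grids[10])
            return self._aggregate(platform, date, band, 10)
        raise ValueError(f"unknown spatial option {spatial!r}")


def run_scenario(
    config: ScenarioConfig,
    bundle: StudyBundle,
    models: Mapping[str, vigai.GaiModel] | None = None,
    k: float = radiation.EXTINCTION_COEFFICIENT,
    exclude_dates: Sequence[dt.date] = (),
) -> ScenarioResult:
    """Execute one scenario end-to-end and regress yield on cumulative APAR."""
    from .synth import default_models  # late import to avoid a cycle

    if models is None:
        models = getattr(bundle.study, "models", None)
    if models is None:
        models = default_models(bundle.study.config)
    model = models[config.spectral]
    if not model.clip_negative:
        model = dataclasses.replace(model, clip_negative=True)

    dates = select_dates(
        bundle.dates, config.platform, config.temporal, exclude_dates=exclude_dates
    )
    cell_size = 20 if config.spatial == "res20" else 10
    grid = bundle.grid(cell_size)
    ymap = bundle.yield_maps[cell_size]

    valid = ymap.layer.valid.copy()
    gai_by_date = []
    for date in dates:
        bands = {}
        for band in _SPECTRAL_BANDS[config.spectral]:
            layer = bundle.band_layer(config.platform, date, band, config.spatial)
            bands[band] = layer.values
            valid &= layer.valid
        vi = vigai.compute_vi(bands, config.spectral if config.spectral != "nir_re" else "nir_re")
        gai_by_date.append(np.asarray(vigai.predict_gai(model, vi), dtype=float))

    season_start = bundle.study.config.season_start
    harvest = bundle.study.config.harvest
    apar = np.full(grid.shape, np.nan)
    for r, c in np.argwhere(valid):
        obs = [(d, float(gai_by_date[i][r, c])) for i, d in enumerate(dates)]
        apar[r, c] = radiation.cumulative_apar(
            obs, bundle.daily, season_start, harvest, k=k
        )

    x = apar[valid]
    y = ymap.layer.values[valid]
    n = int(valid.sum())
    if n < 3:
        raise ValueError("fewer than 3 valid cells for the yield regression")
    slope, intercept = np.polyfit(x, y, 1)
    pred = intercept + slope * x
    r2 = vigai.r_squared(pred, y, "standard")
    r2p = vigai.r_squared(pred, y, "as_printed")
    apar_layer = GridLayer(
        grid, apar, valid, variable="cumulative_apar_mj_m2",
        platform=config.platform,
    )
    return ScenarioResult(
        config=config,
        slope=float(slope),
        intercept=float(intercept),
        r2=float(r2),
        r2_as_printed=float(r2p),
        n_cells=n,
        apar=apar_layer,
        dates=dates,
    )


def run_matrix(
    configs: Sequence[ScenarioConfig],
    bundle: StudyBundle,
    models: Mapping[str, vigai.GaiModel] | None = None,
    k: float = radiation.EXTINCTION_COEFFICIENT,
    exclude_dates: Sequence[dt.date] = (),
) -> tuple[list[ScenarioResult], pd.DataFrame]:
    """Run every scenario; failures are recorded and do not stop the rest."""
    if not configs:
        raise ValueError("need at least one scenario")
    results: list[ScenarioResult] = []
    rows = []
    for cfg in configs:
        try:
            res = run_scenario(
                cfg, bundle, models=models, k=k, exclude_dates=exclude_dates
            )
        except Exception as exc:  # propagate per scenario, continue others
            logger.warning("scenario %s failed: %s", cfg.label, exc)
            rows.append(
                {
                    "platform": cfg.platform,
                    "temporal": cfg.temporal,
                    "spatial": cfg.spatial,
                    "spectral": cfg.spectral,
                    "slope": np.nan,
                    "intercept": np.nan,
                    "r2": np.nan,
                    "n_cells": 0,
                    "error": str(exc),
                }
            )
            continue
        results.append(res)
        rows.append(
            {
                "platform": cfg.platform,
                "temporal": cfg.temporal,
                "spatial": cfg.spatial,
                "spectral": cfg.spectral,
                "slope": res.slope,
                "intercept": res.intercept,
                "r2": res.r2,
                "n_cells": res.n_cells,
                "error": "",
            }
        )
    summary = pd.DataFrame(rows)
    return results, summary
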