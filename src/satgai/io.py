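"""File formats: TIFF rasters, GeoJSON vectors, CSV tables, YAML models.

Rasters travel as single-band float32 TIFFs with the georeferencing and
acquisition metadata carried as JSON in the TIFF description tag, mirrored
in a CSV manifest (filename, platform, band, date).  Vector data (grids,
plot layouts) is GeoJSON in the planar metric CRS; per-cell tables, weather
and yields are CSV; fitted models and study configuration are YAML.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import pathlib

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import mapping, shape

from .geogrid import GridLayer, GridSpec, Raster
from .vigai import GaiModel
from .yieldmap import PlotLayout

NODATA = -9999.0


# ---- rasters ---------------------------------------------------------


def write_raster(raster: Raster, path) -> None:
    meta = {
        "origin_x": raster.origin_x,
        "origin_y": raster.origin_y,
        "pixel_size": raster.pixel_size,
        "band": raster.band,
        "platform": raster.platform,
        "date": raster.date.isoformat(),
        "nodata": NODATA,
    }
    values = raster.values.astype(np.float32)
    values = np.where(np.isfinite(values), values, np.float32(NODATA))
    tifffile.imwrite(path, values, description=json.dumps(meta))


def read_raster(path) -> Raster:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        meta = json.loads(page.description)
        values = page.asarray().astype(float)
    values[values == meta["nodata"]] = np.nan
    return Raster(
        values=values,
        origin_x=float(meta["origin_x"]),
        origin_y=float(meta["origin_y"]),
        pixel_size=float(meta["pixel_size"]),
        band=meta["band"],
        platform=meta["platform"],
        date=dt.date.fromisoformat(meta["date"]),
    )


# ---- grids and layers ------------------------------------------------


def grid_to_geojson(grid: GridSpec, path=None) -> dict:
    features = []
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            x0, y0, x1, y1 = grid.cell_bounds(r, c)
            features.append(
                {
                    "type": "Feature",
                    "properties": {"row": r, "col": c},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [
                            [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
                        ],
                    },
                }
            )
    obj = {"type": "FeatureCollection", "features": features}
    if path is not None:
        pathlib.Path(path).write_text(json.dumps(obj))
    return obj


def layer_to_csv(layer: GridLayer, path) -> None:
    rows = []
    for r in range(layer.grid.n_rows):
        for c in range(layer.grid.n_cols):
            rows.append(
                {
                    "row": r,
                    "col": c,
                    "value": layer.values[r, c],
                    "valid": bool(layer.valid[r, c]),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def layer_from_csv(path, grid: GridSpec, **kwargs) -> GridLayer:
    df = pd.read_csv(path)
    values = np.full(grid.shape, np.nan)
    valid = np.zeros(grid.shape, dtype=bool)
    for rec in df.itertuples(index=False):
        values[rec.row, rec.col] = rec.value
        valid[rec.row, rec.col] = bool(rec.valid)
    return GridLayer(grid, values, valid, **kwargs)


# ---- plot layouts and yields -----------------------------------------


def layout_to_geojson(layout: PlotLayout, path=None) -> dict:
    features = [
        {
            "type": "Feature",
            "properties": {"plot_id": pid},
            "geometry": mapping(poly),
        }
        for pid, poly in sorted(layout.plots.items())
    ]
    features.append(
        {
            "type": "Feature",
            "properties": {"plot_id": "__field__"},
            "geometry": mapping(layout.field),
        }
    )
    obj = {"type": "FeatureCollection", "features": features}
    if path is not None:
        pathlib.Path(path).write_text(json.dumps(obj))
    return obj


def layout_from_geojson(path_or_obj) -> PlotLayout:
    if isinstance(path_or_obj, dict):
        obj = path_or_obj
    else:
        obj = json.loads(pathlib.Path(path_or_obj).read_text())
    plots = {}
    field = None
    for feat in obj["features"]:
        pid = feat["properties"]["plot_id"]
        geom = shape(feat["geometry"])
        if pid == "__field__":
            field = geom
        else:
            plots[pid] = geom
    if field is None:
        raise ValueError("layout GeoJSON lacks the __field__ boundary feature")
    return PlotLayout(plots=plots, field=field)


def yields_to_csv(yields: dict, path) -> None:
    pd.DataFrame(
        sorted(yields.items()), columns=["plot_id", "yield_g_m2"]
    ).to_csv(path, index=False)


def yields_from_csv(path) -> dict:
    df = pd.read_csv(path)
    return dict(zip(df["plot_id"], df["yield_g_m2"].astype(float)))


# ---- weather ---------------------------------------------------------


def weather_to_csv(series, path) -> None:
    df = series.data.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)


def weather_from_csv(path):
    from .radiation import WeatherSeries

    df = pd.read_csv(path)
    return WeatherSeries(df)


# ---- models ----------------------------------------------------------


def models_to_yaml(models: dict, path) -> None:
    payload = {
        name: {
            "form": m.form,
            "coefficients": {k: float(v) for k, v in m.coefficients.items()},
            "vi": m.vi,
            "clip_negative": m.clip_negative,
            "exponential_additive": m.exponential_additive,
        }
        for name, m in models.items()
    }
    pathlib.Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def models_from_yaml(path) -> dict:
    payload = yaml.safe_load(pathlib.Path(path).read_text())
    return {
        name: GaiModel(
            form=spec["form"],
            coefficients=dict(spec["coefficients"]),
            vi=spec.get("vi", ""),
            clip_negative=bool(spec.get("clip_negative", False)),
            exponential_additive=bool(spec.get("exponential_additive", False)),
        )
        for name, spec in payload.items()
    }


# ---- study directories -----------------------------------------------


def write_study(study, out_dir) -> None:
    """Materialise a synthetic study as the formats the pipeline consumes."""
    out = pathlib.Path(out_dir)
    (out / "rasters").mkdir(parents=True, exist_ok=True)
    manifest = []
    for platform, dates in study.dates.items():
        for date in dates:
            for band in ("green", "red", "red_edge", "nir"):
                name = f"{platform}_{date.isoformat()}_{band}.tif"
                write_raster(study.raster(platform, date, band), out / "rasters" / name)
                manifest.append(
                    {
                        "filename": f"rasters/{name}",
                        "platform": platform,
                        "band": band,
                        "date": date.isoformat(),
                    }
                )
    pd.DataFrame(manifest).to_csv(out / "manifest.csv", index=False)
    layout_to_geojson(study.layout, out / "layout.geojson")
    yields_to_csv(study.yields, out / "yields.csv")
    weather_to_csv(study.weather, out / "weather.csv")
    from .synth import default_models

    models_to_yaml(default_models(study.config), out / "models.yaml")
    cfg = study.config
    meta = {
        "field_bounds": list(cfg.field_bounds),
        "season_start": cfg.season_start.isoformat(),
        "harvest": cfg.harvest.isoformat(),
        "seed": cfg.seed,
    }
    (out / "study.yaml").write_text(yaml.safe_dump(meta))


@dataclasses.dataclass
class _DiskConfig:
    field_bounds: tuple
    season_start: dt.date
    harvest: dt.date


class DiskStudy:
    """A study loaded back from a directory written by :func:`write_study`.

    Satisfies the interface :class:`satgai.scenarios.StudyBundle` expects.
    """

    def __init__(self, path):
        from .radiation import daily_weather

        self.path = pathlib.Path(path)
        meta = yaml.safe_load((self.path / "study.yaml").read_text())
        self.config = _DiskConfig(
            field_bounds=tuple(meta["field_bounds"]),
            season_start=dt.date.fromisoformat(meta["season_start"]),
            harvest=dt.date.fromisoformat(meta["harvest"]),
        )
        self.layout = layout_from_geojson(self.path / "layout.geojson")
        self.yields = yields_from_csv(self.path / "yields.csv")
        self.weather = weather_from_csv(self.path / "weather.csv")
        self.daily = daily_weather(self.weather)
        self.models = models_from_yaml(self.path / "models.yaml")
        self._manifest = pd.read_csv(self.path / "manifest.csv")

    @property
    def dates(self) -> dict:
        out = {}
        for platform, grp in self._manifest.groupby("platform"):
            out[platform] = sorted(
                dt.date.fromisoformat(d) for d in grp["date"].unique()
            )
        return out

    def raster(self, platform: str, date: dt.date, band: str) -> Raster:
        sel = self._manifest[
            (self._manifest["platform"] == platform)
            & (self._manifest["date"] == date.isoformat())
            & (self._manifest["band"] == band)
        ]
        if sel.empty:
            raise KeyError(f"no raster for {platform}/{date}/{band}")
        return read_raster(self.path / sel.iloc[0]["filename"])
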