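"""Seeded synthetic plot-trial studies for exercising the full pipeline.

The generator emulates a winter-wheat plot trial as seen by two multispectral
platforms: rectangular plots separated by bare-soil tramlines, per-plot
seasonal GAI phenology (logistic green-up from 0.3 m²/m², plateau, linear
senescence to 0 at harvest), hourly weather, and per-date reflectance rasters
for a centimetre-resolution UAV sensor and a 10 m satellite sensor whose
red-edge band is native 20 m.

Reflectance is produced by *inverting* the configured simple-ratio GAI
models (the red-edge reflectance of vegetated ground is held at a reference
value, the other bands follow from the GAI-implied ratios), not by a
radiative-transfer model: the object under test is the monitoring pipeline,
not canopy physics.  Satellite acquisitions can carry per-date artefacts —
an additive shift δ_d and a multiplicative rotation γ_d applied to the
NIR/RE simple ratio, i.e. GAI-equivalently — reproducing the scattered,
shifted or rotated date-specific point clouds seen in real satellite/UAV
comparisons.  Plot yields are linear in the plot's cumulative absorbed PAR
(computed with the pipeline's own course-assembly and Lambert–Beer rules on
the UAV acquisition calendar) plus Gaussian noise.

Everything is deterministic per seed: each random draw uses a generator
keyed on (seed, stream, date, band), so outputs do not depend on call order.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Mapping

import numpy as np
import pandas as pd
from shapely.geometry import box

from . import radiation
from .geogrid import BANDS, Raster
from .vigai import GaiModel
from .yieldmap import PlotLayout

_BAND_INDEX = {b: i for i, b in enumerate(BANDS)}
_PLATFORM_INDEX = {"uav": 1, "satellite": 2}

# rng stream labels (kept below 2**31 when combined with user seeds)
_STREAM_PHENOLOGY = 11
_STREAM_WEATHER = 12
_STREAM_BIAS = 13
_STREAM_YIELD = 14
_STREAM_RASTER = 15
_STREAM_SCATTER = 16


def _default_uav_dates() -> tuple[dt.date, ...]:
    # an irregular but dense flight calendar, March to mid-July
    d = dt.date
    return (
        d(2019, 3, 10), d(2019, 3, 20), d(2019, 4, 1), d(2019, 4, 10),
        d(2019, 4, 24), d(2019, 5, 3), d(2019, 5, 15), d(2019, 5, 29),
        d(2019, 6, 10), d(2019, 6, 24), d(2019, 7, 3), d(2019, 7, 12),
    )


def _default_satellite_dates() -> tuple[dt.date, ...]:
    # cloud-limited calendar; one acquisition (Apr 16) has no UAV flight
    # within the 5-day matching window
    d = dt.date
    return (
        d(2019, 3, 14), d(2019, 4, 3), d(2019, 4, 16), d(2019, 5, 8),
        d(2019, 5, 31), d(2019, 6, 13), d(2019, 6, 26), d(2019, 7, 8),
    )


@dataclasses.dataclass
class SyntheticConfig:
    """Study conditions of a synthetic plot trial.

    Defaults describe a 120 m × 80 m trial of 10 m × 6 m plots separated by
    2 m bare tramlines, a February–July winter-wheat season in a maritime
    temperate climate, a 0.08 m UAV sensor and a 10 m satellite sensor with
    a 20 m red-edge band.
    """

    seed: int = 0
    # field geometry (planar metres; origin at (0, 0), y up to field_height)
    field_width: float = 120.0
    field_height: float = 80.0
    plot_width: float = 10.0
    plot_height: float = 6.0
    strip: float = 2.0  # bare tramline width between plots
    margin: float = 2.0  # bare border inside the field boundary
    # season / phenology
    season_start: dt.date = dt.date(2019, 2, 1)
    harvest: dt.date = dt.date(2019, 7, 25)
    gai_max_mean: float = 6.0
    gai_max_sd: float = 0.9
    greenup_mid_doy: float = 110.0  # ~Apr 20
    greenup_mid_sd: float = 7.0
    greenup_tau: float = 9.0  # logistic time constant, days
    senescence_start_doy: float = 166.0  # ~Jun 15
    senescence_start_sd: float = 6.0
    # acquisition calendars
    uav_dates: tuple = dataclasses.field(default_factory=_default_uav_dates)
    satellite_dates: tuple = dataclasses.field(
        default_factory=_default_satellite_dates
    )
    # sensors
    uav_pixel: float = 0.08
    satellite_pixel: float = 10.0
    satellite_re_pixel: float = 20.0
    render_pixel: float = 0.5  # fine lattice used to mix surfaces into satellite pixels
    noise_sigma: dict = dataclasses.field(
        default_factory=lambda: {
            "green": 0.003,
            "red": 0.003,
            "red_edge": 0.005,
            "nir": 0.010,
        }
    )
    # sensor closure: simple-ratio models GAI = a + b·SR used for inversion
    sr_models: dict = dataclasses.field(
        default_factory=lambda: {
            "nir_re": (-9.781, 8.712),
            "nir_green": (0.0, 0.22),
            "nir_red": (0.0, 0.07),
        }
    )
    viquo_weights: tuple = (0.06, 0.04, 0.90)  # weights on (green, red, re) ratios
    re_reference: float = 0.30  # red-edge reflectance of vegetated ground
    soil_reflectance: dict = dataclasses.field(
        default_factory=lambda: {
            "green": 0.08,
            "red": 0.10,
            "red_edge": 0.16,
            "nir": 0.1796,  # soil NIR/RE ratio ~1.1227 reads as GAI ≈ 0
        }
    )
    # satellite per-date artefacts on the NIR/RE simple ratio: a global
    # shift/rotation (delta, gamma) plus spatially varying scatter at the
    # red-edge block scale, so satellite point clouds are shifted, rotated
    # *and* scattered relative to the 1:1 line
    bias_enabled: bool = True
    bias_gamma_sd: float = 0.15
    bias_delta_sd: float = 0.08
    bias_scatter_sd: float = 0.08  # SR units, per 20 m block and date
    # weather
    temp_annual_mean: float = 9.0
    temp_seasonal_amp: float = 8.0
    temp_diurnal_amp: float = 4.0
    temp_noise_sd: float = 1.0
    par_base: float = 5.0
    par_seasonal_amp: float = 4.0
    par_noise_sd: float = 1.0
    # yield model: plot yield = alpha + beta * plot APAR + N(0, sigma_y)
    yield_alpha: float = -200.0  # g/m2
    yield_beta: float = 1.15  # g/MJ
    yield_sigma: float = 25.0  # g/m2

    @classmethod
    def loop_closure(cls, seed: int = 0) -> "SyntheticConfig":
        """Noise-free, bias-free study with grid-aligned 20 m plots.

        Plots tile the satellite lattice exactly (no tramlines), every 10 m
        and 20 m cell is pure, and all stochastic terms except the weather's
        (shared by truth and pipeline) are off — the configuration under
        which the pipeline can reproduce the generating yield relation
        exactly.
        """
        return cls(
            seed=seed,
            plot_width=20.0,
            plot_height=20.0,
            strip=0.0,
            margin=0.0,
            noise_sigma={b: 0.0 for b in BANDS},
            bias_enabled=False,
            yield_sigma=0.0,
            uav_pixel=0.5,
        )

    @property
    def field_bounds(self) -> tuple[float, float, float, float]:
        return (0.0, 0.0, self.field_width, self.field_height)

    def validate(self) -> None:
        if self.field_width <= 0 or self.field_height <= 0:
            raise ValueError("degenerate field extent")
        step_x = self.plot_width + self.strip
        step_y = self.plot_height + self.strip
        if step_x <= 0 or step_y <= 0 or self.plot_width <= 0 or self.plot_height <= 0:
            raise ValueError("degenerate plot geometry")
        if self.field_width - 2 * self.margin < self.plot_width:
            raise ValueError("field too narrow for a single plot")
        if self.field_height - 2 * self.margin < self.plot_height:
            raise ValueError("field too short for a single plot")


@dataclasses.dataclass
class PlotPhenology:
    gai_max: float
    greenup_mid: float  # day of year
    tau: float
    senescence_start: float  # day of year

    def curve(self, doy: np.ndarray, season_start_doy: float, harvest_doy: float) -> np.ndarray:
        """Daily GAI: anchored logistic rise, plateau, linear senescence."""
        doy = np.asarray(doy, dtype=float)

        def logistic(x):
            return 1.0 / (1.0 + np.exp(-(x - self.greenup_mid) / self.tau))

        l0 = logistic(season_start_doy)
        l1 = logistic(self.senescence_start)
        rise = radiation.START_GAI_DEFAULT + (self.gai_max - radiation.START_GAI_DEFAULT) * (
            (logistic(doy) - l0) / (l1 - l0)
        )
        fall = self.gai_max * (harvest_doy - doy) / (harvest_doy - self.senescence_start)
        out = np.where(doy <= self.senescence_start, rise, fall)
        return np.clip(out, 0.0, None)


def make_layout(config: SyntheticConfig) -> PlotLayout:
    """Rectangular plots on a regular lattice with bare strips between."""
    config.validate()
    step_x = config.plot_width + config.strip
    step_y = config.plot_height + config.strip
    usable_w = config.field_width - 2 * config.margin + config.strip
    usable_h = config.field_height - 2 * config.margin + config.strip
    n_px = int(usable_w // step_x)
    n_py = int(usable_h // step_y)
    plots = {}
    for iy in range(n_py):
        for ix in range(n_px):
            x0 = config.margin + ix * step_x
            y0 = config.margin + iy * step_y
            pid = f"P{iy:02d}_{ix:02d}"
            plots[pid] = box(x0, y0, x0 + config.plot_width, y0 + config.plot_height)
    field = box(*config.field_bounds)
    return PlotLayout(plots=plots, field=field)


def make_phenology(layout: PlotLayout, config: SyntheticConfig) -> dict:
    """Seeded per-plot phenology parameter draws."""
    rng = np.random.default_rng([config.seed, _STREAM_PHENOLOGY])
    out = {}
    for pid in sorted(layout.plots):
        gai_max = float(
            np.clip(rng.normal(config.gai_max_mean, config.gai_max_sd), 2.5, 8.5)
        )
        mid = float(rng.normal(config.greenup_mid_doy, config.greenup_mid_sd))
        # senescence onset snapped to a whole day so the daily ground-truth
        # curve attains the configured maximum exactly
        sen = float(
            np.round(
                np.clip(
                    rng.normal(config.senescence_start_doy, config.senescence_start_sd),
                    mid + 20,
                    config.harvest.timetuple().tm_yday - 10,
                )
            )
        )
        out[pid] = PlotPhenology(gai_max, mid, config.greenup_tau, sen)
    return out


def make_gai_truth(
    layout: PlotLayout, config: SyntheticConfig, phenology: Mapping | None = None
) -> pd.DataFrame:
    """Daily ground-truth GAI per plot (columns: plots, index: dates)."""
    phen = phenology if phenology is not None else make_phenology(layout, config)
    days = pd.date_range(config.season_start, config.harvest, freq="D")
    doy = days.dayofyear.to_numpy(dtype=float)
    start_doy = float(config.season_start.timetuple().tm_yday)
    harvest_doy = float(config.harvest.timetuple().tm_yday)
    data = {
        pid: phen[pid].curve(doy, start_doy, harvest_doy) for pid in sorted(phen)
    }
    return pd.DataFrame(data, index=[d.date() for d in days])


def make_weather(config: SyntheticConfig) -> radiation.WeatherSeries:
    """Hourly temperature and PAR over the season (seasonal + diurnal sinusoids)."""
    rng = np.random.default_rng([config.seed, _STREAM_WEATHER])
    hours = pd.date_range(
        config.season_start,
        dt.datetime.combine(config.harvest, dt.time(23)),
        freq="h",
    )
    doy = hours.dayofyear.to_numpy(dtype=float)
    hod = hours.hour.to_numpy(dtype=float)
    temp = (
        config.temp_annual_mean
        - config.temp_seasonal_amp * np.cos(2 * np.pi * (doy - 15) / 365.0)
        + config.temp_diurnal_amp * np.sin(2 * np.pi * (hod - 9) / 24.0)
        + rng.normal(0.0, config.temp_noise_sd, hours.size)
    )
    # daily PAR total, split over daylight hours with a sin^2 profile
    days = pd.date_range(config.season_start, config.harvest, freq="D")
    doy_d = days.dayofyear.to_numpy(dtype=float)
    par_day = (
        config.par_base
        - config.par_seasonal_amp * np.cos(2 * np.pi * doy_d / 365.0)
        + rng.normal(0.0, config.par_noise_sd, days.size)
    )
    par_day = np.clip(par_day, 0.2, None)
    profile = np.zeros(24)
    daylight = np.arange(5, 21)
    profile[daylight] = np.sin(np.pi * (daylight - 5) / 16.0) ** 2
    profile /= profile.sum()
    par = (par_day[:, None] * profile[None, :]).ravel()[: hours.size]
    df = pd.DataFrame({"timestamp": hours, "temp_c": temp, "par_mj_m2": par})
    return radiation.WeatherSeries(df)


def make_biases(config: SyntheticConfig) -> dict:
    """Per-satellite-date (delta, gamma) artefacts on the NIR/RE ratio."""
    rng = np.random.default_rng([config.seed, _STREAM_BIAS])
    out = {}
    for d in sorted(config.satellite_dates):
        gamma = float(np.clip(rng.normal(1.0, config.bias_gamma_sd), 0.5, 1.5))
        delta = float(rng.normal(0.0, config.bias_delta_sd))
        if not config.bias_enabled:
            gamma, delta = 1.0, 0.0
        out[d] = (delta, gamma)
    return out


def default_models(config: SyntheticConfig, clip_negative: bool = True) -> dict:
    """GAI models consistent with the generator's sensor closure.

    Returns ``{"nir_re": GaiModel, "viquo": GaiModel}``; both platforms use
    the same closure, so the same models serve UAV and satellite scenarios.
    """
    a_re, b_re = config.sr_models["nir_re"]
    a_g, b_g = config.sr_models["nir_green"]
    a_r, b_r = config.sr_models["nir_red"]
    w_g, w_r, w_re = config.viquo_weights
    viquo = {
        "a": w_g * a_g + w_r * a_r + w_re * a_re,
        "b": w_g * b_g,
        "c": w_r * b_r,
        "d": w_re * b_re,
    }
    return {
        "nir_re": GaiModel(
            "linear_sr", {"a": a_re, "b": b_re}, "nir_re", clip_negative=clip_negative
        ),
        "viquo": GaiModel("linear_multi", viquo, "viquo", clip_negative=clip_negative),
    }


class SyntheticStudy:
    """A complete seeded study: layout, truth, weather, rasters, yields.

    Rasters are rendered lazily and deterministically — the pixel noise of a
    raster depends only on (seed, platform, date, band), never on the order
    of requests.
    """

    def __init__(self, config: SyntheticConfig):
        config.validate()
        self.config = config
        self.layout = make_layout(config)
        self.phenology = make_phenology(self.layout, config)
        self.gai_truth = make_gai_truth(self.layout, config, self.phenology)
        self.weather = make_weather(config)
        self.daily = radiation.daily_weather(self.weather)
        self.biases = make_biases(config)
        self.apar_truth = self._compute_apar_truth()
        self.yields = make_yields(self.layout, self.apar_truth, config)
        self._plot_index_cache: dict = {}

    # ---- ground truth -------------------------------------------------

    def _compute_apar_truth(self) -> dict:
        """Per-plot cumulative APAR on the UAV acquisition calendar.

        The truth uses the pipeline's own boundary and interpolation rules
        so that the generated yields are exactly linear in the quantity the
        pipeline recovers under noise-free conditions.
        """
        cfg = self.config
        out = {}
        for pid in sorted(self.layout.plots):
            obs = [
                (d, float(self.gai_truth.loc[d, pid])) for d in sorted(cfg.uav_dates)
            ]
            out[pid] = radiation.cumulative_apar(
                obs, self.daily, cfg.season_start, cfg.harvest
            )
        return out

    def plot_gai(self, date: dt.date) -> dict:
        """Ground-truth GAI per plot on one date."""
        return {pid: float(self.gai_truth.loc[date, pid]) for pid in self.gai_truth}

    # ---- rendering ----------------------------------------------------

    def _plot_index_map(self, pixel: float) -> tuple[np.ndarray, np.ndarray]:
        """(plot index per pixel, id order); -1 marks bare soil."""
        key = pixel
        if key in self._plot_index_cache:
            return self._plot_index_cache[key]
        cfg = self.config
        n_cols = int(round(cfg.field_width / pixel))
        n_rows = int(round(cfg.field_height / pixel))
        xs = (np.arange(n_cols) + 0.5) * pixel
        ys = cfg.field_height - (np.arange(n_rows) + 0.5) * pixel
        step_x = cfg.plot_width + cfg.strip
        step_y = cfg.plot_height + cfg.strip
        ids = np.array(sorted(self.layout.plots))
        # lattice arithmetic instead of polygon tests: plots are axis-aligned
        rel_x = xs - cfg.margin
        rel_y = ys - cfg.margin
        ix = np.floor_divide(rel_x, step_x).astype(int)
        iy = np.floor_divide(rel_y, step_y).astype(int)
        in_plot_x = (rel_x >= 0) & (rel_x - ix * step_x < cfg.plot_width)
        in_plot_y = (rel_y >= 0) & (rel_y - iy * step_y < cfg.plot_height)
        n_px = int((cfg.field_width - 2 * cfg.margin + cfg.strip) // step_x)
        n_py = int((cfg.field_height - 2 * cfg.margin + cfg.strip) // step_y)
        ok = (
            in_plot_y[:, None]
            & in_plot_x[None, :]
            & (iy[:, None] < n_py)
            & (ix[None, :] < n_px)
            & (iy[:, None] >= 0)
            & (ix[None, :] >= 0)
        )
        # ids are sorted "P{iy}_{ix}" strings, i.e. row-major over the plot
        # lattice, so the flat plot number is iy * n_px + ix
        idx = np.where(ok, iy[:, None] * n_px + ix[None, :], -1)
        self._plot_index_cache[key] = (idx, ids)
        return idx, ids

    def _band_reflectance(self, gai: np.ndarray, bare: np.ndarray) -> dict:
        """Noise-free reflectance fields for all four bands from a GAI field.

        The NIR/RE ratio carries the (possibly biased, possibly negative)
        GAI-equivalent signal exactly as long as the implied ratio stays
        positive; the green/red ratios, whose closures only invert for
        GAI above a small floor, saturate there instead.
        """
        cfg = self.config
        a_re, b_re = cfg.sr_models["nir_re"]
        a_g, b_g = cfg.sr_models["nir_green"]
        a_r, b_r = cfg.sr_models["nir_red"]
        gai = np.asarray(gai, dtype=float)
        sr_re = np.clip((gai - a_re) / b_re, 0.05, None)
        g_vis = np.clip(gai, 0.05, None)
        sr_g = (g_vis - a_g) / b_g
        sr_r = (g_vis - a_r) / b_r
        if np.any(sr_g <= 0) or np.any(sr_r <= 0):
            raise ValueError("GAI outside the invertible range of the sensor closure")
        re = np.full_like(g_vis, cfg.re_reference)
        nir = re * sr_re
        green = nir / sr_g
        red = nir / sr_r
        fields = {"green": green, "red": red, "red_edge": re, "nir": nir}
        for b, soil_val in cfg.soil_reflectance.items():
            fields[b] = np.where(bare, soil_val, fields[b])
        return fields

    def _gai_field(self, date: dt.date, pixel: float, biased: bool) -> tuple[np.ndarray, np.ndarray]:
        idx, ids = self._plot_index_map(pixel)
        per_plot = np.array(
            [self.gai_truth.loc[date, pid] for pid in ids], dtype=float
        )
        gai = np.where(idx >= 0, per_plot[np.clip(idx, 0, None)], 0.0)
        bare = idx < 0
        if biased:
            cfg = self.config
            delta, gamma = self.biases[date]
            a_re, b_re = cfg.sr_models["nir_re"]
            sr = (gai - a_re) / b_re
            sr = delta + gamma * sr
            if cfg.bias_enabled and cfg.bias_scatter_sd > 0:
                sr = sr + self._scatter_field(date, pixel)
            gai = np.where(bare, 0.0, a_re + b_re * sr)
        return gai, bare

    def _scatter_field(self, date: dt.date, pixel: float) -> np.ndarray:
        """Per-date SR scatter, constant within red-edge-scale blocks."""
        cfg = self.config
        block = cfg.satellite_re_pixel
        nby = int(np.ceil(cfg.field_height / block))
        nbx = int(np.ceil(cfg.field_width / block))
        rng = np.random.default_rng(
            [cfg.seed, _STREAM_SCATTER, date.toordinal()]
        )
        coarse = rng.normal(0.0, cfg.bias_scatter_sd, (nby, nbx))
        rep = int(round(block / pixel))
        fine = np.repeat(np.repeat(coarse, rep, axis=0), rep, axis=1)
        n_rows = int(round(cfg.field_height / pixel))
        n_cols = int(round(cfg.field_width / pixel))
        return fine[:n_rows, :n_cols]

    def raster(self, platform: str, date: dt.date, band: str) -> Raster:
        """Render one reflectance raster (deterministic per seed and key)."""
        cfg = self.config
        if platform == "uav":
            if date not in cfg.uav_dates:
                raise KeyError(f"no UAV acquisition on {date}")
            pixel = cfg.uav_pixel
            gai, bare = self._gai_field(date, pixel, biased=False)
            field = self._band_reflectance(gai, bare)[band]
        elif platform == "satellite":
            if date not in cfg.satellite_dates:
                raise KeyError(f"no satellite acquisition on {date}")
            pixel = (
                cfg.satellite_re_pixel if band == "red_edge" else cfg.satellite_pixel
            )
            # mix surfaces at a fine lattice, then average into sensor pixels
            fine = cfg.render_pixel
            gai, bare = self._gai_field(date, fine, biased=True)
            fine_field = self._band_reflectance(gai, bare)[band]
            block = int(round(pixel / fine))
            nr = fine_field.shape[0] // block
            nc = fine_field.shape[1] // block
            field = fine_field[: nr * block, : nc * block]
            field = field.reshape(nr, block, nc, block).mean(axis=(1, 3))
        else:
            raise ValueError(f"unknown platform {platform!r}")

        sigma = cfg.noise_sigma.get(band, 0.0)
        if sigma > 0:
            rng = np.random.default_rng(
                [
                    cfg.seed,
                    _STREAM_RASTER,
                    _PLATFORM_INDEX[platform],
                    date.toordinal(),
                    _BAND_INDEX[band],
                ]
            )
            field = field + rng.normal(0.0, sigma, field.shape)
        field = np.clip(field, 1e-4, 1.4)
        return Raster(
            values=field,
            origin_x=0.0,
            origin_y=cfg.field_height,
            pixel_size=pixel,
            band=band,
            platform=platform,
            date=date,
        )

    def rasters(self, platform: str, date: dt.date) -> dict:
        return {b: self.raster(platform, date, b) for b in BANDS}

    @property
    def dates(self) -> dict:
        return {
            "uav": sorted(self.config.uav_dates),
            "satellite": sorted(self.config.satellite_dates),
        }


def render_reflectance(
    study: SyntheticStudy, platform: str, date: dt.date
) -> dict:
    """All four band rasters of one acquisition (thin wrapper)."""
    return study.rasters(platform, date)


def make_yields(
    layout: PlotLayout, apar_truth: Mapping[str, float], config: SyntheticConfig
) -> dict:
    """Plot yields linear in plot APAR plus seeded Gaussian noise, floored at 0."""
    rng = np.random.default_rng([config.seed, _STREAM_YIELD])
    out = {}
    for pid in sorted(layout.plots):
        y = (
            config.yield_alpha
            + config.yield_beta * float(apar_truth[pid])
            + (rng.normal(0.0, config.yield_sigma) if config.yield_sigma > 0 else 0.0)
        )
        out[pid] = max(0.0, float(y))
    return out
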