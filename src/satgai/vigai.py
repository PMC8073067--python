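"""Vegetation indices, GAI-model calibration/prediction, and date-effect tests.

The green area index (GAI, m² green area per m² ground) of winter wheat is
predicted from band reflectance through empirical vegetation-index (VI)
models.  Seven model families are supported:

* simple-ratio linear models  ``GAI = a + b·SR`` with SR one of NIR/Green,
  NIR/Red, NIR/RE;
* exponential models ``GAI = a·e^{b·VI}`` with VI one of NDVI, EVI2, RENDVI
  (an additive variant ``a + e^{b·VI}`` exists behind a flag);
* the multi-ratio linear model (VIQUO)
  ``GAI = a + b·NIR/Green + c·NIR/Red + d·NIR/RE``.

Published Sentinel-2 winter-wheat coefficient sets are shipped in
:data:`SENTINEL2_MODELS`.  Because satellite scenes may carry per-acquisition
artefacts, the module also provides an ANOVA-based test for a date effect on
the VI→GAI slope with Tukey-adjusted pairwise comparisons.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "VIDefinition",
    "VI_DEFINITIONS",
    "SENTINEL2_MODELS",
    "GaiModel",
    "CalibrationResult",
    "DateEffectReport",
    "compute_vi",
    "predict_gai",
    "fit_gai_model",
    "mae",
    "r_squared",
    "date_effect_test",
]


@dataclasses.dataclass(frozen=True)
class VIDefinition:
    name: str
    bands_required: tuple[str, ...]


VI_DEFINITIONS: dict[str, VIDefinition] = {
    "nir_green": VIDefinition("nir_green", ("green", "nir")),
    "nir_red": VIDefinition("nir_red", ("red", "nir")),
    "nir_re": VIDefinition("nir_re", ("red_edge", "nir")),
    "ndvi": VIDefinition("ndvi", ("red", "nir")),
    "evi2": VIDefinition("evi2", ("red", "nir")),
    "rendvi": VIDefinition("rendvi", ("red_edge", "nir")),
    # the multi-ratio model consumes three simple ratios at once
    "viquo": VIDefinition("viquo", ("green", "red", "red_edge", "nir")),
}


def _ratio(num, den, label):
    den = np.asarray(den, dtype=float)
    if np.any(den == 0):
        raise ZeroDivisionError(f"zero denominator in {label}")
    return np.asarray(num, dtype=float) / den


def compute_vi(bands: Mapping[str, object], vi: str | VIDefinition):
    """Evaluate a vegetation index from a band→reflectance mapping.

    Accepts scalars or arrays.  For ``viquo`` the three input simple ratios
    are returned stacked along the last axis (NIR/Green, NIR/Red, NIR/RE).
    """
    definition = VI_DEFINITIONS[vi] if isinstance(vi, str) else vi
    name = definition.name
    for b in definition.bands_required:
        if b not in bands:
            raise KeyError(f"band {b!r} required for {name}")
        arr = np.asarray(bands[b], dtype=float)
        if not np.all(np.isfinite(arr) | np.isnan(arr)):
            raise ValueError(f"band {b!r} contains non-finite values")
        with np.errstate(invalid="ignore"):
            if np.any(arr < 0):
                raise ValueError(f"band {b!r} contains negative reflectance")
    g = {b: np.asarray(bands[b], dtype=float) for b in definition.bands_required}
    if name == "nir_green":
        return _ratio(g["nir"], g["green"], name)
    if name == "nir_red":
        return _ratio(g["nir"], g["red"], name)
    if name == "nir_re":
        return _ratio(g["nir"], g["red_edge"], name)
    if name == "ndvi":
        return _ratio(g["nir"] - g["red"], g["nir"] + g["red"], name)
    if name == "evi2":
        return _ratio(2.5 * (g["nir"] - g["red"]), g["nir"] + 2.4 * g["red"] + 1.0, name)
    if name == "rendvi":
        return _ratio(g["nir"] - g["red_edge"], g["nir"] + g["red_edge"], name)
    if name == "viquo":
        return np.stack(
            [
                _ratio(g["nir"], g["green"], "nir_green"),
                _ratio(g["nir"], g["red"], "nir_red"),
                _ratio(g["nir"], g["red_edge"], "nir_re"),
            ],
            axis=-1,
        )
    raise ValueError(f"unknown vegetation index {name!r}")


_FORM_COEFS = {
    "linear_sr": ("a", "b"),
    "linear_multi": ("a", "b", "c", "d"),
    "exponential": ("a", "b"),
}


@dataclasses.dataclass
class GaiModel:
    """A fitted (or injected) VI→GAI model of one of the seven families."""

    form: str
    coefficients: dict[str, float]
    vi: str
    clip_negative: bool = False
    exponential_additive: bool = False

    def __post_init__(self) -> None:
        if self.form not in _FORM_COEFS:
            raise ValueError(f"unknown model form {self.form!r}")
        needed = _FORM_COEFS[self.form]
        missing = [k for k in needed if k not in self.coefficients]
        if missing:
            raise ValueError(f"form {self.form} requires coefficients {missing}")

    def predict(self, vi_values):
        return predict_gai(self, vi_values)


def predict_gai(model: GaiModel, vi_values):
    """Apply a GAI model to VI values (scalar or array).

    For the multi-ratio form, ``vi_values`` stacks (NIR/Green, NIR/Red,
    NIR/RE) along the last axis.  When ``clip_negative`` is set — the rule
    used in the crop-monitoring stage — negative predictions are set to 0.
    """
    v = np.asarray(vi_values, dtype=float)
    c = model.coefficients
    if model.form == "linear_sr":
        out = c["a"] + c["b"] * v
    elif model.form == "linear_multi":
        if v.shape[-1] != 3:
            raise ValueError("multi-ratio model expects three stacked ratios")
        out = c["a"] + c["b"] * v[..., 0] + c["c"] * v[..., 1] + c["d"] * v[..., 2]
    elif model.form == "exponential":
        if model.exponential_additive:
            out = c["a"] + np.exp(c["b"] * v)
        else:
            out = c["a"] * np.exp(c["b"] * v)
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(model.form)
    if model.clip_negative:
        out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)


#: Published Sentinel-2 winter-wheat GAI models (UAV-referenced calibration).
SENTINEL2_MODELS: dict[str, GaiModel] = {
    "nir_green": GaiModel("linear_sr", {"a": 0.2040, "b": 0.2179}, "nir_green"),
    "nir_red": GaiModel("linear_sr", {"a": 1.13776, "b": 0.0639}, "nir_red"),
    "nir_re": GaiModel("linear_sr", {"a": -9.781, "b": 8.712}, "nir_re"),
    "ndvi": GaiModel("exponential", {"a": 0.09, "b": 4.1858}, "ndvi"),
    "rendvi": GaiModel("exponential", {"a": 0.2908, "b": 10.9942}, "rendvi"),
    "evi2": GaiModel("exponential", {"a": 0.2638, "b": 2.4013}, "evi2"),
    "viquo": GaiModel(
        "linear_multi",
        {"a": -9.236087, "b": -0.023062, "c": -0.002741, "d": 8.142750},
        "viquo",
    ),
}


@dataclasses.dataclass
class CalibrationResult:
    model: GaiModel
    mae: float
    r2: float
    r2_as_printed: float
    n: int
    residuals: np.ndarray


def mae(predictions: Sequence[float], observations: Sequence[float]) -> float:
    """Mean absolute error between predictions and observations (m²/m²)."""
    y = np.asarray(predictions, dtype=float)
    x = np.asarray(observations, dtype=float)
    if y.shape != x.shape:
        raise ValueError("length mismatch")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(y - x)))


def r_squared(
    predictions: Sequence[float],
    observations: Sequence[float],
    formula: str = "standard",
) -> float:
    """Coefficient of determination between predictions and observations.

    ``standard`` is 1 − SSres/SStot.  ``as_printed`` is the ratio
    Σ(yᵢ−ȳ)² / Σ(xᵢ−ȳ)² with yᵢ the predictions, xᵢ the observations and ȳ
    the *prediction* mean; for an OLS fit with intercept the two agree, but
    they differ in general, so both are exposed.
    """
    y = np.asarray(predictions, dtype=float)
    x = np.asarray(observations, dtype=float)
    if y.shape != x.shape:
        raise ValueError("length mismatch")
    if y.size < 2:
        raise ValueError("need at least two observations")
    if formula == "standard":
        ss_tot = float(np.sum((x - x.mean()) ** 2))
        if ss_tot == 0:
            raise ValueError("constant observations: R² undefined")
        ss_res = float(np.sum((x - y) ** 2))
        return 1.0 - ss_res / ss_tot
    if formula == "as_printed":
        ybar = y.mean()
        denom = float(np.sum((x - ybar) ** 2))
        if denom == 0:
            raise ValueError("degenerate denominator: R² undefined")
        return float(np.sum((y - ybar) ** 2)) / denom
    raise ValueError(f"unknown formula {formula!r}")


def fit_gai_model(
    vi_values,
    gai_reference,
    form: str,
    vi_name: str = "",
    exponential_additive: bool = False,
) -> CalibrationResult:
    """Fit one of the model families to (VI, reference-GAI) data.

    Linear forms use ordinary least squares.  The exponential form is first
    fitted by OLS on ``log(GAI)`` (strictly positive GAI only), then refined
    by nonlinear least squares on the original scale over all points.
    """
    v = np.asarray(vi_values, dtype=float)
    g = np.asarray(gai_reference, dtype=float)
    if form not in _FORM_COEFS:
        raise ValueError(f"unknown model form {form!r}")
    n_coef = len(_FORM_COEFS[form])
    if form == "linear_multi":
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("multi-ratio fit expects an (n, 3) predictor array")
        n = v.shape[0]
    else:
        v = v.ravel()
        n = v.size
    if g.size != n:
        raise ValueError("predictor/response length mismatch")
    if n < n_coef + 1:
        raise ValueError("insufficient observations for the model form")
    cols = v if form == "linear_multi" else v[:, None]
    if np.any(cols.std(axis=0) == 0):
        raise ValueError("degenerate predictor (zero variance)")

    if form in ("linear_sr", "linear_multi"):
        X = np.column_stack([np.ones(n), cols])
        beta, *_ = np.linalg.lstsq(X, g, rcond=None)
        names = _FORM_COEFS[form]
        coef = {k: float(b) for k, b in zip(names, beta)}
        model = GaiModel(form, coef, vi_name)
    else:
        pos = g > 0
        if pos.sum() < 3:
            raise ValueError("too few positive GAI values for the log fit")
        A = np.column_stack([np.ones(int(pos.sum())), v[pos]])
        sol, *_ = np.linalg.lstsq(A, np.log(g[pos]), rcond=None)
        a0, b0 = float(np.exp(sol[0])), float(sol[1])

        if exponential_additive:
            def f(x, a, b):
                return a + np.exp(b * x)
            p0 = (0.0, b0)
        else:
            def f(x, a, b):
                return a * np.exp(b * x)
            p0 = (a0, b0)
        try:
            popt, _ = optimize.curve_fit(f, v, g, p0=p0, maxfev=10000)
        except RuntimeError:
            popt = p0
        model = GaiModel(
            "exponential",
            {"a": float(popt[0]), "b": float(popt[1])},
            vi_name,
            exponential_additive=exponential_additive,
        )

    pred = np.asarray(predict_gai(model, v), dtype=float)
    residuals = pred - g
    return CalibrationResult(
        model=model,
        mae=mae(pred, g),
        r2=r_squared(pred, g, "standard"),
        r2_as_printed=r_squared(pred, g, "as_printed"),
        n=n,
        residuals=residuals,
    )


@dataclasses.dataclass
class DateEffectReport:
    """Per-acquisition-date slope comparison of the VI→GAI relation."""

    slopes: pd.DataFrame  # columns: date, slope, se (interaction model)
    f_stat: float
    p_value: float
    pairwise: pd.DataFrame  # columns: date_a, date_b, diff, se, t, p_adj
    letters: dict
    alpha: float = 0.05
    common_slope: float = float("nan")  # additive (no-interaction) model

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    @property
    def n_groups(self) -> int:
        return len(set(self.letters.values()))


def _compact_letters(items: Sequence, estimates: Mapping, significant: set) -> dict:
    """Insert-and-absorb compact letter display.

    ``significant`` holds frozensets {i, j} of pairs whose difference is
    significant; members of such a pair may not share a letter.
    """
    order = sorted(items, key=lambda k: -estimates[k])
    groups: list[set] = [set(order)]
    for i, j in [tuple(p) for p in significant]:
        new: list[set] = []
        for grp in groups:
            if i in grp and j in grp:
                new.extend([grp - {i}, grp - {j}])
            else:
                new.append(grp)
        # absorb subsets
        groups = []
        for grp in sorted(new, key=len, reverse=True):
            if grp and not any(grp <= other for other in groups):
                groups.append(grp)
    # stable ordering of letters by best member
    groups.sort(key=lambda grp: min(order.index(m) for m in grp))
    letters = {k: "" for k in items}
    for idx, grp in enumerate(groups):
        ch = chr(ord("a") + idx)
        for m in grp:
            letters[m] += ch
    return {k: "".join(sorted(vv)) for k, vv in letters.items()}


def date_effect_test(records, alpha: float = 0.05) -> DateEffectReport:
    """Test whether the VI→GAI slope differs between acquisition dates.

    ``records`` is an iterable of ``(vi, gai, date)`` or a DataFrame with
    columns ``vi, gai, date``.  Two linear models are fitted: the additive
    model (common slope, date-specific intercepts) and the interaction model
    (date-specific slopes and intercepts).  The slope-heterogeneity F-test
    compares them; pairwise slope contrasts are adjusted with the
    studentized-range (Tukey) distribution and summarised as compact
    letters.
    """
    if isinstance(records, pd.DataFrame):
        df = records[["vi", "gai", "date"]].copy()
    else:
        df = pd.DataFrame(list(records), columns=["vi", "gai", "date"])
    dates = sorted(df["date"].unique())
    k = len(dates)
    if k < 2:
        raise ValueError("need at least two acquisition dates")
    counts = df.groupby("date").size()
    if (counts < 3).any():
        raise ValueError("need at least three records per date")
    n = len(df)
    d_idx = df["date"].map({d: i for i, d in enumerate(dates)}).to_numpy()
    v = df["vi"].to_numpy(dtype=float)
    y = df["gai"].to_numpy(dtype=float)

    # additive: per-date intercepts + common slope
    Xa = np.zeros((n, k + 1))
    Xa[np.arange(n), d_idx] = 1.0
    Xa[:, k] = v
    beta_a, *_ = np.linalg.lstsq(Xa, y, rcond=None)
    sse_a = float(np.sum((y - Xa @ beta_a) ** 2))

    # interaction: per-date intercepts + per-date slopes
    Xi = np.zeros((n, 2 * k))
    Xi[np.arange(n), d_idx] = 1.0
    Xi[np.arange(n), k + d_idx] = v
    beta_i, *_ = np.linalg.lstsq(Xi, y, rcond=None)
    resid = y - Xi @ beta_i
    dof = n - 2 * k
    sse_i = float(np.sum(resid**2))
    sigma2 = sse_i / dof

    f_stat = ((sse_a - sse_i) / (k - 1)) / sigma2
    p_value = float(stats.f.sf(f_stat, k - 1, dof))

    cov = sigma2 * np.linalg.inv(Xi.T @ Xi)
    slopes = beta_i[k:]
    slope_se = np.sqrt(np.diag(cov)[k:])
    slopes_df = pd.DataFrame({"date": dates, "slope": slopes, "se": slope_se})

    rows = []
    sig_pairs: set[frozenset] = set()
    for i in range(k):
        for j in range(i + 1, k):
            diff = slopes[i] - slopes[j]
            se = np.sqrt(cov[k + i, k + i] + cov[k + j, k + j] - 2 * cov[k + i, k + j])
            t = diff / se
            p_adj = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, dof))
            rows.append((dates[i], dates[j], diff, se, t, p_adj))
            if p_adj < alpha:
                sig_pairs.add(frozenset({dates[i], dates[j]}))
    pairwise = pd.DataFrame(
        rows, columns=["date_a", "date_b", "diff", "se", "t", "p_adj"]
    )
    letters = _compact_letters(
        dates, dict(zip(dates, slopes)), sig_pairs
    )
    return DateEffectReport(
        slopes_df, float(f_stat), p_value, pairwise, letters, alpha,
        common_slope=float(beta_a[k]),
    )
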