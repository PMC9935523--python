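"""Spatial interpolation of per-sample values to regular rasters.

Two interpolators are provided behind one interface: inverse distance
weighting (IDW, power 2 by default) and ordinary kriging (OK) with a
classical semivariogram (spherical, exponential or gaussian) fitted to the
empirical semivariogram by weighted least squares.  Both use a circular
search neighbourhood (default radius 500 m); raster cells with no sample
inside the radius are written as nodata.  The default raster resolution is
10 m.

Ordinary kriging is an exact interpolator when the nugget is zero, and its
weights sum to one (the unbiasedness constraint); both properties are the
scientific contract replacing the proprietary interpolator of the
reference workflow.  Rasters are written as ESRI ASCII grids, a plain-text
format readable by every GIS.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

VARIOGRAM_MODELS = ("spherical", "exponential", "gaussian")


@dataclass(frozen=True)
class RasterSpec:
    """Geometry of a regular output raster (planar metres)."""

    origin_x: float
    origin_y: float
    cell_size: float = 10.0
    n_cols: int = 100
    n_rows: int = 100
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if not self.cell_size > 0:
            raise ValueError("cell size must be strictly positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("raster dimensions must be >= 1")

    @classmethod
    def from_bounds(cls, minx: float, miny: float, maxx: float, maxy: float,
                    cell_size: float = 10.0, nodata: float = -9999.0
                    ) -> "RasterSpec":
        n_cols = max(1, int(math.ceil((maxx - minx) / cell_size)))
        n_rows = max(1, int(math.ceil((maxy - miny) / cell_size)))
        return cls(minx, miny, cell_size, n_cols, n_rows, nodata)

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) arrays of cell centres; row 0 is the TOP row (max y)."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys[::-1]


@dataclass(frozen=True)
class InterpolatorConfig:
    """Interpolation method and neighbourhood settings."""

    method: str = "idw"
    search_radius: float = 500.0
    idw_power: float = 2.0
    variogram_model: str = "spherical"
    min_neighbours: int = 1
    max_neighbours: int = 32

    def __post_init__(self) -> None:
        if self.method not in ("idw", "ordinary_kriging"):
            raise ValueError(
                f"method must be 'idw' or 'ordinary_kriging', got {self.method!r}")
        if not self.search_radius > 0:
            raise ValueError("search radius must be strictly positive")
        if not self.idw_power > 0:
            raise ValueError("IDW power must be strictly positive")
        if self.variogram_model not in VARIOGRAM_MODELS:
            raise ValueError(
                f"variogram model must be one of {VARIOGRAM_MODELS}")


def variogram(model: str, h, nugget: float, psill: float, vrange: float):
    """Semivariance gamma(h) of a named model.

    ``psill`` is the partial sill (sill - nugget); ``vrange`` the (effective)
    range.  gamma(0) = 0 by convention.
    """
    h = np.asarray(h, dtype=float)
    if model == "spherical":
        g = np.where(h >= vrange, psill,
                     psill * (1.5 * h / vrange - 0.5 * (h / vrange) ** 3))
    elif model == "exponential":
        g = psill * (1.0 - np.exp(-3.0 * h / vrange))
    elif model == "gaussian":
        g = psill * (1.0 - np.exp(-3.0 * (h / vrange) ** 2))
    else:
        raise ValueError(f"unknown variogram model {model!r}")
    return np.where(h > 0, nugget + g, 0.0)


def empirical_variogram(x: np.ndarray, y: np.ndarray, values: np.ndarray,
                        n_bins: int = 12, max_lag: float | None = None
                        ) -> pd.DataFrame:
    """Binned empirical semivariogram.

    Returns a DataFrame ``lag, gamma, n_pairs`` over at least 8 distance
    bins (empty bins dropped).
    """
    n_bins = max(8, n_bins)
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    d = np.hypot(dx, dy)
    dv2 = 0.5 * (values[:, None] - values[None, :]) ** 2
    iu = np.triu_indices(len(x), k=1)
    d, dv2 = d[iu], dv2[iu]
    if max_lag is None:
        max_lag = d.max() / 2.0
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (d > lo) & (d <= hi)
        if sel.sum() == 0:
            continue
        rows.append({"lag": float(d[sel].mean()),
                     "gamma": float(dv2[sel].mean()),
                     "n_pairs": int(sel.sum())})
    return pd.DataFrame(rows)


@dataclass
class FittedInterpolator:
    """A fitted interpolation model ready for prediction."""

    config: InterpolatorConfig
    x: np.ndarray
    y: np.ndarray
    values: np.ndarray
    nugget: float = 0.0
    psill: float = 0.0
    vrange: float = 1.0
    constant: float | None = None  # degenerate all-equal fallback
    _tree: cKDTree = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._tree = cKDTree(np.column_stack([self.x, self.y]))

    @property
    def sill(self) -> float:
        return self.nugget + self.psill

    def _gamma(self, h):
        return variogram(self.config.variogram_model, h,
                         self.nugget, self.psill, self.vrange)

    def ok_weights(self, px: float, py: float,
                   idx: np.ndarray) -> tuple[np.ndarray, float]:
        """Ordinary kriging weights (sum to 1) and the kriging variance for
        one prediction point given neighbour indices."""
        xs, ys, vs = self.x[idx], self.y[idx], self.values[idx]
        m = len(idx)
        h = np.hypot(xs[:, None] - xs[None, :], ys[:, None] - ys[None, :])
        a = np.empty((m + 1, m + 1))
        a[:m, :m] = self._gamma(h)
        a[m, :m] = 1.0
        a[:m, m] = 1.0
        a[m, m] = 0.0
        h0 = np.hypot(xs - px, ys - py)
        b = np.empty(m + 1)
        b[:m] = self._gamma(h0)
        b[m] = 1.0
        try:
            sol = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            sol, *_ = np.linalg.lstsq(a, b, rcond=None)
        w, lam = sol[:m], sol[m]
        var = float(w @ b[:m] + lam)
        return w, max(var, 0.0)

    def predict(self, px: np.ndarray, py: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
        """Predict at arbitrary points.

        Returns (predictions, variance); points with no neighbour inside
        the search radius get NaN.  The variance array is the kriging
        variance for OK and NaN for IDW.
        """
        px = np.atleast_1d(np.asarray(px, dtype=float))
        py = np.atleast_1d(np.asarray(py, dtype=float))
        pred = np.full(px.shape, np.nan)
        var = np.full(px.shape, np.nan)
        cfg = self.config
        neighbours = self._tree.query_ball_point(
            np.column_stack([px, py]), r=cfg.search_radius)
        for i, idx in enumerate(neighbours):
            if len(idx) < cfg.min_neighbours or len(idx) == 0:
                continue
            idx = np.asarray(idx)
            if len(idx) > cfg.max_neighbours:
                d = np.hypot(self.x[idx] - px[i], self.y[idx] - py[i])
                idx = idx[np.argsort(d)[:cfg.max_neighbours]]
            if self.constant is not None:
                pred[i] = self.constant
                var[i] = 0.0
                continue
            d = np.hypot(self.x[idx] - px[i], self.y[idx] - py[i])
            exact = d < 1e-9
            if exact.any():
                pred[i] = self.values[idx[np.argmax(exact)]]
                var[i] = 0.0 if self.nugget == 0 else np.nan
                continue
            if cfg.method == "idw":
                w = 1.0 / d ** cfg.idw_power
                pred[i] = float(w @ self.values[idx] / w.sum())
            else:
                w, kv = self.ok_weights(px[i], py[i], idx)
                pred[i] = float(w @ self.values[idx])
                var[i] = kv
        return pred, var


def fit_interpolator(samples: pd.DataFrame, value_col: str,
                     config: InterpolatorConfig | None = None
                     ) -> FittedInterpolator:
    """Fit an interpolation model to point samples.

    *samples* needs finite ``x``, ``y`` and *value_col* columns with at
    least 5 rows; duplicate coordinates are averaged (with a log entry).
    For ordinary kriging the empirical semivariogram is computed on >= 8
    distance bins and the configured model fitted by weighted least squares
    (weights = pair counts).  If all values are identical the model
    degenerates to a constant surface (with a warning).  For IDW no fitting
    is required beyond the config.
    """
    config = config or InterpolatorConfig()
    df = samples[["x", "y", value_col]].dropna()
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError("samples contain non-finite coordinates or values")
    before = len(df)
    df = df.groupby(["x", "y"], as_index=False)[value_col].mean()
    if len(df) < before:
        logger.info("averaged %d duplicate-coordinate samples",
                    before - len(df))
    if len(df) < 5:
        raise ValueError("need at least 5 distinct sample locations")
    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    v = df[value_col].to_numpy(dtype=float)

    model = FittedInterpolator(config, x, y, v)
    if np.ptp(v) == 0:
        warnings.warn("all sample values identical; interpolator degenerates "
                      "to a constant surface", stacklevel=2)
        model.constant = float(v[0])
        return model
    if config.method == "idw":
        return model

    emp = empirical_variogram(x, y, v)
    lags = emp["lag"].to_numpy()
    gammas = emp["gamma"].to_numpy()
    npairs = emp["n_pairs"].to_numpy(dtype=float)
    s0 = float(v.var())
    r0 = float(lags.max()) / 2.0 or 1.0

    def f(h, nugget, psill, vrange):
        return variogram(config.variogram_model, h, nugget, psill, vrange)

    try:
        popt, _ = curve_fit(
            f, lags, gammas, p0=[0.0, s0, r0],
            sigma=1.0 / np.sqrt(npairs), absolute_sigma=False,
            bounds=([0.0, 1e-12, 1e-6],
                    [max(gammas.max(), 1e-9), np.inf, np.inf]),
            maxfev=20000)
        model.nugget, model.psill, model.vrange = map(float, popt)
    except RuntimeError:
        logger.warning("variogram WLS fit failed to converge; using "
                       "moment-based fallback (nugget 0, sill = variance)")
        model.nugget, model.psill, model.vrange = 0.0, s0, r0
    return model


def predict_grid(model: FittedInterpolator, spec: RasterSpec
                 ) -> tuple[np.ndarray, np.ndarray | None]:
    """Predict onto a raster grid.

    Returns (prediction raster, variance raster or None).  Rasters are
    (n_rows, n_cols) with row 0 at the top; cells with no sample inside
    the search radius hold ``spec.nodata``.
    """
    xs, ys = model.x, model.y
    gx, gy = spec.cell_centres()
    xmax = spec.origin_x + spec.n_cols * spec.cell_size
    ymax = spec.origin_y + spec.n_rows * spec.cell_size
    if (xs.max() < spec.origin_x or xs.min() > xmax
            or ys.max() < spec.origin_y or ys.min() > ymax):
        warnings.warn("raster does not overlap the data extent; output is "
                      "all nodata", stacklevel=2)
    gxx, gyy = np.meshgrid(gx, gy)
    pred, var = model.predict(gxx.ravel(), gyy.ravel())
    pred = pred.reshape(spec.n_rows, spec.n_cols)
    var = var.reshape(spec.n_rows, spec.n_cols)
    out = np.where(np.isnan(pred), spec.nodata, pred)
    if model.config.method == "ordinary_kriging":
        var_out = np.where(np.isnan(var), spec.nodata, var)
        return out, var_out
    return out, None


def cross_validate(samples: pd.DataFrame, value_col: str,
                   config: InterpolatorConfig | None = None) -> dict:
    """Leave-one-out cross-validation of an interpolation configuration.

    Each sample is predicted from all the others; returns
    ``{"mean_error": ..., "rmse": ..., "n": ..., "n_predicted": ...}``
    (samples with no neighbour inside the search radius are excluded from
    the summary but counted in ``n``).
    """
    config = config or InterpolatorConfig()
    df = samples[["x", "y", value_col]].dropna().reset_index(drop=True)
    if len(df) < 10:
        raise ValueError("cross-validation requires at least 10 samples")
    errors = []
    for i in range(len(df)):
        train = df.drop(index=i)
        model = fit_interpolator(train, value_col, config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred, _ = model.predict(df.at[i, "x"], df.at[i, "y"])
        if np.isfinite(pred[0]):
            errors.append(pred[0] - df.at[i, value_col])
    errors = np.asarray(errors)
    if errors.size == 0:
        raise ValueError("no sample had neighbours within the search radius")
    return {"mean_error": float(errors.mean()),
            "rmse": float(np.sqrt((errors ** 2).mean())),
            "n": int(len(df)), "n_predicted": int(errors.size)}


def write_esri_ascii(path: str | Path, raster: np.ndarray,
                     spec: RasterSpec) -> None:
    """Write a raster as an ESRI ASCII grid (plain text).

    Header fields: ncols, nrows, xllcorner, yllcorner, cellsize,
    NODATA_value; data rows from the top row down.
    """
    raster = np.asarray(raster)
    if raster.shape != (spec.n_rows, spec.n_cols):
        raise ValueError(
            f"raster shape {raster.shape} does not match spec "
            f"({spec.n_rows}, {spec.n_cols})")
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.origin_x:.6f}\n")
        fh.write(f"yllcorner {spec.origin_y:.6f}\n")
        fh.write(f"cellsize {spec.cell_size:.6f}\n")
        fh.write(f"NODATA_value {spec.nodata:g}\n")
        for row in raster:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_esri_ascii(path: str | Path) -> tuple[np.ndarray, RasterSpec]:
    """Read an ESRI ASCII grid written by :func:`write_esri_ascii`."""
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    spec = RasterSpec(header["xllcorner"], header["yllcorner"],
                      header["cellsize"], int(header["ncols"]),
                      int(header["nrows"]), header["nodata_value"])
    return np.atleast_2d(data), spec
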