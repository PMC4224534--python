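"""Spatial interpolation (universal kriging) and GLMs for community indices.

Station coordinates are projected to kilometres with a local equirectangular
projection about the station centroid, adequate at the sub-basin scale the
indices are mapped at.  Interpolation follows the universal-kriging recipe:
a deterministic drift (default linear in x, y) is removed by OLS, a
parametric semivariogram is fitted to the residuals by weighted least
squares, and predictions solve the universal-kriging system per grid cell,
returning both the BLUP and its kriging variance.

Index-versus-environment models are Gaussian identity-link GLMs of an index
on bottom temperature and depth, with polynomial coordinate terms soaking up
broad-scale spatial autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.linalg import lu_factor, lu_solve
from scipy.spatial.distance import cdist, pdist, squareform

EARTH_RADIUS_KM = 6371.0


def project_coordinates(
    lon, lat, origin: tuple[float, float] | None = None,
    window: tuple[float, float, float, float] | None = None,
):
    """Project lon/lat (degrees) to local (x, y) kilometres.

    Equirectangular about ``origin`` (default: the centroid of the points):
    x = R cos(lat0) dlon, y = R dlat, angles in radians, R = 6371 km.
    Returns (x, y, origin).  ``window`` = (lon_min, lon_max, lat_min, lat_max)
    optionally bounds acceptable inputs.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if window is not None:
        lo1, hi1, lo2, hi2 = window
        if np.any((lon < lo1) | (lon > hi1) | (lat < lo2) | (lat > hi2)):
            raise ValueError("coordinates outside the declared study window")
    if origin is None:
        origin = (float(lon.mean()), float(lat.mean()))
    lon0, lat0 = origin
    x = EARTH_RADIUS_KM * np.cos(np.radians(lat0)) * np.radians(lon - lon0)
    y = EARTH_RADIUS_KM * np.radians(lat - lat0)
    return x, y, origin


_MODELS = {
    "exponential": lambda h, a: 1.0 - np.exp(-h / a),
    "spherical": lambda h, a: np.where(
        h < a, 1.5 * (h / a) - 0.5 * (h / a) ** 3, 1.0
    ),
    "gaussian": lambda h, a: 1.0 - np.exp(-((h / a) ** 2)),
}


@dataclass
class Variogram:
    """Fitted semivariogram: gamma(h) = nugget + psill * shape(h / range)."""

    model: str
    nugget: float
    psill: float
    range_: float
    bin_centers: np.ndarray | None = field(default=None, repr=False)
    bin_gamma: np.ndarray | None = field(default=None, repr=False)
    bin_counts: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown variogram model {self.model!r}")
        if self.nugget < 0 or self.psill < 0 or self.range_ <= 0:
            raise ValueError("variogram parameters out of range")

    def __call__(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        gamma = self.nugget + self.psill * _MODELS[self.model](h, self.range_)
        return np.where(h == 0, 0.0, gamma)

    @property
    def sill(self) -> float:
        return self.nugget + self.psill


def _drift_matrix(x: np.ndarray, y: np.ndarray, drift: str) -> np.ndarray:
    if drift == "constant":
        return np.ones((len(x), 1))
    if drift == "linear":
        return np.column_stack([np.ones_like(x), x, y])
    raise ValueError(f"unknown drift {drift!r} (use 'constant' or 'linear')")


def fit_variogram(
    points: np.ndarray,
    values: np.ndarray,
    drift: str = "linear",
    model: str = "exponential",
    n_bins: int = 15,
    max_dist: float | None = None,
) -> Variogram:
    """Fit a semivariogram to OLS-drift residuals by weighted least squares.

    The empirical semivariogram is binned by pair distance up to ``max_dist``
    (default: a third of the maximum pairwise distance, where bin estimates
    are still reliable); following the gstat convention, bins are weighted by
    pair count over squared lag (N_j / h_j^2) in the parametric fit.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(points) < 30:
        raise ValueError("need at least 30 points for a stable semivariogram")
    F = _drift_matrix(points[:, 0], points[:, 1], drift)
    beta, *_ = np.linalg.lstsq(F, values, rcond=None)
    resid = values - F @ beta

    d = pdist(points)
    dz2 = 0.5 * pdist(resid[:, None], metric="sqeuclidean")
    if max_dist is None:
        max_dist = d.max() / 3.0
    edges = np.linspace(0, max_dist, n_bins + 1)
    idx = np.digitize(d, edges) - 1
    ok = (idx >= 0) & (idx < n_bins)
    counts = np.bincount(idx[ok], minlength=n_bins)
    sums = np.bincount(idx[ok], weights=dz2[ok], minlength=n_bins)
    nonempty = counts > 0
    centers = 0.5 * (edges[:-1] + edges[1:])[nonempty]
    gamma = sums[nonempty] / counts[nonempty]
    counts = counts[nonempty]

    resid_var = float(resid.var(ddof=1))
    if resid_var < 1e-12 or np.all(gamma < 1e-12):
        # noiseless drift field: degenerate flat variogram
        return Variogram(model, 0.0, 1e-12, max(max_dist / 3.0, 1e-6),
                         centers, gamma, counts)

    shape = _MODELS[model]
    w = np.sqrt(counts.astype(float)) / centers

    def residuals(theta):
        nugget, psill, rng = theta
        return w * (nugget + psill * shape(centers, rng) - gamma)

    x0 = np.array([0.0, resid_var, max_dist / 3.0])
    res = optimize.least_squares(
        residuals, x0,
        bounds=([0.0, 1e-12, 1e-6], [np.inf, np.inf, 10 * max_dist]),
    )
    nugget, psill, rng = res.x
    return Variogram(model, float(nugget), float(psill), float(rng),
                     centers, gamma, counts)


@dataclass
class KrigedSurface:
    """Gridded universal-kriging predictions and variances for one index."""

    x: np.ndarray
    y: np.ndarray
    prediction: np.ndarray
    variance: np.ndarray
    index_name: str = ""
    year: int | None = None
    origin: tuple[float, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "x": self.x,
                "y": self.y,
                "prediction": self.prediction,
                "variance": self.variance,
            }
        )
        if self.origin is not None:
            lon0, lat0 = self.origin
            df["lon"] = lon0 + np.degrees(
                self.x / (EARTH_RADIUS_KM * np.cos(np.radians(lat0)))
            )
            df["lat"] = lat0 + np.degrees(self.y / EARTH_RADIUS_KM)
        return df


def universal_krige(
    points: np.ndarray,
    values: np.ndarray,
    grid: np.ndarray,
    variogram: Variogram,
    drift: str = "linear",
    jitter_duplicates: bool = True,
) -> KrigedSurface:
    """Best linear unbiased prediction with drift on a grid of (x, y) points.

    Solves the universal-kriging system (semivariogram form with Lagrange
    multipliers for the drift terms) for every grid cell.  With zero nugget
    the prediction at a data point reproduces the observation exactly and
    its kriging variance is zero.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    n = len(points)
    D = squareform(pdist(points))
    if np.any(D[~np.eye(n, dtype=bool)] < 1e-9):
        if not jitter_duplicates:
            raise ValueError("duplicate point locations make the kriging system singular")
        rng = np.random.default_rng(0)
        points = points + rng.normal(scale=1e-6, size=points.shape)
        D = squareform(pdist(points))
    F = _drift_matrix(points[:, 0], points[:, 1], drift)
    q = F.shape[1]
    A = np.zeros((n + q, n + q))
    A[:n, :n] = variogram(D)
    A[:n, n:] = F
    A[n:, :n] = F.T
    lu = lu_factor(A)

    gamma0 = variogram(cdist(points, grid))  # (n, m)
    f0 = _drift_matrix(grid[:, 0], grid[:, 1], drift).T  # (q, m)
    rhs = np.vstack([gamma0, f0])
    sol = lu_solve(lu, rhs)
    lam, mu = sol[:n], sol[n:]
    pred = lam.T @ values
    var = np.einsum("im,im->m", lam, gamma0) + np.einsum("qm,qm->m", mu, f0)
    return KrigedSurface(
        x=grid[:, 0], y=grid[:, 1],
        prediction=pred, variance=np.maximum(var, 0.0),
    )


def make_grid(points: np.ndarray, spacing_km: float = 20.0) -> np.ndarray:
    """Regular grid over the bounding box of the stations."""
    points = np.asarray(points, dtype=float)
    xs = np.arange(points[:, 0].min(), points[:, 0].max() + spacing_km, spacing_km)
    ys = np.arange(points[:, 1].min(), points[:, 1].max() + spacing_km, spacing_km)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass
class GLMFit:
    """Gaussian identity-link GLM of an index on temperature, depth and space.

    Marginal effects are reported on field-standard scales: per degree C for
    temperature and per 100 m for depth.  Standardized coefficients are
    raw coefficient * SD(predictor) / SD(response).
    """

    response: str
    terms: list[str]
    coefficients: pd.Series
    std_errors: pd.Series
    p_values: pd.Series
    standardized: pd.Series
    marginal_effects: dict[str, float]
    nobs: int
    result: object = field(repr=False, default=None)

    def summary_text(self) -> str:
        lines = [f"GLM (gaussian/identity): {self.response} ~ {' + '.join(self.terms)}",
                 f"n = {self.nobs}"]
        for t in self.coefficients.index:
            lines.append(
                f"  {t:>12s}: coef={self.coefficients[t]: .4f} "
                f"se={self.std_errors[t]:.4f} p={self.p_values[t]:.3g} "
                f"std={self.standardized.get(t, float('nan')): .3f}"
            )
        for k, v in self.marginal_effects.items():
            lines.append(f"  marginal effect {k}: {v:.3f}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.coefficients,
                "std_error": self.std_errors,
                "p_value": self.p_values,
                "standardized": self.standardized,
            }
        )


def fit_index_glm(
    indices: pd.DataFrame,
    response: str,
    coord_poly_degree: int = 2,
    condition_threshold: float = 1e8,
) -> GLMFit:
    """Fit index ~ temperature + depth + polynomial(x, y) by Gaussian GLM.

    Coordinates are projected internally from lon/lat; polynomial terms up to
    ``coord_poly_degree`` (degree 2 adds x2, y2, xy) absorb broad-scale
    spatial trend so the temperature and depth effects are not inflated by
    autocorrelation.
    """
    if response not in indices.columns:
        raise ValueError(f"response {response!r} not in indices table")
    df = indices.dropna(subset=[response, "temperature", "depth"]).copy()
    x, y, _ = project_coordinates(df["lon"], df["lat"])
    terms: dict[str, np.ndarray] = {
        "temperature": df["temperature"].to_numpy(float),
        "depth": df["depth"].to_numpy(float),
        "x": x,
        "y": y,
    }
    if coord_poly_degree >= 2:
        for d in range(2, coord_poly_degree + 1):
            terms[f"x{d}"] = x**d
            terms[f"y{d}"] = y**d
        terms["xy"] = x * y
    X = pd.DataFrame(terms, index=df.index)
    degenerate = [c for c in X.columns if X[c].std(ddof=0) < 1e-12]
    if degenerate:
        raise ValueError(f"degenerate (constant) predictor(s): {degenerate}")
    Xz = (X - X.mean()) / X.std(ddof=1)
    if np.linalg.cond(Xz.to_numpy()) > condition_threshold:
        corr = Xz.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        aliased = sorted(set(corr.stack().idxmax()))
        raise ValueError(f"collinear design; near-aliased terms: {aliased}")
    design = sm.add_constant(X)
    fit = sm.GLM(df[response].to_numpy(float), design,
                 family=sm.families.Gaussian()).fit()
    sd_y = float(df[response].std(ddof=1))
    standardized = pd.Series(
        {c: float(fit.params[c]) * float(X[c].std(ddof=1)) / sd_y for c in X.columns}
    )
    marginal = {
        "per_degC": float(fit.params["temperature"]),
        "per_100m": float(fit.params["depth"]) * 100.0,
    }
    return GLMFit(
        response=response,
        terms=list(X.columns),
        coefficients=pd.Series(fit.params),
        std_errors=pd.Series(fit.bse),
        p_values=pd.Series(fit.pvalues),
        standardized=standardized,
        marginal_effects=marginal,
        nobs=int(fit.nobs),
        result=fit,
    )
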