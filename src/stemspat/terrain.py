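"""Quadrat topography, habitat classification, kriging and environmental PCA.

Topography conventions (CTFS-style): quadrat elevation is the mean of its
four corner posts; slope is the mean tilt angle of the four planes through
each triple of corners; convexity is the focal quadrat elevation minus the
mean elevation of its (up to 8) neighbouring quadrats, with edge quadrats
falling back to centre-point elevation minus own corner mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import curve_fit
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .plot_io import PlotWindow, RasterSurface

log = logging.getLogger(__name__)

HABITATS = (
    "disturbed", "high_valley", "low_valley", "high_ridge", "low_ridge",
    "high_slope", "low_slope",
)

QUADRAT_SIZE = 20.0
GRID_CELL = 5.0


# ---------------------------------------------------------------------------
# quadrat topography


def quadrat_topography(posts: np.ndarray, quadrat_size: float = QUADRAT_SIZE
                       ) -> pd.DataFrame:
    """Per-quadrat mean elevation, convexity and slope from corner posts.

    ``posts`` has shape (ny+1, nx+1): elevations on the quadrat-corner grid,
    row 0 at the southern edge. Returns one row per quadrat with columns
    ``ix, iy, mean_elev, convexity, slope``.
    """
    posts = np.asarray(posts, dtype=float)
    if posts.ndim != 2 or posts.shape[0] < 2 or posts.shape[1] < 2:
        raise ValueError("posts must be a (ny+1, nx+1) corner grid with ny, nx >= 1")
    ny, nx = posts.shape[0] - 1, posts.shape[1] - 1

    z00 = posts[:-1, :-1]  # SW corner of each quadrat
    z10 = posts[:-1, 1:]   # SE
    z01 = posts[1:, :-1]   # NW
    z11 = posts[1:, 1:]    # NE
    mean_elev = (z00 + z10 + z01 + z11) / 4.0

    # slope: mean tilt of the 4 planes through each corner triple
    s = quadrat_size
    angles = np.zeros((4, ny, nx))
    # One triple per omitted corner; the plane gradient comes from the two
    # axis-aligned legs meeting at the right-angle vertex (both of length s).
    grads = [
        ((z10 - z00) / s, (z01 - z00) / s),  # omit NE
        ((z10 - z00) / s, (z11 - z10) / s),  # omit NW
        ((z11 - z01) / s, (z01 - z00) / s),  # omit SE
        ((z11 - z01) / s, (z11 - z10) / s),  # omit SW
    ]
    for k, (gx, gy) in enumerate(grads):
        angles[k] = np.degrees(np.arctan(np.hypot(gx, gy)))
    slope = angles.mean(axis=0)

    # convexity: focal mean elevation minus mean of the 8 neighbours;
    # edge quadrats: centre-point elevation minus own corner mean.
    conv = np.zeros((ny, nx))
    padded = np.full((ny + 2, nx + 2), np.nan)
    padded[1:-1, 1:-1] = mean_elev
    neigh_sum = np.zeros((ny, nx))
    neigh_cnt = np.zeros((ny, nx))
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            block = padded[1 + dy: 1 + dy + ny, 1 + dx: 1 + dx + nx]
            ok = ~np.isnan(block)
            neigh_sum[ok] += block[ok]
            neigh_cnt[ok] += 1
    interior = neigh_cnt == 8
    with np.errstate(invalid="ignore"):
        conv[interior] = mean_elev[interior] - neigh_sum[interior] / 8.0
    # centre elevation from bilinear interpolation of the 4 corners equals
    # their mean, so the edge fallback evaluates to 0 by construction.
    centre = (z00 + z10 + z01 + z11) / 4.0
    conv[~interior] = (centre - mean_elev)[~interior]

    iy, ix = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    return pd.DataFrame({
        "ix": ix.ravel(), "iy": iy.ravel(),
        "mean_elev": mean_elev.ravel(),
        "convexity": conv.ravel(),
        "slope": slope.ravel(),
    })


# ---------------------------------------------------------------------------
# habitat classification


@dataclass
class HabitatMap:
    """Per-20-m-quadrat habitat labels (integer codes into HABITATS)."""

    labels: np.ndarray  # (ny, nx) of str
    quadrat_size: float = QUADRAT_SIZE
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(self.labels.ravel()) - set(HABITATS)
        if bad:
            raise ValueError(f"unknown habitat labels {sorted(bad)}")

    @property
    def shape(self):
        return self.labels.shape

    def counts(self) -> dict[str, int]:
        vals, cnts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(vals.tolist(), cnts.tolist()))

    def area_by_habitat(self) -> dict[str, float]:
        """Habitat areas in m^2 (quadrat count times quadrat area)."""
        a = self.quadrat_size ** 2
        return {h: c * a for h, c in self.counts().items()}

    def label_at(self, x, y) -> np.ndarray:
        ix = np.floor((np.asarray(x, float) - self.origin[0]) / self.quadrat_size).astype(int)
        iy = np.floor((np.asarray(y, float) - self.origin[1]) / self.quadrat_size).astype(int)
        ny, nx = self.labels.shape
        if np.any((ix < 0) | (ix >= nx) | (iy < 0) | (iy >= ny)):
            raise ValueError("point outside the habitat map")
        return self.labels[iy, ix].astype(str)


def classify_habitats(topo: pd.DataFrame,
                      disturbed_mask: set[tuple[int, int]] | None = None,
                      convexity_breaks: tuple[float, float] = (-2.0, 2.0),
                      elevation_break: float = 450.0) -> HabitatMap:
    """Seven-class habitat rule set.

    A quadrat in the disturbed mask is ``disturbed`` regardless of topography.
    Otherwise convexity < breaks[0] gives valley, convexity >= breaks[1] gives
    ridge, the half-open band in between gives slope; elevation >= the break
    maps to the "high" stratum, below it to "low".
    """
    disturbed_mask = disturbed_mask or set()
    lo_c, hi_c = convexity_breaks
    nx = int(topo["ix"].max()) + 1
    ny = int(topo["iy"].max()) + 1
    labels = np.empty((ny, nx), dtype=object)
    for row in topo.itertuples(index=False):
        if (row.ix, row.iy) in disturbed_mask:
            labels[row.iy, row.ix] = "disturbed"
            continue
        if row.convexity < lo_c:
            terrain = "valley"
        elif row.convexity < hi_c:
            terrain = "slope"
        else:
            terrain = "ridge"
        stratum = "high" if row.mean_elev >= elevation_break else "low"
        labels[row.iy, row.ix] = f"{stratum}_{terrain}"
    if (labels == None).any():  # noqa: E711 -- object array fill check
        raise ValueError("topography table does not cover every quadrat")
    return HabitatMap(labels=labels)


# ---------------------------------------------------------------------------
# variograms and kriging


def empirical_semivariogram(xy: np.ndarray, values: np.ndarray,
                            lag_bins: np.ndarray) -> pd.DataFrame:
    """Matheron estimator: half the mean squared difference over the pairs
    whose separation falls in each bin. Returns columns lag, gamma, n_pairs;
    empty bins carry n_pairs 0 and gamma NaN.
    """
    xy = np.asarray(xy, dtype=float)
    values = np.asarray(values, dtype=float)
    lag_bins = np.asarray(lag_bins, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least two samples")
    from scipy.spatial.distance import pdist

    d = pdist(xy)
    dv2 = pdist(values[:, None], metric="sqeuclidean")
    which = np.digitize(d, lag_bins) - 1
    nbin = len(lag_bins) - 1
    gamma = np.full(nbin, np.nan)
    count = np.zeros(nbin, dtype=int)
    for b in range(nbin):
        sel = which == b
        count[b] = int(sel.sum())
        if count[b]:
            gamma[b] = 0.5 * dv2[sel].mean()
    mid = 0.5 * (lag_bins[:-1] + lag_bins[1:])
    return pd.DataFrame({"lag": mid, "gamma": gamma, "n_pairs": count})


@dataclass
class VariogramModel:
    """Exponential variogram gamma(h) = nugget + psill * (1 - exp(-h/range))."""

    nugget: float
    psill: float
    range: float

    @property
    def sill(self) -> float:
        return self.nugget + self.psill

    def __call__(self, h):
        h = np.asarray(h, dtype=float)
        return self.nugget + self.psill * (1.0 - np.exp(-h / self.range))

    def covariance(self, h):
        """Stationary covariance implied by the variogram (sill - gamma)."""
        h = np.asarray(h, dtype=float)
        c = self.psill * np.exp(-h / self.range)
        return np.where(h == 0.0, self.psill + self.nugget, c)


def fit_variogram(emp: pd.DataFrame, model: str = "exponential") -> VariogramModel:
    """Weighted least squares fit (weights = pair counts) of the exponential
    model to an empirical semivariogram; empty bins are excluded."""
    if model != "exponential":
        raise ValueError("only the exponential model is supported")
    ok = emp["n_pairs"].to_numpy() > 0
    lag = emp["lag"].to_numpy()[ok]
    gam = emp["gamma"].to_numpy()[ok]
    w = emp["n_pairs"].to_numpy()[ok].astype(float)
    if len(lag) < 3:
        raise ValueError("need at least 3 non-empty lag bins")
    var0 = max(gam.max(), 1e-12)

    def f(h, nugget, psill, rng):
        return nugget + psill * (1.0 - np.exp(-h / rng))

    p0 = (0.1 * var0, 0.9 * var0, lag.mean())
    bounds = ([0.0, 1e-12, 1e-6], [var0 * 2, var0 * 4, lag.max() * 10])
    try:
        popt, _ = curve_fit(f, lag, gam, p0=p0, sigma=1.0 / np.sqrt(w),
                            bounds=bounds, maxfev=20000)
    except RuntimeError:
        log.warning("variogram fit did not converge; using initial values")
        popt = p0
    return VariogramModel(nugget=float(popt[0]), psill=float(popt[1]),
                          range=float(popt[2]))


def krige_block(xy: np.ndarray, values: np.ndarray, model: VariogramModel,
                window: PlotWindow, cell_size: float = GRID_CELL,
                name: str = "", sub: int = 2) -> RasterSurface:
    """Ordinary block kriging onto a regular grid.

    Each prediction cell is approximated by the average of a ``sub x sub``
    sub-point grid. The ordinary-kriging system is factorised once and solved
    for all cells; weights sum to 1 through the Lagrange constraint. A
    singular system falls back to nearest-sample prediction (logged).
    """
    if model.sill <= 0:
        raise ValueError("variogram sill must be positive")
    xy = np.asarray(xy, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(values)
    nx = int(round(window.x_extent / cell_size))
    ny = int(round(window.y_extent / cell_size))

    # covariance form of the OK system
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = model.covariance(cdist(xy, xy))
    a[n, :n] = 1.0
    a[:n, n] = 1.0
    a[n, n] = 0.0
    try:
        factor = lu_factor(a)
    except Exception:  # pragma: no cover - degenerate sample configurations
        factor = None
    if factor is None or not np.all(np.isfinite(factor[0])):
        log.warning("singular kriging system; falling back to nearest-sample values")
        return _nearest_surface(xy, values, window, cell_size, name)

    # sub-point offsets within a cell
    off = (np.arange(sub) + 0.5) / sub * cell_size
    ox, oy = np.meshgrid(off, off)
    offsets = np.column_stack([ox.ravel(), oy.ravel()])

    x0, y0 = window.origin
    cells_x = x0 + np.arange(nx) * cell_size
    cells_y = y0 + np.arange(ny) * cell_size
    gx, gy = np.meshgrid(cells_x, cells_y)
    corners = np.column_stack([gx.ravel(), gy.ravel()])  # cell lower-left
    n_cells = corners.shape[0]
    n_sub = offsets.shape[0]
    pred = np.empty(n_cells)
    chunk = max(1, 4_000_000 // (max(n, 1) * n_sub))
    for start in range(0, n_cells, chunk):
        batch = corners[start:start + chunk]
        m = batch.shape[0]
        # block covariance per cell = mean covariance over its sub-points
        pts = (batch[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
        c0 = model.covariance(cdist(xy, pts)).reshape(n, m, n_sub).mean(axis=2)
        rhs = np.vstack([c0, np.ones((1, m))])
        sol = lu_solve(factor, rhs)
        pred[start:start + m] = values @ sol[:n]
    return RasterSurface(values=pred.reshape(ny, nx), cell_size=cell_size,
                         origin=window.origin, name=name)


def _nearest_surface(xy, values, window, cell_size, name):
    nx = int(round(window.x_extent / cell_size))
    ny = int(round(window.y_extent / cell_size))
    x0, y0 = window.origin
    cx = x0 + (np.arange(nx) + 0.5) * cell_size
    cy = y0 + (np.arange(ny) + 0.5) * cell_size
    gx, gy = np.meshgrid(cx, cy)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    idx = np.argmin(cdist(centers, xy), axis=1)
    out = values[idx].reshape(ny, nx)
    return RasterSurface(values=out, cell_size=cell_size, origin=window.origin,
                         name=name)


# ---------------------------------------------------------------------------
# environmental PCA


@dataclass
class EnvironmentStack:
    """Aligned environmental surfaces and their orthogonal components.

    ``components[k]`` holds the k-th component score surface (standardised
    variables rotated onto the eigenvectors of the correlation matrix,
    ordered by explained variance).
    """

    surfaces: list[RasterSurface]
    components: list[RasterSurface]
    loadings: np.ndarray            # (n_vars, n_components)
    explained_variance: np.ndarray  # eigenvalues of the correlation matrix
    variable_names: list[str]

    @property
    def n_components(self) -> int:
        return len(self.components)

    def component_values_at(self, x, y) -> np.ndarray:
        """(n_points, n_components) matrix of component scores."""
        return np.column_stack([c.value_at(x, y) for c in self.components])

    def component_matrix(self) -> np.ndarray:
        """(n_cells, n_components) matrix over flattened grid cells."""
        return np.column_stack([c.values.ravel() for c in self.components])


def pca_environment(surfaces: list[RasterSurface]) -> EnvironmentStack:
    """Standardise the input surfaces over grid cells and rotate them to
    orthogonal components ordered by explained variance.

    Constant surfaces are dropped with a warning before rotation.
    """
    if not surfaces:
        raise ValueError("no surfaces supplied")
    shape = surfaces[0].shape
    for s in surfaces:
        if s.shape != shape or s.cell_size != surfaces[0].cell_size:
            raise ValueError("surfaces must share one grid")
    keep, names = [], []
    for s in surfaces:
        if np.std(s.values) < 1e-12:
            log.warning("dropping constant surface %r before PCA", s.name)
            continue
        keep.append(s)
        names.append(s.name)
    if not keep:
        raise ValueError("all surfaces are constant")
    mat = np.column_stack([s.values.ravel() for s in keep])
    std = (mat - mat.mean(axis=0)) / mat.std(axis=0)
    pca = PCA(n_components=std.shape[1], svd_solver="full")
    scores = pca.fit_transform(std)
    comps = []
    for k in range(scores.shape[1]):
        comps.append(RasterSurface(
            values=scores[:, k].reshape(shape),
            cell_size=keep[0].cell_size,
            origin=keep[0].origin,
            name=f"PC{k + 1}",
        ))
    # eigenvalues of the correlation matrix (population convention)
    explained = pca.explained_variance_ * (std.shape[0] - 1) / std.shape[0]
    return EnvironmentStack(
        surfaces=keep, components=comps, loadings=pca.components_.T,
        explained_variance=explained, variable_names=names,
    )
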