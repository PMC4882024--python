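"""Edge-corrected second-order summary statistics and Monte-Carlo inference.

Implements Ripley's K, the (inhomogeneous) pair correlation function with
Epanechnikov smoothing, pointwise rank envelopes and the scale-integrated
goodness-of-fit test with rank p-value ``(1 + #{u_sim >= u_obs}) / (n_sim+1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .plot_io import PlotWindow, PointPattern, RasterSurface

CORRECTIONS = ("none", "isotropic", "translation")

#: Stoyan's constant for the pair-correlation bandwidth rule 0.15 / sqrt(lambda).
STOYAN_C = 0.15


def default_r_grid(r_max: float, step: float = 0.5) -> np.ndarray:
    """Distance grid from 0 to r_max in fixed steps (default 0.5 m)."""
    n = int(round(r_max / step))
    return np.linspace(0.0, n * step, n + 1)


@dataclass
class SummaryCurve:
    r: np.ndarray
    values: np.ndarray
    statistic_name: str = "K"
    correction: str = "isotropic"

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.r.ndim != 1 or self.r.shape != self.values.shape:
            raise ValueError("r and values must be equal-length vectors")
        if self.r.size and (self.r[0] < 0 or np.any(np.diff(self.r) <= 0)):
            raise ValueError("r grid must be non-negative and strictly increasing")


@dataclass
class EnvelopeResult:
    observed: SummaryCurve
    lower: np.ndarray
    upper: np.ndarray
    n_sim: int
    level: float
    scale_range: tuple[float, float]
    exceeds_above: np.ndarray = field(default=None)
    significant: bool = False


@dataclass
class GofResult:
    u_obs: float
    u_sims: np.ndarray
    p_value: float
    range: tuple[float, float]


def _pair_geometry(pattern: PointPattern, d_max: float | None = None):
    """Condensed (i<j) pair distances and index arrays, optionally keeping
    only pairs closer than ``d_max`` (edge weights are costly per pair)."""
    coords = pattern.coords()
    d = pdist(coords)
    n = pattern.n
    ii, jj = np.triu_indices(n, k=1)
    if d_max is not None:
        keep = d <= d_max
        d, ii, jj = d[keep], ii[keep], jj[keep]
    return d, ii, jj


def ripley_disc_fraction(x, y, t, window: PlotWindow) -> np.ndarray:
    """Fraction of the circle of radius ``t`` centred at (x, y) inside a
    rectangular window (the reciprocal of Ripley's isotropic edge weight).

    Valid for radii small enough that an arc never crosses two opposite
    edges at once (t < min(extent)/2 is always safe; larger t is fine for
    points away from the boundary).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    t = np.asarray(t, float)
    (x0, x1), (y0, y1) = window.xrange, window.yrange
    with np.errstate(divide="ignore", invalid="ignore"):
        aL = np.arccos(np.clip(np.where(t > 0, (x - x0) / t, 2.0), -1, 1))
        aR = np.arccos(np.clip(np.where(t > 0, (x1 - x) / t, 2.0), -1, 1))
        aD = np.arccos(np.clip(np.where(t > 0, (y - y0) / t, 2.0), -1, 1))
        aU = np.arccos(np.clip(np.where(t > 0, (y1 - y) / t, 2.0), -1, 1))
    aL = np.where((x - x0) >= t, 0.0, aL)
    aR = np.where((x1 - x) >= t, 0.0, aR)
    aD = np.where((y - y0) >= t, 0.0, aD)
    aU = np.where((y1 - y) >= t, 0.0, aU)
    exterior = 2.0 * (aL + aR + aD + aU)
    t2 = t * t
    for ah, dh, av, dv in (
        (aL, x - x0, aD, y - y0),
        (aL, x - x0, aU, y1 - y),
        (aR, x1 - x, aD, y - y0),
        (aR, x1 - x, aU, y1 - y),
    ):
        corner = (dh * dh + dv * dv) < t2
        exterior = np.where(corner, exterior - (ah + av - np.pi / 2.0), exterior)
    frac = 1.0 - exterior / (2.0 * np.pi)
    return np.clip(frac, 1e-12, 1.0)


def _edge_weights(pattern: PointPattern, d, ii, jj, correction: str):
    """Ordered-pair edge-correction weights, returned as the pair of arrays
    (w_ij, w_ji) aligned with the condensed i<j ordering."""
    if correction not in CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}")
    if correction == "none":
        one = np.ones_like(d)
        return one, one
    w = pattern.window
    if correction == "translation":
        dx = np.abs(pattern.x[ii] - pattern.x[jj])
        dy = np.abs(pattern.y[ii] - pattern.y[jj])
        e = w.area / ((w.x_extent - dx) * (w.y_extent - dy))
        return e, e
    # isotropic: weight depends on which point is the circle centre
    e_ij = 1.0 / ripley_disc_fraction(pattern.x[ii], pattern.y[ii], d, w)
    e_ji = 1.0 / ripley_disc_fraction(pattern.x[jj], pattern.y[jj], d, w)
    return e_ij, e_ji


def ripley_K(pattern: PointPattern, r_grid, correction: str = "isotropic") -> SummaryCurve:
    """Edge-corrected estimator of Ripley's K.

    ``K(r) = |W| / (n (n-1)) * sum_{i != j} e_ij 1(d_ij <= r)``.
    """
    if pattern.n < 2:
        raise ValueError("ripley_K requires at least two points")
    r_grid = np.asarray(r_grid, dtype=float)
    d, ii, jj = _pair_geometry(pattern, d_max=float(r_grid[-1]))
    e_ij, e_ji = _edge_weights(pattern, d, ii, jj, correction)
    wsum = e_ij + e_ji  # both ordered directions of each unordered pair
    order = np.argsort(d)
    csum = np.concatenate([[0.0], np.cumsum(wsum[order])])
    idx = np.searchsorted(d[order], r_grid, side="right")
    k = pattern.window.area / (pattern.n * (pattern.n - 1)) * csum[idx]
    return SummaryCurve(r_grid, k, statistic_name="K", correction=correction)


def ripley_K_inhom(pattern: PointPattern, intensity: RasterSurface, r_grid,
                   correction: str = "isotropic") -> SummaryCurve:
    """Inhomogeneous K with pair contributions weighted by 1/(lambda_i lambda_j)."""
    if pattern.n < 2:
        raise ValueError("ripley_K_inhom requires at least two points")
    lam = _intensity_at_points(pattern, intensity)
    r_grid = np.asarray(r_grid, dtype=float)
    d, ii, jj = _pair_geometry(pattern, d_max=float(r_grid[-1]))
    e_ij, e_ji = _edge_weights(pattern, d, ii, jj, correction)
    wsum = (e_ij + e_ji) / (lam[ii] * lam[jj])
    order = np.argsort(d)
    csum = np.concatenate([[0.0], np.cumsum(wsum[order])])
    idx = np.searchsorted(d[order], r_grid, side="right")
    k = csum[idx] / pattern.window.area
    return SummaryCurve(r_grid, k, statistic_name="K_inhom", correction=correction)


def stoyan_bandwidth(pattern: PointPattern) -> float:
    return STOYAN_C / np.sqrt(pattern.intensity)


def _pcf_from_pairs(d, weights, r_grid, bandwidth, area, norm):
    """Shared kernel-smoothing core: Epanechnikov kernel of half-width
    ``bandwidth`` applied to the weighted pair-distance distribution."""
    r_grid = np.asarray(r_grid, dtype=float)
    g = np.zeros_like(r_grid)
    h = bandwidth
    order = np.argsort(d)
    ds = d[order]
    ws = weights[order]
    for k, r in enumerate(r_grid):
        lo, hi = np.searchsorted(ds, (r - h, r + h))
        if hi > lo:
            u = (r - ds[lo:hi]) / h
            g[k] = np.sum(ws[lo:hi] * 0.75 / h * (1.0 - u * u))
    # divide by the ring circumference; copy the first positive-r value to r=0
    with np.errstate(divide="ignore", invalid="ignore"):
        g = g / (2.0 * np.pi * r_grid * area * norm)
    if r_grid.size and r_grid[0] == 0.0:
        g[0] = g[1] if r_grid.size > 1 else 0.0
    return g


def pair_correlation(pattern: PointPattern, r_grid, correction: str = "isotropic",
                     bandwidth: float | None = None) -> SummaryCurve:
    """Kernel-smoothed pair correlation function, normalised so the CSR
    expectation is 1 (intensity estimated as n/|W|)."""
    if pattern.n < 2:
        raise ValueError("pair_correlation requires at least two points")
    if bandwidth is None:
        bandwidth = stoyan_bandwidth(pattern)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    d, ii, jj = _pair_geometry(pattern,
                               d_max=float(np.max(r_grid)) + bandwidth)
    e_ij, e_ji = _edge_weights(pattern, d, ii, jj, correction)
    lam = pattern.intensity
    g = _pcf_from_pairs(d, e_ij + e_ji, r_grid, bandwidth,
                        pattern.window.area, lam * lam)
    return SummaryCurve(np.asarray(r_grid, float), g, statistic_name="g",
                        correction=correction)


def _intensity_at_points(pattern: PointPattern, intensity: RasterSurface) -> np.ndarray:
    lam = intensity.value_at(pattern.x, pattern.y)
    bad = np.argwhere(lam <= 0).ravel()
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"non-positive intensity at data point {i} "
            f"({pattern.x[i]:.2f}, {pattern.y[i]:.2f})"
        )
    return lam


def pair_correlation_inhom(pattern: PointPattern, intensity: RasterSurface,
                           r_grid, correction: str = "isotropic",
                           bandwidth: float | None = None) -> SummaryCurve:
    """Inhomogeneous pair correlation: pair contributions weighted by
    ``1/(lambda(x_i) lambda(x_j))``. Reduces to :func:`pair_correlation`
    when the intensity surface is constant at n/|W|."""
    if pattern.n < 2:
        raise ValueError("pair_correlation_inhom requires at least two points")
    lam = _intensity_at_points(pattern, intensity)
    if bandwidth is None:
        bandwidth = stoyan_bandwidth(pattern)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    d, ii, jj = _pair_geometry(pattern,
                               d_max=float(np.max(r_grid)) + bandwidth)
    e_ij, e_ji = _edge_weights(pattern, d, ii, jj, correction)
    g = _pcf_from_pairs(d, (e_ij + e_ji) / (lam[ii] * lam[jj]), r_grid,
                        bandwidth, pattern.window.area, 1.0)
    return SummaryCurve(np.asarray(r_grid, float), g, statistic_name="g_inhom",
                        correction=correction)


def _range_mask(r: np.ndarray, scale_range) -> np.ndarray:
    lo, hi = scale_range
    mask = (r >= lo) & (r <= hi) & (r > 0)
    if not mask.any():
        raise ValueError(f"scale range {scale_range} covers no grid point")
    return mask


def _stack_sims(observed: SummaryCurve, simulated) -> np.ndarray:
    r = observed.r
    rows = []
    for c in simulated:
        if c.r.shape != r.shape or not np.allclose(c.r, r):
            raise ValueError("simulated curves must share the observed r grid")
        rows.append(c.values)
    return np.vstack(rows)


def envelope(observed: SummaryCurve, simulated: list[SummaryCurve],
             level: float = 0.95, scale_range: tuple[float, float] | None = None
             ) -> EnvelopeResult:
    """Pointwise rank envelope at the given two-sided level.

    With m = floor((n_sim + 1) * (1 - level) / 2), the bounds are the m-th
    lowest and m-th highest simulated values at each r (for 199 simulations
    at 95% this is the 5th lowest / 5th highest). ``significant`` is True
    when the observed curve lies strictly above the upper bound at any r in
    ``scale_range`` (one-sided, aggregation only).
    """
    sims = _stack_sims(observed, simulated)
    n_sim = sims.shape[0]
    m = int(np.floor((n_sim + 1) * (1.0 - level) / 2.0))
    if m < 1:
        raise ValueError(
            f"{n_sim} simulations are too few for a {level:.0%} rank envelope")
    sims_sorted = np.sort(sims, axis=0)
    lower = sims_sorted[m - 1]
    upper = sims_sorted[n_sim - m]
    r = observed.r
    if scale_range is None:
        scale_range = (float(r[0]), float(r[-1]))
    mask = _range_mask(r, scale_range)
    finite = np.isfinite(observed.values) & np.isfinite(upper)
    exceeds = (observed.values > upper) & mask & finite
    return EnvelopeResult(
        observed=observed, lower=lower, upper=upper, n_sim=n_sim, level=level,
        scale_range=tuple(scale_range), exceeds_above=exceeds,
        significant=bool(exceeds.any()),
    )


def gof_loosmore(observed: SummaryCurve, simulated: list[SummaryCurve],
                 r_range: tuple[float, float]) -> GofResult:
    """Scale-integrated squared-deviation test.

    For every curve i (observed and simulated alike),
    ``u_i = sum_r (H_i(r) - Hbar_{-i}(r))^2 dr`` where ``Hbar_{-i}`` is the
    mean of all other curves; the p-value is the rank of u_obs among the
    simulated u values.
    """
    if len(simulated) < 1:
        raise ValueError("gof_loosmore requires simulated curves")
    r = observed.r
    lo, hi = r_range
    if lo < r[0] - 1e-9 or hi > r[-1] + 1e-9:
        raise ValueError(f"gof range {r_range} extends beyond the r grid")
    mask = _range_mask(r, r_range)
    sims = _stack_sims(observed, simulated)
    all_curves = np.vstack([observed.values[None, :], sims])[:, mask]
    all_curves = np.nan_to_num(all_curves, nan=0.0)
    dr = np.gradient(r[mask])
    total = all_curves.sum(axis=0)
    m = all_curves.shape[0]
    u = np.empty(m)
    for i in range(m):
        others_mean = (total - all_curves[i]) / (m - 1)
        u[i] = np.sum((all_curves[i] - others_mean) ** 2 * dr)
    n_sim = m - 1
    p = (1.0 + np.sum(u[1:] >= u[0])) / (n_sim + 1.0)
    return GofResult(u_obs=float(u[0]), u_sims=u[1:], p_value=float(p),
                     range=(float(lo), float(hi)))


def curve_table(result: EnvelopeResult):
    """Envelope as a plain array table (r, observed, lower, upper, exceeds)."""
    import pandas as pd

    return pd.DataFrame({
        "r": result.observed.r,
        "observed": result.observed.values,
        "lower": result.lower,
        "upper": result.upper,
        "exceeds_above": result.exceeds_above.astype(int),
    })
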