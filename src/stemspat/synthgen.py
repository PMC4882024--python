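"""Synthetic forest-plot generator with a full ground-truth ledger.

Produces terrain (corner-post elevations plus analytic truth surfaces),
correlated soil sample tables, a disturbed-quadrat mask, and multi-species
multi-stage stem tables drawn from log-Gaussian Cox or inhomogeneous Thomas
mechanisms with stage-varying environmental coefficients and residual
clustering. Everything regenerates bit-identically from (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster_null import ThomasParams, simulate_thomas
from .joint_cox import MaternParams, simulate_gaussian_field
from .plot_io import PlotWindow, PointPattern, RasterSurface, StemTable
from .terrain import GRID_CELL, QUADRAT_SIZE

STAGES = ("sapling", "juvenile", "adult")
SYNDROMES = ("gravity-ballistic", "animal", "wind")

#: DBH intervals (cm) per growth form and stage; adults are open above so a
#: synthetic upper bound is used for mark generation only.
DBH_INTERVALS = {
    "canopy": {"sapling": (1.0, 5.0), "juvenile": (5.0, 15.0), "adult": (15.0, 40.0)},
    "subcanopy": {"sapling": (1.0, 2.5), "juvenile": (2.5, 5.0), "adult": (5.0, 15.0)},
    "shrub": {"sapling": (1.0, 1.5), "juvenile": (1.5, 2.5), "adult": (2.5, 8.0)},
}

TRUTH_VARIABLES = ("elevation", "convexity", "slope", "totalC", "totalN",
                   "totalP", "pH")


# ---------------------------------------------------------------------------
# terrain


@dataclass
class TerrainTruth:
    """Corner posts plus analytic truth surfaces on the 5-m grid."""

    posts: np.ndarray                 # (ny+1, nx+1) elevations at 20-m corners
    surfaces: dict[str, RasterSurface]  # elevation / convexity / slope at 5 m
    window: PlotWindow
    bumps: np.ndarray                 # (k, 4): cx, cy, width, amplitude
    z_offset: float
    z_scale: float

    def elevation_at(self, x, y):
        return _bump_field(np.asarray(x, float), np.asarray(y, float),
                           self.bumps) * self.z_scale + self.z_offset


def _bump_field(x, y, bumps):
    z = np.zeros(np.broadcast(x, y).shape, dtype=float)
    for cx, cy, w, a in bumps:
        z += a * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * w ** 2))
    return z


def _bump_gradient(x, y, bumps):
    gx = np.zeros(np.broadcast(x, y).shape, dtype=float)
    gy = np.zeros_like(gx)
    for cx, cy, w, a in bumps:
        e = a * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * w ** 2))
        gx += e * -(x - cx) / w ** 2
        gy += e * -(y - cy) / w ** 2
    return gx, gy


def _bump_laplacian(x, y, bumps):
    lap = np.zeros(np.broadcast(x, y).shape, dtype=float)
    for cx, cy, w, a in bumps:
        r2 = (x - cx) ** 2 + (y - cy) ** 2
        e = a * np.exp(-r2 / (2.0 * w ** 2))
        lap += e * (r2 / w ** 4 - 2.0 / w ** 2)
    return lap


def make_terrain(window: PlotWindow | None = None, relief: float = 300.0,
                 smoothness: float = 50.0, n_bumps: int = 40,
                 base_elevation: float = 300.0,
                 rng: np.random.Generator | int | None = None) -> TerrainTruth:
    """Smooth random topography from superposed Gaussian bumps, rescaled so
    the corner-post elevation span equals ``relief``.

    ``smoothness`` is the typical bump width (m); truth slope (degrees, from
    the analytic gradient) and truth convexity (negative scaled Laplacian)
    surfaces are evaluated on the 5-m grid for oracle checks.
    """
    window = window or PlotWindow()
    rng = np.random.default_rng(rng)
    (x0, x1), (y0, y1) = window.xrange, window.yrange
    bumps = np.column_stack([
        rng.uniform(x0, x1, n_bumps),
        rng.uniform(y0, y1, n_bumps),
        rng.uniform(0.6 * smoothness, 1.6 * smoothness, n_bumps),
        rng.uniform(-1.0, 1.0, n_bumps),
    ])
    nx = int(round(window.x_extent / QUADRAT_SIZE))
    ny = int(round(window.y_extent / QUADRAT_SIZE))
    px, py = np.meshgrid(x0 + np.arange(nx + 1) * QUADRAT_SIZE,
                         y0 + np.arange(ny + 1) * QUADRAT_SIZE)
    raw = _bump_field(px, py, bumps)
    span = raw.max() - raw.min()
    if relief == 0 or span == 0:
        z_scale = 0.0
        z_offset = base_elevation
    else:
        z_scale = relief / span
        z_offset = base_elevation - raw.min() * z_scale
    posts = raw * z_scale + z_offset

    ncx = int(round(window.x_extent / GRID_CELL))
    ncy = int(round(window.y_extent / GRID_CELL))
    cx = x0 + (np.arange(ncx) + 0.5) * GRID_CELL
    cy = y0 + (np.arange(ncy) + 0.5) * GRID_CELL
    gx, gy = np.meshgrid(cx, cy)
    elev = _bump_field(gx, gy, bumps) * z_scale + z_offset
    dzx, dzy = _bump_gradient(gx, gy, bumps)
    slope = np.degrees(np.arctan(np.hypot(dzx, dzy) * abs(z_scale)))
    # convexity truth: negative Laplacian scaled by the neighbourhood radius,
    # positive on crests and negative in hollows like the quadrat statistic
    conv = -_bump_laplacian(gx, gy, bumps) * z_scale * (QUADRAT_SIZE ** 2 / 8.0)
    surfaces = {
        "elevation": RasterSurface(elev, GRID_CELL, window.origin, "elevation"),
        "convexity": RasterSurface(conv, GRID_CELL, window.origin, "convexity"),
        "slope": RasterSurface(slope, GRID_CELL, window.origin, "slope"),
    }
    return TerrainTruth(posts=posts, surfaces=surfaces, window=window,
                        bumps=bumps, z_offset=z_offset, z_scale=z_scale)


# ---------------------------------------------------------------------------
# soils

SOIL_RANGES = {  # plausible output ranges for the affine rescaling
    "totalC": (8.0, 60.0),
    "totalN": (0.5, 4.0),
    "totalP": (0.1, 0.8),
    "pH": (4.4, 5.1),
}


@dataclass
class SoilTruth:
    samples: pd.DataFrame                  # x, y, totalC, totalN, totalP, pH
    surfaces: dict[str, RasterSurface]     # noiseless truth fields at 5 m


def make_soils(terrain: TerrainTruth,
               correlation_with_topo: dict[str, float] | None = None,
               nugget: float = 0.1, n_random: int = 800,
               rng: np.random.Generator | int | None = None) -> SoilTruth:
    """Soil fields as linear combinations of (standardised) elevation and a
    smooth independent noise field, sampled on a mixed regular/random design.

    ``correlation_with_topo`` maps each soil variable to the weight of the
    elevation component (|r| <= 1); ``nugget`` is the sd of white measurement
    noise added to samples, in units of the field's standardised scale.
    """
    rng = np.random.default_rng(rng)
    corr = {"totalC": 0.6, "totalN": 0.5, "totalP": -0.4, "pH": -0.6}
    corr.update(correlation_with_topo or {})
    window = terrain.window
    elev = terrain.surfaces["elevation"].values
    estd = ((elev - elev.mean()) / elev.std()) if elev.std() > 0 else np.zeros_like(elev)

    surfaces = {}
    fields_std = {}
    for var in ("totalC", "totalN", "totalP", "pH"):
        c = corr[var]
        if abs(c) > 1:
            raise ValueError("|correlation| must be <= 1")
        noise = make_terrain(window, relief=1.0, smoothness=40.0, n_bumps=25,
                             base_elevation=0.0, rng=rng).surfaces["elevation"].values
        nstd = ((noise - noise.mean()) / noise.std()) if noise.std() > 0 else noise
        f = c * estd + np.sqrt(max(0.0, 1.0 - c * c)) * nstd
        fields_std[var] = f
        lo, hi = SOIL_RANGES[var]
        span = f.max() - f.min()
        vals = (np.full_like(f, 0.5 * (lo + hi)) if span == 0
                else lo + (f - f.min()) / span * (hi - lo))
        surfaces[var] = RasterSurface(vals, GRID_CELL, window.origin, var)

    # regular 20-m sampling at quadrat centres plus random in-fill
    (x0, x1), (y0, y1) = window.xrange, window.yrange
    qx = np.arange(x0 + QUADRAT_SIZE / 2, x1, QUADRAT_SIZE)
    qy = np.arange(y0 + QUADRAT_SIZE / 2, y1, QUADRAT_SIZE)
    gx, gy = np.meshgrid(qx, qy)
    sx = np.concatenate([gx.ravel(), rng.uniform(x0, x1, n_random)])
    sy = np.concatenate([gy.ravel(), rng.uniform(y0, y1, n_random)])
    table = {"x": sx, "y": sy}
    for var in ("totalC", "totalN", "totalP", "pH"):
        surf = surfaces[var]
        vals = surf.value_at(sx, sy)
        lo, hi = SOIL_RANGES[var]
        scale = (hi - lo) / max(np.ptp(fields_std[var]), 1e-12)
        vals = vals + rng.normal(0.0, nugget * scale, vals.size)
        table[var] = np.clip(vals, lo, hi)
    return SoilTruth(samples=pd.DataFrame(table), surfaces=surfaces)


# ---------------------------------------------------------------------------
# species patterns


@dataclass
class StageTruth:
    abundance: float
    beta: np.ndarray                 # coefficients on the standardised truth covariates
    mechanism: str                   # "cox" or "thomas"
    matern: MaternParams | None = None
    thomas: ThomasParams | None = None
    true_pve: float = np.nan


@dataclass
class SpeciesConfig:
    code: str
    growth_form: str
    dispersal_syndrome: str
    stages: dict[str, StageTruth] = field(default_factory=dict)


def standardized_truth_stack(terrain: TerrainTruth, soils: SoilTruth
                             ) -> list[RasterSurface]:
    """The generator's seven true covariate surfaces, standardised over cells."""
    out = []
    named = dict(terrain.surfaces)
    named.update(soils.surfaces)
    for name in TRUTH_VARIABLES:
        v = named[name].values
        sd = v.std()
        z = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
        out.append(RasterSurface(z, GRID_CELL, terrain.window.origin, name))
    return out


def _env_predictor(covariates: list[RasterSurface], beta: np.ndarray) -> np.ndarray:
    pred = np.zeros(covariates[0].shape)
    for b, s in zip(beta, covariates):
        if b != 0.0:
            pred = pred + b * s.values
    return pred


def true_pve(covariates: list[RasterSurface], stage: StageTruth) -> float:
    """Ground-truth PVE on the log-intensity scale, using the same convention
    as the estimator's variance decomposition."""
    v_env = float(np.var(_env_predictor(covariates, stage.beta)))
    v_res = stage.matern.variance if stage.matern is not None else 0.0
    if stage.mechanism == "thomas" and stage.thomas is not None:
        # log-intensity variance proxy for a Thomas residual is not defined;
        # report NaN unless clustering is absent
        v_res = np.nan
    total = v_env + v_res
    return v_env / total if total > 0 else np.nan


def make_species_pattern(stage_truth: StageTruth,
                         covariates: list[RasterSurface],
                         window: PlotWindow,
                         rng: np.random.Generator | int | None = None
                         ) -> PointPattern:
    """Realise one species-stage pattern from its generative mechanism.

    ``cox``: log intensity = mu + H beta + D with D a unit-mean-corrected
    Matern Gaussian field; ``thomas``: a Thomas process thinned by the
    environmental surface exp(H beta) (habitat-independent when beta = 0).
    The intercept is solved so the expected count equals the configured
    abundance.
    """
    rng = np.random.default_rng(rng)
    cell = covariates[0].cell_size
    area = cell * cell
    pred = _env_predictor(covariates, stage_truth.beta)
    w = np.exp(pred)
    a = stage_truth.abundance

    if stage_truth.mechanism == "cox":
        lam0 = a / (w.sum() * area)
        lam = lam0 * w
        if stage_truth.matern is not None:
            d = simulate_gaussian_field(pred.shape, cell, stage_truth.matern, rng)
            lam = lam * np.exp(d - stage_truth.matern.variance / 2.0)
        counts = rng.poisson(lam * area)
        return _scatter_counts(counts, covariates[0], window, rng)

    if stage_truth.mechanism == "thomas":
        th = stage_truth.thomas
        pmax = w.max()
        accept_mean = w.mean() / pmax
        # inflate offspring count so the post-thinning expectation equals a
        target_lambda = a / window.area / accept_mean
        params = ThomasParams(kappa=th.kappa, sigma=th.sigma,
                              mu=target_lambda / th.kappa)
        pat = simulate_thomas(params, window, rng)
        if pat.n == 0:
            return pat
        p = covariates[0]  # any surface for the grid geometry
        iy, ix = p.cell_index(pat.x, pat.y)
        keep = rng.uniform(0.0, 1.0, pat.n) < (w[iy, ix] / pmax)
        return PointPattern(pat.x[keep], pat.y[keep], window)

    raise ValueError(f"unknown mechanism {stage_truth.mechanism!r}")


def _scatter_counts(counts, grid: RasterSurface, window: PlotWindow, rng):
    total = int(counts.sum())
    if total == 0:
        return PointPattern(np.empty(0), np.empty(0), window)
    cell = grid.cell_size
    iy, ix = np.nonzero(counts)
    reps = counts[iy, ix]
    x = np.repeat(grid.origin[0] + ix * cell, reps) + rng.uniform(0, cell, total)
    y = np.repeat(grid.origin[1] + iy * cell, reps) + rng.uniform(0, cell, total)
    (x0, x1), (y0, y1) = window.xrange, window.yrange
    x = np.clip(x, x0, np.nextafter(x1, x0))
    y = np.clip(y, y0, np.nextafter(y1, y0))
    return PointPattern(x, y, window)


# ---------------------------------------------------------------------------
# community


@dataclass
class SyntheticPlotBundle:
    window: PlotWindow
    terrain: TerrainTruth
    soils: SoilTruth
    disturbed_mask: set[tuple[int, int]]
    covariates: list[RasterSurface]
    stems: StemTable
    species: list[SpeciesConfig]
    syndromes: dict[str, str]
    seed: int

    def truth_ledger(self) -> dict:
        ledger = {"seed": self.seed, "species": {}}
        for cfg in self.species:
            entry = {"growth_form": cfg.growth_form,
                     "syndrome": cfg.dispersal_syndrome, "stages": {}}
            for st, t in cfg.stages.items():
                entry["stages"][st] = {
                    "abundance": t.abundance,
                    "beta": np.asarray(t.beta).tolist(),
                    "mechanism": t.mechanism,
                    "true_pve": None if np.isnan(t.true_pve) else t.true_pve,
                    "matern": (None if t.matern is None else
                               [t.matern.variance, t.matern.scale,
                                t.matern.smoothness]),
                    "thomas": (None if t.thomas is None else
                               [t.thomas.kappa, t.thomas.sigma, t.thomas.mu]),
                }
            ledger["species"][cfg.code] = entry
        return ledger

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from .plot_io import write_ascii_grid, write_stem_table

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        posts = RasterSurface(self.terrain.posts, QUADRAT_SIZE,
                              self.window.origin, "elevation_posts")
        paths["elevation_posts"] = outdir / "elevation_posts.asc"
        write_ascii_grid(posts, paths["elevation_posts"])
        paths["soil"] = outdir / "soil_samples.csv"
        self.soils.samples.to_csv(paths["soil"], index=False, float_format="%.6f")
        paths["stems"] = outdir / "stems.csv"
        write_stem_table(self.stems, paths["stems"])
        paths["disturbed"] = outdir / "disturbed_quadrats.csv"
        pd.DataFrame(sorted(self.disturbed_mask), columns=["ix", "iy"]).to_csv(
            paths["disturbed"], index=False)
        paths["syndromes"] = outdir / "dispersal_syndromes.csv"
        pd.DataFrame(sorted(self.syndromes.items()),
                     columns=["sp", "syndrome"]).to_csv(paths["syndromes"],
                                                        index=False)
        paths["truth"] = outdir / "truth_ledger.json"
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth_ledger(), fh, indent=2)
        return paths


STAGE_ENV_VARIANCE = {  # target variance of the predictor H(u) beta per stage
    "env_increasing": {"sapling": 0.05, "juvenile": 0.10, "adult": 0.55},
    "flat": {"sapling": 0.25, "juvenile": 0.25, "adult": 0.25},
}
STAGE_CLUSTER_VARIANCE = {  # Matern residual variance per stage
    "cluster_decreasing": {"sapling": 1.6, "juvenile": 0.9, "adult": 0.25},
    "flat": {"sapling": 0.8, "juvenile": 0.8, "adult": 0.8},
}

#: covariates that drive the habitat classes (directly or through strong
#: correlation); most species' preferences load on one of these so the
#: habitat-association machinery has something to find
CLASS_ALIGNED_COVARIATES = (0, 1, 6)  # elevation, convexity, pH


def make_community(n_species: int = 12,
                   stage_trend: tuple[str, ...] | None = ("env_increasing",
                                                          "cluster_decreasing"),
                   syndrome_mix: dict[str, int] | None = None,
                   window: PlotWindow | None = None,
                   abundance_range: tuple[float, float] = (250.0, 600.0),
                   env_variance_scale: float = 1.0,
                   seed: int | None = 0) -> SyntheticPlotBundle:
    """Build a full synthetic plot with known truth.

    With the default trends, the environmental predictor variance scales up
    and the residual-cluster variance scales down from sapling to adult, so
    true PVE increases with stage for every species. Each species prefers a
    single true covariate (usually one that shapes the habitat classes) and
    its coefficient is normalised so the realised predictor variance hits
    the stage target exactly. Wind-dispersed species get a larger Matern
    scale (bigger clusters) and a steeper stage-wise growth of the
    environmental variance. ``stage_trend=None`` (or an empty tuple) makes
    the stages exchangeable -- the negative control.
    """
    if n_species < 2:
        raise ValueError("need at least two species")
    window = window or PlotWindow()
    for extent in (window.x_extent, window.y_extent):
        if abs(extent / QUADRAT_SIZE - round(extent / QUADRAT_SIZE)) > 1e-9:
            raise ValueError("window extents must be multiples of the 20-m "
                             "quadrat size")
    rng = np.random.default_rng(seed)
    trends = set(stage_trend or ())
    env_key = "env_increasing" if "env_increasing" in trends else "flat"
    clu_key = "cluster_decreasing" if "cluster_decreasing" in trends else "flat"

    terrain = make_terrain(window, rng=rng)
    soils = make_soils(terrain, rng=rng)
    covariates = standardized_truth_stack(terrain, soils)

    # disturbed mask: a 3x3 block in the north-east corner
    nx = int(round(window.x_extent / QUADRAT_SIZE))
    ny = int(round(window.y_extent / QUADRAT_SIZE))
    disturbed = {(ix, iy) for ix in range(nx - 3, nx) for iy in range(ny - 3, ny)}

    if syndrome_mix is None:
        n_wind = max(1, round(n_species / 6))
        n_grav = max(1, round(n_species / 6))
        syndrome_mix = {"animal": n_species - n_wind - n_grav,
                        "wind": n_wind, "gravity-ballistic": n_grav}
    syn_list = [s for s, k in syndrome_mix.items() for _ in range(k)]
    if len(syn_list) != n_species:
        raise ValueError("syndrome_mix must sum to n_species")
    growth_forms = ["canopy", "subcanopy", "shrub"]

    species: list[SpeciesConfig] = []
    rows = []
    syndromes: dict[str, str] = {}
    tag = 1
    for i in range(n_species):
        code = f"SP{i + 1:02d}"
        gf = growth_forms[i % 3]
        syn = syn_list[i]
        syndromes[code] = syn
        # habitat preference: a single true covariate, usually one of the
        # class-shaping ones, with random sign
        if rng.uniform() < 0.75:
            pick = int(rng.choice(CLASS_ALIGNED_COVARIATES))
        else:
            pick = int(rng.integers(len(TRUTH_VARIABLES)))
        direction = np.zeros(len(TRUTH_VARIABLES))
        direction[pick] = rng.choice([-1.0, 1.0])
        pred_var = float(np.var(_env_predictor(covariates, direction)))
        wind_boost = 1.2 if syn == "wind" else 1.0
        matern_scale = rng.uniform(18.0, 30.0) if syn == "wind" else rng.uniform(6.0, 14.0)
        abundance = rng.uniform(*abundance_range)

        cfg = SpeciesConfig(code=code, growth_form=gf, dispersal_syndrome=syn)
        for s_idx, st in enumerate(STAGES):
            v_env = env_variance_scale * STAGE_ENV_VARIANCE[env_key][st]
            if env_key == "env_increasing":
                v_env *= wind_boost ** s_idx
            beta = np.sqrt(v_env / max(pred_var, 1e-12)) * direction
            var = STAGE_CLUSTER_VARIANCE[clu_key][st]
            mat = MaternParams(variance=var, scale=matern_scale, smoothness=0.5)
            truth = StageTruth(abundance=abundance, beta=beta, mechanism="cox",
                               matern=mat)
            truth.true_pve = true_pve(covariates, truth)
            cfg.stages[st] = truth
            pat = make_species_pattern(truth, covariates, window, rng)
            lo, hi = DBH_INTERVALS[gf][st]
            dbh = rng.uniform(lo, hi, pat.n)
            for x, y, d in zip(pat.x, pat.y, dbh):
                rows.append({"tag": f"T{tag:06d}", "sp": code, "gf": gf,
                             "gx": x, "gy": y, "dbh": d})
                tag += 1
        species.append(cfg)

    data = pd.DataFrame(rows, columns=["tag", "sp", "gf", "gx", "gy", "dbh"])
    stems = StemTable(data=data, window=window)
    return SyntheticPlotBundle(
        window=window, terrain=terrain, soils=soils, disturbed_mask=disturbed,
        covariates=covariates, stems=stems, species=species,
        syndromes=syndromes, seed=seed if seed is not None else -1,
    )
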