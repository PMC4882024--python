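"""Benchmark routines that measure the package's statistical behaviour on
synthetic data with known truth: estimator calibration, parameter recovery,
test operating characteristics, and the end-to-end stage-trend experiment.

Each function regenerates its own inputs from a seed and returns a flat dict
of measured quantities; the acceptance test suite asserts on these numbers
and ``scripts/acceptance.py`` reports them.
"""

from __future__ import annotations

import numpy as np

from .cluster_null import (
    ThomasParams, fit_thomas, habitat_association_test, simulate_csr,
    simulate_thomas,
)
from .inhom_null import (
    LogLinearIntensityModel, dispersal_limitation_test, simulate_ipp,
)
from .joint_cox import (
    CoxModel, MaternParams, select_cox_model, simulate_cox,
    variance_decomposition,
)
from .pipeline import (
    AnalysisConfig, build_environment, build_habitat_map, run_full_analysis,
)
from .plot_io import PlotWindow, PointPattern, RasterSurface
from .sumstats import ripley_K
from .synthgen import make_community, make_soils, make_terrain, standardized_truth_stack
from .terrain import pca_environment


def _rng(seed):
    return np.random.default_rng(seed)


def brute_force_K_none(pattern: PointPattern, r_grid) -> np.ndarray:
    """Vectorised but independent O(n^2) oracle for the uncorrected K:
    full distance matrix, direct pair counting per r."""
    dx = pattern.x[:, None] - pattern.x[None, :]
    dy = pattern.y[:, None] - pattern.y[None, :]
    d = np.sqrt(dx * dx + dy * dy)
    np.fill_diagonal(d, np.inf)
    n = pattern.n
    return np.array([
        pattern.window.area / (n * (n - 1)) * np.sum(d <= r) for r in r_grid])


def oracle_equivalence(seed: int = 0, n_patterns: int = 50) -> dict:
    """Criterion 1: K with no correction vs brute-force pair counting."""
    rng = _rng(seed)
    w = PlotWindow(100, 100)
    worst = 0.0
    for _ in range(n_patterns):
        n = int(rng.integers(10, 201))
        p = simulate_csr(n, w, rng)
        r = np.linspace(0, 30, 13)
        fast = ripley_K(p, r, correction="none").values
        slow = brute_force_K_none(p, r)
        worst = max(worst, float(np.max(np.abs(fast - slow))))
    return {"n_patterns": n_patterns, "max_abs_difference": worst}


def csr_calibration(seed: int = 0, n_rep_k: int = 200,
                    n_rep_env: int = 400, n_sim_env: int = 199) -> dict:
    """Criterion 2: mean isotropic K(10) under CSR, and the one-sided
    envelope exceedance rate at a fixed r."""
    rng = _rng(seed)
    w = PlotWindow(100, 100)
    kvals = [ripley_K(simulate_csr(500, w, rng), [0.0, 10.0]).values[1]
             for _ in range(n_rep_k)]
    mean_k = float(np.mean(kvals))

    # envelope exceedance at r = 10, n = 100 per pattern
    m = int(np.floor((n_sim_env + 1) * 0.025))
    hits = 0
    for _ in range(n_rep_env):
        obs = ripley_K(simulate_csr(100, w, rng), [0.0, 10.0]).values[1]
        sims = np.sort([
            ripley_K(simulate_csr(100, w, rng), [0.0, 10.0]).values[1]
            for _ in range(n_sim_env)])
        hits += obs > sims[n_sim_env - m]
    return {
        "mean_K10": mean_k,
        "target_K10": float(np.pi * 100),
        "relative_error_K10": abs(mean_k - np.pi * 100) / (np.pi * 100),
        "exceedance_rate": hits / n_rep_env,
        "nominal_rate": m / (n_sim_env + 1),
        "n_rep_env": n_rep_env,
    }


def thomas_recovery(seed: int = 0, n_rep: int = 20) -> dict:
    """Criterion 3: minimum-contrast recovery of kappa and sigma at E[n]=800."""
    rng = _rng(seed)
    true = ThomasParams(kappa=5e-4, sigma=5.0, mu=10.0)
    w = PlotWindow(400, 400)
    err_k, err_s = [], []
    for _ in range(n_rep):
        p = simulate_thomas(true, w, rng)
        f = fit_thomas(p)
        err_k.append(abs(f.kappa - true.kappa) / true.kappa)
        err_s.append(abs(f.sigma - true.sigma) / true.sigma)
    return {
        "median_rel_err_kappa": float(np.median(err_k)),
        "median_rel_err_sigma": float(np.median(err_s)),
        "n_rep": n_rep,
    }


def _test_habitat_setup(seed: int):
    w = PlotWindow(240, 240)
    rng = _rng(seed)
    terrain = make_terrain(w, rng=rng)
    from .terrain import classify_habitats, quadrat_topography

    hmap = classify_habitats(quadrat_topography(terrain.posts))
    return w, hmap


def association_operating_characteristics(seed: int = 0, n_rep_null: int = 200,
                                          n_rep_power: int = 100,
                                          n_sim: int = 199) -> dict:
    """Criterion 4: per-habitat type-I rate under a habitat-independent
    Thomas null, and power when one habitat's intensity is tripled."""
    w, hmap = _test_habitat_setup(seed)
    rng = _rng(seed + 1)
    params = ThomasParams(kappa=1.2e-3, sigma=5.0, mu=6.0)

    false_pos = 0
    tests = 0
    for _ in range(n_rep_null):
        p = simulate_thomas(params, w, rng)
        if p.n < 30:
            continue
        res = habitat_association_test(p, hmap, n_sim=n_sim, rng=rng)
        if not res.testable:
            continue
        false_pos += sum(v == "positive" for v in res.classification.values())
        tests += len(res.classification)

    # power: thin a 3x-intensity Thomas pattern so one habitat keeps all its
    # points and the others keep a third
    target = max(hmap.counts(), key=lambda h: hmap.counts()[h])
    power_hits = 0
    power_tests = 0
    for _ in range(n_rep_power):
        dense = simulate_thomas(
            ThomasParams(params.kappa * 3, params.sigma, params.mu), w, rng)
        labels = hmap.label_at(dense.x, dense.y)
        keep = (labels == target) | (rng.uniform(size=dense.n) < 1 / 3)
        p = PointPattern(dense.x[keep], dense.y[keep], w)
        res = habitat_association_test(p, hmap, n_sim=n_sim, rng=rng)
        if not res.testable:
            continue
        power_tests += 1
        power_hits += res.classification.get(target) == "positive"
    return {
        "type1_rate": false_pos / max(tests, 1),
        "n_null_tests": tests,
        "power": power_hits / max(power_tests, 1),
        "n_power_tests": power_tests,
        "tripled_habitat": target,
    }


def _env_for(seed: int, window: PlotWindow):
    rng = _rng(seed)
    terrain = make_terrain(window, rng=rng)
    soils = make_soils(terrain, n_random=300, rng=rng)
    return pca_environment(standardized_truth_stack(terrain, soils))


def _lgcp_truth(env, window, beta, variance, scale, expected_n):
    pc1 = env.components[0].values
    lam = np.exp(beta * pc1)
    lam *= expected_n / (lam.sum() * env.components[0].cell_size ** 2)
    surf = RasterSurface(lam, env.components[0].cell_size,
                         env.components[0].origin, "lam")
    im = LogLinearIntensityModel(
        intercept=float(np.log(lam.mean())), coefficients=np.array([beta]),
        terms=[(0, 1)], surface=surf, window=window)
    matern = MaternParams(variance, scale, 0.5) if variance > 0 else None
    return CoxModel(im, matern)


def dispersal_operating_characteristics(seed: int = 0, n_rep: int = 100,
                                        n_sim: int = 99) -> dict:
    """Criterion 5: envelope flag rate and GoF rejection rate on
    heterogeneous-Poisson data, and flag rate on trend-plus-cluster data."""
    w = PlotWindow(240, 240)
    env = _env_for(seed, w)
    rng = _rng(seed + 1)
    null_model = _lgcp_truth(env, w, beta=0.6, variance=0.0, scale=10.0,
                             expected_n=300.0)

    null_flags = 0
    gof_rejects = 0
    for _ in range(n_rep):
        p = simulate_ipp(null_model.intensity_model, rng)
        res = dispersal_limitation_test(p, env, n_sim=n_sim, rng=rng)
        null_flags += res.flagged
        gof_rejects += res.gof.p_value <= 0.05

    alt_model = _lgcp_truth(env, w, beta=0.6, variance=1.5, scale=6.0,
                            expected_n=350.0)
    alt_flags = 0
    for _ in range(n_rep):
        p = simulate_cox(alt_model, rng)
        res = dispersal_limitation_test(p, env, n_sim=n_sim, rng=rng)
        alt_flags += res.flagged
    return {
        "null_flag_rate": null_flags / n_rep,
        "null_gof_reject_rate": gof_rejects / n_rep,
        "power_flag_rate": alt_flags / n_rep,
        "n_rep": n_rep,
    }


def pve_recovery(seed: int = 0, n_rep: int = 20, n_sim_select: int = 39) -> dict:
    """Criterion 6: PVE estimation error at true PVE 0.2 and 0.6, plus the
    paired ordering rate."""
    w = PlotWindow(240, 240)
    env = _env_for(seed, w)
    rng = _rng(seed + 1)
    pc1_var = float(np.var(env.components[0].values))

    estimates = {}
    for target in (0.2, 0.6):
        variance = 1.0
        beta = float(np.sqrt(target / (1 - target) * variance / pc1_var))
        truth = _lgcp_truth(env, w, beta=beta, variance=variance, scale=10.0,
                            expected_n=600.0)
        vals = []
        for _ in range(n_rep):
            p = simulate_cox(truth, rng)
            model = select_cox_model(p, env, n_sim=n_sim_select, rng=rng,
                                     criterion="bic")
            try:
                vals.append(variance_decomposition(model, env).pve)
            except ValueError:
                vals.append(np.nan)
        estimates[target] = np.array(vals)

    mae = {t: float(np.nanmedian(np.abs(v - t))) for t, v in estimates.items()}
    a, b = estimates[0.2], estimates[0.6]
    ok = ~np.isnan(a) & ~np.isnan(b)
    ordering = float(np.mean(b[ok] > a[ok])) if ok.any() else np.nan
    return {
        "mae_pve_02": mae[0.2],
        "mae_pve_06": mae[0.6],
        "median_pve_02": float(np.nanmedian(a)),
        "median_pve_06": float(np.nanmedian(b)),
        "ordering_rate": ordering,
        "n_rep": n_rep,
    }


E2E_CONFIG = AnalysisConfig(assoc_n_sim=199, disp_n_sim=49, cox_n_sim=19,
                            screen_n_sim=39)


def _stage_trends(stage_table) -> dict:
    t = stage_table.set_index("stage")
    ha = [t.loc[s, "pct_habitat_associated"] for s in ("sapling", "juvenile",
                                                       "adult")]
    dl = [t.loc[s, "pct_dispersal_limited"] for s in ("sapling", "juvenile",
                                                      "adult")]
    pv = [t.loc[s, "mean_pve"] for s in ("sapling", "juvenile", "adult")]
    return {
        "assoc_nondecreasing": ha[0] <= ha[1] + 1e-9 and ha[1] <= ha[2] + 1e-9,
        "dispersal_nonincreasing": dl[0] >= dl[1] - 1e-9 and dl[1] >= dl[2] - 1e-9,
        "pve_increasing": pv[0] < pv[1] < pv[2],
        "pct_habitat_associated": ha,
        "pct_dispersal_limited": dl,
        "mean_pve": pv,
    }


def run_community(seed: int, trend: bool, config: AnalysisConfig = E2E_CONFIG,
                  n_species: int = 12, env_cache: dict | None = None) -> dict:
    """One full pipeline run on a synthetic community; returns trend flags
    and the stage summary numbers."""
    trends = ("env_increasing", "cluster_decreasing") if trend else None
    bundle = make_community(n_species=n_species, stage_trend=trends, seed=seed)
    if env_cache is not None and seed in env_cache:
        env, hmap = env_cache[seed]
    else:
        env, topo = build_environment(bundle.terrain.posts,
                                      bundle.soils.samples, bundle.window)
        hmap = build_habitat_map(topo, bundle.disturbed_mask, config)
        if env_cache is not None:
            env_cache[seed] = (env, hmap)
    summary = run_full_analysis(bundle.stems, env, hmap, bundle.syndromes,
                                config, seed=seed)
    out = _stage_trends(summary.stage_table)
    out["n_exceptions"] = len(summary.exceptions)
    out["all_trends"] = (out["assoc_nondecreasing"]
                         and out["dispersal_nonincreasing"]
                         and out["pve_increasing"])
    return out


def stage_trend_experiment(seed: int = 0, n_seeds: int = 10,
                           config: AnalysisConfig = E2E_CONFIG) -> dict:
    """Criterion 7: trend reproduction over master seeds, with the
    exchangeable-stage community as negative control.

    The terrain and soils only depend on the seed, so the kriged environment
    is shared between the trend and control run of each seed.
    """
    cache: dict = {}
    trend_hits = 0
    control_hits = 0
    details = []
    for k in range(n_seeds):
        s = seed * 1000 + k
        t = run_community(s, trend=True, config=config, env_cache=cache)
        c = run_community(s, trend=False, config=config, env_cache=cache)
        trend_hits += t["all_trends"]
        control_hits += c["all_trends"]
        details.append({"seed": s, "trend": t, "control": c})
    return {
        "trend_pass_count": trend_hits,
        "control_pass_count": control_hits,
        "n_seeds": n_seeds,
        "details": details,
    }
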