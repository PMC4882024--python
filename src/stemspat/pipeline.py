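"""Orchestration: life-stage assignment, species selection, the three
analyses per species and stage, and community-level aggregation.

Reproducibility: one master seed; every species x stage x analysis draws its
random stream from a deterministically derived ``numpy.random.SeedSequence``
child, so a full run is bit-for-bit repeatable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cluster_null import csr_aggregation_screen, habitat_association_test
from .inhom_null import dispersal_limitation_test, stepwise_select
from .joint_cox import pve_increments, select_cox_model, variance_decomposition
from .plot_io import PlotWindow, StemTable
from .terrain import (
    EnvironmentStack, HabitatMap, classify_habitats, empirical_semivariogram,
    fit_variogram, krige_block, pca_environment, quadrat_topography,
    QUADRAT_SIZE,
)

log = logging.getLogger(__name__)

STAGES = ("sapling", "juvenile", "adult")
PROCESS_CLASSES = ("environment_only", "dispersal_only", "both", "neither")

ANALYSES = ("assoc", "dispersal", "cox")


@dataclass(frozen=True)
class LifeStageScheme:
    """Half-open DBH intervals (cm) per growth form; the adult class is open
    above, so the stored upper bound is +inf. Intervals partition [1, inf)."""

    breaks: dict = field(default_factory=lambda: {
        "canopy": (1.0, 5.0, 15.0),
        "subcanopy": (1.0, 2.5, 5.0),
        "shrub": (1.0, 1.5, 2.5),
    })

    def intervals(self, growth_form: str) -> dict[str, tuple[float, float]]:
        if growth_form not in self.breaks:
            raise KeyError(f"unknown growth form {growth_form!r}")
        b = self.breaks[growth_form]
        return {"sapling": (b[0], b[1]), "juvenile": (b[1], b[2]),
                "adult": (b[2], np.inf)}


def assign_life_stage(growth_form: str, dbh, scheme: LifeStageScheme | None = None):
    """Stage label(s) by half-open interval lookup; vectorised over dbh."""
    scheme = scheme or LifeStageScheme()
    if growth_form not in scheme.breaks:
        raise KeyError(f"unknown growth form {growth_form!r}")
    b = scheme.breaks[growth_form]
    d = np.asarray(dbh, dtype=float)
    if np.any(d < b[0]):
        raise ValueError(f"dbh below the census minimum {b[0]}")
    out = np.where(d >= b[2], "adult", np.where(d >= b[1], "juvenile", "sapling"))
    return out.item() if out.ndim == 0 else out


def stage_stems(stems: StemTable, scheme: LifeStageScheme | None = None) -> pd.DataFrame:
    """Stem table with a ``stage`` column appended."""
    scheme = scheme or LifeStageScheme()
    df = stems.data.copy()
    stage = np.empty(len(df), dtype=object)
    for gf in df["gf"].unique():
        sel = df["gf"] == gf
        stage[sel.to_numpy()] = assign_life_stage(gf, df.loc[sel, "dbh"].to_numpy(),
                                                  scheme)
    df["stage"] = stage
    return df


@dataclass
class AnalysisConfig:
    """Tuning knobs; the defaults are the published protocol values."""

    assoc_n_sim: int = 999
    assoc_level: float = 0.99
    disp_n_sim: int = 199
    disp_level: float = 0.95
    disp_scale_range: tuple[float, float] = (0.0, 20.0)
    screen_n_sim: int = 199
    screen_range: tuple[float, float] = (0.0, 30.0)
    cox_n_sim: int = 39
    cox_gof_range: tuple[float, float] = (0.5, 20.0)
    fit_r_max: float = 100.0
    assoc_fit_r_max: float = 25.0
    cox_fit_r_max: float = 50.0
    stepwise_criterion: str = "aic"
    r_step: float = 0.5
    min_n: int = 40
    convexity_breaks: tuple[float, float] = (-2.0, 2.0)
    elevation_break: float = 450.0
    check_cox_adequacy: bool = False
    correction: str = "isotropic"

    def to_dict(self) -> dict:
        return asdict(self)


def build_environment(posts: np.ndarray, soil_samples: pd.DataFrame,
                      window: PlotWindow) -> tuple[EnvironmentStack, pd.DataFrame]:
    """From raw inputs to the orthogonal-component stack.

    The three quadrat topographic variables and the four soil variables are
    all interpolated to the 5-m grid by ordinary block kriging with a WLS-
    fitted exponential variogram, then standardised and rotated by PCA.
    Returns (stack, quadrat topography table).
    """
    topo = quadrat_topography(posts)
    qx = (topo["ix"].to_numpy() + 0.5) * QUADRAT_SIZE + window.origin[0]
    qy = (topo["iy"].to_numpy() + 0.5) * QUADRAT_SIZE + window.origin[1]
    lags = np.linspace(0.0, min(window.x_extent, window.y_extent) / 2.0, 13)
    surfaces = []
    for name, xy, vals in (
        [(v, np.column_stack([qx, qy]), topo[v].to_numpy())
         for v in ("mean_elev", "convexity", "slope")]
        + [(v, soil_samples[["x", "y"]].to_numpy(), soil_samples[v].to_numpy())
           for v in ("totalC", "totalN", "totalP", "pH")]
    ):
        emp = empirical_semivariogram(xy, vals, lags)
        model = fit_variogram(emp)
        surfaces.append(krige_block(xy, vals, model, window, name=name))
    return pca_environment(surfaces), topo


def build_habitat_map(topo: pd.DataFrame, disturbed_mask=None,
                      config: AnalysisConfig | None = None) -> HabitatMap:
    config = config or AnalysisConfig()
    return classify_habitats(topo, disturbed_mask,
                             convexity_breaks=config.convexity_breaks,
                             elevation_break=config.elevation_break)


def select_species(stems: StemTable, config: AnalysisConfig | None = None,
                   scheme: LifeStageScheme | None = None,
                   rng: np.random.Generator | int | None = None,
                   staged: pd.DataFrame | None = None) -> list[str]:
    """Species with more than ``min_n`` individuals in *every* stage that
    also pass the CSR aggregation screen in every stage."""
    config = config or AnalysisConfig()
    rng = np.random.default_rng(rng)
    if staged is None:
        staged = stage_stems(stems, scheme)
    selected = []
    for sp in sorted(staged["sp"].unique()):
        sub = staged[staged["sp"] == sp]
        counts = sub.groupby("stage")["sp"].count()
        if any(counts.get(st, 0) <= config.min_n for st in STAGES):
            continue
        ok = True
        for st in STAGES:
            pat = _pattern_of(sub[sub["stage"] == st], stems.window)
            if not csr_aggregation_screen(
                    pat, n_sim=config.screen_n_sim, r_range=config.screen_range,
                    r_step=config.r_step, correction=config.correction, rng=rng):
                ok = False
                break
        if ok:
            selected.append(sp)
    return selected


def _pattern_of(df: pd.DataFrame, window: PlotWindow):
    from .plot_io import PointPattern

    return PointPattern(df["gx"].to_numpy(), df["gy"].to_numpy(), window)


def classify_process_combination(h_selected: bool, d_retained: bool) -> str:
    """Exclusive four-way class from the Cox-model flags."""
    if h_selected and d_retained:
        return "both"
    if h_selected:
        return "environment_only"
    if d_retained:
        return "dispersal_only"
    return "neither"


def _child_rng(master_seed: int, sp_idx: int, stage_idx: int, analysis: str):
    a_idx = ANALYSES.index(analysis)
    ss = np.random.SeedSequence([int(master_seed), sp_idx, stage_idx, a_idx])
    return np.random.default_rng(ss)


@dataclass
class StageSummary:
    """Per-species records plus community-level aggregates per stage."""

    species_table: pd.DataFrame
    stage_table: pd.DataFrame
    by_scale: pd.DataFrame              # dispersal-limitation flags per r
    increments: pd.DataFrame
    exceptions: list[dict]
    config: AnalysisConfig
    seed: int
    selected_species: list[str]


def run_full_analysis(stems: StemTable, env: EnvironmentStack,
                      habitat_map: HabitatMap, syndromes: dict[str, str],
                      config: AnalysisConfig | None = None, seed: int = 0,
                      scheme: LifeStageScheme | None = None,
                      species: list[str] | None = None) -> StageSummary:
    """Run all three analyses for every selected species and stage and
    aggregate to the community level.

    Per-species failures are quarantined into ``StageSummary.exceptions``
    and the run continues.
    """
    config = config or AnalysisConfig()
    scheme = scheme or LifeStageScheme()
    staged = stage_stems(stems, scheme)
    if species is None:
        species = select_species(stems, config, scheme,
                                 rng=np.random.default_rng(
                                     np.random.SeedSequence([seed, 971])),
                                 staged=staged)
    rows = []
    scale_rows = []
    exceptions = []
    sp_order = sorted(staged["sp"].unique())
    for sp in species:
        sp_idx = sp_order.index(sp)
        for stage_idx, st in enumerate(STAGES):
            sub = staged[(staged["sp"] == sp) & (staged["stage"] == st)]
            pat = _pattern_of(sub, stems.window)
            rec = {"sp": sp, "stage": st, "n": pat.n,
                   "syndrome": syndromes.get(sp, "unknown")}
            try:
                assoc = habitat_association_test(
                    pat, habitat_map, n_sim=config.assoc_n_sim,
                    level=config.assoc_level, r_max=config.assoc_fit_r_max,
                    r_step=config.r_step,
                    rng=_child_rng(seed, sp_idx, stage_idx, "assoc"))
                rec["habitat_associated"] = assoc.any_positive
                rec["positive_habitats"] = ";".join(
                    h for h, c in assoc.classification.items() if c == "positive")
                rec["assoc_testable"] = assoc.testable

                disp_model = stepwise_select(
                    pat, env, criterion=config.stepwise_criterion)
                disp = dispersal_limitation_test(
                    pat, env, n_sim=config.disp_n_sim, level=config.disp_level,
                    scale_range=config.disp_scale_range, model=disp_model,
                    r_step=config.r_step, correction=config.correction,
                    rng=_child_rng(seed, sp_idx, stage_idx, "dispersal"))
                rec["dispersal_limited"] = disp.flagged
                rec["disp_gof_p"] = disp.gof.p_value
                r = disp.envelope.observed.r
                for rr, ex in zip(r, disp.envelope.exceeds_above):
                    scale_rows.append({"sp": sp, "stage": st, "r": float(rr),
                                       "exceeds": bool(ex)})

                cox = select_cox_model(
                    pat, env, n_sim=config.cox_n_sim,
                    gof_range=config.cox_gof_range, r_max=config.cox_fit_r_max,
                    r_step=config.r_step, correction=config.correction,
                    check_adequacy=config.check_cox_adequacy, step1=disp_model,
                    rng=_child_rng(seed, sp_idx, stage_idx, "cox"))
                rec["h_selected"] = cox.h_selected
                rec["d_retained"] = cox.d_retained
                rec["process_class"] = classify_process_combination(
                    cox.h_selected, cox.d_retained)
                try:
                    dec = variance_decomposition(cox, env)
                    rec["pve"], rec["pvd"] = dec.pve, dec.pvd
                except ValueError:
                    rec["pve"] = rec["pvd"] = np.nan
            except Exception as exc:  # quarantine, keep going
                log.exception("analysis failed for %s/%s", sp, st)
                exceptions.append({"sp": sp, "stage": st, "error": str(exc)})
                continue
            rows.append(rec)

    species_table = pd.DataFrame(rows)
    stage_table = aggregate_stages(species_table)
    by_scale = _aggregate_scales(pd.DataFrame(scale_rows))
    if not species_table.empty:
        inc = pve_increments(species_table[["sp", "stage", "pve"]].dropna(),
                             list(STAGES), syndromes)
    else:
        inc = pd.DataFrame(columns=["sp", "syndrome", "from_stage", "to_stage",
                                    "delta_pve"])
    return StageSummary(species_table=species_table, stage_table=stage_table,
                        by_scale=by_scale, increments=inc,
                        exceptions=exceptions, config=config, seed=seed,
                        selected_species=list(species))


def aggregate_stages(species_table: pd.DataFrame) -> pd.DataFrame:
    """Community percentages per stage; recomputable from the species table
    (the consistency invariant checked in the test suite)."""
    rows = []
    for st in STAGES:
        sub = species_table[species_table["stage"] == st] if not species_table.empty \
            else species_table
        n = len(sub)
        row = {"stage": st, "n_species": n}
        if n == 0:
            rows.append(row)
            continue
        row["pct_habitat_associated"] = 100.0 * sub["habitat_associated"].mean()
        row["pct_dispersal_limited"] = 100.0 * sub["dispersal_limited"].mean()
        for cls in PROCESS_CLASSES:
            row[f"pct_{cls}"] = 100.0 * (sub["process_class"] == cls).mean()
        row["mean_pve"] = float(sub["pve"].mean(skipna=True))
        rows.append(row)
    return pd.DataFrame(rows)


def _aggregate_scales(scale_rows: pd.DataFrame) -> pd.DataFrame:
    if scale_rows.empty:
        return pd.DataFrame(columns=["stage", "r", "pct_exceeding"])
    g = (scale_rows.groupby(["stage", "r"])["exceeds"].mean() * 100.0)
    return g.rename("pct_exceeding").reset_index()
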