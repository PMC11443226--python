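"""Season orchestration: the daily loop over days 91-242.

Each simulated day executes five subprocesses in fixed order:

1. update the sky radiation model (CSRM daily radiation -> 72+1 source dome
   at daylight-mean intensity),
2. compute per-leaf light interception and the coupled leaf gas exchange,
3. run the per-plant source-sink allocation and respiration charges,
4. apply the morphology rules (organ initiation by phenology, length
   advance, geometry refresh from new biomass),
5. append the day's output records.

Organ state is held in flat arrays (one row per organ over all plants) so
the whole loop is vectorized; organ objects are a construction scaffold and
are synchronized at the end of a run.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import morphology as morph
from .canopy_light import LightResult, OpticalProps, SceneGeometry, TracerConfig, intercept
from .leaf_physiology import PhotosynthesisParams, coupled_leaf_flux
from .morphology import (
    LeafArchParams,
    PhenologySchedule,
    Plant,
    PlantLayout,
    beta_growth_cumulative_arrays,
    build_leaf_geometry_batch,
    build_scene,
    default_schedule,
    init_plant,
)
from .source_sink import (
    FreshWeightFactors,
    RespirationParams,
    co2_mol_to_glucose_g,
)
from .weather_sky import (
    SolarGeometry,
    SyntheticWeatherConfig,
    WeatherDay,
    build_sky_dome,
    csrm_daily_radiation,
    extraterrestrial_radiation,
    generate_synthetic_weather,
)

__all__ = ["SimulationConfig", "SimulationState", "SeasonResult", "step", "run"]

_KIND_CODE = {"leaf": 0, "scape": 1, "bud": 2}


@dataclass(frozen=True)
class SimulationConfig:
    """Everything a season run needs; all stochastic draws hang off ``seed``."""

    scenario: object = None  # PlantingScenario-like (pattern/rows/spacing)
    start_doy: int = 91
    end_doy: int = 242
    seed: int = 1
    latitude: float = 40.13
    longitude: float = 113.90
    weather_config: SyntheticWeatherConfig = field(default_factory=SyntheticWeatherConfig)
    tracer: TracerConfig = field(default_factory=TracerConfig)
    optics: OpticalProps = field(default_factory=OpticalProps)
    photosynthesis: PhotosynthesisParams = field(default_factory=PhotosynthesisParams)
    respiration: RespirationParams = field(default_factory=RespirationParams)
    fresh_factors: FreshWeightFactors = field(default_factory=FreshWeightFactors)
    schedule: Optional[PhenologySchedule] = None
    arch: LeafArchParams = field(default_factory=LeafArchParams)
    shoots: int = 6
    emergence_rate: float = 0.5
    buds_per_scape: int = 40
    n_facets: int = 3
    initial_pool: float = 40.0  # g glucose per plant, overwintered rhizome reserve
    reserve_days: int = 50  # the reserve is released evenly over this many days
    plot_x: Optional[float] = None  # None -> sized from the scenario
    plot_y: Optional[float] = None
    plot_target: tuple[float, float] = (3.2, 1.5)

    def __post_init__(self) -> None:
        if self.start_doy >= self.end_doy:
            raise ValueError("start_doy must precede end_doy")


def _auto_plot(cfg: SimulationConfig) -> tuple[float, float]:
    scn = cfg.scenario
    period = scn.wide_row if scn.pattern == "ER" else scn.wide_row + scn.narrow_row
    min_periods = 3 if scn.pattern == "ER" else 2
    n_per = max(min_periods, int(round(cfg.plot_target[0] / period)))
    ny = max(6, int(round(cfg.plot_target[1] / scn.plant_spacing)))
    return n_per * period, ny * scn.plant_spacing


@dataclass
class _OrganArrays:
    """Flat per-organ state across all plants."""

    plant_idx: np.ndarray
    kind: np.ndarray  # codes: 0 leaf, 1 scape, 2 bud
    rank: np.ndarray
    birth: np.ndarray
    azimuth: np.ndarray
    base_xy: np.ndarray  # (n, 2) shoot base position
    l0: np.ndarray
    lm: np.ndarray
    le: np.ndarray
    lw: np.ndarray
    d0: np.ndarray
    dm: np.ndarray
    de: np.ndarray
    dw: np.ndarray
    biomass: np.ndarray
    length: np.ndarray
    refs: list

    @classmethod
    def from_plants(cls, plants: Sequence[Plant]) -> "_OrganArrays":
        rows = []
        refs = []
        for pi, plant in enumerate(plants):
            px, py = plant.position
            for organ in plant.organs():
                bx, by = plant.shoot_bases[organ.shoot] if plant.shoot_bases is not None else (0.0, 0.0)
                gl, gd = organ.growth_len, organ.growth_dm
                rows.append(
                    (
                        pi, _KIND_CODE[organ.kind], organ.rank, organ.birth_day,
                        organ.azimuth, px + bx, py + by,
                        gl.t_0, gl.t_m, gl.t_e, gl.w_max,
                        gd.t_0, gd.t_m, gd.t_e, gd.w_max,
                    )
                )
                refs.append(organ)
        a = np.array(rows, dtype=float)
        return cls(
            plant_idx=a[:, 0].astype(np.int64), kind=a[:, 1].astype(np.int64),
            rank=a[:, 2].astype(np.int64), birth=a[:, 3], azimuth=a[:, 4],
            base_xy=a[:, 5:7].copy(),
            l0=a[:, 7], lm=a[:, 8], le=a[:, 9], lw=a[:, 10],
            d0=a[:, 11], dm=a[:, 12], de=a[:, 13], dw=a[:, 14],
            biomass=np.zeros(len(a)), length=np.zeros(len(a)), refs=refs,
        )

    def sync_refs(self) -> None:
        for i, o in enumerate(self.refs):
            o.biomass_dm = float(self.biomass[i])
            o.length = float(self.length[i])


@dataclass
class SimulationState:
    doy: int
    plants: list
    layout: PlantLayout
    organs: _OrganArrays
    pool: np.ndarray  # (n_plants,) g glucose
    daily_rows: list = field(default_factory=list)
    carbon_rows: list = field(default_factory=list)
    organ_rows: list = field(default_factory=list)


def _init_state(cfg: SimulationConfig) -> SimulationState:
    if cfg.scenario is None:
        raise ValueError("config.scenario is required")
    plot_x, plot_y = (cfg.plot_x, cfg.plot_y)
    if plot_x is None or plot_y is None:
        plot_x, plot_y = _auto_plot(cfg)
    layout = build_scene(cfg.scenario, plot_x, plot_y)
    schedule = cfg.schedule or default_schedule(buds_per_scape=cfg.buds_per_scape)
    rng = np.random.default_rng([cfg.seed, 20_220_401])
    plants = []
    for k in range(layout.n_plants):
        plant = init_plant(
            position=tuple(layout.positions[k]), shoots=cfg.shoots, schedule=schedule,
            rng=rng, emergence_rate=cfg.emergence_rate, buds_per_scape=cfg.buds_per_scape,
        )
        plant.interior = bool(layout.interior[k])
        plant.pool = cfg.initial_pool
        plants.append(plant)
    organs = _OrganArrays.from_plants(plants)
    # organs born before the season window carry their pre-season growth
    # (spring regrowth funded by the overwintered rhizome) as initial state
    organs.biomass = beta_growth_cumulative_arrays(
        cfg.start_doy, organs.d0, organs.dm, organs.de, organs.dw
    )
    organs.length = beta_growth_cumulative_arrays(
        cfg.start_doy, organs.l0, organs.lm, organs.le, organs.lw
    )
    pool = np.zeros(layout.n_plants)  # the rhizome reserve is released daily
    return SimulationState(
        doy=cfg.start_doy, plants=plants, layout=layout, organs=organs, pool=pool
    )


def step(state: SimulationState, wd: WeatherDay, cfg: SimulationConfig) -> SimulationState:
    """Advance the state by exactly one day (mutates and returns ``state``)."""
    if wd.doy != state.doy:
        raise ValueError(f"weather day {wd.doy} does not match simulation day {state.doy}")
    org = state.organs
    doy = state.doy
    n_plants = len(state.pool)

    # (1) sky radiation update
    geom = SolarGeometry(cfg.latitude, cfg.longitude, doy)
    h_o = extraterrestrial_radiation(geom)
    h = csrm_daily_radiation(wd, h_o)
    daylen = geom.daylength_seconds
    h_day = h * 86400.0 / daylen if daylen > 0 else 0.0
    dome = build_sky_dome(h_day, geom, wd.cloud)

    # (2) light interception + coupled leaf gas exchange
    org.length = beta_growth_cumulative_arrays(doy, org.l0, org.lm, org.le, org.lw)
    leaf_mask = (org.kind == 0) & (org.length > 1e-3) & (org.biomass > 1e-8)
    assim = np.zeros(n_plants)
    mean_ppfd = mean_tleaf = mean_anet = float("nan")
    if leaf_mask.any() and h_day > 0.0 and daylen > 0.0:
        areas = morph.SLA * org.biomass[leaf_mask]
        o3, u3, v3, fidx = build_leaf_geometry_batch(
            org.length[leaf_mask], areas, org.azimuth[leaf_mask],
            org.base_xy[leaf_mask], cfg.n_facets, cfg.arch,
        )
        scene = SceneGeometry(
            origins=o3, u_vecs=u3, v_vecs=v3, leaf_index=fidx,
            n_leaves=int(leaf_mask.sum()),
            plot_x=state.layout.plot_x, plot_y=state.layout.plot_y, periodic=True,
        )
        light = intercept(scene, dome, cfg.optics, cfg.tracer)
        flux = light.leaf_flux  # W m-2 leaf, daylight-mean
        ppfd = light.leaf_ppfd
        t_day = wd.tmean + 0.25 * (wd.tmax - wd.tmin)
        lf = coupled_leaf_flux(
            ppfd, t_day, wd.rh, wd.co2, wd.wind, cfg.photosynthesis, absorbed_sw=flux
        )
        leaf_glucose = co2_mol_to_glucose_g(lf.a_net * 1e-6 * areas * daylen)
        assim = np.bincount(org.plant_idx[leaf_mask], weights=leaf_glucose, minlength=n_plants)
        w = areas / areas.sum()
        mean_ppfd = float(ppfd @ w)
        mean_tleaf = float(lf.t_leaf @ w)
        mean_anet = float(lf.a_net @ w)

    # (3) source-sink allocation and respiration (vectorized per plant)
    # spring release of the overwintered rhizome reserve, spread over the
    # first reserve_days so the daily root draw cannot void it at once
    reserve = (
        cfg.initial_pool / cfg.reserve_days
        if cfg.reserve_days > 0 and doy < cfg.start_doy + cfg.reserve_days
        else 0.0
    )
    pool_prev = state.pool.copy()
    avail = np.maximum(0.0, state.pool + assim + reserve)
    assim_eff = avail - pool_prev - reserve
    inc = beta_growth_cumulative_arrays(doy + 1, org.d0, org.dm, org.de, org.dw) - \
        beta_growth_cumulative_arrays(doy, org.d0, org.dm, org.de, org.dw)
    s_tot = np.bincount(org.plant_idx, weights=inc, minlength=n_plants)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = inc / s_tot[org.plant_idx] * avail[org.plant_idx]
    gr = np.minimum(np.where(s_tot[org.plant_idx] > 0, share, 0.0), inc)
    p = cfg.respiration
    g_tot = np.bincount(org.plant_idx, weights=gr, minlength=n_plants)
    struct = np.bincount(org.plant_idx, weights=org.biomass, minlength=n_plants)
    maint = p.maintenance_rate * struct
    need = p.growth_conversion * g_tot + maint
    scale = np.ones(n_plants)
    short = (need > avail) & (g_tot > 0)
    scale[short] = np.clip(
        (avail[short] - maint[short]) / (p.growth_conversion * g_tot[short]), 0.0, 1.0
    )
    gr = gr * scale[org.plant_idx]
    g_tot = g_tot * scale
    growth_resp = (p.growth_conversion - 1.0) * g_tot
    pool = np.maximum(0.0, avail - p.growth_conversion * g_tot)
    maint_paid = np.minimum(pool, maint)
    pool -= maint_paid
    root = p.root_fraction * pool
    pool -= root
    state.pool = pool
    org.biomass = org.biomass + gr

    # (4) morphology rules: length advance to end of day, geometry refreshes
    # from the new biomass on the next light pass
    org.length = beta_growth_cumulative_arrays(doy + 1, org.l0, org.lm, org.le, org.lw)

    # (5) output records
    state.daily_rows.append(
        {
            "day": doy, "h_wm2": h, "h_day_wm2": h_day,
            "mean_ppfd": mean_ppfd, "mean_tleaf_c": mean_tleaf, "mean_anet": mean_anet,
            "assim_g_total": float(assim.sum()),
        }
    )
    interior = np.asarray(state.layout.interior)
    int_organ = interior[org.plant_idx]
    scape_m = (org.kind == 1) & int_organ
    bud_m = (org.kind == 2) & int_organ
    state.organ_rows.append(
        {
            "day": doy,
            "scape_len_m": float(org.length[scape_m].mean()) if scape_m.any() else 0.0,
            "bud_len_m": float(org.length[bud_m].mean()) if bud_m.any() else 0.0,
            "bud_dm_g": float(org.biomass[bud_m].mean()) if bud_m.any() else 0.0,
            "leaf_dm_g": float(
                np.bincount(org.plant_idx, weights=org.biomass * (org.kind == 0),
                            minlength=n_plants)[interior].mean()
            ),
        }
    )
    for pi in range(n_plants):
        state.carbon_rows.append(
            (doy, pi, float(assim_eff[pi]), reserve, float(g_tot[pi]),
             float(growth_resp[pi]), float(maint_paid[pi]), float(root[pi]),
             float(pool[pi]))
        )
    state.doy += 1
    return state


@dataclass
class SeasonResult:
    summary: dict
    daily: pd.DataFrame
    organs: pd.DataFrame
    carbon: pd.DataFrame
    state: SimulationState

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.daily.to_csv(out / "light.csv", index=False)
        self.organs.to_csv(out / "organs.csv", index=False)
        self.carbon.to_csv(out / "carbon.csv", index=False)
        (out / "summary.json").write_text(json.dumps(self.summary, indent=2))


def run(cfg: SimulationConfig, weather: Optional[Sequence[WeatherDay]] = None) -> SeasonResult:
    """Run the full season and summarize yield and organ endpoints."""
    if weather is None:
        wc = replace(cfg.weather_config, seed=cfg.seed,
                     start_doy=cfg.start_doy, end_doy=cfg.end_doy)
        weather = generate_synthetic_weather(wc)
    wmap = {w.doy: w for w in weather}
    state = _init_state(cfg)
    for doy in range(cfg.start_doy, cfg.end_doy + 1):
        if doy not in wmap:
            raise ValueError(f"weather day {doy} missing")
        step(state, wmap[doy], cfg)
    state.organs.sync_refs()

    org = state.organs
    interior = np.asarray(state.layout.interior)
    int_ids = np.flatnonzero(interior)
    bud_ratio = cfg.fresh_factors.ratio("bud")
    bud_mask = org.kind == 2
    n_plants_int = len(int_ids)

    # per-scape bud statistics over interior plants
    scape_count = np.zeros(len(state.pool))
    bud_fresh_per_plant = np.zeros(len(state.pool))
    bud_count = np.zeros(len(state.pool))
    for pi in range(len(state.pool)):
        m = bud_mask & (org.plant_idx == pi)
        bud_fresh_per_plant[pi] = bud_ratio * org.biomass[m].sum()
        bud_count[pi] = int(m.sum())
        scape_count[pi] = ((org.kind == 1) & (org.plant_idx == pi)).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        per_scape_fresh = np.where(scape_count > 0, bud_fresh_per_plant / scape_count, np.nan)
        buds_per_scape = np.where(scape_count > 0, bud_count / scape_count, np.nan)
    flowering_int = int_ids[scape_count[int_ids] > 0]

    density = state.layout.realized_density
    mean_position_fresh = float(bud_fresh_per_plant[int_ids].mean()) if n_plants_int else 0.0
    yield_t_ha = mean_position_fresh * density / 1e6
    yield_g_per_plant = (
        float(np.nanmean(per_scape_fresh[flowering_int])) if len(flowering_int) else 0.0
    )
    bud_len_final = org.length[bud_mask & interior[org.plant_idx]]
    mean_bud_len = float(bud_len_final.mean()) if len(bud_len_final) else 0.0
    bud_dm_per_scape = yield_g_per_plant / bud_ratio

    organs_df = pd.DataFrame(state.organ_rows)
    scape_215 = float(
        organs_df.loc[organs_df["day"] <= 215, "scape_len_m"].max()
    ) if len(organs_df) else 0.0

    summary = {
        "scenario_id": getattr(cfg.scenario, "id", None),
        "n_plants": int(len(state.pool)),
        "n_interior": int(n_plants_int),
        "density_realized": density,
        "yield_t_ha": yield_t_ha,
        "yield_g_per_plant": yield_g_per_plant,
        "mean_bud_length_m": mean_bud_len,
        "bud_dm_per_scape_g": bud_dm_per_scape,
        "buds_per_scape": float(np.nanmean(buds_per_scape[flowering_int]))
        if len(flowering_int) else 0.0,
        "scape_len_by_day215_m": scape_215,
        "seed": cfg.seed,
    }
    carbon_df = pd.DataFrame(
        state.carbon_rows,
        columns=["day", "plant_id", "assim_g", "reserve_g", "growth_g",
                 "growth_resp_g", "maint_g", "root_g", "pool_g"],
    )
    return SeasonResult(
        summary=summary, daily=pd.DataFrame(state.daily_rows), organs=organs_df,
        carbon=carbon_df, state=state,
    )
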