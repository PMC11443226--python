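"""Planting-configuration catalogue, sweep driver and selection rules.

36 planting configurations spanning three patterns (double row big ridge
DRBR, equidistant row ER, narrow-wide row NWR), wide+narrow row sums of
0.8-1.8 m, plant spacings of 0.15-0.3 m and nominal densities of
63,000-100,000 plants per hectare.  The sweep runs the full season
simulation for each configuration under one shared weather realization and
the selector applies the dual quality criteria: mean bud length >= 0.12 m
and per-hectare yield >= 35 t.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlantingScenario",
    "SweepSummary",
    "load_table1",
    "density_from_geometry",
    "run_sweep",
    "select_optimal",
]


@dataclass(frozen=True)
class PlantingScenario:
    """One planting configuration (a catalogue row)."""

    id: int
    pattern: str  # DRBR | ER | NWR
    wide_row: float  # m
    narrow_row: float  # m
    wn_sum: float  # m, wide + narrow
    plant_spacing: float  # m
    nominal_density: float  # plants per hectare (catalogue label, rounded)

    def __post_init__(self) -> None:
        if self.pattern not in ("DRBR", "ER", "NWR"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if abs(self.wn_sum - (self.wide_row + self.narrow_row)) > 1e-9:
            raise ValueError("wn_sum must equal wide_row + narrow_row")
        if self.wide_row <= 0 or self.narrow_row <= 0 or self.plant_spacing <= 0:
            raise ValueError("spacings must be > 0")


# id, pattern, wide, narrow, spacing, nominal density (plants/ha)
_TABLE1 = [
    (1, "DRBR", 1.6, 0.2, 0.15, 74_000), (2, "ER", 0.9, 0.9, 0.15, 74_000),
    (3, "NWR", 1.2, 0.6, 0.15, 74_000), (4, "DRBR", 1.4, 0.2, 0.15, 83_000),
    (5, "ER", 0.8, 0.8, 0.15, 83_000), (6, "NWR", 1.1, 0.5, 0.15, 83_000),
    (7, "DRBR", 1.2, 0.2, 0.15, 95_000), (8, "ER", 0.7, 0.7, 0.15, 95_000),
    (9, "NWR", 1.0, 0.4, 0.15, 95_000), (10, "DRBR", 1.4, 0.2, 0.2, 63_000),
    (11, "ER", 0.8, 0.8, 0.2, 63_000), (12, "NWR", 1.1, 0.5, 0.2, 63_000),
    (13, "DRBR", 1.2, 0.2, 0.2, 72_000), (14, "ER", 0.7, 0.7, 0.2, 72_000),
    (15, "NWR", 1.0, 0.4, 0.2, 72_000), (16, "DRBR", 1.0, 0.2, 0.2, 83_000),
    (17, "ER", 0.6, 0.6, 0.2, 83_000), (18, "NWR", 0.8, 0.4, 0.2, 83_000),
    (19, "DRBR", 0.8, 0.2, 0.2, 100_000), (20, "ER", 0.5, 0.5, 0.2, 100_000),
    (21, "NWR", 0.6, 0.4, 0.2, 100_000), (22, "DRBR", 1.0, 0.2, 0.25, 67_000),
    (23, "ER", 0.6, 0.6, 0.25, 67_000), (24, "NWR", 0.8, 0.4, 0.25, 67_000),
    (25, "DRBR", 0.8, 0.2, 0.25, 80_000), (26, "ER", 0.5, 0.5, 0.25, 80_000),
    (27, "NWR", 0.7, 0.3, 0.25, 80_000), (28, "DRBR", 0.6, 0.2, 0.25, 100_000),
    (29, "ER", 0.4, 0.4, 0.25, 100_000), (30, "NWR", 0.5, 0.3, 0.25, 100_000),
    (31, "DRBR", 0.8, 0.2, 0.3, 67_000), (32, "ER", 0.5, 0.5, 0.3, 67_000),
    (33, "NWR", 0.7, 0.3, 0.3, 67_000), (34, "DRBR", 0.6, 0.2, 0.3, 83_000),
    (35, "ER", 0.4, 0.4, 0.3, 83_000), (36, "NWR", 0.5, 0.3, 0.3, 83_000),
]


def load_table1() -> list[PlantingScenario]:
    """The 36 catalogue configurations."""
    return [
        PlantingScenario(
            id=i, pattern=p, wide_row=w, narrow_row=n, wn_sum=round(w + n, 9),
            plant_spacing=s, nominal_density=d,
        )
        for i, p, w, n, s, d in _TABLE1
    ]


def density_from_geometry(
    pattern: str, wide: float, narrow: float, spacing: float
) -> tuple[float, int]:
    """Planting density from geometry: (exact plants/ha, rounded to 1000).

    ER allots wide x spacing per plant; DRBR and NWR place two rows per
    (wide + narrow) period, i.e. (wide + narrow)/2 x spacing per plant.
    """
    if spacing <= 0 or wide <= 0 or (pattern != "ER" and narrow <= 0):
        raise ValueError("spacings must be > 0")
    if pattern == "ER":
        exact = 1e4 / (wide * spacing)
    else:
        exact = 2e4 / ((wide + narrow) * spacing)
    rounded = int(exact / 1000.0 + 0.5) * 1000
    return exact, rounded


@dataclass
class SweepSummary:
    """Sweep output: one summary row per scenario + the daily indicator series."""

    table: pd.DataFrame
    daily: pd.DataFrame  # per-scenario per-day canopy aggregates

    def group_means(self, by: str) -> pd.DataFrame:
        return self.table.groupby(by)[["yield_t_ha", "yield_g_plant", "mean_bud_len_m"]].mean()


def run_sweep(
    scenarios: Sequence[PlantingScenario],
    base_config,
    weather=None,
) -> SweepSummary:
    """Run the season simulation for each scenario under shared weather.

    All scenarios see the identical weather realization and the same seeds
    (a paired design), so differences in the summary are attributable to
    the planting geometry alone.
    """
    from .simulator import SimulationConfig, run  # late import, no cycle at module load

    if weather is None:
        from .weather_sky import SyntheticWeatherConfig, generate_synthetic_weather

        weather = generate_synthetic_weather(
            SyntheticWeatherConfig(seed=base_config.seed)
        )
    rows = []
    dailies = []
    for scn in scenarios:
        cfg = replace(base_config, scenario=scn)
        result = run(cfg, weather=weather)
        s = result.summary
        rows.append(
            {
                "id": scn.id,
                "pattern": scn.pattern,
                "wide": scn.wide_row,
                "narrow": scn.narrow_row,
                "wn": scn.wn_sum,
                "spacing": scn.plant_spacing,
                "density_nominal": scn.nominal_density,
                "density_realized": s["density_realized"],
                "yield_t_ha": s["yield_t_ha"],
                "yield_g_plant": s["yield_g_per_plant"],
                "mean_bud_len_m": s["mean_bud_length_m"],
                "bud_dm_g": s["bud_dm_per_scape_g"],
            }
        )
        d = result.daily.copy()
        d.insert(0, "scenario_id", scn.id)
        dailies.append(d)
    return SweepSummary(table=pd.DataFrame(rows), daily=pd.concat(dailies, ignore_index=True))


def select_optimal(
    summary: pd.DataFrame | SweepSummary,
    bud_length_min: float = 0.12,
    yield_min: float = 35.0,
) -> tuple[list[int], Optional[int]]:
    """Scenario ids meeting both quality thresholds, and the yield-best one.

    Returns ``(qualifying_ids, best_id)``; an empty qualifying set yields
    ``([], None)``.
    """
    df = summary.table if isinstance(summary, SweepSummary) else summary
    ok = df[(df["mean_bud_len_m"] >= bud_length_min) & (df["yield_t_ha"] >= yield_min)]
    ids = sorted(int(i) for i in ok["id"])
    if not len(ok):
        return [], None
    best = int(ok.loc[ok["yield_t_ha"].idxmax(), "id"])
    return ids, best
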