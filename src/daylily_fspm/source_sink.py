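"""Source-sink carbon allocation.

Daily bookkeeping of the shared assimilate pool *ap* (g glucose) of one
plant: leaf photosynthesis replenishes the pool; organs draw from it in
proportion to their potential sink strengths (the growth-function
derivative), capped at their potential growth; growth respiration,
maintenance respiration (0.014 g glucose per g structural dry matter per
day) and a fixed root draw (0.15 x pool) are then charged in that order.
If the pool cannot cover the respiration charges the day's growth is shrunk
proportionally — biomass is never catabolized and the pool never goes
negative.  Dry matter converts to fresh weight through per-organ ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CarbonPool",
    "SinkDemandLedger",
    "RespirationParams",
    "FreshWeightFactors",
    "DailyCarbonRecord",
    "total_demand",
    "allocate",
    "respire_and_root",
    "fresh_weight",
    "co2_mol_to_glucose_g",
]

#: g glucose per mol CO2 fixed (C6H12O6: 180 g per 6 CO2).
GLUCOSE_PER_MOL_CO2 = 180.0 / 6.0


def co2_mol_to_glucose_g(mol_co2) -> float:
    """Convert mol CO2 assimilated to g glucose equivalents."""
    return GLUCOSE_PER_MOL_CO2 * mol_co2


@dataclass
class CarbonPool:
    """Shared assimilate pool of one plant (g glucose); never negative."""

    ap: float = 0.0

    def __post_init__(self) -> None:
        if self.ap < 0:
            raise ValueError("assimilate pool cannot be negative")

    def add(self, g: float) -> None:
        self.ap += g

    def withdraw(self, g: float) -> float:
        taken = min(self.ap, g)
        self.ap -= taken
        return taken


@dataclass(frozen=True)
class RespirationParams:
    growth_conversion: float = 1.39  # g glucose per g new structural DM
    maintenance_rate: float = 0.014  # g glucose per g DM per day
    root_fraction: float = 0.15  # of the pool, per day

    def __post_init__(self) -> None:
        if self.growth_conversion < 1.0:
            raise ValueError("growth conversion >= 1 (includes the structural gram)")
        if self.maintenance_rate < 0:
            raise ValueError("maintenance rate >= 0")
        if not 0.0 <= self.root_fraction < 1.0:
            raise ValueError("root fraction in [0, 1)")


@dataclass(frozen=True)
class FreshWeightFactors:
    """Per-organ fresh:dry mass ratios (empirical constants)."""

    ratios: Mapping[str, float] = field(
        default_factory=lambda: {"leaf": 6.0, "scape": 8.0, "bud": 12.0}
    )

    def __post_init__(self) -> None:
        for kind, r in self.ratios.items():
            if r < 1.0:
                raise ValueError(f"fresh:dry ratio for {kind} must be > 1")

    def ratio(self, kind: str) -> float:
        try:
            return self.ratios[kind]
        except KeyError:
            raise KeyError(f"no fresh:dry factor for organ kind {kind!r}") from None


@dataclass
class SinkDemandLedger:
    """Per-organ potential growth rates (g day-1) and the step length."""

    rates: np.ndarray  # (n_organs,)
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates < 0):
            raise ValueError("negative sink strength")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def total(self) -> float:
        return float(self.rates.sum() * self.dt)


def total_demand(rates: Sequence[float] | np.ndarray, dt: float = 1.0) -> float:
    """Total carbon demand: sum of potential growth rates x dt (g)."""
    return SinkDemandLedger(np.asarray(rates, dtype=float), dt).total


def allocate(ap: float, ledger: SinkDemandLedger) -> np.ndarray:
    """Actual growth per organ (g): proportional share of the pool, capped
    at the organ's potential; surplus stays in the pool.

        gr_real_i = min(S_i / S_tot * ap, S_i * dt)
    """
    if ap < 0:
        raise ValueError("ap must be >= 0")
    s_tot = ledger.total
    if s_tot <= 0.0 or ap == 0.0:
        return np.zeros_like(ledger.rates)
    share = ledger.rates * ledger.dt / s_tot * ap
    return np.minimum(share, ledger.rates * ledger.dt)


def respire_and_root(
    pool: CarbonPool,
    gr_real: np.ndarray,
    structural_dm: float,
    p: RespirationParams = RespirationParams(),
) -> tuple[np.ndarray, dict]:
    """Charge growth respiration, maintenance and the root draw.

    ``pool`` must already have had the day's structural growth withdrawn
    (sum of ``gr_real``).  If the remaining pool cannot cover growth
    respiration + maintenance, the day's growth is scaled back
    proportionally (the withheld glucose re-credits the pool) and
    maintenance is paid as far as possible.  Returns the (possibly scaled)
    per-organ growth and a charge breakdown; the pool ends >= 0.
    """
    gr_real = np.asarray(gr_real, dtype=float)
    g_tot = float(gr_real.sum())
    growth_resp = (p.growth_conversion - 1.0) * g_tot
    maint = p.maintenance_rate * structural_dm
    scale = 1.0
    avail = pool.ap + g_tot  # pool before the growth withdrawal
    need = p.growth_conversion * g_tot + maint
    if need > avail and g_tot > 0:
        scale = max(0.0, (avail - maint) / (p.growth_conversion * g_tot))
        gr_real = gr_real * scale
        g_tot = float(gr_real.sum())
        growth_resp = (p.growth_conversion - 1.0) * g_tot
        pool.ap = avail - g_tot  # re-credit withheld growth
    pool.ap = max(0.0, pool.ap - growth_resp)
    maint_paid = pool.withdraw(maint)
    root = p.root_fraction * pool.ap
    pool.ap -= root
    return gr_real, {
        "growth_g": g_tot,
        "growth_resp_g": growth_resp,
        "maint_g": maint_paid,
        "root_g": root,
        "growth_scale": scale,
    }


def fresh_weight(organ, factors: FreshWeightFactors = FreshWeightFactors()) -> float:
    """Fresh weight (g) = fresh:dry ratio x dry mass for the organ's kind."""
    return factors.ratio(organ.kind) * organ.biomass_dm


@dataclass
class DailyCarbonRecord:
    """One row of the daily carbon ledger CSV."""

    day: int
    plant_id: int
    assim_g: float
    growth_g: float
    growth_resp_g: float
    maint_g: float
    root_g: float
    pool_g: float
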