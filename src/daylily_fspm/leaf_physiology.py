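"""Coupled C3 leaf gas exchange.

Per leaf and per day the model solves the steady state of four coupled
relations (Farquhar–von Caemmerer–Berry biochemistry, Ball–Woodrow–Berry
stomatal conductance, CO2 diffusion, and the leaf energy balance):

    A   = min(Wc, Wj) * (1 - Gamma*/Ci) - Rd
    gs  = g0 + m * A * h_s / Cs          (floored at g0)
    Ci  = Ca - A * (1.6/gs + 1.37/gb)
    0   = absorbed_SW - 2 eps sigma (Tl^4 - Ta^4) - H(Tl) - lambda E(Tl)

by damped successive substitution.  All functions are vectorized over
leaves; scalars work too.

The default parameter set is the package's own calibration for daylily (the
species' gas-exchange constants are not published alongside the model it
re-implements); values are ordinary C3 crop magnitudes chosen so that a
default-density canopy can sustain the reported organ growth endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "PhotosynthesisParams",
    "LeafState",
    "fvcb_assimilation",
    "bwb_conductance",
    "leaf_energy_balance",
    "coupled_leaf_flux",
    "saturation_vapor_pressure",
    "boundary_layer_conductance",
]

ArrayLike = Union[float, np.ndarray]

R_GAS = 8.314  # J mol-1 K-1
O2_MBAR = 210.0  # mbar, atmospheric O2 partial pressure
CP_MOL = 29.2  # J mol-1 K-1, molar heat capacity of air
LAMBDA_MOL = 44_100.0  # J mol-1, latent heat of vaporization
SIGMA = 5.670e-8  # W m-2 K-4
PRESSURE = 101_325.0  # Pa


@dataclass(frozen=True)
class PhotosynthesisParams:
    """FvCB + BWB + energy-balance parameters (25 degC reference values)."""

    vcmax25: float = 55.0  # umol m-2 s-1
    jmax25: float = 110.0  # umol m-2 s-1
    rd25: float = 0.6  # umol m-2 s-1
    alpha: float = 0.26  # mol e- per mol photons (incident basis)
    theta: float = 0.70  # J response curvature
    kc25: float = 404.9  # ubar
    ko25: float = 278.4  # mbar
    gamma_star25: float = 42.75  # ubar
    ea_vcmax: float = 65_330.0  # J mol-1 activation energies
    ea_rd: float = 46_390.0
    ea_kc: float = 79_430.0
    ea_ko: float = 36_380.0
    ea_gamma: float = 37_830.0
    ea_jmax: float = 43_540.0  # peaked response for Jmax
    hd_jmax: float = 152_040.0
    s_jmax: float = 495.0
    bwb_m: float = 9.0
    bwb_g0: float = 0.01  # mol m-2 s-1
    leaf_width: float = 0.012  # m, characteristic dimension for gb
    emissivity: float = 0.97

    def __post_init__(self) -> None:
        if not 0.0 < self.theta <= 1.0:
            raise ValueError("theta in (0, 1]")
        if self.bwb_g0 < 0:
            raise ValueError("g0 >= 0")
        for name in ("vcmax25", "jmax25", "rd25", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class LeafState:
    """Converged (or flagged) leaf gas-exchange state."""

    a_net: np.ndarray  # umol CO2 m-2 s-1
    gs: np.ndarray  # mol m-2 s-1
    ci: np.ndarray  # umol mol-1
    t_leaf: np.ndarray  # degC
    converged: np.ndarray  # bool


def _arrhenius(k25: ArrayLike, ea: float, t_c: ArrayLike) -> ArrayLike:
    tk = np.asarray(t_c, dtype=float) + 273.15
    return k25 * np.exp(ea * (tk - 298.15) / (R_GAS * 298.15 * tk))


def _peaked(k25: float, ea: float, hd: float, s: float, t_c: ArrayLike) -> ArrayLike:
    tk = np.asarray(t_c, dtype=float) + 273.15
    arr = _arrhenius(k25, ea, t_c)
    num = 1.0 + np.exp((s * 298.15 - hd) / (R_GAS * 298.15))
    den = 1.0 + np.exp((s * tk - hd) / (R_GAS * tk))
    return arr * num / den


def saturation_vapor_pressure(t_c: ArrayLike) -> ArrayLike:
    """Saturation vapor pressure (Pa), Magnus form."""
    t = np.asarray(t_c, dtype=float)
    return 611.2 * np.exp(17.62 * t / (243.12 + t))


def boundary_layer_conductance(wind: ArrayLike, leaf_width: float = 0.012) -> ArrayLike:
    """One-sided boundary-layer conductance to water vapor (mol m-2 s-1)."""
    u = np.maximum(np.asarray(wind, dtype=float), 0.1)
    return 0.147 * np.sqrt(u / leaf_width)


def fvcb_assimilation(
    ci: ArrayLike, ppfd: ArrayLike, t_leaf: ArrayLike,
    p: PhotosynthesisParams = PhotosynthesisParams(),
) -> ArrayLike:
    """Net assimilation A_net (umol CO2 m-2 s-1) at intercellular CO2 ``ci``.

    A = min(Wc, Wj) (1 - Gamma*/Ci) - Rd with the Rubisco-limited rate
    Wc = Vcmax Ci / (Ci + Kc (1 + O/Ko)) and the electron-transport-limited
    rate Wj = J Ci / (4 Ci + 8 Gamma*); J follows the non-rectangular
    hyperbola in absorbed PPFD.
    """
    ci = np.asarray(ci, dtype=float)
    if np.any(~np.isfinite(ci)) or np.any(~np.isfinite(np.asarray(ppfd, dtype=float))):
        raise ValueError("non-finite inputs")
    if np.any(ci <= 0):
        raise ValueError("Ci must be > 0")
    vcmax = _arrhenius(p.vcmax25, p.ea_vcmax, t_leaf)
    rd = _arrhenius(p.rd25, p.ea_rd, t_leaf)
    kc = _arrhenius(p.kc25, p.ea_kc, t_leaf)
    ko = _arrhenius(p.ko25, p.ea_ko, t_leaf)
    gamma = _arrhenius(p.gamma_star25, p.ea_gamma, t_leaf)
    jmax = _peaked(p.jmax25, p.ea_jmax, p.hd_jmax, p.s_jmax, t_leaf)

    i2 = p.alpha * np.asarray(ppfd, dtype=float)
    j = (i2 + jmax - np.sqrt((i2 + jmax) ** 2 - 4.0 * p.theta * i2 * jmax)) / (2.0 * p.theta)

    wc = vcmax * ci / (ci + kc * (1.0 + O2_MBAR / ko))
    wj = j * ci / (4.0 * ci + 8.0 * gamma)
    return np.minimum(wc, wj) * (1.0 - gamma / ci) - rd


def bwb_conductance(
    a_net: ArrayLike, rh_surface: ArrayLike, cs: ArrayLike,
    p: PhotosynthesisParams = PhotosynthesisParams(),
) -> ArrayLike:
    """Stomatal conductance gs = g0 + m A h_s / Cs, floored at g0."""
    cs = np.asarray(cs, dtype=float)
    if np.any(cs <= 0):
        raise ValueError("Cs must be > 0")
    gs = p.bwb_g0 + p.bwb_m * np.asarray(a_net, dtype=float) * np.asarray(rh_surface) / cs
    return np.maximum(gs, p.bwb_g0)


def leaf_energy_balance(
    absorbed: ArrayLike, t_air: ArrayLike, wind: ArrayLike, gs: ArrayLike,
    rh: ArrayLike, p: PhotosynthesisParams = PhotosynthesisParams(),
    max_iter: int = 25,
) -> ArrayLike:
    """Leaf temperature (degC) closing the energy balance.

    absorbed shortwave = 2-sided longwave loss against air temperature
    + sensible heat + latent heat, solved by Newton iteration.
    """
    absorbed = np.asarray(absorbed, dtype=float)
    if np.any(absorbed < 0):
        raise ValueError("absorbed flux must be >= 0")
    t_air = np.asarray(t_air, dtype=float)
    gs = np.asarray(gs, dtype=float)
    gb = boundary_layer_conductance(wind, p.leaf_width)
    gtw = 1.0 / (1.0 / np.maximum(gs, 1e-9) + 1.0 / gb)
    e_air = np.asarray(rh, dtype=float) * saturation_vapor_pressure(t_air)

    tl = t_air + 0.0 * absorbed  # broadcast
    for _ in range(max_iter):
        res = _balance_residual(tl, absorbed, t_air, gb, gtw, e_air, p)
        d_res = (
            _balance_residual(tl + 0.01, absorbed, t_air, gb, gtw, e_air, p) - res
        ) / 0.01
        step = res / np.where(np.abs(d_res) > 1e-12, d_res, -1.0)
        tl = tl - np.clip(step, -5.0, 5.0)
        if np.all(np.abs(res) < 1e-4):
            break
    res = _balance_residual(tl, absorbed, t_air, gb, gtw, e_air, p)
    if np.any(np.abs(res) > 0.1):
        raise RuntimeError("leaf energy balance did not converge")
    return tl


def _balance_residual(tl, absorbed, t_air, gb, gtw, e_air, p):
    tk_l = tl + 273.15
    tk_a = t_air + 273.15
    longwave = 2.0 * p.emissivity * SIGMA * (tk_l**4 - tk_a**4)
    sensible = 2.0 * CP_MOL * 0.924 * gb * (tl - t_air)
    e_leaf = saturation_vapor_pressure(tl)
    latent = LAMBDA_MOL * gtw * np.maximum(e_leaf - e_air, 0.0) / PRESSURE
    return absorbed - longwave - sensible - latent


def coupled_leaf_flux(
    ppfd: ArrayLike,
    t_air: ArrayLike,
    rh: ArrayLike,
    co2: ArrayLike,
    wind: ArrayLike,
    p: PhotosynthesisParams = PhotosynthesisParams(),
    absorbed_sw: ArrayLike | None = None,
    max_iter: int = 50,
    tol: float = 1e-4,
    damping: float = 0.5,
) -> LeafState:
    """Joint fixed point of FvCB + BWB + diffusion + energy balance.

    ``absorbed_sw`` (W m-2 leaf) defaults to ppfd / 2.275 (the same
    radiation-to-PPFD factor used on the way in).  Returns the converged
    state; leaves that fail to converge within ``max_iter`` are flagged and
    carry their last iterate.
    """
    ppfd = np.atleast_1d(np.asarray(ppfd, dtype=float))
    shape = ppfd.shape
    t_air_a = np.broadcast_to(np.asarray(t_air, dtype=float), shape).copy()
    rh_a = np.broadcast_to(np.asarray(rh, dtype=float), shape).copy()
    ca = np.broadcast_to(np.asarray(co2, dtype=float), shape).copy()
    wind_a = np.broadcast_to(np.asarray(wind, dtype=float), shape).copy()
    if absorbed_sw is None:
        absorbed_sw = ppfd / 2.275
    sw = np.broadcast_to(np.asarray(absorbed_sw, dtype=float), shape).copy()

    gb = boundary_layer_conductance(wind_a, p.leaf_width)
    ci = 0.7 * ca
    tl = t_air_a.copy()
    gs = np.full(shape, max(p.bwb_g0, 0.05))
    a = fvcb_assimilation(ci, ppfd, tl, p)
    converged = np.zeros(shape, dtype=bool)

    for _ in range(max_iter):
        a_new = fvcb_assimilation(ci, ppfd, tl, p)
        cs = np.maximum(ca - a_new * 1.37 / gb, 1.0)
        h_air_at_leaf = np.clip(
            rh_a * saturation_vapor_pressure(t_air_a) / saturation_vapor_pressure(tl),
            0.0, 1.0,
        )
        h_s = (gs * 1.0 + gb * h_air_at_leaf) / (gs + gb)
        gs_new = bwb_conductance(a_new, h_s, cs, p)
        ci_new = np.clip(ca - a_new * (1.6 / gs_new + 1.37 / gb), 1.0, ca)
        tl_new = leaf_energy_balance(sw, t_air_a, wind_a, gs_new, rh_a, p)

        da = np.abs(a_new - a) / np.maximum(np.abs(a_new), 1e-3)
        dg = np.abs(gs_new - gs) / np.maximum(gs_new, 1e-6)
        dc = np.abs(ci_new - ci) / np.maximum(ci_new, 1.0)
        dt = np.abs(tl_new - tl) / np.maximum(np.abs(tl_new) + 273.15, 1.0)
        converged = (da < tol) & (dg < tol) & (dc < tol) & (dt < tol)

        a = a_new
        gs = damping * gs + (1.0 - damping) * gs_new
        ci = damping * ci + (1.0 - damping) * ci_new
        tl = damping * tl + (1.0 - damping) * tl_new
        if converged.all():
            gs, ci, tl = gs_new, ci_new, tl_new
            break

    a = fvcb_assimilation(ci, ppfd, tl, p)
    return LeafState(a_net=a, gs=gs, ci=ci, t_leaf=tl, converged=converged)
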