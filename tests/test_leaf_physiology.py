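"""Leaf gas exchange: FvCB limits, BWB arithmetic, energy balance, coupled solver."""

import numpy as np
import pytest

from daylily_fspm.leaf_physiology import (
    O2_MBAR,
    PhotosynthesisParams,
    R_GAS,
    boundary_layer_conductance,
    bwb_conductance,
    coupled_leaf_flux,
    fvcb_assimilation,
    leaf_energy_balance,
    saturation_vapor_pressure,
)


def _oracle_fvcb(ci, ppfd, t_c, p):
    """Independent scalar evaluation of the two limitation laws (written
    directly from the rate equations, no shared code with the package)."""
    import math

    tk = t_c + 273.15

    def arrh(k25, ea):
        return k25 * math.exp(ea * (tk - 298.15) / (R_GAS * 298.15 * tk))

    vcmax = arrh(p.vcmax25, p.ea_vcmax)
    rd = arrh(p.rd25, p.ea_rd)
    kc = arrh(p.kc25, p.ea_kc)
    ko = arrh(p.ko25, p.ea_ko)
    gam = arrh(p.gamma_star25, p.ea_gamma)
    jm = arrh(p.jmax25, p.ea_jmax)
    num = 1.0 + math.exp((p.s_jmax * 298.15 - p.hd_jmax) / (R_GAS * 298.15))
    den = 1.0 + math.exp((p.s_jmax * tk - p.hd_jmax) / (R_GAS * tk))
    jm *= num / den
    i2 = p.alpha * ppfd
    j = (i2 + jm - math.sqrt((i2 + jm) ** 2 - 4 * p.theta * i2 * jm)) / (2 * p.theta)
    wc = vcmax * ci / (ci + kc * (1 + O2_MBAR / ko))
    wj = j * ci / (4 * ci + 8 * gam)
    return min(wc, wj) * (1 - gam / ci) - rd, wc, wj


def test_dark_assimilation_is_negative_respiration():
    p = PhotosynthesisParams()
    a = fvcb_assimilation(280.0, 0.0, 25.0, p)
    assert a == pytest.approx(-p.rd25, rel=1e-9)


def test_compensation_point():
    p = PhotosynthesisParams()
    a = fvcb_assimilation(p.gamma_star25, 800.0, 25.0, p)
    assert a == pytest.approx(-p.rd25, rel=1e-9)


@pytest.mark.parametrize("ci,ppfd,t", [(300.0, 1500.0, 25.0), (150.0, 300.0, 18.0),
                                       (500.0, 900.0, 32.0)])
def test_fvcb_matches_independent_oracle(ci, ppfd, t):
    p = PhotosynthesisParams(vcmax25=60.0, jmax25=120.0)
    got = fvcb_assimilation(ci, ppfd, t, p)
    want, _, _ = _oracle_fvcb(ci, ppfd, t, p)
    assert got == pytest.approx(want, rel=1e-9)


def test_limitation_crossover():
    p = PhotosynthesisParams(vcmax25=60.0, jmax25=120.0)
    # at low Ci the Rubisco-limited branch is active, at low light the
    # electron-transport branch
    _, wc, wj = _oracle_fvcb(80.0, 1500.0, 25.0, p)
    assert wc < wj
    _, wc, wj = _oracle_fvcb(300.0, 60.0, 25.0, p)
    assert wj < wc


def test_light_response_monotone():
    p = PhotosynthesisParams()
    ppfd = np.linspace(0.0, 1500.0, 40)
    a = fvcb_assimilation(np.full(40, 280.0), ppfd, np.full(40, 25.0), p)
    assert np.all(np.diff(a) >= -1e-12)


def test_fvcb_rejects_bad_inputs():
    with pytest.raises(ValueError):
        fvcb_assimilation(0.0, 100.0, 25.0)
    with pytest.raises(ValueError):
        fvcb_assimilation(float("nan"), 100.0, 25.0)


def test_bwb_hand_case_and_floor():
    p = PhotosynthesisParams(bwb_m=10.0, bwb_g0=0.01)
    assert bwb_conductance(10.0, 0.6, 400.0, p) == pytest.approx(0.16)
    assert bwb_conductance(-2.0, 0.6, 400.0, p) == p.bwb_g0
    assert bwb_conductance(0.0, 0.6, 400.0, p) == p.bwb_g0
    # doubling Cs halves the variable term
    g1 = bwb_conductance(10.0, 0.6, 400.0, p) - p.bwb_g0
    g2 = bwb_conductance(10.0, 0.6, 800.0, p) - p.bwb_g0
    assert g2 == pytest.approx(g1 / 2.0)
    with pytest.raises(ValueError):
        bwb_conductance(10.0, 0.6, 0.0, p)


def test_energy_balance_residual_is_closed():
    p = PhotosynthesisParams()
    tl = leaf_energy_balance(350.0, 24.0, 2.0, 0.15, 0.5, p)
    # recompute the residual independently
    gb = boundary_layer_conductance(2.0, p.leaf_width)
    gtw = 1.0 / (1.0 / 0.15 + 1.0 / gb)
    lw = 2 * p.emissivity * 5.670e-8 * ((tl + 273.15) ** 4 - (24.0 + 273.15) ** 4)
    h = 2 * 29.2 * 0.924 * gb * (tl - 24.0)
    e_leaf = saturation_vapor_pressure(tl)
    e_air = 0.5 * saturation_vapor_pressure(24.0)
    le = 44_100.0 * gtw * max(e_leaf - e_air, 0.0) / 101_325.0
    assert abs(350.0 - lw - h - le) < 0.1


def test_energy_balance_strong_coupling_limit():
    # no shortwave load, closed stomata, high wind -> leaf temperature
    # pinned to air temperature
    tl = leaf_energy_balance(0.0, 20.0, 10.0, 1e-9, 0.99)
    assert tl == pytest.approx(20.0, abs=0.2)


def test_energy_balance_monotone_in_load():
    loads = [0.0, 100.0, 250.0, 450.0]
    tls = [leaf_energy_balance(q, 25.0, 2.0, 0.2, 0.5) for q in loads]
    assert np.all(np.diff(tls) > 0)


def test_coupled_dark_state():
    p = PhotosynthesisParams()
    st = coupled_leaf_flux(0.0, 25.0, 0.5, 400.0, 2.0, p)
    assert st.a_net[0] == pytest.approx(-p.rd25, rel=0.1)
    assert st.gs[0] == pytest.approx(p.bwb_g0)
    assert st.converged[0]


def test_coupled_fixed_point_satisfies_all_subequations():
    p = PhotosynthesisParams()
    ppfd = np.array([50.0, 200.0, 600.0, 1200.0])
    st = coupled_leaf_flux(ppfd, 24.0, 0.55, 420.0, 2.4, p)
    assert st.converged.all()
    gb = boundary_layer_conductance(2.4, p.leaf_width)
    for k in range(len(ppfd)):
        a = fvcb_assimilation(st.ci[k], ppfd[k], st.t_leaf[k], p)
        assert a == pytest.approx(st.a_net[k], rel=1e-3, abs=1e-3)
        ci = 420.0 - st.a_net[k] * (1.6 / st.gs[k] + 1.37 / gb)
        assert ci == pytest.approx(st.ci[k], rel=1e-3)
        # positive assimilation draws intercellular CO2 below ambient
        if st.a_net[k] > 0:
            assert st.ci[k] < 420.0
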