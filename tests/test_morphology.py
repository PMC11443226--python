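"""Growth function identities, leaf geometry, plant construction, scene layout."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from daylily_fspm.morphology import (
    SLA,
    BetaGrowthParams,
    LeafArchParams,
    Organ,
    beta_growth_cumulative,
    beta_growth_cumulative_arrays,
    beta_growth_rate,
    build_leaf_geometry,
    build_leaf_geometry_batch,
    build_scene,
    default_schedule,
    init_plant,
    leaf_area_from_biomass,
)
from daylily_fspm.scenarios import load_table1


@st.composite
def growth_params(draw):
    t0 = draw(st.floats(0.0, 100.0))
    tm = t0 + draw(st.floats(2.0, 60.0))
    te = tm + draw(st.floats(2.0, 80.0))
    w = draw(st.floats(0.01, 50.0))
    return BetaGrowthParams(t0, tm, te, w)


def test_rate_identities():
    p = BetaGrowthParams(0.0, 50.0, 100.0, 1.0)
    assert beta_growth_rate(50.0, p) == pytest.approx(p.c_m)
    assert beta_growth_rate(100.0, p) == 0.0
    assert beta_growth_rate(-1.0, p) == 0.0
    assert beta_growth_rate(101.0, p) == 0.0
    # hand case with c_m normalized to 1: rate(75) = (25/50)*(75/50)^1 = 0.75
    assert beta_growth_rate(75.0, p) / p.c_m == pytest.approx(0.75)


def test_rate_maximum_is_at_tm():
    p = BetaGrowthParams(10.0, 40.0, 90.0, 2.0)
    t = np.linspace(10.0, 90.0, 2001)
    rates = np.array([beta_growth_rate(x, p) for x in t])
    assert abs(t[np.argmax(rates)] - 40.0) < 0.1
    assert rates.max() == pytest.approx(p.c_m, rel=1e-6)


@given(p=growth_params(), frac=st.floats(0.05, 1.0))
@settings(max_examples=60, deadline=None)
def test_cumulative_matches_quadrature(p, frac):
    t = p.t_0 + frac * (p.t_e - p.t_0)
    oracle, _ = quad(lambda x: beta_growth_rate(x, p), p.t_0, t, limit=200)
    assert beta_growth_cumulative(t, p) == pytest.approx(oracle, rel=1e-6, abs=1e-9)


@given(p=growth_params())
@settings(max_examples=40, deadline=None)
def test_cumulative_endpoints_and_monotonicity(p):
    assert beta_growth_cumulative(p.t_0, p) == 0.0
    assert beta_growth_cumulative(p.t_e, p) == pytest.approx(p.w_max, rel=1e-9)
    t = np.linspace(p.t_0, p.t_e, 200)
    w = np.array([beta_growth_cumulative(x, p) for x in t])
    assert np.all(np.diff(w) >= -1e-12)


def test_cumulative_array_form_matches_scalar():
    p = BetaGrowthParams(5.0, 30.0, 70.0, 3.0)
    t = 42.0
    arr = beta_growth_cumulative_arrays(
        t, np.array([5.0]), np.array([30.0]), np.array([70.0]), np.array([3.0])
    )
    assert arr[0] == pytest.approx(beta_growth_cumulative(t, p), rel=1e-12)


def test_invalid_growth_params_raise():
    with pytest.raises(ValueError):
        BetaGrowthParams(10.0, 5.0, 20.0, 1.0)
    with pytest.raises(ValueError):
        BetaGrowthParams(0.0, 10.0, 20.0, -1.0)


def test_leaf_area_from_biomass():
    assert leaf_area_from_biomass(1.0) == pytest.approx(0.0023)
    assert leaf_area_from_biomass(0.0) == 0.0
    assert leaf_area_from_biomass(10.0) == pytest.approx(0.023)
    with pytest.raises(ValueError):
        leaf_area_from_biomass(-0.1)


def _leaf(length=0.5, area=0.005, azimuth=0.3):
    return Organ(
        kind="leaf", rank=1, shoot=0, birth_day=0.0, growth_len=None, growth_dm=None,
        biomass_dm=area / SLA, length=length, azimuth=azimuth,
    )


def test_leaf_geometry_single_facet():
    g = build_leaf_geometry(_leaf(), n_facets=1)
    assert g.areas.sum() == pytest.approx(0.005)
    assert len(g.origins) == 1


def test_leaf_geometry_area_consistency_and_width_scaling():
    g5 = build_leaf_geometry(_leaf(), n_facets=5)
    assert g5.areas.sum() == pytest.approx(0.005, rel=1e-6)
    double = build_leaf_geometry(_leaf(area=0.010), n_facets=5)
    np.testing.assert_allclose(
        np.linalg.norm(double.v_vecs, axis=1),
        2.0 * np.linalg.norm(g5.v_vecs, axis=1),
        rtol=1e-9,
    )
    with pytest.raises(ValueError):
        build_leaf_geometry(_leaf(), n_facets=0)


def test_leaf_geometry_facets_connect_tip_to_base():
    g = build_leaf_geometry(_leaf(), n_facets=4)
    mids = g.origins + 0.5 * g.v_vecs  # base midpoints of each facet
    for k in range(3):
        np.testing.assert_allclose(mids[k] + g.u_vecs[k], mids[k + 1], atol=1e-12)


def test_batch_geometry_matches_single_builder():
    leaf = _leaf(length=0.7, area=0.004, azimuth=1.1)
    single = build_leaf_geometry(leaf, n_facets=3, base=(0.2, -0.1, 0.0))
    o, u, v, idx = build_leaf_geometry_batch(
        np.array([0.7]), np.array([0.004]), np.array([1.1]),
        np.array([[0.2, -0.1]]), n_facets=3,
    )
    np.testing.assert_allclose(o, single.origins, atol=1e-12)
    np.testing.assert_allclose(u, single.u_vecs, atol=1e-12)
    np.testing.assert_allclose(v, single.v_vecs, atol=1e-12)
    assert list(idx) == [0, 0, 0]


def test_init_plant_emergence_extremes_and_determinism():
    sched = default_schedule()
    rng = np.random.default_rng(0)
    none = init_plant((0, 0), 6, sched, rng, emergence_rate=0.0)
    assert not none.has_scape and len(none.buds) == 0
    rng = np.random.default_rng(0)
    full = init_plant((0, 0), 6, sched, rng, emergence_rate=1.0, buds_per_scape=40)
    assert len(full.scapes) == 6
    assert len(full.buds) == 6 * 40
    # half emergence: exactly round(0.5 * 6) = 3 scape-bearing shoots
    rng = np.random.default_rng(0)
    half = init_plant((0, 0), 6, sched, rng, emergence_rate=0.5)
    assert len(half.scapes) == 3
    # determinism under a fixed seed
    a = init_plant((0, 0), 6, sched, np.random.default_rng(5))
    b = init_plant((0, 0), 6, sched, np.random.default_rng(5))
    assert [o.azimuth for o in a.leaves] == [o.azimuth for o in b.leaves]


def test_init_plant_ranks_in_birth_order():
    plant = init_plant((0, 0), 2, default_schedule(), np.random.default_rng(1))
    for shoot in (0, 1):
        ranked = [ph for ph in plant.phytomers if ph.shoot == shoot]
        births = [ph.leaf_pair[0].birth_day for ph in ranked]
        assert births == sorted(births)
        assert [ph.rank for ph in ranked] == list(range(1, 14))


def _scn(sid):
    return {s.id: s for s in load_table1()}[sid]


def test_er_scene_counts_and_density():
    layout = build_scene(_scn(5), 4.8, 3.0)  # ER 0.8 m rows, 0.15 m spacing
    assert layout.n_plants == 6 * 20
    assert layout.realized_density == pytest.approx(1e4 / (0.8 * 0.15))
    assert layout.interior.sum() == 4 * 18  # guard row/column stripped


def test_nwr_row_gaps_alternate():
    layout = build_scene(_scn(6), 3.2, 0.9)  # NWR 1.1/0.5
    xs = np.unique(np.round(layout.positions[:, 0], 6))
    gaps = np.round(np.diff(xs), 6)
    assert set(gaps) == {0.5, 1.1}


def test_drbr_paired_rows_on_ridges():
    layout = build_scene(_scn(13), 2.8, 1.0)  # DRBR 1.2/0.2
    xs = np.unique(np.round(layout.positions[:, 0], 6))
    gaps = np.round(np.diff(xs), 6)
    assert gaps[0] == 0.2 and set(gaps) == {0.2, 1.2}


def test_scene_error_cases():
    import dataclasses

    bad = dataclasses.replace(_scn(5))
    with pytest.raises(ValueError):
        build_scene(dataclasses.replace(bad, plant_spacing=0.0), 4.8, 3.0)  # type: ignore[arg-type]
    with pytest.raises(ValueError):
        build_scene(_scn(5), 0.3, 3.0)  # plot smaller than one row period


def test_obj_export_round_trips_facets(tmp_path):
    trimesh = pytest.importorskip("trimesh")
    from daylily_fspm.morphology import export_obj

    g = build_leaf_geometry(_leaf(), n_facets=4)
    path = tmp_path / "scene.obj"
    export_obj([g], path)
    mesh = trimesh.load(path, force="mesh")
    assert mesh.area == pytest.approx(g.areas.sum(), rel=1e-6)


def test_scene_density_matches_catalogue_for_most_rows():
    hits = 0
    for s in load_table1():
        layout = build_scene(s, 6.0 if s.pattern != "ER" else 4.8, 3.0)
        rounded = int(layout.realized_density / 1000.0 + 0.5) * 1000
        hits += rounded == s.nominal_density
    assert hits >= 30
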