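"""Sky radiation: extraterrestrial integral, CSRM, dome closure, synthetic weather."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from daylily_fspm.weather_sky import (
    PPFD_PER_WATT,
    SOLAR_CONSTANT,
    SolarGeometry,
    SyntheticWeatherConfig,
    WeatherDay,
    build_sky_dome,
    csrm_clearness_ratio,
    csrm_daily_radiation,
    extraterrestrial_radiation,
    generate_synthetic_weather,
    radiation_to_ppfd,
    read_weather_csv,
    write_weather_csv,
)


def _h_o_by_integration(lat: float, doy: int) -> float:
    """Independent oracle: numeric integral of the instantaneous beam on the
    horizontal over the full day."""
    geom = SolarGeometry(lat, 0.0, doy)
    e0 = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    hours = np.linspace(0.0, 24.0, 20_001)
    sin_el = np.array([max(0.0, math.sin(geom.elevation(h))) for h in hours])
    return SOLAR_CONSTANT * e0 * float(np.trapezoid(sin_el, hours)) / 24.0


@pytest.mark.parametrize("lat,doy", [(0.0, 80), (40.13, 91), (40.13, 172), (40.13, 242)])
def test_extraterrestrial_matches_day_arc_integration(lat, doy):
    h_o = extraterrestrial_radiation(SolarGeometry(lat, 0.0, doy))
    oracle = _h_o_by_integration(lat, doy)
    assert h_o == pytest.approx(oracle, rel=2e-3)


def test_polar_night_is_zero():
    assert extraterrestrial_radiation(SolarGeometry(90.0, 0.0, 355)) == 0.0


def test_solstice_exceeds_early_spring():
    g91 = extraterrestrial_radiation(SolarGeometry(40.13, 0.0, 91))
    g172 = extraterrestrial_radiation(SolarGeometry(40.13, 0.0, 172))
    assert g172 > g91 > 0


def test_h_o_symmetric_about_solstice():
    for off in (10, 30, 50):
        a = extraterrestrial_radiation(SolarGeometry(40.13, 0.0, 172 - off))
        b = extraterrestrial_radiation(SolarGeometry(40.13, 0.0, 172 + off))
        assert abs(a - b) / a < 0.01


def test_csrm_hand_case():
    # ratio = -0.08 + 0.21*sqrt(16) - 0.012*0.4 = 0.7552
    day = WeatherDay(doy=180, tmax=30.0, tmin=14.0, cloud=0.4, rh=0.5, co2=400, wind=2.0)
    assert csrm_daily_radiation(day, 400.0) == pytest.approx(302.08, abs=1e-9)


def test_csrm_clamps_at_zero_for_no_temperature_range():
    day = WeatherDay(doy=180, tmax=20.0, tmin=20.0, cloud=0.0, rh=0.5, co2=400, wind=2.0)
    assert csrm_daily_radiation(day, 400.0) == 0.0


def test_csrm_rejects_negative_range():
    with pytest.raises(ValueError):
        csrm_clearness_ratio(10.0, 20.0, 0.2)


@given(
    dtr=st.floats(0.0, 30.0),
    cloud=st.floats(0.0, 1.0),
    extra_cloud=st.floats(0.01, 0.5),
)
@settings(max_examples=100, deadline=None)
def test_csrm_ratio_bounds_and_cloud_monotonicity(dtr, cloud, extra_cloud):
    r1 = csrm_clearness_ratio(dtr, 0.0, cloud)
    assert 0.0 <= r1 <= 1.0  # H never exceeds H_o
    r2 = csrm_clearness_ratio(dtr, 0.0, min(1.0, cloud + extra_cloud))
    assert r2 <= r1 + 1e-12  # more cloud, less radiation


def test_dome_closure_and_structure():
    geom = SolarGeometry(40.13, 113.9, 172)
    dome = build_sky_dome(300.0, geom, 0.4)
    assert dome.diffuse_directions.shape == (72, 3)
    assert np.all(dome.all_weights >= 0)
    total = float(dome.all_weights.sum())
    assert abs(total - 300.0) / 300.0 < 1e-9
    # unit direction vectors, all above the horizon
    norms = np.linalg.norm(dome.all_directions, axis=1)
    np.testing.assert_allclose(norms, 1.0, atol=1e-9)
    assert np.all(dome.diffuse_directions[:, 2] > 0)


def test_dome_zero_flux_and_overcast_limits():
    geom = SolarGeometry(40.13, 113.9, 172)
    dark = build_sky_dome(0.0, geom, 0.4)
    assert dark.total_flux == 0.0 and dark.sun_weight == 0.0
    assert np.all(dark.diffuse_weights == 0.0)
    overcast = build_sky_dome(250.0, geom, 1.0)
    assert overcast.sun_weight == pytest.approx(0.0, abs=1e-12)
    assert overcast.diffuse_weights.sum() == pytest.approx(250.0)


def test_ppfd_conversion():
    assert radiation_to_ppfd(1.0) == pytest.approx(2.275)
    assert radiation_to_ppfd(0.0) == 0.0
    assert radiation_to_ppfd(248.7) == pytest.approx(565.79, abs=0.01)
    assert PPFD_PER_WATT == 2.275
    with pytest.raises(ValueError):
        radiation_to_ppfd(-1.0)


def test_synthetic_weather_reproduces_season_statistics():
    cfg = SyntheticWeatherConfig(seed=1)
    days = generate_synthetic_weather(cfg)
    assert len(days) == 152
    tmean = np.mean([d.tmean for d in days])
    assert abs(tmean - 19.1) < 0.4
    cloud = np.mean([d.cloud for d in days])
    assert abs(cloud - 0.4) / 0.4 < 0.02
    h = np.mean(
        [
            csrm_daily_radiation(
                d, extraterrestrial_radiation(SolarGeometry(40.13, 113.9, d.doy))
            )
            for d in days
        ]
    )
    assert abs(h - 248.7) / 248.7 < 0.02


def test_synthetic_weather_deterministic_and_seed_sensitive():
    a = generate_synthetic_weather(SyntheticWeatherConfig(seed=7))
    b = generate_synthetic_weather(SyntheticWeatherConfig(seed=7))
    c = generate_synthetic_weather(SyntheticWeatherConfig(seed=8))
    assert a == b
    assert a != c


def test_synthetic_weather_rejects_infeasible_cloud():
    with pytest.raises(ValueError):
        SyntheticWeatherConfig(mean_cloud=1.4)


def test_weather_csv_round_trip(tmp_path):
    days = generate_synthetic_weather(SyntheticWeatherConfig(seed=3))[:10]
    path = tmp_path / "weather.csv"
    write_weather_csv(days, path)
    back = read_weather_csv(path)
    assert len(back) == len(days)
    for a, b in zip(back, days):
        assert a.doy == b.doy
        for f in ("tmax", "tmin", "cloud", "rh", "co2", "wind"):
            assert getattr(a, f) == pytest.approx(getattr(b, f), rel=1e-12)
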