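"""Growth-curve calibration statistics and PLS path modeling."""

import numpy as np
import pandas as pd
import pytest

from daylily_fspm.morphology import BetaGrowthParams
from daylily_fspm.stat_analysis import (
    OrganSeries,
    PlsPmSpec,
    fit_beta,
    fit_plspm,
    generate_organ_series,
    gof_metrics,
    indirect_effects,
)


def test_gof_perfect_prediction():
    y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    r2, rmse, f, p = gof_metrics(y, y)
    assert r2 == pytest.approx(1.0)
    assert rmse == pytest.approx(0.0)
    assert p < 1e-6


def test_gof_mean_prediction_gives_zero_r2():
    y = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
    r2, _, _, _ = gof_metrics(y, np.full(5, y.mean()))
    assert r2 == pytest.approx(0.0)


def test_gof_hand_computed_case():
    obs = np.array([1.0, 2.0, 2.5, 4.0, 5.0])
    pred = np.array([1.2, 1.8, 2.7, 3.8, 5.2])
    # hand arithmetic: SSE = 0.04+0.04+0.04+0.04+0.04 = 0.20,
    # SST = sum((obs-2.9)^2) = 3.61+0.81+0.16+1.21+4.41 = 10.20
    r2, rmse, f, p = gof_metrics(obs, pred)
    assert r2 == pytest.approx(1.0 - 0.20 / 10.20)
    assert rmse == pytest.approx(np.sqrt(0.20 / 5.0))
    assert f > 0 and 0 <= p < 1


def test_gof_input_validation():
    with pytest.raises(ValueError):
        gof_metrics([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        gof_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


def test_fit_beta_recovers_noise_free_parameters():
    true = BetaGrowthParams(100.0, 140.0, 180.0, 1.2)
    series = generate_organ_series(true, every=3.0, n_points=48, noise_frac=0.0)
    fit = fit_beta(series)
    assert abs(fit.params.t_m - true.t_m) < 0.5
    assert abs(fit.params.t_e - true.t_e) < 0.5
    assert abs(fit.params.w_max - true.w_max) / true.w_max < 1e-3
    assert fit.r2 > 0.999


def test_fit_beta_under_field_noise():
    """2% multiplicative noise, 48 points every 3 days: parameters recovered
    within 5% and the fit lands in the reported goodness-of-fit band."""
    true = BetaGrowthParams(91.0, 130.0, 175.0, 0.85)
    series = generate_organ_series(true, every=3.0, n_points=48, noise_frac=0.02, seed=11)
    fit = fit_beta(series)
    assert abs(fit.params.t_m - true.t_m) / (true.t_m - true.t_0) < 0.05
    assert abs(fit.params.t_e - true.t_e) / (true.t_e - true.t_0) < 0.05
    assert abs(fit.params.w_max - true.w_max) / true.w_max < 0.05
    assert fit.r2 > 0.95
    assert 0.88 <= fit.r2 <= 1.0
    assert fit.p_value < 0.05


def test_fit_beta_rejects_degenerate_series():
    flat = OrganSeries("x", np.arange(10.0), np.full(10, 2.0))
    with pytest.raises(ValueError):
        fit_beta(flat)
    with pytest.raises(ValueError):
        fit_beta(OrganSeries("x", np.arange(4.0), np.arange(4.0)))


# --- PLS-PM ----------------------------------------------------------------


def _chain_dataset(n=500, seed=1, loading=0.97):
    """Known three-construct linear chain: xi1 -(0.6)-> xi2 -(0.5)-> xi3,
    each measured by three high-reliability indicators (composite paths
    attenuate with indicator error, so path recovery to 0.05 needs
    loadings near 1)."""
    rng = np.random.default_rng(seed)

    def _std(v):
        return (v - v.mean()) / v.std(ddof=1)

    def _innov(base):
        e = rng.normal(size=n)
        e = e - base * (e @ base) / (base @ base)  # exact sample orthogonality
        return _std(e)

    xi1 = _std(rng.normal(size=n))
    xi2 = 0.6 * xi1 + np.sqrt(1 - 0.36) * _innov(xi1)
    xi3 = 0.5 * xi2 + np.sqrt(1 - 0.25) * _innov(xi2)
    cols = {}
    for name, xi in [("a", xi1), ("b", xi2), ("c", xi3)]:
        for k in range(3):
            cols[f"{name}{k}"] = loading * xi + np.sqrt(1 - loading**2) * rng.normal(size=n)
    return pd.DataFrame(cols)


def _chain_spec():
    return PlsPmSpec(
        blocks={"xi1": ["a0", "a1", "a2"], "xi2": ["b0", "b1", "b2"],
                "xi3": ["c0", "c1", "c2"]},
        paths=[("xi1", "xi2"), ("xi2", "xi3")],
    )


def test_plspm_recovers_known_chain():
    res = fit_plspm(_chain_dataset(), _chain_spec())
    assert res.converged
    assert res.paths[("xi1", "xi2")] == pytest.approx(0.6, abs=0.05)
    assert res.paths[("xi2", "xi3")] == pytest.approx(0.5, abs=0.05)
    eff = indirect_effects(res, [("xi1", "xi2", "xi3")])
    assert eff[("xi1", "xi2", "xi3")] == pytest.approx(0.30, abs=0.05)
    # indirect effect is exactly the product of the direct coefficients
    assert eff[("xi1", "xi2", "xi3")] == pytest.approx(
        res.paths[("xi1", "xi2")] * res.paths[("xi2", "xi3")], abs=1e-10
    )


def test_plspm_reliabilities_in_valid_ranges():
    res = fit_plspm(_chain_dataset(), _chain_spec())
    for c in ("xi1", "xi2", "xi3"):
        assert 0.7 < res.alpha[c] <= 1.0
        assert 0.7 < res.rho_c[c] <= 1.0
        assert 0.0 < res.ave[c] <= 1.0
    for v in res.paths.values():
        assert abs(v) <= 1.0


def test_plspm_single_indicator_construct_reliability_is_one():
    df = _chain_dataset()
    spec = PlsPmSpec(
        blocks={"xi1": ["a0", "a1", "a2"], "out": ["c0"]},
        paths=[("xi1", "out")],
    )
    res = fit_plspm(df, spec)
    assert res.alpha["out"] == res.rho_a["out"] == res.rho_c["out"] == res.ave["out"] == 1.0


def test_plspm_perfectly_correlated_indicators_alpha_one():
    rng = np.random.default_rng(0)
    x = rng.normal(size=200)
    df = pd.DataFrame({"p0": x, "p1": x.copy(), "q0": rng.normal(size=200) + 0.5 * x})
    spec = PlsPmSpec(blocks={"p": ["p0", "p1"], "q": ["q0"]}, paths=[("p", "q")])
    res = fit_plspm(df, spec)
    assert res.alpha["p"] == pytest.approx(1.0)


def test_plspm_spec_validation():
    with pytest.raises(ValueError):  # cyclic structural model
        PlsPmSpec(blocks={"a": ["a0"], "b": ["b0"]}, paths=[("a", "b"), ("b", "a")])
    with pytest.raises(ValueError):  # indicator in two blocks
        PlsPmSpec(blocks={"a": ["x"], "b": ["x"]}, paths=[("a", "b")])
    with pytest.raises(ValueError):  # unknown construct in a path
        PlsPmSpec(blocks={"a": ["a0"]}, paths=[("a", "zz")])


def test_plspm_input_validation():
    df = _chain_dataset(n=5)
    with pytest.raises(ValueError):
        fit_plspm(df, _chain_spec())  # too few rows
    df2 = _chain_dataset()
    df2.loc[0, "a0"] = np.nan
    with pytest.raises(ValueError):
        fit_plspm(df2, _chain_spec())


def test_indirect_effects_require_known_paths():
    res = fit_plspm(_chain_dataset(), _chain_spec())
    with pytest.raises(KeyError):
        indirect_effects(res, [("xi1", "xi3", "xi2")])
    with pytest.raises(ValueError):
        indirect_effects(res, [("xi1", "xi2")])
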