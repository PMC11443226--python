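"""Calibration statistics and PLS path modeling.

Three layers:

* fitting the determinate growth curve to per-organ time series (the
  calibration step that recovers t_m, t_e and the final size from
  every-3-day field-style measurements), with R2 / RMSE / F metrics;
* a generator of synthetic organ series for calibration tests;
* partial least squares path modeling (PLS-PM) over the planting-scenario
  sweep: reflective measurement blocks, Lohmoeller's iterative outer/inner
  estimation with the path weighting scheme, construct reliabilities
  (Cronbach's alpha, Dijkstra-Henseler rho_a, composite rho_c, AVE),
  structural paths by per-endogenous OLS on the construct scores, and
  specific indirect effects as products along directed chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .morphology import BetaGrowthParams, beta_growth_cumulative

__all__ = [
    "OrganSeries",
    "FitResult",
    "PlsPmSpec",
    "PlsPmResult",
    "fit_beta",
    "gof_metrics",
    "fit_plspm",
    "indirect_effects",
    "generate_organ_series",
    "build_plspm_dataset",
    "default_plspm_spec",
]


# --- growth-curve calibration ---------------------------------------------


@dataclass
class OrganSeries:
    """Observed growth of one organ: times (days) and sizes (m or g)."""

    organ_id: str
    times: np.ndarray
    values: np.ndarray
    t_0: Optional[float] = None  # birth day; defaults to the first time

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("values must be >= 0")
        if self.t_0 is None:
            self.t_0 = float(self.times[0])


@dataclass
class FitResult:
    params: BetaGrowthParams
    r2: float
    rmse: float
    f_stat: float
    p_value: float


def gof_metrics(observed, predicted, n_params: int = 2) -> tuple[float, float, float, float]:
    """R2, RMSE, regression F and its p-value for observed vs predicted.

    F is the regression F of observed ~ predicted with (1, n - 2) degrees
    of freedom.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if len(obs) != len(pred) or len(obs) < 3:
        raise ValueError("need equal-length series of at least 3 points")
    sst = float(((obs - obs.mean()) ** 2).sum())
    if sst <= 0:
        raise ValueError("observed series has zero variance")
    sse = float(((obs - pred) ** 2).sum())
    r2 = 1.0 - sse / sst
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    # regression of observed on predicted
    if float(np.ptp(pred)) == 0.0:  # constant prediction carries no signal
        return r2, rmse, 0.0, 1.0
    slope, intercept = np.polyfit(pred, obs, 1)
    fitted = slope * pred + intercept
    ssr = float(((fitted - obs.mean()) ** 2).sum())
    sse_reg = float(((obs - fitted) ** 2).sum())
    dfe = len(obs) - 2
    f = ssr / (sse_reg / dfe) if sse_reg > 0 else float("inf")
    p = float(stats.f.sf(f, 1, dfe))
    return r2, rmse, f, p


def fit_beta(series: OrganSeries) -> FitResult:
    """Least-squares fit of the cumulative growth curve to one series.

    Fits (t_m, t_e, w_max) with the birth day fixed at ``series.t_0``;
    metrics are computed between the observations and the fitted curve.
    """
    t = series.times
    y = series.values
    if len(t) < 5:
        raise ValueError("need at least 5 points spanning growth")
    if float(np.ptp(y)) <= 0:
        raise ValueError("degenerate (constant) series cannot be fitted")
    t0 = float(series.t_0)

    def model(tt, tm, te, wmax):
        te_eff = max(te, tm + 0.5)
        p = BetaGrowthParams(t0, tm, te_eff, max(wmax, 1e-12))
        return np.array([beta_growth_cumulative(x, p) for x in np.atleast_1d(tt)])

    w0 = float(y.max())
    dy = np.diff(y) / np.diff(t)
    tm0 = float(t[:-1][np.argmax(dy)]) if np.any(dy > 0) else float(t[len(t) // 2])
    above = t[y >= 0.95 * w0]
    te0 = float(above[0]) if len(above) else float(t[-1])
    tm0 = min(max(tm0, t0 + 1.0), te0 - 1.0)
    span = float(t[-1] - t0)
    popt, _ = optimize.curve_fit(
        model, t, y, p0=[tm0, max(te0, tm0 + 2.0), w0],
        bounds=([t0 + 0.5, t0 + 1.5, 1e-9], [t0 + 3 * span, t0 + 3 * span, 10 * w0]),
        maxfev=20_000,
    )
    tm, te, wmax = popt
    te = max(te, tm + 0.5)
    params = BetaGrowthParams(t0, float(tm), float(te), float(wmax))
    pred = model(t, *popt)
    r2, rmse, f, p = gof_metrics(y, pred)
    return FitResult(params=params, r2=r2, rmse=rmse, f_stat=f, p_value=p)


def generate_organ_series(
    params: BetaGrowthParams,
    every: float = 3.0,
    n_points: int = 48,
    noise_frac: float = 0.02,
    seed: int = 0,
    organ_id: str = "organ",
) -> OrganSeries:
    """Synthetic every-``every``-days organ measurements with multiplicative
    Gaussian noise (sd = noise_frac x w_max), emulating a field campaign."""
    rng = np.random.default_rng(seed)
    t = params.t_0 + every * np.arange(n_points)
    y = np.array([beta_growth_cumulative(x, params) for x in t])
    y = np.maximum(0.0, y + rng.normal(0.0, noise_frac * params.w_max, n_points))
    return OrganSeries(organ_id=organ_id, times=t, values=y, t_0=params.t_0)


# --- PLS path modeling ----------------------------------------------------


@dataclass
class PlsPmSpec:
    """Reflective measurement blocks + directed structural paths (a DAG)."""

    blocks: Mapping[str, Sequence[str]]
    paths: Sequence[tuple[str, str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for c, cols in self.blocks.items():
            for col in cols:
                if col in seen:
                    raise ValueError(f"indicator {col!r} in both {seen[col]!r} and {c!r}")
                seen[col] = c
        for a, b in self.paths:
            if a not in self.blocks or b not in self.blocks:
                raise ValueError(f"path {a} -> {b} references unknown construct")
        self.order = self._toposort()

    def _toposort(self) -> list[str]:
        nodes = list(self.blocks)
        incoming = {n: set() for n in nodes}
        for a, b in self.paths:
            incoming[b].add(a)
        order, ready = [], [n for n in nodes if not incoming[n]]
        pending = {n: set(v) for n, v in incoming.items()}
        while ready:
            n = ready.pop()
            order.append(n)
            for m in nodes:
                if n in pending[m]:
                    pending[m].discard(n)
                    if not pending[m] and m not in order and m not in ready:
                        ready.append(m)
        if len(order) != len(nodes):
            raise ValueError("structural model must be acyclic")
        return order

    def predecessors(self, c: str) -> list[str]:
        return [a for a, b in self.paths if b == c]

    def successors(self, c: str) -> list[str]:
        return [b for a, b in self.paths if a == c]


@dataclass
class PlsPmResult:
    weights: dict  # construct -> {indicator: outer weight}
    loadings: dict  # construct -> {indicator: loading}
    paths: dict  # (source, target) -> standardized coefficient
    alpha: dict
    rho_a: dict
    rho_c: dict
    ave: dict
    r_squared: dict
    scores: pd.DataFrame
    iterations: int
    converged: bool


def fit_plspm(
    data: pd.DataFrame,
    spec: PlsPmSpec,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> PlsPmResult:
    """Lohmoeller-style PLS-PM with the path weighting scheme.

    Indicators are standardized internally; scores are unit-variance; inner
    paths are per-endogenous OLS on scores; reliabilities follow the
    standard formulas (rho_a in the Dijkstra-Henseler form).
    """
    if len(data) < 10:
        raise ValueError("need at least 10 rows")
    cols = [c for cols in spec.blocks.values() for c in cols]
    if data[cols].isna().any().any():
        raise ValueError("missing values in indicator columns")
    n = len(data)
    X = {}
    for c, bcols in spec.blocks.items():
        x = data[list(bcols)].to_numpy(dtype=float)
        sd = x.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            raise ValueError(f"constant indicator in block {c!r}")
        X[c] = (x - x.mean(axis=0)) / sd

    constructs = list(spec.blocks)
    w = {c: np.ones(X[c].shape[1]) for c in constructs}

    def make_scores(wts):
        sc = {}
        for c in constructs:
            s = X[c] @ wts[c]
            sd = s.std(ddof=1)
            sc[c] = s / (sd if sd > 0 else 1.0)
        return sc

    scores = make_scores(w)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # inner weights, path scheme
        inner = {}
        for c in constructs:
            z = np.zeros(n)
            preds = spec.predecessors(c)
            if preds:
                Zp = np.column_stack([scores[p] for p in preds])
                beta, *_ = np.linalg.lstsq(Zp, scores[c], rcond=None)
                z = z + Zp @ beta
            for s in spec.successors(c):
                r = float(np.corrcoef(scores[c], scores[s])[0, 1])
                z = z + r * scores[s]
            if not preds and not spec.successors(c):
                z = scores[c]
            sd = z.std(ddof=1)
            inner[c] = z / (sd if sd > 0 else 1.0)
        # outer weights, mode A
        w_new = {}
        for c in constructs:
            wc = X[c].T @ inner[c] / (n - 1)
            if wc.sum() < 0:
                wc = -wc
            w_new[c] = wc
        new_scores = make_scores(w_new)
        delta = max(
            float(np.max(np.abs(np.abs(w_new[c]) / np.linalg.norm(w_new[c])
                                - np.abs(w[c]) / np.linalg.norm(w[c]))))
            for c in constructs
        )
        w, scores = w_new, new_scores
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(f"PLS-PM did not converge in {max_iter} iterations")

    loadings = {
        c: {
            col: float(np.corrcoef(X[c][:, k], scores[c])[0, 1])
            for k, col in enumerate(spec.blocks[c])
        }
        for c in constructs
    }
    # orient each construct so loadings are predominantly positive
    for c in constructs:
        if sum(loadings[c].values()) < 0:
            scores[c] = -scores[c]
            w[c] = -w[c]
            loadings[c] = {k: -v for k, v in loadings[c].items()}

    path_coefs = {}
    r2 = {}
    for c in constructs:
        preds = spec.predecessors(c)
        if not preds:
            continue
        Zp = np.column_stack([scores[p] for p in preds])
        beta, *_ = np.linalg.lstsq(Zp, scores[c], rcond=None)
        for p_name, b in zip(preds, beta):
            path_coefs[(p_name, c)] = float(b)
        fitted = Zp @ beta
        r2[c] = float(1.0 - ((scores[c] - fitted) ** 2).sum() / ((scores[c]) ** 2).sum())

    alpha, rho_a, rho_c, ave = {}, {}, {}, {}
    for c in constructs:
        k = X[c].shape[1]
        lam = np.array([loadings[c][col] for col in spec.blocks[c]])
        if k == 1:
            alpha[c] = rho_a[c] = rho_c[c] = ave[c] = 1.0
            continue
        S = np.corrcoef(X[c], rowvar=False)
        rbar = (S.sum() - k) / (k * (k - 1))
        alpha[c] = float(k * rbar / (1.0 + (k - 1) * rbar))
        sl = np.abs(lam).sum()
        rho_c[c] = float(sl**2 / (sl**2 + (1.0 - lam**2).sum()))
        ave[c] = float((lam**2).mean())
        wc = w[c] / np.linalg.norm(w[c])
        off_S = S - np.diag(np.diag(S))
        ww = np.outer(wc, wc)
        off_ww = ww - np.diag(np.diag(ww))
        denom = float(wc @ off_ww @ wc)
        rho_a[c] = float((wc @ wc) ** 2 * (wc @ off_S @ wc) / denom) if denom != 0 else 1.0

    return PlsPmResult(
        weights={c: dict(zip(spec.blocks[c], w[c])) for c in constructs},
        loadings=loadings,
        paths=path_coefs,
        alpha=alpha, rho_a=rho_a, rho_c=rho_c, ave=ave, r_squared=r2,
        scores=pd.DataFrame(scores),
        iterations=it,
        converged=converged,
    )


def indirect_effects(
    result: PlsPmResult, chains: Sequence[Sequence[str]]
) -> dict[tuple[str, ...], float]:
    """Specific indirect effects: the product of direct coefficients along
    each chain of structural paths."""
    out = {}
    for chain in chains:
        if len(chain) < 3:
            raise ValueError("a chain needs at least one mediator")
        eff = 1.0
        for a, b in zip(chain[:-1], chain[1:]):
            if (a, b) not in result.paths:
                raise KeyError(f"path {a} -> {b} not in the structural model")
            eff *= result.paths[(a, b)]
        out[tuple(chain)] = eff
    return out


# --- sweep -> PLS-PM dataset ----------------------------------------------

_PATTERN_CODE = {"DRBR": 1.0, "ER": 2.0, "NWR": 3.0}
_WINDOWS = {"early": (91, 130), "mid": (130, 180), "late": (180, 243)}


def build_plspm_dataset(sweep) -> pd.DataFrame:
    """Per-scenario indicator table from a sweep.

    Configuration blocks come straight from the catalogue geometry; the
    physiological blocks are growth-stage-window means of the daily canopy
    aggregates (leaf radiation as PPFD, leaf temperature, leaf net
    photosynthesis); the bud block is the final per-scape bud dry mass.
    """
    table, daily = sweep.table, sweep.daily
    rows = []
    for _, r in table.iterrows():
        d = daily[daily["scenario_id"] == r["id"]]
        row = {
            "id": r["id"],
            "pattern_code": _PATTERN_CODE[r["pattern"]],
            "wide_m": r["wide"],
            "narrow_m": r["narrow"],
            "wn_m": r["wn"],
            "spacing_m": r["spacing"],
            "density": r["density_realized"],
            "bud_dm_g": r["bud_dm_g"],
        }
        for wname, (lo, hi) in _WINDOWS.items():
            win = d[(d["day"] >= lo) & (d["day"] < hi)]
            row[f"ppfd_{wname}"] = float(win["mean_ppfd"].mean())
            row[f"tleaf_{wname}"] = float(win["mean_tleaf_c"].mean())
            row[f"anet_{wname}"] = float(win["mean_anet"].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def default_plspm_spec() -> PlsPmSpec:
    """Construct/indicator map and structural graph for the sweep analysis.

    Configuration constructs (pattern, row distance, plant spacing,
    density) drive leaf radiation; radiation drives leaf temperature; both
    drive leaf photosynthesis; photosynthesis drives the bud outcome.
    """
    blocks = {
        "pattern": ["pattern_code"],
        "row_distance": ["wn_m", "wide_m", "narrow_m"],
        "spacing": ["spacing_m"],
        "density": ["density"],
        "leaf_radiation": ["ppfd_early", "ppfd_mid", "ppfd_late"],
        "leaf_temperature": ["tleaf_early", "tleaf_mid", "tleaf_late"],
        "leaf_photosynthesis": ["anet_early", "anet_mid", "anet_late"],
        "bud": ["bud_dm_g"],
    }
    paths = [
        ("pattern", "leaf_radiation"),
        ("row_distance", "leaf_radiation"),
        ("spacing", "leaf_radiation"),
        ("density", "leaf_radiation"),
        ("leaf_radiation", "leaf_temperature"),
        ("leaf_radiation", "leaf_photosynthesis"),
        ("leaf_temperature", "leaf_photosynthesis"),
        ("leaf_photosynthesis", "bud"),
    ]
    return PlsPmSpec(blocks=blocks, paths=paths)
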