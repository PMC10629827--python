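"""Cellular retinol accumulation kinetics: partitioning models and fits.

Free retinol accumulates in barrier cells in proportion to the fluid-phase
concentration ``c_f``.  Two nested models describe the normalized cellular
concentration ``c_cell / c_f``:

Model 1 — simple first-order partitioning,

    c_cell / c_f = Kp * (1 - exp(-k1 * t))

with partition coefficient Kp (µM cell per µM fluid) and rate constant k1
(1/min).  Model 2 adds a second uptake phase that is triggered once the
cellular concentration crosses a threshold c*, i.e. after a lag

    t_lag = -ln(1 - c* / (Kp * c_f)) / k1

    c_cell / c_f = Kp  * (1 - exp(-k1  * t))
                 + Kp* * (1 - exp(-k1* * (t - t_lag)))   for t >= t_lag

with the second term clamped to zero before the lag, which makes the curve
continuous at t_lag.  When c* >= Kp * c_f the first phase alone can never
reach the threshold and the second phase stays inactive (t_lag = +inf).
Model 1 is the Kp* = 0 special case of model 2, so the extra-sum-of-squares
F-test applies for model selection.

The biological reading of the threshold is saturation of the intracellular
retinol-buffering capacity (CRBP1-like), beyond which a secondary storage
route (retinyl-ester synthesis) engages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

__all__ = [
    "UptakeParams1",
    "UptakeParams2",
    "Timecourse",
    "UptakeFit",
    "ModelComparison",
    "UptakeError",
    "model1_predict",
    "lag_time",
    "model2_predict",
    "fit_uptake",
    "compare_models",
    "free_contribution_fraction",
]

_EXP_CLIP = 700.0  # largest safe argument for exp()


class UptakeError(ValueError):
    """Invalid uptake-kinetics input."""


@dataclass(frozen=True)
class UptakeParams1:
    """Single-phase partitioning parameters."""

    Kp: float
    k1: float

    def __post_init__(self) -> None:
        if self.Kp < 0 or self.k1 < 0:
            raise UptakeError("Kp and k1 must be non-negative")


@dataclass(frozen=True)
class UptakeParams2:
    """Biphasic (threshold-triggered) partitioning parameters.

    ``c_star`` is the cellular concentration (µM) at which the second
    phase engages; the per-condition lag time is derived from it, never
    stored independently.
    """

    Kp: float
    k1: float
    Kp_star: float
    k1_star: float
    c_star: float

    def __post_init__(self) -> None:
        if min(self.Kp, self.k1, self.Kp_star, self.k1_star, self.c_star) < 0:
            raise UptakeError("all biphasic parameters must be non-negative")

    def t_lag(self, c_fluid: float) -> float:
        return lag_time(self.c_star, self.Kp, c_fluid, self.k1)


@dataclass
class Timecourse:
    """One accumulation time course at a fixed fluid-phase concentration.

    ``c_cell`` is (n_replicates, n_times), µM.  The fluid concentration is
    treated as constant over the assay (bulk depletion is negligible on the
    2 h scale at these volumes).
    """

    label: str
    c_fluid: float
    times: np.ndarray
    c_cell: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.c_cell = np.atleast_2d(np.asarray(self.c_cell, dtype=float))
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0) or self.times[0] < 0:
            raise UptakeError("times must be 1-D, strictly increasing, starting >= 0")
        if self.c_cell.shape[1] != self.times.size:
            raise UptakeError("c_cell must have one column per time point")
        if np.any(self.c_cell < 0):
            raise UptakeError("c_cell must be non-negative")
        if not self.c_fluid > 0:
            raise UptakeError("c_fluid must be positive")

    @property
    def mean(self) -> np.ndarray:
        return self.c_cell.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.c_cell.std(axis=0, ddof=1) if self.c_cell.shape[0] > 1 else np.zeros_like(self.times)


def _expm1_neg(x: np.ndarray) -> np.ndarray:
    """1 - exp(-x) for x >= 0, overflow-safe."""
    return -np.expm1(-np.clip(x, 0.0, _EXP_CLIP))


def model1_predict(t, c_fluid: float, p: UptakeParams1):
    """Cellular concentration (µM) under single-phase partitioning."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise UptakeError("t must be non-negative")
    out = c_fluid * p.Kp * _expm1_neg(p.k1 * t)
    return float(out) if out.ndim == 0 else out


def lag_time(c_star: float, Kp: float, c_fluid: float, k1: float) -> float:
    """Time for the first phase to reach the triggering concentration c*.

    Returns +inf when the single-phase plateau Kp*c_fluid never reaches
    c*, i.e. the second phase stays inactive for that condition.
    """
    if c_star < 0:
        raise UptakeError("c_star must be non-negative")
    if not (Kp > 0 and c_fluid > 0 and k1 > 0):
        raise UptakeError("Kp, c_fluid, k1 must be positive")
    if c_star == 0:
        return 0.0
    plateau = Kp * c_fluid
    if c_star >= plateau:
        return math.inf
    return -math.log1p(-c_star / plateau) / k1


def model2_predict(t, c_fluid: float, p: UptakeParams2):
    """Cellular concentration (µM) under the threshold-triggered model."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise UptakeError("t must be non-negative")
    out = c_fluid * p.Kp * _expm1_neg(p.k1 * t)
    if p.Kp_star > 0 and p.Kp > 0 and p.k1 > 0:
        tl = lag_time(p.c_star, p.Kp, c_fluid, p.k1)
        if math.isfinite(tl):
            active = t >= tl
            second = c_fluid * p.Kp_star * _expm1_neg(p.k1_star * (t - tl))
            out = out + np.where(active, second, 0.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class UptakeFit:
    """Least-squares fit of one uptake model to one or more time courses."""

    model: int
    params: dict
    se: dict
    ssr: float
    n_obs: int
    n_params: int
    normalized: bool
    t_lag: dict = field(default_factory=dict)
    flagged: list = field(default_factory=list)

    def as_params(self):
        if self.model == 1:
            return UptakeParams1(self.params["Kp"], self.params["k1"])
        return UptakeParams2(
            self.params["Kp"], self.params["k1"],
            self.params["Kp_star"], self.params["k1_star"], self.params["c_star"],
        )

    @property
    def aic(self) -> float:
        """Gaussian-likelihood AIC (up to an additive constant shared by nested fits)."""
        return self.n_obs * math.log(self.ssr / self.n_obs) + 2 * (self.n_params + 1)


_PARAM_NAMES = {1: ("Kp", "k1"), 2: ("Kp", "k1", "Kp_star", "k1_star", "c_star")}


def _residuals(theta: np.ndarray, model: int, tcs: list[Timecourse], normalized: bool) -> np.ndarray:
    if model == 1:
        p = UptakeParams1(max(theta[0], 0.0), max(theta[1], 0.0))
        predict = model1_predict
    else:
        p = UptakeParams2(*np.maximum(theta, 0.0))
        predict = model2_predict
    res = []
    for tc in tcs:
        pred = predict(tc.times, tc.c_fluid, p)
        obs = tc.c_cell
        if normalized:
            pred = pred / tc.c_fluid
            obs = obs / tc.c_fluid
        res.append((obs - pred[None, :]).ravel())
    return np.concatenate(res)


def _heuristic_start(tcs: list[Timecourse], model: int) -> np.ndarray:
    """Data-driven initial guess: plateau of the lowest-concentration curve
    sets Kp; the half-rise time sets k1; the excess of the highest curve
    seeds the second phase."""
    lo = min(tcs, key=lambda tc: tc.c_fluid)
    hi = max(tcs, key=lambda tc: tc.c_fluid)
    kp0 = max(lo.mean[-1] / lo.c_fluid, 1.0)
    # time at which the low curve reaches ~half its final value
    half = 0.5 * lo.mean[-1]
    idx = int(np.searchsorted(lo.mean, half))
    t_half = lo.times[min(idx, lo.times.size - 1)] or lo.times[1]
    k10 = math.log(2.0) / max(t_half, 1e-6)
    if model == 1:
        return np.array([kp0, k10])
    excess = max(hi.mean[-1] / hi.c_fluid - kp0, 1.0)
    cstar0 = max(0.5 * kp0 * hi.c_fluid, lo.c_fluid * kp0)
    return np.array([kp0, k10, excess, 0.5 * k10, cstar0])


def fit_uptake(
    timecourses: list[Timecourse] | Timecourse,
    model: int = 2,
    *,
    shared: bool = True,
    normalized: bool = True,
    n_starts: int = 10,
    seed: int = 0,
) -> UptakeFit | dict[str, UptakeFit]:
    """Fit model 1 or model 2 to accumulation time courses.

    With ``shared=True`` (default) a single global parameter set is fit
    jointly across all conditions; with ``shared=False`` each condition is
    fit independently and a dict keyed by label is returned.  Optimization
    is bounded nonlinear least squares with a data-driven start plus
    ``n_starts`` log-uniform multistarts (fixed ``seed``); the lowest SSR
    wins, ties broken by first occurrence.
    """
    if model not in (1, 2):
        raise UptakeError("model must be 1 or 2")
    if isinstance(timecourses, Timecourse):
        timecourses = [timecourses]
    if not shared:
        return {
            tc.label: fit_uptake([tc], model, shared=True, normalized=normalized,
                                 n_starts=n_starts, seed=seed)
            for tc in timecourses
        }
    for tc in timecourses:
        if tc.times.size < 4:
            raise UptakeError(f"condition {tc.label!r} has fewer than 4 time points")

    names = _PARAM_NAMES[model]
    k = len(names)
    rng = np.random.default_rng(seed)
    starts = [_heuristic_start(timecourses, model)]
    lo_bounds = np.zeros(k)
    hi_bounds = np.full(k, 1e4)
    for _ in range(max(n_starts - 1, 0)):
        draw = [10 ** rng.uniform(0.0, 2.5), 10 ** rng.uniform(-2.5, -0.5)]
        if model == 2:
            draw += [10 ** rng.uniform(0.0, 2.5), 10 ** rng.uniform(-2.5, -0.5),
                     10 ** rng.uniform(0.0, 2.5)]
        starts.append(np.array(draw))

    best = None
    for x0 in starts:
        try:
            sol = least_squares(
                _residuals, np.clip(x0, lo_bounds + 1e-8, hi_bounds),
                args=(model, timecourses, normalized),
                bounds=(lo_bounds, hi_bounds), method="trf", xtol=1e-12, ftol=1e-12,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    if best is None:
        raise UptakeError("all optimization starts failed")

    theta = best.x
    resid = _residuals(theta, model, timecourses, normalized)
    ssr = float(resid @ resid)
    n = resid.size
    dof = max(n - k, 1)
    s2 = ssr / dof
    J = best.jac
    JTJ = J.T @ J
    flagged: list[str] = []
    try:
        cov = s2 * np.linalg.inv(JTJ)
        se_vals = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(JTJ)
        se_vals = np.sqrt(np.maximum(np.diag(cov), 0.0))
        flagged = list(names)
    cond = np.linalg.cond(JTJ)
    if cond > 1e12:
        flagged = sorted(set(flagged) | set(names))
        import warnings

        warnings.warn(
            f"uptake fit may be unidentifiable (condition number {cond:.2g}); "
            f"parameter SEs unreliable", stacklevel=2,
        )

    params = dict(zip(names, theta))
    fit = UptakeFit(
        model=model, params=params, se=dict(zip(names, se_vals)), ssr=ssr,
        n_obs=n, n_params=k, normalized=normalized, flagged=flagged,
    )
    if model == 2:
        p2 = fit.as_params()
        fit.t_lag = {tc.label: p2.t_lag(tc.c_fluid) for tc in timecourses}
    return fit


@dataclass(frozen=True)
class ModelComparison:
    """Extra-sum-of-squares comparison of nested uptake fits."""

    f_stat: float
    p_value: float
    df: tuple[int, int]
    aic1: float
    aic2: float

    @property
    def prefers_model2(self) -> bool:
        return self.p_value < 0.05


def compare_models(fit1: UptakeFit, fit2: UptakeFit) -> ModelComparison:
    """Extra-sum-of-squares F-test of model 1 against model 2.

    Model 1 (2 parameters) is nested in model 2 (5 parameters); both fits
    must be on the same data (same n_obs) and normalization.
    """
    if fit1.model != 1 or fit2.model != 2:
        raise UptakeError("compare_models expects (model-1 fit, model-2 fit)")
    if fit1.n_obs != fit2.n_obs or fit1.normalized != fit2.normalized:
        raise UptakeError("fits are not on the same data")
    df1 = fit2.n_params - fit1.n_params
    df2 = fit2.n_obs - fit2.n_params
    if df2 <= 0:
        raise UptakeError("not enough observations for the F-test")
    if fit2.ssr <= 0:
        return ModelComparison(math.inf, 0.0, (df1, df2), fit1.aic, fit2.aic)
    f = max((fit1.ssr - fit2.ssr) / df1, 0.0) / (fit2.ssr / df2)
    p = float(stats.f.sf(f, df1, df2))
    return ModelComparison(f, p, (df1, df2), fit1.aic, fit2.aic)


def free_contribution_fraction(
    free_tc: Timecourse, bound_tc: Timecourse
) -> tuple[np.ndarray, np.ndarray]:
    """Percent of protein-delivered accumulation attributable to free ROH.

    ``free_tc`` is the accumulation measured at the speciation-matched free
    concentration alone; ``bound_tc`` the accumulation from the protein
    preparation.  Free means are linearly interpolated onto the bound time
    grid when the grids differ.  Points where the denominator is zero
    (typically t = 0) are omitted rather than propagated as NaN.

    Returns ``(times, percent)``.
    """
    free_mean = np.interp(bound_tc.times, free_tc.times, free_tc.mean)
    denom = bound_tc.mean
    keep = denom > 0
    return bound_tc.times[keep], 100.0 * free_mean[keep] / denom[keep]
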