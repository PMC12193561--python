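"""The STETI estimation pipeline.

The pipeline has five stages:

1. *Base fit* — fit the trend family to the fully observed diagnosis-year
   cohort averages (ordinary least squares; spreadsheet-style log-linear
   least squares for the exponential family).
2. *Anchor* — take the most recent usable diagnosis year t_r and the base
   curve's height S_r there; the updated curve is constrained to pass
   through (t_r, S_r).
3. *Steepness regression* — with the anchor fixed, regress the single
   steepness parameter of the induced death-year relation against the
   end-cohort averages, which include data too recent for the base fit.
4. *Back-transform* — the result is already a start-time model (the
   death-year relation is evaluated through it), so the updated
   diagnosis-year curve is immediate.
5. *Compare and project* — Gaussian least-squares AIC, relative likelihood
   exp(Δ/2) between model families, likelihood-threshold uncertainty bands,
   and a combined headline projection.

For the linear family the death-year relation
``S_te(te) = S_r + u (te − S_r − t_r)`` with ``u = M/(M+1)`` is linear in
u, so the steepness regression is a closed-form one-parameter least
squares through the anchored origin; nonlinear families use bounded 1-D
minimization over the steepness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

from steti.cohorts import CohortTable
from steti.trendmodels import Family, TrendModel, eval_end, eval_start

#: RSS floor keeping the Gaussian AIC finite on perfect fits.
RSS_FLOOR = 1e-12

_LN2 = math.log(2.0)
#: Steepness search bounds: linear u in (-0.99, 0.99); exponential |d| in
#: [1, 10000] years, sign-matched to the data trend; logistic |k| <= 10.
_U_BOUND = 0.99
_D_MIN, _D_MAX = 1.0, 10000.0
_K_BOUND = 10.0

__all__ = [
    "FitResult",
    "ProjectionBand",
    "fit_base",
    "anchor_from_base",
    "fit_steti_steepness",
    "goodness_of_fit",
    "relative_likelihood",
    "uncertainty_band",
    "combine_projections",
]


@dataclass(frozen=True)
class FitResult:
    """A fitted trend model with its residual diagnostics."""

    model: TrendModel
    n: int
    k: int
    residuals: tuple[float, ...]
    rss: float
    rmse: float
    aic: float

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "n": self.n,
            "k": self.k,
            "residuals": list(self.residuals),
            "rss": self.rss,
            "rmse": self.rmse,
            "aic": self.aic,
        }


@dataclass(frozen=True)
class ProjectionBand:
    """Point projection plus the spread of likelihood-plausible variations.

    ``lo`` and ``hi`` bound the projections at ``target_year`` over all
    steepness variations whose relative likelihood against the best fit is
    at least ``threshold``.
    """

    target_year: float
    point: float
    lo: float
    hi: float
    threshold: float

    def __post_init__(self) -> None:
        if not (self.lo <= self.point <= self.hi):
            raise ValueError(
                f"band [{self.lo}, {self.hi}] does not contain point {self.point}"
            )


def _gaussian_aic(rss: float, n: int, k: int) -> float:
    """AIC for Gaussian least squares up to a constant: n ln(RSS/n) + 2k."""
    return n * math.log(max(rss, RSS_FLOOR) / n) + 2 * k


def goodness_of_fit(
    observed: CohortTable,
    model: TrendModel,
    evaluator: Literal["start", "end"],
    k: int,
) -> tuple[float, float, float]:
    """(RSS, RMSE, AIC) of a model against a cohort table.

    ``evaluator`` selects whether cohort years are interpreted as diagnosis
    years (start-time curve) or death years (induced end-time relation).
    """
    resid = _residuals(observed, model, evaluator)
    n = resid.size
    rss = float(resid @ resid)
    rmse = math.sqrt(rss / n)
    return rss, rmse, _gaussian_aic(rss, n, k)


def _residuals(
    observed: CohortTable, model: TrendModel, evaluator: Literal["start", "end"]
) -> np.ndarray:
    f = eval_start if evaluator == "start" else eval_end
    return observed.means - np.asarray(f(model, observed.years), dtype=float)


def _fit_result(
    observed: CohortTable,
    model: TrendModel,
    evaluator: Literal["start", "end"],
    k: int,
) -> FitResult:
    resid = _residuals(observed, model, evaluator)
    n = resid.size
    rss = float(resid @ resid)
    return FitResult(
        model=model,
        n=n,
        k=k,
        residuals=tuple(float(r) for r in resid),
        rss=rss,
        rmse=math.sqrt(rss / n),
        aic=_gaussian_aic(rss, n, k),
    )


def fit_base(
    start_table: CohortTable,
    family: Family,
    method: Literal["loglinear", "nls"] = "loglinear",
    L: float | None = None,
) -> FitResult:
    """Fit the trend family to diagnosis-year cohort averages.

    The linear family is ordinary least squares.  The exponential family
    defaults to log-linear least squares on ln(mean) — the way spreadsheet
    exponential trendlines work — converted to an anchored doubling-time
    form; ``method="nls"`` instead minimizes squared error on the original
    scale.  The logistic family (ceiling ``L``, default the observation
    window) is nonlinear least squares with k = 3 free parameters.
    Residuals, RSS, RMSE and AIC are always on the original (years) scale.
    """
    years, means = start_table.years, start_table.means
    k = 3 if family == "logistic" else 2
    min_pts = 3 if family == "logistic" else 2
    if len(start_table) < min_pts:
        raise ValueError(
            f"{family} base fit needs at least {min_pts} start-cohort points, "
            f"got {len(start_table)}"
        )
    t0 = float(years[0])

    if family == "linear":
        slope, intercept = np.polyfit(years, means, 1)
        model = TrendModel("linear", t0, float(intercept + slope * t0), float(slope))
    elif family == "exponential":
        if np.any(means <= 0):
            raise ValueError("exponential fit requires positive cohort means")
        rate, logint = np.polyfit(years, np.log(means), 1)
        S0 = float(np.exp(logint + rate * t0))
        d = _LN2 / rate if rate != 0 else 1e12  # rate 0: effectively flat
        model = TrendModel("exponential", t0, S0, float(d))
        if method == "nls":
            p0 = (S0, model.theta)
            popt, _ = curve_fit(
                lambda t, S0_, d_: S0_ * np.exp2((t - t0) / d_), years, means, p0=p0
            )
            model = TrendModel("exponential", t0, float(popt[0]), float(popt[1]))
        elif method != "loglinear":
            raise ValueError(f"unknown exponential fit method {method!r}")
    elif family == "logistic":
        L = float(L if L is not None else start_table.window_N)
        if np.any(means >= L):
            raise ValueError(f"logistic fit requires cohort means below L={L}")
        p0 = (float(means[0]), 0.05)
        popt, _ = curve_fit(
            lambda t, S0_, k_: L / (1.0 + (L - S0_) / S0_ * np.exp(-k_ * (t - t0))),
            years,
            means,
            p0=p0,
            bounds=([1e-9, -_K_BOUND], [L - 1e-9, _K_BOUND]),
            maxfev=20000,
        )
        model = TrendModel("logistic", t0, float(popt[0]), float(popt[1]), L=L)
    else:
        raise ValueError(f"unknown model family {family!r}")
    return _fit_result(start_table, model, "start", k)


def anchor_from_base(
    base: FitResult, start_table: CohortTable
) -> tuple[float, float]:
    """Anchor (t_r, S_r): last usable diagnosis year and the fitted curve's
    height there (the curve's height, not the raw data point)."""
    t_r = float(start_table.years[-1])
    return t_r, float(eval_start(base.model, t_r))


def _model_from_internal(
    family: Family, p: float, t_r: float, S_r: float, L: float | None
) -> TrendModel:
    """Map the internal steepness coordinate to an anchored model.

    linear: p = u = M/(M+1); exponential: p = signed growth rate per year,
    d = ln2/p; logistic: p = k directly.  The internal coordinate keeps the
    1-D search well behaved near flat trends (u, rate and k all pass
    smoothly through 0 where the doubling time diverges).
    """
    if family == "linear":
        return TrendModel("linear", t_r, S_r, p / (1.0 - p))
    if family == "exponential":
        return TrendModel("exponential", t_r, S_r, _LN2 / p)
    return TrendModel("logistic", t_r, S_r, p, L=L)


def _internal_of(model: TrendModel) -> float:
    """Inverse of _model_from_internal for a fitted model's steepness."""
    if model.family == "linear":
        return model.theta / (1.0 + model.theta)
    if model.family == "exponential":
        return _LN2 / model.theta
    return model.theta


def _internal_domain(family: Family) -> tuple[float, float]:
    if family == "linear":
        return -_U_BOUND, _U_BOUND
    if family == "exponential":
        return -_LN2 / _D_MIN, _LN2 / _D_MIN
    return -_K_BOUND, _K_BOUND


def fit_steti_steepness(
    anchor: tuple[float, float],
    family: Family,
    end_table: CohortTable,
    L: float | None = None,
) -> FitResult:
    """Regress the steepness of the anchored model on end-cohort data.

    The returned model is the *start-time* model through the anchor whose
    induced death-year relation best fits the end-cohort averages in least
    squares; k = 1 (the anchor is fixed, not estimated from this data).
    With a single end-cohort point the steepness solves it exactly.
    """
    t_r, S_r = float(anchor[0]), float(anchor[1])
    if len(end_table) < 1:
        raise ValueError("steepness regression needs at least one end-cohort point")
    if S_r <= 0:
        raise ValueError(f"anchor value must be positive, got {S_r}")

    if family == "linear":
        # S_te(te) = S_r + u (te - S_r - t_r) is linear in u through the
        # anchored origin: closed-form slope of a no-intercept regression.
        x = end_table.years - S_r - t_r
        y = end_table.means - S_r
        sxx = float(x @ x)
        u = float(x @ y) / sxx if sxx > 0 else 0.0
        if u >= 1.0:
            raise ValueError(
                f"end-cohort trend implies u = M/(M+1) = {u:.4f} >= 1 "
                "(infinite diagnosis-year slope)"
            )
        model = TrendModel("linear", t_r, S_r, u / (1.0 - u))
    elif family in ("exponential", "logistic"):
        if family == "logistic":
            L = float(L if L is not None else end_table.window_N)
            if S_r >= L:
                raise ValueError(f"anchor {S_r} must lie below the ceiling L={L}")

        def rss_of(p: float) -> float:
            m = _model_from_internal(family, p, t_r, S_r, L)
            try:
                r = _residuals(end_table, m, "end")
            except ValueError:
                # steepness for which some death years are unattainable
                return 1e30
            return float(r @ r)

        # Sign-match the search to the data trend, then minimize |steepness|
        # magnitude on that side (ties broken toward the flatter model by
        # the lower search bound).
        x = end_table.years - S_r - t_r
        y = end_table.means - S_r
        sign = 1.0 if float(x @ y) >= 0 else -1.0
        if family == "exponential":
            lo, hi = _LN2 / _D_MAX, _LN2 / _D_MIN
        else:
            lo, hi = 1e-7, _K_BOUND
        res = minimize_scalar(
            lambda q: rss_of(sign * q),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-12},
        )
        model = _model_from_internal(family, sign * float(res.x), t_r, S_r, L)
    else:
        raise ValueError(f"unknown model family {family!r}")
    return _fit_result(end_table, model, "end", k=1)


def relative_likelihood(aic_a: float, aic_b: float) -> float:
    """AIC evidence ratio exp(Δ/2) with Δ = AIC_min − AIC_other.

    Symmetric in its arguments, always in (0, 1], and 1 exactly when the
    AICs are equal; values near 1 mean no preference between the models.
    """
    return math.exp(-abs(aic_a - aic_b) / 2.0)


def uncertainty_band(
    anchor: tuple[float, float],
    family: Family,
    end_table: CohortTable,
    target_year: float,
    threshold: float = 0.5,
    L: float | None = None,
    grid_size: int = 801,
) -> ProjectionBand:
    """Projection range over steepness variations that remain plausible.

    A dense grid of steepness values spanning the family's search domain is
    scored against the end-cohort data with the anchor fixed; variations
    whose relative likelihood against the best fit is >= ``threshold`` are
    retained and the band is the min/max of their start-time projections at
    ``target_year``.  A lower threshold retains more variations, so its
    band contains that of any higher threshold.  On a (near-)perfect best
    fit the band degenerates to the point estimate.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    best = fit_steti_steepness(anchor, family, end_table, L=L)
    t_r, S_r = float(anchor[0]), float(anchor[1])
    if family == "logistic":
        L = float(L if L is not None else end_table.window_N)
    point = float(eval_start(best.model, target_year))
    if best.rss <= 2.0 * RSS_FLOOR:
        return ProjectionBand(target_year, point, point, point, threshold)

    def scan(grid: np.ndarray) -> tuple[list[float], list[float]]:
        kept_p: list[float] = []
        projs: list[float] = []
        for p in grid:
            m = _model_from_internal(family, float(p), t_r, S_r, L)
            try:
                r = _residuals(end_table, m, "end")
            except ValueError:  # variation cannot reach these death years
                continue
            aic = _gaussian_aic(float(r @ r), r.size, 1)
            if math.exp((best.aic - aic) / 2.0) >= threshold:
                kept_p.append(float(p))
                projs.append(float(eval_start(m, target_year)))
        return kept_p, projs

    def domain_grid(lo_p: float, hi_p: float) -> np.ndarray:
        grid = np.linspace(lo_p, hi_p, grid_size)
        if family == "exponential":
            # splice out the unreachable |d| > d_max sliver around rate 0
            grid = grid[np.abs(grid) >= _LN2 / _D_MAX]
        return grid

    lo_p, hi_p = _internal_domain(family)
    step = (hi_p - lo_p) / (grid_size - 1)
    p_best = _internal_of(best.model)
    # coarse pass over the whole domain, then a fine pass over the retained
    # neighbourhood so narrow likelihood peaks are resolved
    kept, _ = scan(domain_grid(lo_p, hi_p))
    kept.append(p_best)
    fine_lo = max(lo_p, min(kept) - step)
    fine_hi = min(hi_p, max(kept) + step)
    _, projs = scan(domain_grid(fine_lo, fine_hi))
    projs.append(point)
    return ProjectionBand(target_year, point, min(projs), max(projs), threshold)


def combine_projections(
    proj_linear: float,
    proj_exponential: float,
    rel_lik: float,
    preferred: Literal["linear", "exponential"] | None = None,
    threshold: float = 0.5,
) -> float:
    """Headline estimate from the linear and exponential projections.

    When the relative likelihood shows no preference (>= ``threshold``),
    average the two projections; otherwise take the lower-AIC model's
    projection.  The headline is rounded half-up to two decimals.
    """
    if not (0.0 < rel_lik <= 1.0):
        raise ValueError(f"relative likelihood must be in (0, 1], got {rel_lik}")
    if rel_lik >= threshold:
        value = (proj_linear + proj_exponential) / 2.0
    else:
        if preferred not in ("linear", "exponential"):
            raise ValueError(
                "a preferred model is required when the relative likelihood "
                f"{rel_lik} falls below the threshold {threshold}"
            )
        value = proj_linear if preferred == "linear" else proj_exponential
    return float(
        Decimal(repr(float(value))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )
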