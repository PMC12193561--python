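"""Start-time trend models and their death-year (end-time) transforms.

A start-time model S(t_b) gives the N-year average survival time for the
diagnosis-year cohort t_b.  Because a patient diagnosed at t_b who survives
S years dies at t_e = t_b + S, any start-time trend induces a death-year
relation S_te(t_e) defined implicitly by

    S_te(t_b + S(t_b)) = S(t_b).

For a linear trend S(t_b) = S0 + M (t_b − t0) the induced relation is again
linear with the flatter slope M/(M+1); for exponential and logistic trends
the inverse t_b(t_e) has no convenient closed form and is obtained by
bracketed root-finding on the strictly increasing map t_b ↦ t_b + S(t_b).

All models use an anchored parameterization (t0, S0, θ): the curve passes
through (t0, S0) and θ is the family's single steepness parameter — slope M
(years/year) for linear, doubling time d (years) for exponential, maximum
steepness k for logistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.optimize import brentq

Family = Literal["linear", "exponential", "logistic"]

FAMILIES: tuple[Family, ...] = ("linear", "exponential", "logistic")

#: Absolute tolerance (years) of the numeric end-time inversion.
INVERSION_TOL = 1e-10

__all__ = [
    "Family",
    "FAMILIES",
    "TrendModel",
    "EndTimeModel",
    "eval_start",
    "end_time_of",
    "eval_end",
    "linear_end_coefficients",
]


@dataclass(frozen=True)
class TrendModel:
    """Anchored survival trend: family, anchor (t0, S0), steepness theta.

    theta is the slope M for ``linear``, the doubling time d (years) for
    ``exponential``, and the maximum steepness k for ``logistic``; the
    logistic additionally needs a ceiling ``L`` (years), naturally the
    observation window N since an N-year average cannot exceed N.
    """

    family: Family
    t0: float
    S0: float
    theta: float
    L: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.S0 <= 0:
            raise ValueError(f"anchor value S0 must be positive, got {self.S0}")
        if self.family == "linear" and self.theta <= -1:
            raise ValueError(
                f"linear slope must exceed -1 (got {self.theta}); otherwise "
                "diagnosis year + survival is not increasing"
            )
        if self.family == "exponential" and self.theta == 0:
            raise ValueError("exponential doubling time must be nonzero")
        if self.family == "logistic":
            if self.L is None:
                raise ValueError("logistic model requires a ceiling L")
            if not (0 < self.S0 < self.L):
                raise ValueError(
                    f"logistic anchor S0={self.S0} must lie in (0, L={self.L})"
                )

    def to_dict(self) -> dict:
        d = {"family": self.family, "t0": self.t0, "S0": self.S0, "theta": self.theta}
        if self.L is not None:
            d["L"] = self.L
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrendModel":
        return cls(
            family=d["family"],
            t0=float(d["t0"]),
            S0=float(d["S0"]),
            theta=float(d["theta"]),
            L=float(d["L"]) if d.get("L") is not None else None,
        )

    def with_theta(self, theta: float) -> "TrendModel":
        return replace(self, theta=theta)


@dataclass(frozen=True)
class EndTimeModel:
    """Death-year view of a start-time trend; fully determined by ``base``."""

    base: TrendModel

    @property
    def min_end_time(self) -> float:
        """Earliest death year on the curve's natural domain t_b >= t0."""
        return self.base.t0 + self.base.S0

    def __call__(self, te):
        return eval_end(self.base, te)


def eval_start(model: TrendModel, tb):
    """Evaluate the start-time trend at diagnosis year(s) ``tb``."""
    tb = np.asarray(tb, dtype=float)
    dt = tb - model.t0
    with np.errstate(over="ignore"):  # far extrapolation may hit inf; harmless
        if model.family == "linear":
            out = model.S0 + model.theta * dt
        elif model.family == "exponential":
            out = model.S0 * np.exp2(dt / model.theta)
        else:  # logistic
            L = model.L
            out = L / (1.0 + (L - model.S0) / model.S0 * np.exp(-model.theta * dt))
    return out if out.ndim else float(out)


def end_time_of(model: TrendModel, tb):
    """Death year of the average patient diagnosed at ``tb``: tb + S(tb)."""
    tb = np.asarray(tb, dtype=float)
    out = tb + eval_start(model, tb)
    return out if out.ndim else float(out)


def eval_end(model: TrendModel, te):
    """Evaluate the induced death-year relation S_te at death year(s) ``te``.

    Linear models use the closed form
    ``S_te(te) = S0 + M (te − S0 − t0) / (M + 1)``; nonlinear families
    invert the strictly increasing map tb ↦ tb + S(tb) by bisection and
    return S at the recovered diagnosis year.
    """
    te = np.asarray(te, dtype=float)
    if model.family == "linear":
        M = model.theta
        out = model.S0 + M * (te - model.S0 - model.t0) / (M + 1.0)
        return out if out.ndim else float(out)
    if te.ndim == 0:
        return float(eval_start(model, _invert_end_time(model, float(te))))
    return eval_start(model, _invert_end_time_array(model, te.ravel()).reshape(te.shape))


def _invert_end_time(model: TrendModel, te: float) -> float:
    """Solve end_time_of(model, tb) = te for tb by bracketed root-finding."""

    def g(tb: float) -> float:
        return end_time_of(model, tb) - te

    # te bounds the root from above whenever S(root) >= 0; both ends are
    # expanded on demand to cover extrapolation into S < 0 territory
    lo, hi = model.t0 - 200.0, te
    span = 200.0
    while g(lo) > 0:
        span *= 2.0
        lo = model.t0 - span
        if span > 1e8:
            raise ValueError(
                f"death year {te} precedes the model's attainable end times "
                f"(no bracket below t0={model.t0})"
            )
    span = 200.0
    while g(hi) < 0:
        hi += span
        span *= 2.0
        if span > 1e8:
            raise ValueError(f"failed to bracket the diagnosis year for te={te}")
    return float(brentq(g, lo, hi, xtol=INVERSION_TOL))


def _invert_end_time_array(model: TrendModel, te: np.ndarray) -> np.ndarray:
    """Vectorized bisection solving end_time_of(tb) = te elementwise.

    Same bracket as the scalar path; a fixed 90 halvings of an initial
    bracket no wider than ~1e8 years reaches well below INVERSION_TOL.
    """
    hi = te.astype(float).copy()
    span = 200.0
    lo = np.full_like(hi, model.t0 - span)
    while True:
        bad = end_time_of(model, lo) > te
        if not bad.any():
            break
        span *= 2.0
        if span > 1e8:
            raise ValueError(
                "some death years precede the model's attainable end times"
            )
        lo[bad] = model.t0 - span
    span = 200.0
    while True:
        bad = end_time_of(model, hi) < te
        if not bad.any():
            break
        hi[bad] += span
        span *= 2.0
        if span > 1e8:
            raise ValueError("failed to bracket some diagnosis years")
    for _ in range(90):
        mid = 0.5 * (lo + hi)
        below = end_time_of(model, mid) < te
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


def linear_end_coefficients(model: TrendModel) -> tuple[float, float]:
    """Slope and value at te = t0 of the linear death-year relation.

    The induced line has slope M/(M+1); returning its value at the anchor
    year lets the transform be checked coefficient-wise.
    """
    if model.family != "linear":
        raise ValueError(f"linear transform requested for {model.family} model")
    M = model.theta
    if M == -1:
        raise ValueError("slope M = -1 degenerates the end-time transform")
    slope = M / (M + 1.0)
    value_at_t0 = model.S0 - slope * model.S0  # = S0 / (M + 1)
    return slope, value_at_t0
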