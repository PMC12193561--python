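"""Synthetic registry-style records with a known survival-improvement trend.

Emulates a case listing of patients who were both diagnosed and died
within the data range: for each diagnosis year the individual survival
times are drawn from a distribution whose mean follows a prescribed
start-time trend, then rounded to whole calendar years the way a
year-resolution registry extract would report them.  The ground truth
trend is known exactly, so cohort construction and the full estimation
pipeline can be checked for parameter recovery.

Noise models (on individual survival times, per-year mean fixed to the
trend): ``none`` (every patient gets the cohort mean), ``gamma`` with a
shape parameter (right-skewed, variance mean^2/shape — a realistic shape
for survival times), or ``lognormal`` with a log-scale sigma.  The truth
curve is the mean of the *untruncated* distribution; configurations must
keep the trend well inside (0, N) so window truncation is negligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from steti.cohorts import (
    CohortTable,
    DataRange,
    PatientRecord,
    eligible_end_cohorts,
    eligible_start_cohorts,
)
from steti.trendmodels import TrendModel, eval_start

NoiseKind = Literal["none", "gamma", "lognormal"]
Rounding = Literal["floor", "round", "none"]

__all__ = ["SimulationConfig", "simulate_records", "expected_cohort_table"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study design of one synthetic extract.

    ``n_per_year`` is diagnoses per calendar year; ``noise_param`` is the
    gamma shape or lognormal sigma (ignored for ``noise="none"``).
    ``rounding="round"`` rounds survival half-up to whole years (the
    default, matching integer-year registry data); ``"none"`` keeps
    real-valued survival for noiseless closure tests.  ``seed`` is
    mandatory whenever the noise model is stochastic.
    """

    data_range: DataRange
    window_N: int
    true_model: TrendModel
    n_per_year: int
    noise: NoiseKind = "none"
    noise_param: float | None = None
    rounding: Rounding = "round"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_year < 1:
            raise ValueError(f"n_per_year must be positive, got {self.n_per_year}")
        if self.window_N < 1:
            raise ValueError(f"window_N must be positive, got {self.window_N}")
        if self.noise not in ("none", "gamma", "lognormal"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.noise != "none":
            if self.seed is None:
                raise ValueError("a seed is mandatory for stochastic noise")
            if self.noise_param is None or self.noise_param <= 0:
                raise ValueError(
                    f"{self.noise} noise needs a positive noise_param, "
                    f"got {self.noise_param}"
                )
        if self.rounding not in ("floor", "round", "none"):
            raise ValueError(f"unknown rounding mode {self.rounding!r}")
        years = np.arange(self.data_range.year_min, self.data_range.year_max + 1)
        trend = np.asarray(eval_start(self.true_model, years))
        if np.any(trend <= 0) or np.any(trend >= self.window_N):
            raise ValueError(
                "true trend must stay strictly inside (0, window_N) across the "
                "data range so that window truncation is negligible; got range "
                f"[{trend.min():.3f}, {trend.max():.3f}] against N={self.window_N}"
            )


def _year_rng(seed: int, year: int) -> np.random.Generator:
    # one substream per diagnosis year: adding years never perturbs the
    # draws of existing years
    return np.random.default_rng(np.random.SeedSequence((seed, year)))


def _draw_survival(config: SimulationConfig, year: int, mean: float) -> np.ndarray:
    n = config.n_per_year
    if config.noise == "none":
        return np.full(n, mean)
    rng = _year_rng(config.seed, year)
    if config.noise == "gamma":
        shape = config.noise_param
        return rng.gamma(shape, mean / shape, size=n)
    sigma = config.noise_param
    mu = math.log(mean) - sigma**2 / 2.0  # lognormal mean = exp(mu + sigma^2/2)
    return rng.lognormal(mu, sigma, size=n)


def _apply_rounding(surv: np.ndarray, mode: Rounding) -> np.ndarray:
    if mode == "floor":
        return np.floor(surv)
    if mode == "round":
        return np.floor(surv + 0.5)  # half-up, not banker's
    return surv


def simulate_records(config: SimulationConfig) -> list[PatientRecord]:
    """Draw the synthetic extract; reproducible given the seed.

    Emits ``n_per_year`` records per diagnosis year.  Identical
    (diagnosis, death) pairs are aggregated via the record ``count`` when
    survival is rounded to integers; with ``rounding="none"`` every patient
    keeps its own real-valued record.
    """
    records: list[PatientRecord] = []
    for year in range(config.data_range.year_min, config.data_range.year_max + 1):
        mean = float(eval_start(config.true_model, year))
        surv = _apply_rounding(_draw_survival(config, year, mean), config.rounding)
        if config.rounding == "none":
            records.extend(PatientRecord(year, year + float(s)) for s in surv)
        else:
            values, counts = np.unique(surv, return_counts=True)
            records.extend(
                PatientRecord(year, year + int(v), int(c))
                for v, c in zip(values, counts)
            )
    return records


def expected_cohort_table(config: SimulationConfig, kind: str) -> CohortTable:
    """Noiseless oracle: the cohort table a noise-free extract produces.

    Computed directly from the truth curve (not by calling the cohort
    builder) so it can stand as an independent check of the pipeline.
    Requires ``noise="none"``: with noise the expected table is not exact.
    """
    if config.noise != "none":
        raise ValueError("expected_cohort_table is defined only for noise='none'")
    rng_years = range(config.data_range.year_min, config.data_range.year_max + 1)
    surv = {
        y: float(
            _apply_rounding(
                np.asarray([eval_start(config.true_model, y)]), config.rounding
            )[0]
        )
        for y in rng_years
    }
    entries: dict[int, tuple[float, int]] = {}
    if kind == "start":
        for y in eligible_start_cohorts(config.data_range, config.window_N):
            if 0.0 <= surv[y] <= config.window_N:
                entries[y] = (surv[y], config.n_per_year)
    elif kind == "end":
        for e in eligible_end_cohorts(config.data_range, config.window_N):
            contrib = [
                surv[y]
                for y in rng_years
                if 0.0 <= surv[y] <= config.window_N and y + surv[y] == e
            ]
            if contrib:
                entries[e] = (float(np.mean(contrib)), config.n_per_year * len(contrib))
    else:
        raise ValueError(f"cohort kind must be 'start' or 'end', got {kind!r}")
    if not entries:
        raise ValueError(f"no eligible {kind} cohort has data under this design")
    return CohortTable(kind, config.window_N, entries)
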