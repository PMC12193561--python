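"""Retrospective hold-out validation of STETI against the base method.

The data range is truncated at a cutoff year, both methods are fitted on
the truncated records only, and their start-time curves are scored against
the held-out diagnosis-year cohort averages that become computable from the
full range.  Shrinking the cutoff starves the base method of start cohorts
(down to a single point, where no slope can be fitted at all) while STETI
still has end-cohort data to regress its steepness on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from steti.cohorts import (
    CohortTable,
    DataRange,
    PatientRecord,
    build_cohort_table,
    eligible_start_cohorts,
)
from steti.fit import FitResult, _gaussian_aic, anchor_from_base, fit_base, fit_steti_steepness
from steti.trendmodels import Family, eval_start

__all__ = ["HoldoutResult", "holdout_experiment", "prediction_metrics"]


@dataclass(frozen=True)
class HoldoutResult:
    """Outcome of one truncated-range prediction experiment.

    ``base`` is absent (with a recorded reason) when the truncated range
    leaves too few start cohorts to fit the base trend.  RMSE and AIC are
    computed on the held-out points, not on the training fit: a 2-point
    base regression has zero fit residual yet can miss the held-out data
    badly, and it is the out-of-sample miss that matters here.
    """

    cutoff_year: int
    base: FitResult | None
    base_absent_reason: str | None
    steti: FitResult
    heldout_years: tuple[int, ...]
    heldout_means: tuple[float, ...]
    predictions_base: tuple[float, ...] | None
    predictions_steti: tuple[float, ...]
    prediction_rmse_base: float | None
    prediction_rmse_steti: float
    prediction_aic_base: float | None
    prediction_aic_steti: float

    def to_dict(self) -> dict:
        return {
            "cutoff_year": self.cutoff_year,
            "base": self.base.to_dict() if self.base else None,
            "base_absent_reason": self.base_absent_reason,
            "steti": self.steti.to_dict(),
            "heldout_years": list(self.heldout_years),
            "heldout_means": list(self.heldout_means),
            "predictions_base": (
                list(self.predictions_base) if self.predictions_base else None
            ),
            "predictions_steti": list(self.predictions_steti),
            "prediction_rmse_base": self.prediction_rmse_base,
            "prediction_rmse_steti": self.prediction_rmse_steti,
            "prediction_aic_base": self.prediction_aic_base,
            "prediction_aic_steti": self.prediction_aic_steti,
        }


def prediction_metrics(
    predictions: Sequence[tuple[float, float]],
    observed: CohortTable,
    k: int,
) -> tuple[float, float]:
    """(RMSE, AIC) of out-of-sample predictions against observed cohorts.

    AIC uses the Gaussian least-squares form with n = number of held-out
    points and the k of the model that produced the predictions.
    """
    resid = []
    for year, pred in predictions:
        if year not in observed.entries:
            raise ValueError(f"no observed cohort mean for predicted year {year}")
        resid.append(observed.entries[year][0] - pred)
    r = np.asarray(resid, dtype=float)
    n = r.size
    rss = float(r @ r)
    return math.sqrt(rss / n), _gaussian_aic(rss, n, k)


def holdout_experiment(
    records: Iterable[PatientRecord],
    full_range: DataRange,
    cutoff_year: int,
    window_N: int,
    family: Family = "linear",
) -> HoldoutResult:
    """Fit on records observable by ``cutoff_year``; score on later cohorts.

    Training data are the records whose death falls on or before the
    cutoff (nothing later would exist in an extract taken at that time).
    The base method needs >= 2 start cohorts (3 for logistic); below that
    it is recorded as absent and the STETI anchor falls back to the single
    start-cohort mean.  STETI's steepness always comes from the
    training-range end cohorts.
    """
    if cutoff_year >= full_range.year_max:
        raise ValueError(
            f"cutoff {cutoff_year} must precede the full range end "
            f"{full_range.year_max}"
        )
    records = list(records)
    train_range = DataRange(full_range.year_min, cutoff_year)
    train_records = [r for r in records if r.death_year <= cutoff_year]

    start_table = build_cohort_table(train_records, train_range, window_N, "start")
    end_table = build_cohort_table(train_records, train_range, window_N, "end")

    min_pts = 3 if family == "logistic" else 2
    base: FitResult | None = None
    reason: str | None = None
    if len(start_table) >= min_pts:
        base = fit_base(start_table, family)
        anchor = anchor_from_base(base, start_table)
    else:
        reason = (
            f"only {len(start_table)} start cohort(s) by {cutoff_year}; "
            f"{family} base fit needs {min_pts} (one data point does not "
            "support fitting a slope)"
        )
        t_r = int(start_table.years[-1])
        anchor = (float(t_r), start_table.entries[t_r][0])
    steti = fit_steti_steepness(anchor, family, end_table)

    full_start = build_cohort_table(records, full_range, window_N, "start")
    trained_years = set(int(y) for y in start_table.years)
    heldout_years = [
        y
        for y in eligible_start_cohorts(full_range, window_N)
        if y in full_start.entries and y not in trained_years
    ]
    if not heldout_years:
        raise ValueError(
            f"no held-out start cohorts beyond cutoff {cutoff_year} in the full range"
        )
    heldout_means = [full_start.entries[y][0] for y in heldout_years]
    heldout_table = CohortTable(
        "start",
        window_N,
        {y: full_start.entries[y] for y in heldout_years},
    )

    pred_steti = [float(eval_start(steti.model, y)) for y in heldout_years]
    rmse_s, aic_s = prediction_metrics(
        list(zip(heldout_years, pred_steti)), heldout_table, k=1
    )
    pred_base = rmse_b = aic_b = None
    if base is not None:
        pred_base = [float(eval_start(base.model, y)) for y in heldout_years]
        rmse_b, aic_b = prediction_metrics(
            list(zip(heldout_years, pred_base)), heldout_table, k=base.k
        )

    return HoldoutResult(
        cutoff_year=cutoff_year,
        base=base,
        base_absent_reason=reason,
        steti=steti,
        heldout_years=tuple(heldout_years),
        heldout_means=tuple(heldout_means),
        predictions_base=tuple(pred_base) if pred_base is not None else None,
        predictions_steti=tuple(pred_steti),
        prediction_rmse_base=rmse_b,
        prediction_rmse_steti=rmse_s,
        prediction_aic_base=aic_b,
        prediction_aic_steti=aic_s,
    )
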