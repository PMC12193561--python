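"""Base fitting, anchored steepness regression, AIC comparison, bands."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from steti.cohorts import CohortTable
from steti.fit import (
    RSS_FLOOR,
    anchor_from_base,
    combine_projections,
    fit_base,
    fit_steti_steepness,
    goodness_of_fit,
    relative_likelihood,
    uncertainty_band,
)
from steti.trendmodels import TrendModel, eval_end, eval_start


def _start_table(points: dict[int, float], N: int = 20) -> CohortTable:
    return CohortTable("start", N, {y: (v, 100) for y, v in points.items()})


def _end_table(points: dict[int, float], N: int = 20) -> CohortTable:
    return CohortTable("end", N, {y: (v, 100) for y, v in points.items()})


class TestFitBase:
    def test_line_through_two_points(self):
        fit = fit_base(_start_table({2000: 3.0, 2010: 4.0}), "linear")
        assert fit.model.theta == pytest.approx(0.1)
        assert eval_start(fit.model, 2000) == pytest.approx(3.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)
        assert fit.k == 2

    def test_collinear_points_have_zero_rmse(self):
        fit = fit_base(_start_table({2000: 3.0, 2005: 3.5, 2010: 4.0}), "linear")
        assert fit.rmse == pytest.approx(0.0, abs=1e-10)

    def test_exponential_noiseless_recovery(self):
        truth = TrendModel("exponential", 1992, 3.0748, 93.0)
        table = _start_table(
            {y: float(eval_start(truth, y)) for y in range(1992, 2001)}
        )
        fit = fit_base(table, "exponential")
        assert fit.model.theta == pytest.approx(93.0, abs=1e-6)
        assert fit.model.S0 == pytest.approx(3.0748, abs=1e-9)

    def test_nls_matches_loglinear_on_exact_data(self):
        truth = TrendModel("exponential", 1992, 3.0748, 93.0)
        table = _start_table(
            {y: float(eval_start(truth, y)) for y in range(1992, 2001)}
        )
        log = fit_base(table, "exponential", method="loglinear")
        nls = fit_base(table, "exponential", method="nls")
        assert nls.model.theta == pytest.approx(log.model.theta, rel=1e-6)

    def test_logistic_noiseless_recovery(self):
        truth = TrendModel("logistic", 1992, 3.0, 0.08, L=20.0)
        table = _start_table(
            {y: float(eval_start(truth, y)) for y in range(1992, 2001)}
        )
        fit = fit_base(table, "logistic", L=20.0)
        assert fit.k == 3
        assert fit.model.theta == pytest.approx(0.08, abs=1e-6)

    def test_insufficient_points_error_names_minimum(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_base(_start_table({2000: 3.0}), "linear")
        with pytest.raises(ValueError, match="at least 3"):
            fit_base(_start_table({2000: 3.0, 2010: 4.0}), "logistic")


class TestAnchor:
    def test_flat_noiseless_data(self):
        fit = fit_base(_start_table({1992: 2.0, 1996: 2.0, 2000: 2.0}), "linear")
        t_r, S_r = anchor_from_base(fit, _start_table({1992: 2.0, 1996: 2.0, 2000: 2.0}))
        assert (t_r, S_r) == (2000, pytest.approx(2.0))

    def test_anchor_is_curve_height_not_data_point(self):
        table = _start_table({2000: 3.0, 2005: 3.4, 2010: 4.1})
        fit = fit_base(table, "linear")
        t_r, S_r = anchor_from_base(fit, table)
        assert t_r == 2010
        assert S_r == pytest.approx(float(eval_start(fit.model, 2010)))
        assert S_r != pytest.approx(4.1, abs=1e-6)  # curve, not the dot

    def test_two_point_line_anchor(self):
        table = _start_table({2000: 3.0, 2010: 4.0})
        fit = fit_base(table, "linear")
        assert anchor_from_base(fit, table) == (2010, pytest.approx(4.0))


class TestSteepnessRegression:
    def test_linear_noiseless_inversion(self):
        anchor = (2000.0, 2.0)
        truth = TrendModel("linear", 2000, 2.0, 0.1)
        points = {y: float(eval_end(truth, y)) for y in range(2012, 2016)}
        assert points[2012] == pytest.approx(2.0 + 0.1 * (2012 - 2 - 2000) / 1.1)
        fit = fit_steti_steepness(anchor, "linear", _end_table(points))
        assert fit.model.theta == pytest.approx(0.1, abs=1e-9)
        assert fit.k == 1

    def test_flat_end_data_gives_zero_slope(self):
        fit = fit_steti_steepness(
            (2000.0, 2.0), "linear", _end_table({2012: 2.0, 2013: 2.0, 2014: 2.0})
        )
        assert fit.model.theta == pytest.approx(0.0, abs=1e-12)

    def test_single_end_point_solved_exactly(self):
        # one diagnosis cohort + one death-year cohort define the line
        fit = fit_steti_steepness((1992.0, 2.2), "linear", _end_table({2012: 2.9}))
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert eval_end(fit.model, 2012.0) == pytest.approx(2.9, abs=1e-9)

    def test_exponential_noiseless_inversion(self):
        truth = TrendModel("exponential", 2000, 3.2623, 106.0)
        points = {y: float(eval_end(truth, y)) for y in range(2012, 2021)}
        fit = fit_steti_steepness((2000.0, 3.2623), "exponential", _end_table(points))
        assert fit.model.theta == pytest.approx(106.0, abs=1e-4)

    def test_logistic_noiseless_inversion(self):
        truth = TrendModel("logistic", 2000, 3.0, 0.06, L=20.0)
        points = {y: float(eval_end(truth, y)) for y in range(2012, 2021)}
        fit = fit_steti_steepness((2000.0, 3.0), "logistic", _end_table(points), L=20.0)
        assert fit.model.theta == pytest.approx(0.06, abs=1e-6)

    def test_infinite_slope_rejected(self):
        # end means rising ~1 year per death year imply u >= 1
        with pytest.raises(ValueError, match="u = M"):
            fit_steti_steepness(
                (2000.0, 2.0), "linear",
                _end_table({2012: 14.0, 2013: 15.2, 2014: 16.4}),
            )

    def test_empty_end_table_rejected(self):
        with pytest.raises(ValueError):
            fit_steti_steepness((2000.0, 2.0), "linear", CohortTable("end", 20, {}))

    @pytest.mark.parametrize("seed", range(5))
    def test_closed_form_u_equals_numeric_optimization(self, seed):
        """The u-substitution solution matches 1-D numeric minimization."""
        rng = np.random.default_rng(seed)
        anchor = (2000.0, float(rng.uniform(1.5, 4.0)))
        years = np.arange(2012, 2021)
        means = np.clip(
            anchor[1] + rng.uniform(-0.02, 0.08) * (years - 2010)
            + rng.normal(0, 0.1, years.size),
            0.1, 19.9,
        )
        table = _end_table(dict(zip((int(y) for y in years), means)))
        fit = fit_steti_steepness(anchor, "linear", table)

        def rss_of_u(u):
            m = TrendModel("linear", anchor[0], anchor[1], u / (1 - u))
            r = table.means - np.asarray(eval_end(m, table.years))
            return float(r @ r)

        res = minimize_scalar(
            rss_of_u, bounds=(-0.99, 0.99), method="bounded",
            options={"xatol": 1e-12},
        )
        u_fit = fit.model.theta / (1 + fit.model.theta)
        assert u_fit == pytest.approx(float(res.x), abs=1e-7)


class TestGoodnessOfFit:
    def test_simple_residual_arithmetic(self):
        model = TrendModel("linear", 2000, 3.0, 0.0)
        table = _start_table({2000: 4.0, 2001: 2.0})  # residuals {1, -1}
        rss, rmse, aic = goodness_of_fit(table, model, "start", k=1)
        assert (rss, rmse) == (pytest.approx(2.0), pytest.approx(1.0))
        assert aic == pytest.approx(2 * math.log(1.0) + 2)

    def test_four_half_residuals(self):
        model = TrendModel("linear", 2000, 3.0, 0.0)
        table = _start_table({y: 3.5 for y in range(2000, 2004)})
        rss, rmse, aic = goodness_of_fit(table, model, "start", k=2)
        assert rss == pytest.approx(1.0)
        assert rmse == pytest.approx(0.5)
        assert aic == pytest.approx(4 * math.log(0.25) + 4)

    def test_perfect_fit_floors_the_aic(self):
        model = TrendModel("linear", 2000, 3.0, 0.1)
        table = _start_table({y: float(eval_start(model, y)) for y in (2000, 2005)})
        rss, rmse, aic = goodness_of_fit(table, model, "start", k=2)
        assert rmse == pytest.approx(0.0, abs=1e-12)
        assert aic == pytest.approx(2 * math.log(RSS_FLOOR / 2) + 4)


class TestRelativeLikelihood:
    @pytest.mark.parametrize(
        "a, b, expected, digits",
        [
            (-86.1, -96.7, 0.005, 3),
            (-54.5, -54.8, 0.86, 2),
            (-14.71, -12.22, 0.29, 2),
        ],
    )
    def test_published_aic_pairs(self, a, b, expected, digits):
        assert round(relative_likelihood(a, b), digits) == expected

    def test_equal_aics_give_one(self):
        assert relative_likelihood(-50.0, -50.0) == 1.0

    def test_symmetric_and_bounded(self):
        for a, b in [(-10, -12), (3, 1.5), (-96.7, -86.1)]:
            assert relative_likelihood(a, b) == relative_likelihood(b, a)
            assert 0 < relative_likelihood(a, b) <= 1


class TestUncertaintyBand:
    def _noisy_end_table(self):
        rng = np.random.default_rng(42)
        truth = TrendModel("linear", 2000, 2.5, 0.06)
        years = np.arange(2012, 2021)
        means = np.asarray(eval_end(truth, years.astype(float)))
        means = means + rng.normal(0, 0.08, years.size)
        return _end_table(dict(zip((int(y) for y in years), means)))

    def test_noiseless_band_collapses_to_point(self):
        truth = TrendModel("linear", 2000, 2.0, 0.1)
        points = {y: float(eval_end(truth, y)) for y in range(2012, 2016)}
        band = uncertainty_band((2000.0, 2.0), "linear", _end_table(points), 2025)
        assert band.lo == band.point == band.hi

    def test_threshold_one_returns_point_only(self):
        band = uncertainty_band(
            (2000.0, 2.5), "linear", self._noisy_end_table(), 2025, threshold=1.0
        )
        assert band.lo == pytest.approx(band.point)
        assert band.hi == pytest.approx(band.point)

    def test_lower_threshold_band_contains_higher(self):
        table = self._noisy_end_table()
        tight = uncertainty_band((2000.0, 2.5), "linear", table, 2025, threshold=0.5)
        wide = uncertainty_band((2000.0, 2.5), "linear", table, 2025, threshold=0.05)
        assert wide.lo <= tight.lo <= tight.point <= tight.hi <= wide.hi
        assert (wide.hi - wide.lo) > (tight.hi - tight.lo)

    def test_exponential_band_brackets_point(self):
        table = self._noisy_end_table()
        band = uncertainty_band((2000.0, 2.5), "exponential", table, 2025)
        assert band.lo <= band.point <= band.hi
        assert band.hi > band.lo


class TestCombineProjections:
    @pytest.mark.parametrize(
        "lin, exp, rel, preferred, expected",
        [
            (1.553, 1.582, 0.75, None, 1.57),
            (3.253, 3.168, 0.005, "exponential", 3.17),
            (3.806, 3.842, 0.86, None, 3.82),
            (2.5, 2.5, 0.3, "linear", 2.5),
        ],
    )
    def test_combination_rule(self, lin, exp, rel, preferred, expected):
        assert combine_projections(lin, exp, rel, preferred) == expected

    def test_rounding_is_half_up(self):
        assert combine_projections(1.565, 1.565, 1.0) == 1.57
        assert combine_projections(1.5649, 1.5649, 1.0) == 1.56

    def test_result_within_input_range(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a, b = rng.uniform(1, 5, 2)
            rel = float(rng.uniform(0.01, 1.0))
            out = combine_projections(a, b, rel, preferred="linear")
            assert min(a, b) - 0.005 <= out <= max(a, b) + 0.005

    def test_preference_required_below_threshold(self):
        with pytest.raises(ValueError, match="preferred"):
            combine_projections(1.0, 2.0, 0.1)
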