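"""Polynomial quality-response models, optima and the recommendation."""

import numpy as np
import pytest

from foamdry import reference as ref
from foamdry.response import (
    fit_response, optimum_of_response, recommend_temperature,
    response_from_coefficients,
)

TEMPS = np.array([50.0, 55.0, 60.0, 65.0, 70.0])


def _brute_force_optimum(coefficients, direction, lo=50.0, hi=70.0, step=0.001):
    grid = np.arange(lo, hi + step / 2, step)
    y = np.polyval(coefficients, grid)
    if direction == "maximize":
        return grid[np.argmax(y)]
    if direction == "minimize":
        return grid[np.argmin(y)]
    target = float(direction.split(":")[1])
    return grid[np.argmin(np.abs(y - target))]


class TestFitResponse:
    def test_exact_quadratic_recovered(self):
        y = 2.0 - 3.0 * TEMPS + 0.5 * TEMPS**2
        model = fit_response("exact", TEMPS, y, direction="minimize")
        np.testing.assert_allclose(model.coefficients, [0.5, -3.0, 2.0], atol=1e-9)
        assert model.R2 == pytest.approx(1.0, abs=1e-12)
        assert model.degree == 2
        assert np.all(model.coefficient_p_values < 0.05)

    def test_moisture_means_match_published_quadratic(self):
        """A quadratic through the published moisture means reproduces the
        published response equation coefficients within 15 %."""
        means = [ref.MOISTURE_WB[T][0] for T in TEMPS]
        model = fit_response("moisture", TEMPS, means, direction="minimize", degree=2)
        published = ref.RESPONSE_EQUATIONS["moisture"]["coeffs"]
        for got, want in zip(model.coefficients, published):
            assert got == pytest.approx(want, rel=0.15)
        assert model.coefficients[0] > 0  # positive curvature

    def test_stepwise_down_selects_quadratic_on_replicate_data(self, rng):
        """With replicate-level data the cubic term is insignificant but
        the quadratic survives the 5 % screen."""
        reps, temps, values = 3, [], []
        for T in TEMPS:
            mean, sd = ref.MOISTURE_WB[T]
            temps += [T] * reps
            values += list(mean + sd * rng.standard_normal(reps))
        model = fit_response("moisture", temps, values, direction="minimize")
        assert model.degree == 2
        assert np.all(model.coefficient_p_values < 0.05)

    def test_constant_data_falls_back_to_insignificant_line(self):
        model = fit_response("flat", TEMPS, np.full(5, 7.0), direction="maximize")
        assert model.degree == 1
        assert model.coefficients[0] == pytest.approx(0.0, abs=1e-9)
        assert model.coefficient_p_values[0] > 0.05  # slope not significant

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_response("short", [50.0, 60.0], [1.0, 2.0], degree=2)


class TestOptimum:
    def test_vertex_of_downward_parabola(self):
        model = response_from_coefficients("peak", [-1.0, 120.0, -3600.0], "maximize")
        assert model.optimum_T == pytest.approx(60.0, abs=1e-9)
        assert model.optimum_kind == "interior"

    def test_published_moisture_vertex(self):
        model = response_from_coefficients(
            "moisture", ref.RESPONSE_EQUATIONS["moisture"]["coeffs"], "minimize"
        )
        assert model.optimum_T == pytest.approx(1.6715 / (2 * 0.0122), abs=1e-9)
        assert model.optimum_T == pytest.approx(68.50, abs=0.01)

    def test_published_vitamin_c_vertex(self):
        model = response_from_coefficients(
            "vc", ref.RESPONSE_EQUATIONS["vc"]["coeffs"], "maximize"
        )
        assert model.optimum_T == pytest.approx(1265.2979 / (2 * 9.3083), abs=1e-6)
        assert model.optimum_T == pytest.approx(67.97, abs=0.01)

    def test_linear_model_optimum_is_favorable_endpoint(self):
        falling = response_from_coefficients("tta", [-0.0296, 6.7451], "maximize")
        assert falling.optimum_T == 50.0 and falling.optimum_kind == "boundary"
        rising = response_from_coefficients("up", [0.1, 0.0], "maximize")
        assert rising.optimum_T == 70.0

    def test_every_published_equation_agrees_with_grid_search(self):
        """Closed-form optima match a 0.001 °C brute-force scan."""
        for name, eq in ref.RESPONSE_EQUATIONS.items():
            model = response_from_coefficients(name, eq["coeffs"], eq["direction"])
            brute = _brute_force_optimum(eq["coeffs"], eq["direction"])
            assert optimum_of_response(model) == pytest.approx(brute, abs=5e-3), name


class TestRecommendation:
    def test_identical_optima(self):
        models = [response_from_coefficients(f"p{i}", [-1.0, 120.0, -3600.0], "maximize")
                  for i in range(3)]
        rec = recommend_temperature(models)
        assert rec.mean_optimum == pytest.approx(60.0)
        assert rec.grid_choice == 60.0

    def test_midpoint_of_spread_optima(self):
        lo = response_from_coefficients("down", [-0.1, 0.0], "maximize")   # 50
        hi = response_from_coefficients("up", [0.1, 0.0], "maximize")      # 70
        rec = recommend_temperature([lo, hi])
        assert rec.mean_optimum == pytest.approx(60.0)
        assert rec.grid_choice == 60.0

    def test_permutation_invariant(self):
        models = [
            response_from_coefficients(name, eq["coeffs"], eq["direction"])
            for name, eq in ref.RESPONSE_EQUATIONS.items()
        ]
        fwd = recommend_temperature(models)
        rev = recommend_temperature(models[::-1])
        assert fwd.mean_optimum == pytest.approx(rev.mean_optimum, rel=1e-12)
        assert fwd.grid_choice == rev.grid_choice

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            recommend_temperature([])

    def test_published_equations_recommend_a_tested_temperature(self):
        models = [
            response_from_coefficients(name, eq["coeffs"], eq["direction"])
            for name, eq in ref.RESPONSE_EQUATIONS.items()
        ]
        rec = recommend_temperature(models)
        assert rec.grid_choice in set(ref.TEMPERATURES_C)
        assert 50.0 <= rec.mean_optimum <= 70.0
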