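"""Quality-parameter-vs-temperature response models and their optima.

Each physicochemical parameter that responds to drying temperature is
modelled as a low-degree polynomial in T (°C), fitted by ordinary least
squares.  The degree is chosen stepwise-down: starting from
``max_degree``, the degree is reduced while any coefficient fails a
two-sided t-test at the 5 % level, stopping at degree 1.  Each fitted
model is then optimized over the tested temperature range in its
desirability direction (maximize a nutrient, minimize moisture, or hold a
colour coordinate near the fresh-pulp value), and the recommended drying
temperature is the arithmetic mean of the per-parameter optima snapped to
the nearest tested temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .fitting import mean_relative_error, standard_deviation_estimate

_DIRECTIONS = ("maximize", "minimize")


@dataclass(frozen=True)
class ResponseModel:
    """Polynomial quality-vs-temperature model with its optimum."""

    parameter_name: str
    direction: str                     # maximize | minimize | target:<value>
    coefficients: np.ndarray           # highest degree first
    coefficient_p_values: np.ndarray
    R2: float
    fit_MRE: float
    fit_SDE: float
    optimum_T: float                   # °C
    optimum_kind: str                  # interior | boundary
    T_range: tuple[float, float] = (50.0, 70.0)

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def predict(self, T) -> np.ndarray:
        return np.polyval(self.coefficients, T)


def _objective(coefficients: np.ndarray, direction: str):
    """Scalar objective h(T) to MINIMIZE, encoding the direction."""
    if direction == "maximize":
        return lambda T: -np.polyval(coefficients, T)
    if direction == "minimize":
        return lambda T: np.polyval(coefficients, T)
    if direction.startswith("target:"):
        target = float(direction.split(":", 1)[1])
        return lambda T: np.abs(np.polyval(coefficients, T) - target)
    raise ValueError(f"unknown direction {direction!r}")


def _optimize_polynomial(
    coefficients: np.ndarray, direction: str, T_range: tuple[float, float]
) -> tuple[float, str]:
    """Best T in ``T_range``: stationary points of the objective + endpoints.

    For plain max/min the candidates are the real roots of the derivative
    polynomial inside the range; for a target direction the candidates
    additionally include the roots of p(T) - target (where |p - target|
    attains 0).  Linear models always resolve to an endpoint.
    """
    lo, hi = T_range
    candidates = [lo, hi]
    deriv_roots = np.roots(np.polyder(coefficients))
    candidates += [
        float(r.real) for r in deriv_roots
        if abs(r.imag) < 1e-9 and lo < r.real < hi
    ]
    if direction.startswith("target:"):
        target = float(direction.split(":", 1)[1])
        shifted = coefficients.copy().astype(float)
        shifted[-1] -= target
        candidates += [
            float(r.real) for r in np.roots(shifted)
            if abs(r.imag) < 1e-9 and lo < r.real < hi
        ]
    h = _objective(coefficients, direction)
    values = [h(T) for T in candidates]
    best = int(np.argmin(values))
    T_opt = candidates[best]
    kind = "boundary" if T_opt in (lo, hi) else "interior"
    return float(T_opt), kind


def fit_response(
    parameter_name: str,
    temps,
    values,
    direction: str = "minimize",
    max_degree: int = 3,
    alpha: float = 0.05,
    degree: int | None = None,
    T_range: tuple[float, float] = (50.0, 70.0),
) -> ResponseModel:
    """OLS polynomial fit of a quality parameter against temperature.

    ``temps``/``values`` may carry replicates (repeated temperatures).
    With ``degree=None`` the degree is selected stepwise-down from
    ``max_degree`` at significance level ``alpha``; passing ``degree``
    fixes it.  Goodness of fit is reported as R^2, MRE (%) and SDE with
    DF = n - (degree + 1).
    """
    temps = np.asarray(temps, dtype=float)
    values = np.asarray(values, dtype=float)
    if temps.shape != values.shape or temps.ndim != 1:
        raise ValueError("temps and values must be 1-D and equal length")

    degrees = [degree] if degree is not None else list(range(max_degree, 0, -1))
    fit = None
    chosen = None
    for d in degrees:
        if len(temps) < d + 2:
            continue
        X = np.vander(temps, d + 1)  # highest degree first, last column = 1
        model = sm.OLS(values, X).fit()
        fit, chosen = model, d
        if degree is not None or np.all(model.pvalues < alpha) or d == 1:
            break
    if fit is None:
        raise ValueError(
            f"{parameter_name}: need at least degree+2 points "
            f"({len(temps)} given)"
        )

    coefficients = np.asarray(fit.params, dtype=float)
    yhat = fit.fittedvalues
    DF = len(values) - (chosen + 1)
    T_opt, kind = _optimize_polynomial(coefficients, direction, T_range)
    return ResponseModel(
        parameter_name=parameter_name,
        direction=direction,
        coefficients=coefficients,
        coefficient_p_values=np.asarray(fit.pvalues, dtype=float),
        R2=float(fit.rsquared),
        fit_MRE=mean_relative_error(values, yhat),
        fit_SDE=standard_deviation_estimate(values, yhat, max(DF, 1)),
        optimum_T=T_opt,
        optimum_kind=kind,
        T_range=T_range,
    )


def response_from_coefficients(
    parameter_name: str,
    coefficients,
    direction: str,
    T_range: tuple[float, float] = (50.0, 70.0),
) -> ResponseModel:
    """Wrap an already-known polynomial (e.g. a published equation)."""
    coefficients = np.asarray(coefficients, dtype=float)
    T_opt, kind = _optimize_polynomial(coefficients, direction, T_range)
    nan = float("nan")
    return ResponseModel(
        parameter_name=parameter_name,
        direction=direction,
        coefficients=coefficients,
        coefficient_p_values=np.full(len(coefficients), nan),
        R2=nan, fit_MRE=nan, fit_SDE=nan,
        optimum_T=T_opt, optimum_kind=kind, T_range=T_range,
    )


def optimum_of_response(model: ResponseModel) -> float:
    """The model's optimal temperature (already solved at fit time)."""
    return model.optimum_T


@dataclass(frozen=True)
class TemperatureRecommendation:
    mean_optimum: float                # °C, arithmetic mean of per-model optima
    grid_choice: float                 # nearest tested temperature
    per_parameter: dict[str, float]


def recommend_temperature(
    models: list[ResponseModel], grid_step: float = 5.0
) -> TemperatureRecommendation:
    """Average the per-parameter optima and snap to the tested grid.

    The grid is built from the shared T_range with ``grid_step`` spacing
    (default 5 °C, the tested temperatures); the recommendation is the
    grid temperature nearest the mean optimum.
    """
    if not models:
        raise ValueError("recommend_temperature needs at least one model")
    optima = {m.parameter_name: m.optimum_T for m in models}
    mean_opt = float(np.mean(list(optima.values())))
    lo, hi = models[0].T_range
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    choice = float(grid[np.argmin(np.abs(grid - mean_opt))])
    return TemperatureRecommendation(
        mean_optimum=mean_opt, grid_choice=choice, per_parameter=optima
    )
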