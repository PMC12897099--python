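"""Bank of seven empirical thin-layer drying models.

Each model expresses the moisture ratio MR as a closed form in drying time
t (minutes) with one to three parameters drawn from {a, k, b, n}, k being
the drying rate constant (min^-1):

======================  ==========================================
Lewis                   exp(-k t)
Page                    exp(-k t^n)
Henderson-Pabis         a exp(-k t)
Logarithmic             a exp(-k t) + b
Modified Midilli        exp(-k t^n) + b t
Diffusion Approximation a exp(-k t) + (1-a) exp(-k b t)
Two-Term Exponential    a exp(-k t) + (1-a) exp(-k a t)
======================  ==========================================

The two-branch forms are written with the complementary (1-a) weight so
that MR(0) = 1, the physically required start of a normalised drying
curve.  t^n at t = 0 is taken as 0 for n > 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DryingModelSpec", "MODEL_BANK", "get_model", "evaluate", "time_to_reach",
]


@dataclass(frozen=True)
class DryingModelSpec:
    """Name, ordered parameter names, and closed form of one model."""

    name: str
    param_names: tuple[str, ...]
    form: Callable[..., np.ndarray]

    @property
    def n_params(self) -> int:
        return len(self.param_names)


def _lewis(t, k):
    return np.exp(-k * t)


def _page(t, k, n):
    return np.exp(-k * np.power(t, n))


def _henderson_pabis(t, a, k):
    return a * np.exp(-k * t)


def _logarithmic(t, a, k, b):
    return a * np.exp(-k * t) + b


def _modified_midilli(t, k, n, b):
    return np.exp(-k * np.power(t, n)) + b * t


def _diffusion_approximation(t, a, k, b):
    return a * np.exp(-k * t) + (1.0 - a) * np.exp(-k * b * t)


def _two_term_exponential(t, a, k):
    return a * np.exp(-k * t) + (1.0 - a) * np.exp(-k * a * t)


MODEL_BANK: dict[str, DryingModelSpec] = {
    spec.name.lower(): spec
    for spec in (
        DryingModelSpec("Lewis", ("k",), _lewis),
        DryingModelSpec("Page", ("k", "n"), _page),
        DryingModelSpec("HendersonPabis", ("a", "k"), _henderson_pabis),
        DryingModelSpec("Logarithmic", ("a", "k", "b"), _logarithmic),
        DryingModelSpec("ModifiedMidilli", ("k", "n", "b"), _modified_midilli),
        DryingModelSpec("DiffusionApproximation", ("a", "k", "b"), _diffusion_approximation),
        DryingModelSpec("TwoTermExponential", ("a", "k"), _two_term_exponential),
    )
}

#: Accepted aliases for registry lookup (case-insensitive).
_ALIASES = {
    "henderson-pabis": "hendersonpabis",
    "henderson_pabis": "hendersonpabis",
    "modified-midilli": "modifiedmidilli",
    "modified_midilli": "modifiedmidilli",
    "diffusion-approximation": "diffusionapproximation",
    "diffusion_approximation": "diffusionapproximation",
    "diffusion-approach": "diffusionapproximation",
    "two-term-exponential": "twotermexponential",
    "two_term_exponential": "twotermexponential",
}


def get_model(name: str) -> DryingModelSpec:
    """Look up a model by name, case-insensitively, with common aliases."""
    key = name.strip().lower()
    key = _ALIASES.get(key, key)
    try:
        return MODEL_BANK[key]
    except KeyError:
        raise KeyError(
            f"unknown drying model {name!r}; known: "
            + ", ".join(s.name for s in MODEL_BANK.values())
        ) from None


def _check_params(model: DryingModelSpec, params: Mapping[str, float]) -> tuple:
    missing = set(model.param_names) - set(params)
    extra = set(params) - set(model.param_names)
    if missing or extra:
        raise ValueError(
            f"{model.name} takes parameters {model.param_names}; "
            f"missing {sorted(missing)}, extra {sorted(extra)}"
        )
    if params["k"] <= 0:
        raise ValueError(f"{model.name}: k must be positive, got {params['k']}")
    return tuple(params[p] for p in model.param_names)


def evaluate(model: DryingModelSpec | str, params: Mapping[str, float], t):
    """Predicted MR of ``model`` with ``params`` at time(s) ``t`` (min)."""
    if isinstance(model, str):
        model = get_model(model)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("drying time must be non-negative")
    values = _check_params(model, params)
    out = model.form(t_arr, *values)
    if np.ndim(t) == 0:
        return float(out)
    return out


def time_to_reach(
    model: DryingModelSpec | str,
    params: Mapping[str, float],
    target_MR: float,
    t_max: float = 1e6,
):
    """Smallest t >= 0 (min) at which the model reaches ``target_MR``.

    Closed form for Lewis and Logarithmic, bisection on [0, t_max]
    otherwise.  Returns ``None`` ("never") when the target lies outside
    the model's range on that interval.
    """
    if isinstance(model, str):
        model = get_model(model)
    _check_params(model, params)
    mr0 = evaluate(model, params, 0.0)
    if target_MR > mr0 + 1e-12:
        return None  # curve starts below the target and decreases
    if target_MR >= mr0 - 1e-12:
        return 0.0

    if model.name == "Lewis":
        if target_MR <= 0:
            return None
        return float(-np.log(target_MR) / params["k"])
    if model.name == "Logarithmic":
        a, k, b = params["a"], params["k"], params["b"]
        # a e^{-kt} + b = target  =>  t = ln(a/(target-b))/k
        if a <= 0 or target_MR <= b:
            return None
        return float(np.log(a / (target_MR - b)) / k)

    f = lambda t: evaluate(model, params, t) - target_MR
    if f(t_max) > 0:
        return None
    return float(brentq(f, 0.0, t_max, xtol=1e-9))
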