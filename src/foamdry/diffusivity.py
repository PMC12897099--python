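"""Effective moisture diffusivity (slope method) and Arrhenius analysis.

For one-dimensional diffusion in a slab with uniform initial moisture,
negligible shrinkage and negligible external resistance, the series
solution of Fick's second law gives

    MR(t) = (8/pi^2) * sum_{n>=0} 1/(2n+1)^2 *
            exp(-(2n+1)^2 pi^2 Deff t / (4 L^2)),

so at long times ln(MR) is linear in t with slope -pi^2 Deff / (4 L^2).
Regressing ln(MR) on time therefore yields Deff per temperature, and the
temperature dependence Deff = D0 exp(-Ea / (R T)) yields the activation
energy Ea from the slope of ln(Deff) against 1/T.

Kinetic time is carried in minutes upstream; this module converts slopes
to s^-1 so diffusivities come out in m^2 s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfc
from scipy.stats import linregress

from .drying import DryingRun

#: Universal gas constant, J mol^-1 K^-1.
R_GAS = 8.314

#: Equivalent-slab characteristic length (m).  For one-face tray drying of
#: the 1.5 cm foam layer the full depth is the appropriate slab length.
DEFAULT_THICKNESS_M = 0.015

SECONDS_PER_MINUTE = 60.0


@dataclass(frozen=True)
class DiffusivityEstimate:
    """Slope-method effective diffusivity at one temperature."""

    temperature_C: float
    slope_per_s: float      # fitted slope of ln(MR) vs t, s^-1 (negative)
    intercept: float
    r2_loglinear: float
    L: float                # characteristic slab length, m
    Deff: float             # m^2 s^-1
    n_points_used: int
    degenerate: bool = False  # flat curve, Deff = 0


@dataclass(frozen=True)
class ArrheniusFit:
    """Arrhenius regression of Deff over temperature."""

    D0: float               # pre-exponential, m^2 s^-1
    Ea: float               # activation energy, J mol^-1
    r2: float               # squared correlation of ln(Deff) vs 1/T
    temperatures_K: np.ndarray

    @property
    def Ea_kJ_mol(self) -> float:
        return self.Ea / 1000.0

    def predict(self, temperature_C) -> np.ndarray:
        """Deff (m^2 s^-1) predicted at the given temperature(s) in °C."""
        T = np.asarray(temperature_C, dtype=float) + 273.15
        return self.D0 * np.exp(-self.Ea / (R_GAS * T))


def fick_series_MR(
    Deff: float, L: float, t, tol: float = 1e-12, max_terms: int = 200
):
    """Fick slab-series moisture ratio at time(s) t in seconds.

    Terms are added until the next term falls below ``tol`` or
    ``max_terms`` terms have been summed; the remaining tail is then
    closed with its integral approximation (an erfc expression), so the
    slow small-time convergence of the series is handled: at t = 0 the
    identity sum 1/(2n+1)^2 = pi^2/8 is reproduced to ~1e-9 and the
    result is well within 1e-4 of 1 at the default 200 terms.
    """
    if Deff <= 0 or L <= 0:
        raise ValueError("Deff and L must be positive")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    beta = np.pi**2 * Deff / (4.0 * L**2)
    s = beta * t_arr
    total = np.zeros_like(t_arr, dtype=float)
    n_summed = 0
    for n in range(max_terms):
        m = 2 * n + 1
        term = np.exp(-(m**2) * s) / m**2
        total += term
        n_summed = n + 1
        if np.all(term < tol):
            break
    # integral tail: sum_{n >= N} e^{-(2n+1)^2 s}/(2n+1)^2
    #   ~ 0.5 * [e^{-s a^2}/a - sqrt(pi s) erfc(a sqrt(s))],  a = 2N
    a = 2.0 * n_summed
    with np.errstate(invalid="ignore"):
        tail = np.where(
            s > 0,
            0.5 * (np.exp(-s * a**2) / a
                   - np.sqrt(np.pi * np.maximum(s, 1e-300))
                   * erfc(a * np.sqrt(np.maximum(s, 1e-300)))),
            0.5 / a,
        )
    out = 8.0 / np.pi**2 * (total + tail)
    if np.ndim(t) == 0:
        return float(out)
    return out


def estimate_Deff(
    run: DryingRun,
    L: float = DEFAULT_THICKNESS_M,
    min_MR: float = 0.0,
) -> DiffusivityEstimate:
    """Effective diffusivity from the ln(MR)-vs-time slope of one run.

    Points with MR <= ``min_MR`` (default: all positive points) are
    excluded from the regression.  The slope is converted from min^-1 to
    s^-1 before Deff = |slope| * 4 L^2 / pi^2.
    """
    if L <= 0:
        raise ValueError("characteristic length L must be positive")
    mask = run.MR > max(min_MR, 0.0)
    if mask.sum() < 3:
        raise ValueError(
            f"need at least 3 positive-MR points, have {int(mask.sum())}"
        )
    t_min = run.times[mask]
    ln_mr = np.log(run.MR[mask])
    res = linregress(t_min, ln_mr)
    slope_per_s = res.slope / SECONDS_PER_MINUTE
    degenerate = res.slope >= 0 or np.isclose(res.slope, 0.0)
    if degenerate:
        deff = 0.0
        slope_per_s = min(slope_per_s, 0.0)
    else:
        deff = abs(slope_per_s) * 4.0 * L**2 / np.pi**2
    return DiffusivityEstimate(
        temperature_C=run.temperature_C,
        slope_per_s=float(slope_per_s),
        intercept=float(res.intercept),
        r2_loglinear=float(res.rvalue**2),
        L=float(L),
        Deff=float(deff),
        n_points_used=int(mask.sum()),
        degenerate=bool(degenerate),
    )


def deff_from_rate_constant(k_per_min: float, L: float = DEFAULT_THICKNESS_M) -> float:
    """Deff implied by an exponential rate constant k (min^-1): k·4L²/π²."""
    if k_per_min <= 0 or L <= 0:
        raise ValueError("k and L must be positive")
    return (k_per_min / SECONDS_PER_MINUTE) * 4.0 * L**2 / np.pi**2


def arrhenius_fit(estimates) -> ArrheniusFit:
    """Arrhenius regression over (temperature °C, Deff m^2 s^-1) pairs.

    Duplicate temperatures are collapsed to the mean Deff.  Requires at
    least two distinct temperatures and positive diffusivities.  When the
    diffusivities are identical at every temperature the activation energy
    is 0 and r^2 is reported as NaN (flagged degenerate correlation).
    """
    pairs = [
        (e.temperature_C, e.Deff) if isinstance(e, DiffusivityEstimate) else tuple(e)
        for e in estimates
    ]
    if any(d <= 0 for _, d in pairs):
        raise ValueError("all diffusivities must be positive")
    by_T: dict[float, list[float]] = {}
    for T, d in pairs:
        by_T.setdefault(float(T), []).append(float(d))
    temps_C = np.array(sorted(by_T))
    if len(temps_C) < 2:
        raise ValueError("need at least two distinct temperatures")
    deff = np.array([np.mean(by_T[T]) for T in temps_C])
    T_K = temps_C + 273.15

    x = 1.0 / T_K
    y = np.log(deff)
    if np.allclose(y, y[0]):
        return ArrheniusFit(
            D0=float(np.exp(y[0])), Ea=0.0, r2=float("nan"), temperatures_K=T_K
        )
    res = linregress(x, y)
    return ArrheniusFit(
        D0=float(np.exp(res.intercept)),
        Ea=float(-res.slope * R_GAS),
        r2=float(res.rvalue**2),
        temperatures_K=T_K,
    )
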