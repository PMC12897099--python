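"""Synthetic drying curves, colour replicates and assay records.

The generator emulates the study conditions of the acerola foam-mat
drying experiment so every pipeline stage is testable without the raw
laboratory data:

* weighing cadence — every 20 min during the first hour, every 30 min for
  the next two hours, hourly thereafter, stopping after the mass is
  constant over three consecutive weighings;
* drying curves — the reference logarithmic model per temperature
  (:data:`foamdry.reference.LOGARITHMIC_PARAMS`), normalized to start at
  MR = 1 and truncated at zero once the curve reaches equilibrium, with
  additive Gaussian noise on the moisture ratio (default sd 0.01, the
  residual scale of the reference fits);
* masses — reconstructed through M = Me + MR (M0 - Me) and
  net mass = dry_mass (1 + M/100), with the initial moisture taken from
  the 91.95 % w.b. fresh foam and the equilibrium moisture from the final
  powder moisture at each temperature;
* quality tables — Gaussian replicates (n = 3) around the published means
  with the published standard deviations.

Randomness is driven by one global seed; each run draws a deterministic
substream keyed by (seed, temperature), so regenerating any single
temperature is reproducible independent of order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference as ref
from .drying import DryingRun, WeighingSeries, build_drying_run
from .models import evaluate, get_model

#: Default oven-dry solids mass (g): a 1.5 cm foam layer on the 35.5 cm
#: tray at the emustab foam density of 0.14367 g/cm^3 weighs ~213 g, of
#: which 8.05 % is solids.
DEFAULT_DRY_MASS = 17.16

DEFAULT_TARE_MASS = 150.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions under which synthetic drying runs are generated."""

    model_name: str = "Logarithmic"
    params_by_temp: dict = field(
        default_factory=lambda: {T: dict(p) for T, p in ref.LOGARITHMIC_PARAMS.items()}
    )
    M0: float = ref.M0_DRY_BASIS                 # % d.b.
    Me_by_temp: dict = field(default_factory=lambda: dict(ref.ME_DRY_BASIS))
    dry_mass: float = DEFAULT_DRY_MASS           # g
    tare_mass: float = DEFAULT_TARE_MASS         # g
    noise_sd: float = 0.01                       # additive Gaussian sd on MR
    seed: int = 42
    t_end_by_temp: dict = field(default_factory=lambda: dict(ref.DRYING_TIME_MIN))

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.dry_mass <= 0:
            raise ValueError("dry mass must be positive")


def weighing_schedule(t_end: float) -> np.ndarray:
    """Weighing times (min): 0-60 by 20, 90-180 by 30, hourly beyond.

    Times are truncated at ``t_end``; ``t_end`` itself is included only
    when it falls on the cadence.
    """
    if t_end < 0:
        raise ValueError("t_end must be non-negative")
    times = np.concatenate([
        np.arange(0, 61, 20),
        np.arange(90, 181, 30),
        np.arange(240, max(t_end, 240) + 1, 60),
    ])
    return times[times <= t_end]


def _run_rng(seed: int, temperature: float) -> np.random.Generator:
    """Deterministic substream for one temperature."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(int(round(temperature * 10)),))
    )


def true_moisture_ratio(config: SyntheticConfig, temperature: float, times) -> np.ndarray:
    """Noise-free MR on the given times: the normalized model, clipped at 0.

    The empirical thin-layer forms with a free intercept (logarithmic,
    Henderson-Pabis) need not pass through MR = 1 at t = 0, but any
    mass-reduced series starts at exactly 1 by construction.  The
    generating curve is therefore the model normalized by its own t = 0
    value, model(t)/model(0): it starts at 1, keeps the model's rate
    constant and zero-crossing, and remains exactly of the model's
    functional form (the normalization only rescales a and b).
    """
    params = config.params_by_temp[temperature]
    times = np.asarray(times, dtype=float)
    model = get_model(config.model_name)
    mr0 = evaluate(model, params, 0.0)
    if mr0 <= 0:
        raise ValueError(f"model value at t = 0 must be positive, got {mr0}")
    mr = evaluate(model, params, times) / mr0
    return np.clip(mr, 0.0, 1.0)


def generate_run(
    config: SyntheticConfig, temperature: float
) -> tuple[WeighingSeries, DryingRun]:
    """One synthetic weighing series plus its noise-free reference run.

    The schedule runs to the drying time for that temperature, then three
    equilibrium-plateau weighings are appended at the hourly cadence (the
    stopping rule: mass constant in three consecutive weighings).  Noise
    is applied to the moisture ratio of the scheduled points (never to the
    known initial point or the plateau), clipped into [0, 1].
    """
    if temperature not in config.params_by_temp:
        raise ValueError(f"no generating parameters for {temperature} °C")
    t_end = config.t_end_by_temp[temperature]
    Me = config.Me_by_temp[temperature]
    times = weighing_schedule(t_end)

    mr_true = true_moisture_ratio(config, temperature, times)
    mr_obs = mr_true.copy()
    if config.noise_sd > 0:
        rng = _run_rng(config.seed, temperature)
        noise = rng.normal(0.0, config.noise_sd, len(times))
        noise[0] = 0.0  # MR(0) = 1 by definition
        mr_obs = np.clip(mr_true + noise, 0.0, 1.0)

    # three consecutive constant weighings at equilibrium, hourly cadence
    plateau_times = times[-1] + 60.0 * np.arange(1, 4)
    times_full = np.concatenate([times, plateau_times])
    mr_obs_full = np.concatenate([mr_obs, np.zeros(3)])
    mr_true_full = np.concatenate(
        [mr_true, true_moisture_ratio(config, temperature, plateau_times)]
    )

    M = Me + mr_obs_full * (config.M0 - Me)
    net = config.dry_mass * (1.0 + M / 100.0)
    # one MR unit spans dry_mass*(M0-Me)/100 grams; allow transient rises
    # far beyond the noise scale before declaring the series invalid
    mass_noise_sd = config.noise_sd * config.dry_mass * (config.M0 - Me) / 100.0
    series = WeighingSeries(
        temperature_C=temperature,
        times=times_full,
        gross_masses=net + config.tare_mass,
        tare_mass=config.tare_mass,
        noise_tolerance=max(2.0, 12.0 * mass_noise_sd),
    )
    truth = DryingRun(
        temperature_C=temperature,
        times=times_full,
        moisture_db=Me + mr_true_full * (config.M0 - Me),
        M0=config.M0,
        Me=Me,
        dry_mass=config.dry_mass,
        MR=np.clip(mr_true_full, 0.0, 1.0),
    )
    return series, truth


def model_mr_run(
    config: SyntheticConfig,
    temperature: float,
    noise_sd: float | None = None,
    rng: np.random.Generator | None = None,
) -> DryingRun:
    """A drying run whose MR is the generating model itself on the schedule.

    Unlike :func:`generate_run`, nothing is pinned to MR(0) = 1 and no
    plateau is appended: the moisture ratio IS the model curve (plus
    optional Gaussian noise clipped into [0, 1]).  Any mass-reduced
    series has MR(0) = 1 identically, so curves from models whose form
    gives MR(0) != 1 can only be represented — and their parameters
    recovered exactly — in this model space.
    """
    if temperature not in config.params_by_temp:
        raise ValueError(f"no generating parameters for {temperature} °C")
    times = weighing_schedule(config.t_end_by_temp[temperature])
    params = config.params_by_temp[temperature]
    mr = np.clip(evaluate(get_model(config.model_name), params, times), 0.0, 1.0)
    sd = config.noise_sd if noise_sd is None else noise_sd
    if sd > 0:
        if rng is None:
            rng = _run_rng(config.seed, temperature)
        mr = np.clip(mr + rng.normal(0.0, sd, len(times)), 0.0, 1.0)
    Me = config.Me_by_temp[temperature]
    return DryingRun(
        temperature_C=temperature,
        times=times,
        moisture_db=Me + mr * (config.M0 - Me),
        M0=config.M0,
        Me=Me,
        dry_mass=config.dry_mass,
        MR=mr,
    )


def generate_all_runs(config: SyntheticConfig) -> dict[float, WeighingSeries]:
    """Synthetic weighing series for every configured temperature."""
    return {T: generate_run(config, T)[0] for T in sorted(config.params_by_temp)}


def generate_quality_tables(seed: int = 42, n_replicates: int = 3,
                            sd_scale: float = 1.0) -> dict[str, pd.DataFrame]:
    """Gaussian replicate tables around the published quality means.

    Returns long-format DataFrames keyed ``"quality"`` (moisture w.b.,
    ash, pH, acidity, sugars, vitamin C, carotenoids; columns sample,
    parameter, replicate, value) and ``"color"`` (columns sample,
    replicate, L, a, b).  ``sd_scale`` scales every published replicate
    sd (0 gives replicates equal to the means).
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(999,)))
    rows = []
    tables = {"moisture_wb": ref.MOISTURE_WB, "ash": ref.ASH_PERCENT, **ref.QUALITY}
    for param, by_sample in tables.items():
        for sample, (mean, sd) in by_sample.items():
            draws = mean + sd * sd_scale * rng.standard_normal(n_replicates)
            for i, v in enumerate(draws):
                rows.append({"sample": sample, "parameter": param,
                             "replicate": i + 1, "value": float(v)})
    quality = pd.DataFrame(rows)

    color_rows = []
    for sample, coords in ref.COLOR.items():
        draws = {
            axis: coords[axis][0] + coords[axis][1] * sd_scale
            * rng.standard_normal(n_replicates)
            for axis in ("L", "a", "b")
        }
        for i in range(n_replicates):
            color_rows.append({
                "sample": sample, "replicate": i + 1,
                "L": float(draws["L"][i]), "a": float(draws["a"][i]),
                "b": float(draws["b"][i]),
            })
    return {"quality": quality, "color": pd.DataFrame(color_rows)}


def reduce_run(config: SyntheticConfig, temperature: float) -> DryingRun:
    """Generate and immediately reduce one run (convenience)."""
    series, _ = generate_run(config, temperature)
    return build_drying_run(series, config.dry_mass)
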