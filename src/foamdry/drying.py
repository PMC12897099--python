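"""Reduction of raw weighing series to dry-basis moisture and moisture ratio.

A drying run is recorded as tray-plus-foam masses at scheduled times.  With
the tare mass and the oven-dry solids mass the series reduces to dry-basis
moisture M(t) = 100 * water/solids and the dimensionless moisture ratio

    MR(t) = (M(t) - Me) / (M0 - Me),

which is 1 at the start and 0 once the sample reaches the equilibrium
plateau (mass constant over three consecutive weighings).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel returned by :func:`detect_equilibrium` when no plateau exists.
NO_PLATEAU = -1

#: Default balance resolution (g): smallest mass step counted as a change.
DEFAULT_BALANCE_RESOLUTION = 0.01


class DegenerateRunError(ValueError):
    """Raised when a run carries no drying signal (M0 == Me)."""


@dataclass(frozen=True)
class WeighingSeries:
    """Raw weighing record of one drying run at one air temperature.

    Net masses (gross minus tare) must be positive and, apart from
    measurement noise, non-increasing: drying only removes water.
    """

    temperature_C: float
    times: np.ndarray          # min, strictly increasing, times[0] == 0
    gross_masses: np.ndarray   # g, tray + foam
    tare_mass: float           # g
    balance_resolution: float = DEFAULT_BALANCE_RESOLUTION
    #: largest transient net-mass increase tolerated as noise (g)
    noise_tolerance: float = 2.0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        gross = np.asarray(self.gross_masses, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "gross_masses", gross)
        if times.ndim != 1 or gross.ndim != 1 or len(times) != len(gross):
            raise ValueError("times and gross_masses must be 1-D and equal length")
        if len(times) == 0 or times[0] != 0:
            raise ValueError("times must start at 0")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        net = gross - self.tare_mass
        if np.any(net <= 0):
            raise ValueError("all net masses (gross - tare) must be positive")
        rises = np.diff(net)
        if np.any(rises > self.noise_tolerance):
            raise ValueError(
                "net masses increase by more than the noise tolerance "
                f"({rises.max():.3f} g > {self.noise_tolerance} g)"
            )

    @property
    def net_masses(self) -> np.ndarray:
        """Foam mass (g) at each weighing."""
        return self.gross_masses - self.tare_mass


@dataclass(frozen=True)
class DryingRun:
    """One temperature's weighing series reduced to moisture coordinates."""

    temperature_C: float
    times: np.ndarray        # min
    moisture_db: np.ndarray  # % dry basis
    M0: float                # initial moisture, % d.b.
    Me: float                # equilibrium moisture, % d.b.
    dry_mass: float          # g dry solids
    MR: np.ndarray           # dimensionless moisture ratio
    plateau_index: int = NO_PLATEAU
    n_clipped: int = 0       # MR values clipped into [0, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_min": self.times, "moisture_db": self.moisture_db, "MR": self.MR}
        )


def moisture_dry_basis(water_mass: float, dry_residue_mass: float) -> float:
    """Moisture content in % dry basis: 100 * water mass / dry-solids mass."""
    if dry_residue_mass <= 0:
        raise ValueError(f"dry residue mass must be positive: {dry_residue_mass}")
    if water_mass < 0:
        raise ValueError(f"water mass must be non-negative: {water_mass}")
    return 100.0 * water_mass / dry_residue_mass


def moisture_ratio(M, M0: float, Me: float, clip: bool = True):
    """Moisture ratio (M - Me)/(M0 - Me), clipped into [0, 1].

    Accepts scalar or array ``M``.  Raises :class:`DegenerateRunError` when
    M0 == Me (no drying signal to normalise by).
    """
    if M0 <= Me:
        raise DegenerateRunError(f"M0 ({M0}) must exceed Me ({Me})")
    mr = (np.asarray(M, dtype=float) - Me) / (M0 - Me)
    if clip:
        clipped = np.clip(mr, 0.0, 1.0)
        n_out = int(np.sum(clipped != mr))
        if n_out:
            logger.info("moisture_ratio clipped %d value(s) into [0, 1]", n_out)
        mr = clipped
    if np.ndim(M) == 0:
        return float(mr)
    return mr


def detect_equilibrium(net_masses, resolution: float = DEFAULT_BALANCE_RESOLUTION) -> int:
    """Index of the first point of a three-constant-weighings plateau.

    Returns the smallest i with |m[i]-m[i+1]| <= resolution and
    |m[i+1]-m[i+2]| <= resolution, or :data:`NO_PLATEAU` if none exists.
    """
    m = np.asarray(net_masses, dtype=float)
    if m.ndim != 1 or len(m) < 3:
        raise ValueError("need at least 3 weighings to detect a plateau")
    steps = np.abs(np.diff(m)) <= resolution
    flat = steps[:-1] & steps[1:]
    idx = np.flatnonzero(flat)
    return int(idx[0]) if len(idx) else NO_PLATEAU


def build_drying_run(series: WeighingSeries, dry_mass: float) -> DryingRun:
    """Reduce a weighing series to dry-basis moisture and moisture ratio.

    The equilibrium moisture Me is taken from the plateau mass (mean of the
    plateau weighings) and the oven-dry solids mass, not fitted.  If the
    series never reaches a three-constant-weighings plateau a warning is
    issued and the final observed mass is used as the equilibrium mass.
    """
    net = series.net_masses
    if dry_mass <= 0:
        raise ValueError(f"dry mass must be positive: {dry_mass}")
    if dry_mass > net.min():
        raise ValueError(
            f"dry mass {dry_mass} g exceeds the smallest net mass {net.min():.4f} g"
        )
    moisture_db = 100.0 * (net - dry_mass) / dry_mass
    M0 = float(moisture_db[0])

    plateau = detect_equilibrium(net, series.balance_resolution) if len(net) >= 3 else NO_PLATEAU
    if plateau == NO_PLATEAU:
        warnings.warn(
            f"run at {series.temperature_C:g} °C has no three-constant-weighings "
            "plateau; using the last observed mass as equilibrium",
            stacklevel=2,
        )
        m_eq = float(net[-1])
    else:
        m_eq = float(net[plateau:].mean())
    Me = float(100.0 * (m_eq - dry_mass) / dry_mass)

    if M0 <= Me:
        raise DegenerateRunError(
            f"run at {series.temperature_C:g} °C shows no net drying (M0 <= Me)"
        )
    raw_mr = (moisture_db - Me) / (M0 - Me)
    mr = np.clip(raw_mr, 0.0, 1.0)
    n_clipped = int(np.sum(mr != raw_mr))
    if n_clipped:
        logger.info(
            "run at %g °C: clipped %d MR value(s) into [0, 1]",
            series.temperature_C, n_clipped,
        )
    return DryingRun(
        temperature_C=series.temperature_C,
        times=series.times.copy(),
        moisture_db=moisture_db,
        M0=M0,
        Me=Me,
        dry_mass=float(dry_mass),
        MR=mr,
        plateau_index=plateau,
        n_clipped=n_clipped,
    )


# -- delimited-text I/O -------------------------------------------------------

def read_weighing_series(
    path,
    temperature_C: float,
    tare_mass: float,
    balance_resolution: float = DEFAULT_BALANCE_RESOLUTION,
) -> WeighingSeries:
    """Read a weighing series from CSV with columns time_min, gross_mass_g."""
    df = pd.read_csv(path)
    missing = {"time_min", "gross_mass_g"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return WeighingSeries(
        temperature_C=temperature_C,
        times=df["time_min"].to_numpy(float),
        gross_masses=df["gross_mass_g"].to_numpy(float),
        tare_mass=tare_mass,
        balance_resolution=balance_resolution,
    )


def write_weighing_series(series: WeighingSeries, path) -> None:
    """Write a weighing series as CSV (columns time_min, gross_mass_g)."""
    pd.DataFrame(
        {"time_min": series.times, "gross_mass_g": series.gross_masses}
    ).to_csv(path, index=False)


def read_drying_run(path, temperature_C: float | None = None) -> DryingRun:
    """Read a reduced drying run written by :func:`write_drying_run`."""
    df = pd.read_csv(path, comment="#")
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = float(value)
    return DryingRun(
        temperature_C=temperature_C if temperature_C is not None
        else meta.get("temperature_C", float("nan")),
        times=df["time_min"].to_numpy(float),
        moisture_db=df["moisture_db"].to_numpy(float),
        M0=meta["M0"],
        Me=meta["Me"],
        dry_mass=meta["dry_mass"],
        MR=df["MR"].to_numpy(float),
        plateau_index=int(meta.get("plateau_index", NO_PLATEAU)),
    )


def write_drying_run(run: DryingRun, path) -> None:
    """Write a reduced drying run as CSV with a # key=value metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# temperature_C = {run.temperature_C}\n")
        fh.write(f"# M0 = {run.M0!r}\n")
        fh.write(f"# Me = {run.Me!r}\n")
        fh.write(f"# dry_mass = {run.dry_mass!r}\n")
        fh.write(f"# plateau_index = {run.plateau_index}\n")
        run.to_frame().to_csv(fh, index=False)
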