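"""Closed-form calculators for foam properties and physicochemical assays.

Foam density and coalesced (drained) volume characterise foam quality
before drying; the remaining calculators convert raw assay readings
(oven masses, titration volumes, absorbances) into the standard
composition parameters: moisture (wet basis), ash, total titratable
acidity as citric acid, reducing sugars (Lane-Eynon), vitamin C
(iodometric), and total carotenoids (450 nm spectrophotometry in
petroleum ether).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Citric acid, the dominant acid of acerola: molecular weight (g/mol) and
#: number of ionizable hydrogens.  Overridable per record.
CITRIC_ACID_MW = 192.12
CITRIC_ACID_N_H = 3

#: Absorptivity coefficient of carotenoids in petroleum ether (A 1%, 1 cm).
CAROTENOID_A1CM = 2592.0

#: Vitamin-C titre factors for 0.02 M and 0.002 M potassium iodate.
VITC_FACTORS = (8.806, 0.8806)


@dataclass(frozen=True)
class FoamMeasurement:
    """Beaker weighing for foam density plus the coalescence reading."""

    mass_glassware_plus_sample: float  # g
    mass_empty_glassware: float        # g
    occupied_volume: float             # cm^3
    beaker_radius: float = 0.0         # cm, for coalesced volume
    coalesced_height: float = 0.0      # cm

    def __post_init__(self):
        if self.occupied_volume <= 0:
            raise ValueError("occupied volume must be positive")
        if self.coalesced_height < 0:
            raise ValueError("coalesced height must be non-negative")


@dataclass(frozen=True)
class MoistureAshRecord:
    """Oven/muffle masses: water lost M, sample P, ash N (g)."""

    water_mass_lost: float
    sample_mass: float
    ash_mass: float = 0.0

    def __post_init__(self):
        if self.sample_mass <= 0:
            raise ValueError("sample mass must be positive")
        if not 0 <= self.water_mass_lost <= self.sample_mass:
            raise ValueError("water mass lost must lie in [0, sample mass]")
        if not 0 <= self.ash_mass <= self.sample_mass:
            raise ValueError("ash mass must lie in [0, sample mass]")


@dataclass(frozen=True)
class TitrationRecord:
    """NaOH titration of total titratable acidity."""

    V_NaOH: float                    # mL
    f: float = 1.0                   # titrant correction factor
    M_NaOH: float = 0.1              # mol/L
    MW: float = CITRIC_ACID_MW       # g/mol of the reference acid
    n_H: int = CITRIC_ACID_N_H       # ionizable hydrogens
    P: float = 5.0                   # sample mass, g

    def __post_init__(self):
        if min(self.f, self.M_NaOH, self.MW, self.P) <= 0 or self.n_H < 1:
            raise ValueError("titration constants must be positive (n_H >= 1)")
        if self.V_NaOH < 0:
            raise ValueError("titrant volume must be non-negative")


@dataclass(frozen=True)
class SugarTitrationRecord:
    """Lane-Eynon (Fehling) titration of reducing sugars."""

    DV: float        # dilution volume, mL
    T_titre: float   # Fehling titre, dimensionless
    V: float         # titrant volume used, mL
    P: float         # sample mass, g

    def __post_init__(self):
        if self.V <= 0 or self.P <= 0:
            raise ValueError("titrant volume and sample mass must be positive")


@dataclass(frozen=True)
class VitaminCRecord:
    """Iodometric vitamin-C titration with potassium iodate."""

    V_KIO3: float    # mL
    F: float = 8.806  # 8.806 (0.02 M KIO3) or 0.8806 (0.002 M)
    P: float = 1.0    # sample mass, g

    def __post_init__(self):
        if self.F not in VITC_FACTORS:
            raise ValueError(f"F must be one of {VITC_FACTORS}, got {self.F}")
        if self.P <= 0 or self.V_KIO3 < 0:
            raise ValueError("sample mass must be positive, volume non-negative")


@dataclass(frozen=True)
class CarotenoidRecord:
    """450 nm absorbance reading for total carotenoids."""

    Abs: float                       # absorbance at 450 nm
    V_aliquot: float                 # mL
    P: float                         # sample mass, g
    A1cm: float = CAROTENOID_A1CM    # absorptivity coefficient

    def __post_init__(self):
        if self.Abs < 0:
            raise ValueError("absorbance must be non-negative")
        if min(self.V_aliquot, self.P, self.A1cm) <= 0:
            raise ValueError("volume, mass and absorptivity must be positive")


def foam_density(m: FoamMeasurement) -> float:
    """Foam density in g/cm^3: net sample mass over occupied volume."""
    net = m.mass_glassware_plus_sample - m.mass_empty_glassware
    if net <= 0:
        raise ValueError("net sample mass must be positive")
    return net / m.occupied_volume


def coalesced_volume(r: float, A: float) -> float:
    """Drained (coalesced) volume pi r^2 A in mL; lower = more stable foam."""
    if r <= 0:
        raise ValueError("beaker radius must be positive")
    if A < 0:
        raise ValueError("coalesced height must be non-negative")
    return float(np.pi * r**2 * A)


def moisture_wet_basis(rec: MoistureAshRecord) -> float:
    """Moisture in % wet basis: 100 * water lost / sample mass."""
    return 100.0 * rec.water_mass_lost / rec.sample_mass


def ash_percent(rec: MoistureAshRecord) -> float:
    """Ash in %: 100 * ash mass / sample mass."""
    return 100.0 * rec.ash_mass / rec.sample_mass


def titratable_acidity(rec: TitrationRecord) -> float:
    """Total titratable acidity in g acid / 100 g sample.

    V * f * M * MW / (10 * P * n_H); the reference acid defaults to citric.
    """
    return rec.V_NaOH * rec.f * rec.M_NaOH * rec.MW / (10.0 * rec.P * rec.n_H)


def reducing_sugars(rec: SugarTitrationRecord) -> float:
    """Reducing sugars in g glucose / 100 g: 100 * DV * T / (V * P)."""
    return 100.0 * rec.DV * rec.T_titre / (rec.V * rec.P)


def vitamin_c(rec: VitaminCRecord) -> float:
    """Vitamin C in mg / 100 g: 100 * V_KIO3 * F / P."""
    return 100.0 * rec.V_KIO3 * rec.F / rec.P


def total_carotenoids(rec: CarotenoidRecord) -> float:
    """Total carotenoids in µg / 100 g: Abs * V_aliquot * 1e4 / (A1cm * P)."""
    return rec.Abs * rec.V_aliquot * 1e4 / (rec.A1cm * rec.P)
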