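"""Reference dataset for acerola-pulp foam-mat drying at 50-70 °C.

Published summary values from a foam-mat drying study of acerola
(*Malpighia emarginata*) pulp foamed with 4 % emustab: fitted logarithmic
drying-curve parameters and drying times per temperature, effective
diffusivities, quality-parameter means with replicate standard deviations,
CIELAB colour coordinates, and the quality-vs-temperature regression
equations.  The raw weighing curves behind these summaries were not
deposited, so this module is the anchor for the synthetic generator
(:mod:`foamdry.synthetic`) and for the worked examples: the generator
produces curves whose fitted statistics should reproduce these numbers.

All kinetic rate constants are per minute (the time base of the weighing
schedule); diffusivities are m^2 s^-1.
"""

from __future__ import annotations

TEMPERATURES_C: tuple[float, ...] = (50.0, 55.0, 60.0, 65.0, 70.0)

#: Published fits of all seven models: per model name, per temperature,
#: (params dict, R2, MRE %, SDE).  "---" entries in the source are simply
#: absent parameters.
REFERENCE_FITS: dict[str, dict[float, tuple[dict[str, float], float, float, float]]] = {
    "TwoTermExponential": {
        50.0: ({"a": 1.5000, "k": 0.0040}, 0.9750, 11.2733, 0.0562),
        55.0: ({"a": 1.5976, "k": 0.0053}, 0.9830, 11.2792, 0.0475),
        60.0: ({"a": 1.6564, "k": 0.0071}, 0.9830, 6.9340, 0.0480),
        65.0: ({"a": 1.6540, "k": 0.0087}, 0.9834, 6.2375, 0.0423),
        70.0: ({"a": 1.6813, "k": 0.0104}, 0.9859, 5.4117, 0.0419),
    },
    "Lewis": {
        50.0: ({"k": 0.0033}, 0.9730, 12.2284, 0.0529),
        55.0: ({"k": 0.0042}, 0.9786, 13.8277, 0.0463),
        60.0: ({"k": 0.0054}, 0.9763, 8.1774, 0.0454),
        65.0: ({"k": 0.0066}, 0.9764, 7.5100, 0.0397),
        70.0: ({"k": 0.0078}, 0.9784, 5.8112, 0.0392),
    },
    "DiffusionApproximation": {
        50.0: ({"a": 1.0605, "k": 0.0028, "b": -0.1932}, 0.9824, 9.1879, 0.0540),
        55.0: ({"a": 1.0000, "k": 0.0042, "b": 1.0000}, 0.9786, 13.8277, 0.0507),
        60.0: ({"a": 1.0000, "k": 0.0054, "b": 1.0000}, 0.9802, 8.2580, 0.0523),
        65.0: ({"a": 1.0000, "k": 0.0066, "b": 1.0000}, 0.9764, 7.5098, 0.0458),
        70.0: ({"a": 1.0000, "k": 0.0078, "b": 1.0000}, 0.9784, 5.8115, 0.0464),
    },
    "Logarithmic": {
        T: (dict(p), r2, mre, sde)
        for T, (p, r2, mre, sde) in {
            50.0: ({"a": 1.1143, "k": 0.0021, "b": -0.1883}, 0.9902, 7.8635, 0.0360),
            55.0: ({"a": 1.1104, "k": 0.0029, "b": -0.1546}, 0.9919, 9.5636, 0.0335),
            60.0: ({"a": 1.1280, "k": 0.0039, "b": -0.1581}, 0.9903, 5.6683, 0.0349),
            65.0: ({"a": 1.2020, "k": 0.0043, "b": -0.2325}, 0.9934, 4.4103, 0.0294),
            70.0: ({"a": 1.1241, "k": 0.0059, "b": -0.1376}, 0.9908, 4.1328, 0.0323),
        }.items()
    },
    "ModifiedMidilli": {
        50.0: ({"n": 0.2027, "k": 0.0821, "b": -0.0011}, 0.9995, 134.0286, 0.3839),
        55.0: ({"n": 0.2796, "k": 0.0554, "b": -0.0014}, 0.9997, 154.4380, 0.3966),
        60.0: ({"n": 0.5663, "k": 0.0226, "b": -0.0012}, 0.9963, 49.5096, 0.2296),
        65.0: ({"n": 0.9146, "k": 0.0079, "b": -0.0004}, 0.9923, 14.4232, 0.0703),
        70.0: ({"n": 1.0583, "k": 0.0052, "b": -0.0001}, 0.9899, 4.7994, 0.0387),
    },
    "Page": {
        50.0: ({"n": 1.0418, "k": 0.0026}, 0.9735, 11.7987, 0.0570),
        55.0: ({"n": 1.1126, "k": 0.0022}, 0.9815, 43.1378, 0.1139),
        60.0: ({"n": 1.1636, "k": 0.0023}, 0.9819, 7.0712, 0.0520),
        65.0: ({"n": 1.1600, "k": 0.0029}, 0.9823, 6.4321, 0.0461),
        70.0: ({"n": 1.1859, "k": 0.0031}, 0.9854, 5.7742, 0.0460),
    },
    "HendersonPabis": {
        50.0: ({"a": 0.9640, "k": 0.0032}, 0.9751, 12.3334, 0.0486),
        55.0: ({"a": 0.9902, "k": 0.0042}, 0.9787, 14.0096, 0.0473),
        60.0: ({"a": 1.0033, "k": 0.0054}, 0.9963, 8.2107, 0.0486),
        65.0: ({"a": 1.0066, "k": 0.0066}, 0.9765, 7.6048, 0.0431),
        70.0: ({"a": 1.0145, "k": 0.0079}, 0.9899, 5.8839, 0.0437),
    },
}

#: Logarithmic model MR = a*exp(-k*t) + b, k in min^-1, per temperature —
#: the best-fitting model at every temperature and the generator default.
LOGARITHMIC_PARAMS: dict[float, dict[str, float]] = {
    T: dict(p) for T, (p, _, _, _) in REFERENCE_FITS["Logarithmic"].items()
}

#: Total drying time (min) until mass was constant, per temperature.
DRYING_TIME_MIN: dict[float, float] = {
    50.0: 840.0,
    55.0: 660.0,
    60.0: 480.0,
    65.0: 360.0,
    70.0: 300.0,
}

#: Effective diffusivity (m^2 s^-1) per temperature, slope method, L = 0.015 m.
DEFF_M2S: dict[float, float] = {
    50.0: 2.570e-9,
    55.0: 3.234e-9,
    60.0: 4.149e-9,
    65.0: 4.427e-9,
    70.0: 5.060e-9,
}

#: Reported activation energy (kJ mol^-1) and Arrhenius correlation.
ACTIVATION_ENERGY_KJ_MOL = 30.88
ARRHENIUS_R2 = 0.9604

#: Foam physical properties per foaming agent: (density g/cm^3, coalesced mL).
FOAM_PROPERTIES: dict[str, tuple[float, float]] = {
    "albumin": (0.83858, 492.3333),
    "neutral_alloy": (0.55595, 26.5867),
    "emustab": (0.14367, 0.0000),
}

#: Moisture content (% w.b.), ash (%), water activity: mean and sd.
#: Key "pulp" is the fresh pulp; floats are dried powders per temperature.
MOISTURE_WB: dict[object, tuple[float, float]] = {
    "pulp": (91.95, 0.02),
    50.0: (21.33, 0.37),
    55.0: (18.95, 0.25),
    60.0: (17.84, 0.32),
    65.0: (17.54, 0.18),
    70.0: (16.89, 0.19),
}
ASH_PERCENT: dict[object, tuple[float, float]] = {
    "pulp": (0.37, 0.11),
    50.0: (4.31, 0.05),
    55.0: (4.342, 0.16),
    60.0: (4.28, 0.17),
    65.0: (3.71, 0.06),
    70.0: (4.08, 0.16),
}

#: pH, titratable acidity (g/100 g citric), soluble solids (°Brix),
#: reducing sugars (%), vitamin C (mg/100 g), carotenoids (µg/100 g).
QUALITY: dict[str, dict[object, tuple[float, float]]] = {
    "pH": {
        "pulp": (3.58, 0.03), 50.0: (3.68, 0.02), 55.0: (3.63, 0.01),
        60.0: (3.66, 0.03), 65.0: (3.63, 0.03), 70.0: (3.62, 0.03),
    },
    "tta": {
        "pulp": (0.84, 0.29), 50.0: (5.27, 3.86), 55.0: (5.09, 2.81),
        60.0: (5.00, 2.72), 65.0: (4.68, 1.78), 70.0: (4.78, 1.58),
    },
    "ssc": {
        "pulp": (7.40, 0.16), 50.0: (29.33, 2.05), 55.0: (27.66, 1.24),
        60.0: (30.33, 2.05), 65.0: (29.66, 0.47), 70.0: (29.00, 0.81),
    },
    "rs": {
        "pulp": (5.29, 0.07), 50.0: (32.44, 2.37), 55.0: (31.60, 1.64),
        60.0: (32.66, 0.89), 65.0: (36.47, 0.54), 70.0: (34.10, 0.59),
    },
    "vc": {
        "pulp": (873.15, 1.92), 50.0: (4013.82, 31.70), 55.0: (5429.15, 29.48),
        60.0: (6399.30, 36.44), 65.0: (6964.80, 22.03), 70.0: (6953.49, 10.06),
    },
    "tc": {
        "pulp": (252.00, 4.96), 50.0: (188.48, 3.20), 55.0: (118.72, 9.53),
        60.0: (82.83, 1.48), 65.0: (68.10, 3.20), 70.0: (58.71, 2.97),
    },
}

#: CIELAB colour coordinates (mean, sd): L*, a*, b*, h*, C*.
COLOR: dict[object, dict[str, tuple[float, float]]] = {
    "pulp": {"L": (55.58, 0.56), "a": (6.28, 0.58), "b": (12.57, 0.29),
             "h": (63.46, 2.53), "C": (14.07, 0.21)},
    50.0: {"L": (58.16, 1.63), "a": (11.02, 0.26), "b": (28.89, 1.73),
           "h": (69.04, 1.41), "C": (30.94, 1.57)},
    55.0: {"L": (62.15, 0.63), "a": (9.01, 0.55), "b": (27.80, 1.06),
           "h": (72.05, 0.54), "C": (29.22, 1.17)},
    60.0: {"L": (59.14, 0.92), "a": (11.26, 0.65), "b": (28.10, 0.16),
           "h": (68.15, 1.13), "C": (30.28, 0.31)},
    65.0: {"L": (56.16, 1.02), "a": (12.62, 0.48), "b": (28.50, 0.88),
           "h": (66.07, 1.35), "C": (31.18, 0.68)},
    70.0: {"L": (55.55, 1.21), "a": (12.51, 0.53), "b": (26.12, 1.69),
           "h": (64.36, 0.54), "C": (28.96, 1.75)},
}

#: Browning index of the dried powders (mean, sd) per temperature.
BROWNING_INDEX: dict[float, tuple[float, float]] = {
    50.0: (79.89, 2.72),
    55.0: (67.94, 0.61),
    60.0: (76.20, 0.40),
    65.0: (84.48, 2.28),
    70.0: (77.78, 0.49),
}

#: Published quality-vs-temperature regression equations, coefficients
#: highest degree first, with desirability direction.  The published L* and
#: a* equations are internally inconsistent with the colour table (the a*
#: equation evaluates to about -1277 at 50 °C against a measured 11.02) —
#: almost certainly a typographic corruption — so only the internally
#: consistent equations are included here.
RESPONSE_EQUATIONS: dict[str, dict[str, object]] = {
    "moisture": {"coeffs": (0.0122, -1.6715, 74.2269), "direction": "minimize"},
    "ash": {"coeffs": (-0.0027, 0.295, -3.6958), "direction": "maximize"},
    "tta": {"coeffs": (-0.0296, 6.7451), "direction": "maximize"},
    "rs": {"coeffs": (0.0122, -1.2357, 63.081), "direction": "maximize"},
    "vc": {"coeffs": (-9.3083, 1265.2979, -35990.4010), "direction": "maximize"},
    "tc": {"coeffs": (0.4054, -54.853, 1914.7668), "direction": "maximize"},
    "hue": {"coeffs": (0.004, -0.8504, 104.26), "direction": "target:63.46"},
}


def wet_to_dry_basis(x_wb: float) -> float:
    """Convert moisture from % wet basis to % dry basis."""
    if not 0 <= x_wb < 100:
        raise ValueError(f"wet-basis moisture must be in [0, 100): {x_wb}")
    return 100.0 * x_wb / (100.0 - x_wb)


def dry_to_wet_basis(x_db: float) -> float:
    """Convert moisture from % dry basis to % wet basis."""
    if x_db < 0:
        raise ValueError(f"dry-basis moisture must be >= 0: {x_db}")
    return 100.0 * x_db / (100.0 + x_db)


#: Initial foam moisture (% d.b.), from the 91.95 % w.b. fresh-foam moisture.
M0_DRY_BASIS = wet_to_dry_basis(91.95)

#: Equilibrium moisture (% d.b.) per temperature, from the final powder
#: wet-basis moisture at that temperature.
ME_DRY_BASIS: dict[float, float] = {
    t: wet_to_dry_basis(MOISTURE_WB[t][0]) for t in TEMPERATURES_C
}
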