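"""CIELAB-derived colour descriptors: chroma, hue angle, browning index.

The browning index condenses L*, a*, b* into a scalar measure of brown
discoloration (non-enzymatic browning):

    Y  = (a* + 1.75 L*) / (5.645 L* + a* - 3.012 b*)
    BI = 100 (Y - 0.31) / 0.17

Note that BI is nonlinear in (L*, a*, b*): the BI of replicate means is
not the mean of replicate BIs.  :func:`browning_index_summary` computes
both when replicates are available and records which one is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class UndefinedHueError(ValueError):
    """Hue angle is undefined at the achromatic point a* = b* = 0."""


def chroma(a_star: float, b_star: float) -> float:
    """Chroma C* = sqrt(a*^2 + b*^2): saturation of the colour."""
    return float(np.hypot(a_star, b_star))


def hue_angle(a_star: float, b_star: float) -> float:
    """Hue angle h* in degrees, quadrant-aware, mapped to [0, 360)."""
    if a_star == 0 and b_star == 0:
        raise UndefinedHueError("hue is undefined at a* = b* = 0")
    return float(np.degrees(np.arctan2(b_star, a_star)) % 360.0)


def browning_Y(L: float, a: float, b: float) -> float:
    """Chromaticity-like intermediate Y of the browning index."""
    denom = 5.645 * L + a - 3.012 * b
    if denom == 0:
        raise ValueError("browning index undefined: 5.645 L* + a* - 3.012 b* = 0")
    return (a + 1.75 * L) / denom


def browning_index(L: float, a: float, b: float) -> float:
    """Browning index BI = 100 (Y - 0.31) / 0.17."""
    return 100.0 * (browning_Y(L, a, b) - 0.31) / 0.17


@dataclass(frozen=True)
class ColorPoint:
    """A CIELAB triple with its derived descriptors."""

    L_star: float
    a_star: float
    b_star: float
    C_star: float = field(init=False)
    h_star: float = field(init=False)
    Y_bi: float = field(init=False)
    BI: float = field(init=False)

    def __post_init__(self):
        if not 0 <= self.L_star <= 100:
            raise ValueError(f"L* must be in [0, 100]: {self.L_star}")
        object.__setattr__(self, "C_star", chroma(self.a_star, self.b_star))
        object.__setattr__(self, "h_star", hue_angle(self.a_star, self.b_star))
        object.__setattr__(self, "Y_bi", browning_Y(self.L_star, self.a_star, self.b_star))
        object.__setattr__(
            self, "BI", browning_index(self.L_star, self.a_star, self.b_star)
        )


def browning_index_summary(L, a, b) -> dict[str, float]:
    """BI of replicate means and mean of per-replicate BIs.

    Returns ``{"bi_of_means": ..., "mean_of_bis": ..., "n": ...}``.  The
    two differ because BI is nonlinear; tables built from published means
    can only provide the former.
    """
    L = np.asarray(L, float)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if not (L.shape == a.shape == b.shape):
        raise ValueError("replicate arrays must share a shape")
    per_rep = [browning_index(Li, ai, bi) for Li, ai, bi in zip(L.ravel(), a.ravel(), b.ravel())]
    return {
        "bi_of_means": browning_index(float(L.mean()), float(a.mean()), float(b.mean())),
        "mean_of_bis": float(np.mean(per_rep)),
        "n": int(L.size),
    }
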