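"""Spectrophotometric pigment assay: absorbance -> mg/g pigment contents.

Chlorophylls and carotenoids extracted in 96 % ethanol absorb maximally at
665, 649 and 470 nm.  From the blank-corrected absorbances the extract
concentrations follow the Lichtenthaler-form equations (all in ug/mL):

    Ca   = 13.95 * A665 - 6.88 * A649
    Cb   = 24.96 * A649 - 7.32 * A665
    Ccar = (1000 * A470 - 2.05 * Ca - 114.8 * Cb) / 245

The Chl terms inside the carotenoid equation are the extract concentrations
Ca and Cb (ug/mL), not the per-gram outputs: that is the standard
Lichtenthaler form and the only reading with consistent units.  Each
concentration converts to tissue content via C * V / (1000 * W) with V the
extract volume (mL) and W the fresh sample mass (g), giving mg per g fresh
weight; total pigment content is the exact sum of the three.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AbsorbanceReading", "PigmentVector", "pigment_from_absorbance", "tpc"]


@dataclass(frozen=True)
class AbsorbanceReading:
    """Blank-corrected absorbances plus extraction volume/mass."""

    dA665: float
    dA649: float
    dA470: float
    V: float  # extract volume, mL
    W: float  # fresh sample mass, g

    def __post_init__(self):
        if self.V <= 0 or self.W <= 0:
            raise ValueError("V and W must be positive")
        if min(self.dA665, self.dA649, self.dA470) < 0:
            raise ValueError("absorbances must be non-negative")


@dataclass(frozen=True)
class PigmentVector:
    """Pigment contents in mg per g fresh weight; tpc = chla + chlb + car.

    ``flagged`` marks vectors with a negative component (possible with noisy
    absorbances); values are preserved, never clipped, so downstream
    statistics stay unbiased.
    """

    chla: float
    chlb: float
    car: float
    tpc: float
    flagged: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.chla, self.chlb, self.car, self.tpc])


def tpc(chla: float, chlb: float, car: float) -> float:
    """Total pigment content: the exact sum of the three components."""
    return chla + chlb + car


def pigment_from_absorbance(a: AbsorbanceReading) -> PigmentVector:
    """Evaluate the assay equations for one reading."""
    ca = 13.95 * a.dA665 - 6.88 * a.dA649  # ug/mL
    cb = 24.96 * a.dA649 - 7.32 * a.dA665
    ccar = (1000.0 * a.dA470 - 2.05 * ca - 114.8 * cb) / 245.0
    scale = a.V / (1000.0 * a.W)  # ug/mL -> mg/g
    chla, chlb, car = ca * scale, cb * scale, ccar * scale
    flagged = min(chla, chlb, car) < 0
    return PigmentVector(chla, chlb, car, tpc(chla, chlb, car), flagged)


def assay_table(readings: pd.DataFrame) -> pd.DataFrame:
    """Vectorized assay over a readings table.

    Expects columns ``sample_id, dA665, dA649, dA470, V_ml, W_g``; returns
    the same table with ``chla, chlb, car, tpc, flag`` appended.
    """
    out = readings.copy()
    rows = [
        pigment_from_absorbance(
            AbsorbanceReading(r.dA665, r.dA649, r.dA470, r.V_ml, r.W_g)
        )
        for r in readings.itertuples()
    ]
    out["chla"] = [r.chla for r in rows]
    out["chlb"] = [r.chlb for r in rows]
    out["car"] = [r.car for r in rows]
    out["tpc"] = [r.tpc for r in rows]
    out["flag"] = [r.flagged for r in rows]
    return out
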