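"""Production-level energy: the intake discount and ME conversion.

At production intakes (taken as three times maintenance) faster ruminal
passage depresses digestibility, so maintenance TDN is discounted before
conversion to metabolizable energy:

    TDN_3x = TDN_1x                              if TDN_1x <= 60
    TDN_3x = TDN_1x - (0.18*TDN_1x - 10.3)*2     if TDN_1x >  60
    ME_3x  = 0.036 * TDN_3x                      (Mcal/kg DM)

The published rule is silent at exactly 60; the no-discount branch is
applied there, which keeps TDN_3x <= TDN_1x everywhere.  The rule is
discontinuous: the discount is 1.0 unit just above 60.  It is applied as
printed, not smoothed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .summative import DndfMethod, TDNPrediction

__all__ = ["EnergyAtProduction", "tdn_3x", "me_3x", "energy_table"]

#: TDN threshold (%) above which the intake discount applies
DISCOUNT_THRESHOLD = 60.0

#: Mcal of metabolizable energy per kg DM per TDN percentage point
ME_PER_TDN = 0.036


def tdn_3x(tdn_1x: float) -> float:
    """Discount maintenance TDN to three-times-maintenance intake."""
    if not math.isfinite(tdn_1x):
        raise ValueError(f"tdn_1x={tdn_1x} must be finite")
    if tdn_1x <= DISCOUNT_THRESHOLD:
        return tdn_1x
    return tdn_1x - (0.18 * tdn_1x - 10.3) * 2.0


def me_3x(tdn_3x_value: float) -> float:
    """Metabolizable energy at production intake, Mcal/kg DM."""
    if tdn_3x_value < 0:
        raise ValueError(f"tdn_3x={tdn_3x_value} must be >= 0")
    return ME_PER_TDN * tdn_3x_value


@dataclass(frozen=True)
class EnergyAtProduction:
    """Maintenance TDN with its production-level discount and ME."""

    feed_id: str
    tdn_1x: float

    @property
    def tdn_3x(self) -> float:
        return tdn_3x(self.tdn_1x)

    @property
    def me_3x(self) -> float:
        return me_3x(self.tdn_3x)


def energy_table(predictions: Sequence[TDNPrediction],
                 method: DndfMethod = DndfMethod.IVdNDF) -> pd.DataFrame:
    """Per-feed energy table (tdn_1x, tdn_3x, me_3x) for one dNDF method.

    The in vitro unit-coefficient model is the default basis, being the
    most precise of the summative variants against observed digestibility.
    """
    rows = []
    for p in predictions:
        if p.method is not method:
            continue
        e = EnergyAtProduction(p.feed_id, p.tdn_1x)
        rows.append({"feed_id": e.feed_id, "tdn_1x": e.tdn_1x,
                     "tdn_3x": e.tdn_3x, "me_3x": e.me_3x})
    return pd.DataFrame(rows, columns=["feed_id", "tdn_1x", "tdn_3x",
                                       "me_3x"])
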