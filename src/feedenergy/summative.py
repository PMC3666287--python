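"""Summative total-digestible-nutrient (TDN) models.

A summative model predicts TDN at maintenance intake as the sum of the
truly digestible nutrient fractions minus a constant metabolic fecal loss:

    TDN_1x = dCP + 2.25*dFA + dNFC + dNDF - 7        (% of DM)

The protein, fat and non-fiber-carbohydrate terms are shared by all model
variants; the variants differ only in how the digestible NDF term is
obtained:

``LSdNDF``
    surface-law form driven by lignin and chemistry alone,
    0.75*((NDF-NDICP)-L)*(1-(L/(NDF-NDICP))^0.667);
``IVdNDF`` / ``IVdNDF_075``
    48-h in vitro NDF degradability scaled by NDF, with unit or 0.75
    coefficient;
``ISdNDF``
    48-h in situ (nylon-bag) NDF degradability scaled by NDF;
``RochaJunior``
    the surface-law form re-fit for tropical conditions,
    0.6232*((NDF-NDICP)-L)*(1-(L/(NDF-NDICP))^1.2258).

All arithmetic is carried at full floating precision; rounding to the
one-decimal presentation of feed tables happens only in report rendering.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .feed_data import (DegradabilityRecord, FeedComposition, FeedTable,
                        FeedValidationError)

__all__ = [
    "DndfMethod",
    "TDNPrediction",
    "MissingDegradabilityError",
    "digestible_cp",
    "digestible_fa",
    "digestible_nfc",
    "dndf_surface_law",
    "dndf_from_degradability",
    "dndf_rocha_junior",
    "predict_tdn",
    "predict_all",
    "predictions_frame",
    "pivot_tdn",
]

#: metabolic fecal (endogenous) TDN loss, percentage units
ENDOGENOUS_TDN_LOSS = 7.0


class DndfMethod(enum.Enum):
    """How the digestible-NDF term of the summative equation is obtained."""

    LSdNDF = "LSdNDF"
    IVdNDF_075 = "0.75IVdNDF"
    IVdNDF = "IVdNDF"
    ISdNDF = "ISdNDF"
    RochaJunior = "Rocha-Junior"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: fixed presentation order for multi-method reports
METHOD_ORDER: tuple[DndfMethod, ...] = (
    DndfMethod.LSdNDF, DndfMethod.IVdNDF_075, DndfMethod.IVdNDF,
    DndfMethod.ISdNDF, DndfMethod.RochaJunior,
)


class MissingDegradabilityError(FeedValidationError):
    """A dNDF method requires a degradability field that is absent."""

    def __init__(self, feed_id: str, method: DndfMethod, field: str):
        self.method = method
        self.field = field
        super().__init__(
            f"method {method.value} requires degradability field "
            f"{field!r}", feed_id)


def digestible_cp(cp: float, adicp: float, feed_class: str) -> float:
    """Truly digestible crude protein, % of DM.

    Unavailability of CP grows with the fraction bound to acid detergent
    fiber; forages use an exponential form, concentrates a linear one:

        forage:       CP * exp(-1.2 * ADICP/CP)
        concentrate:  CP * (1 - 0.4 * ADICP/CP)
    """
    if cp <= 0:
        raise ValueError(f"cp={cp}: digestible CP undefined for cp <= 0")
    if adicp < 0:
        raise ValueError(f"adicp={adicp} must be >= 0")
    ratio = adicp / cp
    if feed_class == "forage":
        return cp * math.exp(-1.2 * ratio)
    if feed_class == "concentrate":
        return cp * max(0.0, 1.0 - 0.4 * ratio)
    raise ValueError(f"unknown feed_class {feed_class!r}")


def digestible_fa(ee: float) -> float:
    """Digestible fatty acids, % of DM: EE - 1, clamped at zero.

    The unit subtraction treats one percentage point of ether extract as
    non-fatty-acid lipid; feeds with EE below 1% contribute no digestible
    fat rather than a negative amount.
    """
    if ee < 0:
        raise ValueError(f"ee={ee} must be >= 0")
    return max(0.0, ee - 1.0)


def digestible_nfc(nfc: float, fap: float = 1.0) -> float:
    """Truly digestible non-fiber carbohydrate: FAP * 0.98 * NFC."""
    if nfc < 0:
        raise ValueError(f"nfc={nfc} must be >= 0")
    if fap <= 0:
        raise ValueError(f"fap={fap} must be > 0")
    return fap * 0.98 * nfc


def _surface_form(ndf: float, ndicp: float, lignin: float,
                  scale: float, exponent: float) -> float:
    pndf = ndf - ndicp  # protein-free NDF mass
    if pndf <= 0:
        raise ValueError(f"ndf-ndicp={pndf} must be > 0")
    if lignin < 0 or lignin > pndf:
        raise ValueError(
            f"lignin={lignin} outside [0, ndf-ndicp={pndf}]")
    return scale * (pndf - lignin) * (1.0 - (lignin / pndf) ** exponent)


def dndf_surface_law(ndf: float, ndicp: float, lignin: float) -> float:
    """Digestible NDF from chemistry alone via the surface law.

    Indigestibility scales with the lignin-to-fiber ratio raised to the
    2/3 power (printed coefficient 0.667), reflecting lignin shielding of
    the digestible fiber surface; 0.75 is the digestion coefficient of the
    potentially digestible fraction.
    """
    return _surface_form(ndf, ndicp, lignin, 0.75, 0.667)


def dndf_rocha_junior(ndf: float, ndicp: float, lignin: float) -> float:
    """Surface-law digestible NDF with coefficients re-fit for tropical
    feeds (scale 0.6232, exponent 1.2258)."""
    return _surface_form(ndf, ndicp, lignin, 0.6232, 1.2258)


def dndf_from_degradability(ndfd: float, ndf: float,
                            coefficient: float = 1.0) -> float:
    """Digestible NDF from a measured 48-h NDF degradability (%).

    ``coefficient`` is 1.0 when the assay is taken at face value and 0.75
    when degradability is treated as the potentially digestible fraction.
    """
    if not 0.0 <= ndfd <= 100.0:
        raise ValueError(f"ndfd={ndfd} outside [0, 100]")
    if ndf < 0:
        raise ValueError(f"ndf={ndf} must be >= 0")
    if coefficient <= 0:
        raise ValueError(f"coefficient={coefficient} must be > 0")
    return coefficient * (ndfd / 100.0) * ndf


@dataclass(frozen=True)
class TDNPrediction:
    """Digestible fractions and maintenance-level TDN for one feed/method.

    ``d_fa`` is stored before the 2.25 energy multiplier; ``tdn_1x``
    always equals ``d_cp + 2.25*d_fa + d_nfc + d_ndf - 7``.
    """

    feed_id: str
    method: DndfMethod
    d_cp: float
    d_fa: float
    d_nfc: float
    d_ndf: float

    @property
    def tdn_1x(self) -> float:
        return (self.d_cp + 2.25 * self.d_fa + self.d_nfc + self.d_ndf
                - ENDOGENOUS_TDN_LOSS)


def _required_field(method: DndfMethod) -> str | None:
    return {
        DndfMethod.IVdNDF: "ivndfd_48",
        DndfMethod.IVdNDF_075: "ivndfd_48",
        DndfMethod.ISdNDF: "isndfd_48",
    }.get(method)


def predict_tdn(comp: FeedComposition,
                degr: DegradabilityRecord | None,
                method: DndfMethod) -> TDNPrediction:
    """Predict maintenance-level TDN for one feed under one dNDF method."""
    if method in (DndfMethod.LSdNDF, DndfMethod.RochaJunior):
        fn = (dndf_surface_law if method is DndfMethod.LSdNDF
              else dndf_rocha_junior)
        d_ndf = fn(comp.ndf, comp.ndicp, comp.lignin)
    else:
        field = _required_field(method)
        value = getattr(degr, field, None) if degr is not None else None
        if value is None:
            raise MissingDegradabilityError(comp.feed_id, method, field)
        coeff = 0.75 if method is DndfMethod.IVdNDF_075 else 1.0
        d_ndf = dndf_from_degradability(value, comp.ndf, coeff)

    if comp.nfc is None:
        raise FeedValidationError("nfc required for dNFC", comp.feed_id)
    return TDNPrediction(
        feed_id=comp.feed_id,
        method=method,
        d_cp=digestible_cp(comp.cp, comp.adicp, comp.feed_class),
        d_fa=digestible_fa(comp.ee),
        d_nfc=digestible_nfc(comp.nfc, comp.fap),
        d_ndf=d_ndf,
    )


def predict_all(table: FeedTable,
                methods: Iterable[DndfMethod] = METHOD_ORDER
                ) -> list[TDNPrediction]:
    """One prediction per feed x method, in input row order then the fixed
    method order.  Per-feed failures propagate with feed_id context."""
    chosen = [m for m in METHOD_ORDER if m in set(methods)]
    out: list[TDNPrediction] = []
    for comp, degr in table:
        for method in chosen:
            out.append(predict_tdn(comp, degr, method))
    return out


def predictions_frame(predictions: Sequence[TDNPrediction]) -> pd.DataFrame:
    """Long-format frame: one row per (feed, method) with all fractions."""
    return pd.DataFrame(
        [{"feed_id": p.feed_id, "method": p.method.value,
          "d_cp": p.d_cp, "d_fa": p.d_fa, "d_nfc": p.d_nfc,
          "d_ndf": p.d_ndf, "tdn_1x": p.tdn_1x}
         for p in predictions],
        columns=["feed_id", "method", "d_cp", "d_fa", "d_nfc", "d_ndf",
                 "tdn_1x"])


def pivot_tdn(predictions: Sequence[TDNPrediction]) -> pd.DataFrame:
    """Feeds x methods table of TDN_1x, mirroring the usual presentation."""
    long = predictions_frame(predictions)
    order = [m.value for m in METHOD_ORDER if m.value in
             set(long["method"])]
    wide = long.pivot(index="feed_id", columns="method", values="tdn_1x")
    feed_order = list(dict.fromkeys(long["feed_id"]))
    return wide.loc[feed_order, order]
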