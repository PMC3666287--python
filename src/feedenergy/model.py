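"""Model/Results facade over the summative-TDN analysis.

:class:`SummativeTDN` is constructed from a :class:`~feedenergy.feed_data.
FeedTable` (or CSV files / DataFrames); ``fit()`` runs every requested
dNDF variant over every feed, regresses each variant's predictions on the
observed 48-h in vitro true DM digestibility, calibrates the in situ
against the in vitro NDF assay, and discounts one variant's TDN to
production intake.  The returned :class:`SummativeTDNResults` carries the
per-feed predictions, the per-method regression fits with their standard
errors, the energy table, and a ``summary()`` rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .energy import energy_table
from .evaluation import (PrecisionReport, RegressionFit, calibrate_ndfd,
                         evaluate_models)
from .feed_data import FeedTable, read_feed_table
from .summative import (METHOD_ORDER, DndfMethod, TDNPrediction,
                        predict_all, predictions_frame, pivot_tdn)

__all__ = ["SummativeTDN", "SummativeTDNResults"]


class SummativeTDN:
    """Summative TDN analysis of a feed table.

    Parameters
    ----------
    table : FeedTable
        Validated feed chemistry and degradability rows.
    methods : iterable of DndfMethod, optional
        dNDF variants to run; all five by default.
    energy_method : DndfMethod
        Variant whose TDN is discounted to production intake
        (default the unit-coefficient in vitro model).
    """

    def __init__(self, table: FeedTable,
                 methods: Iterable[DndfMethod] = METHOD_ORDER,
                 energy_method: DndfMethod = DndfMethod.IVdNDF):
        if len(table) == 0:
            raise ValueError("feed table is empty")
        self.table = table
        self.methods = tuple(m for m in METHOD_ORDER if m in set(methods))
        if not self.methods:
            raise ValueError("at least one dNDF method must be selected")
        self.energy_method = energy_method

    @classmethod
    def from_csv(cls, composition_path: str | Path,
                 degradability_path: str | Path | None = None,
                 **kwargs) -> "SummativeTDN":
        """Build the model from the two-file CSV layout."""
        return cls(read_feed_table(composition_path, degradability_path),
                   **kwargs)

    def fit(self) -> "SummativeTDNResults":
        """Run predictions, precision regressions, the NDFD calibration
        and the energy discount.

        The precision regressions and the calibration are skipped (left
        ``None``) when the table lacks the observed columns they need;
        the energy table is empty when the chosen energy method was not
        run.
        """
        predictions = predict_all(self.table, self.methods)
        precision = calibration = None
        try:
            precision = evaluate_models(self.table, predictions)
        except ValueError:
            pass
        try:
            calibration = calibrate_ndfd(self.table)
        except ValueError:
            pass
        energy = energy_table(predictions, self.energy_method)
        return SummativeTDNResults(
            model=self, predictions=predictions, precision=precision,
            calibration=calibration, energy=energy)


@dataclass
class SummativeTDNResults:
    """Fitted summative-TDN analysis."""

    model: SummativeTDN
    predictions: list[TDNPrediction]
    precision: PrecisionReport | None
    calibration: RegressionFit | None
    energy: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def predictions_long(self) -> pd.DataFrame:
        """One row per (feed, method) with all digestible fractions."""
        return predictions_frame(self.predictions)

    @property
    def tdn_table(self) -> pd.DataFrame:
        """Feeds x methods table of maintenance TDN (%)."""
        return pivot_tdn(self.predictions)

    def summary(self, decimals: int = 1) -> str:
        """Plain-text rendering of the fitted tables."""
        lines = ["Summative TDN analysis",
                 f"  feeds: {len(self.model.table)}   methods: "
                 + ", ".join(m.value for m in self.model.methods), ""]
        lines.append("Predicted TDN at maintenance (% of DM)")
        lines.append(self.tdn_table.round(decimals).to_string())
        if self.precision is not None:
            lines += ["", "Precision: OLS of predicted TDN on observed "
                          "IVTDMD-48"]
            prec = self.precision.to_frame().set_index("method")
            lines.append(prec.round({"intercept": 3, "slope": 4,
                                     "r_squared": 2}).to_string())
        if self.calibration is not None:
            c = self.calibration
            lines += ["", "NDFD calibration (in situ on in vitro, 48 h):",
                      f"  {c}"]
        if not self.energy.empty:
            lines += ["", "Energy at production intake "
                          f"({self.model.energy_method.value} basis)"]
            lines.append(self.energy.set_index("feed_id")
                         .round({"tdn_1x": decimals, "tdn_3x": decimals,
                                 "me_3x": 1}).to_string())
        return "\n".join(lines)

    def plot_precision(self, method: DndfMethod, ax=None):
        """Scatter of predicted TDN against observed IVTDMD-48 with the
        fitted line and the identity line."""
        import matplotlib.pyplot as plt

        if self.precision is None:
            raise ValueError("no precision fits available")
        fit = self.precision[method]
        obs = {c.feed_id: d.ivtdmd_48 for c, d in self.model.table
               if d is not None}
        pts = [(obs[p.feed_id], p.tdn_1x) for p in self.predictions
               if p.method is method]
        x, y = zip(*pts)
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(x, y, color="k")
        ax.plot(sorted(x), fit.predict(sorted(x)), label=str(fit))
        lims = [min(x), max(x)]
        ax.plot(lims, lims, ls="--", color="grey", label="identity")
        ax.set_xlabel("observed IVTDMD-48 (%)")
        ax.set_ylabel(f"predicted TDN, {method.value} (%)")
        ax.legend(fontsize=8)
        return ax

    def plot_calibration(self, ax=None):
        """In situ vs in vitro 48-h NDF degradability with the OLS line."""
        import matplotlib.pyplot as plt

        if self.calibration is None:
            raise ValueError("no calibration fit available")
        pairs = [(d.ivndfd_48, d.isndfd_48) for _, d in self.model.table
                 if d is not None and d.ivndfd_48 is not None
                 and d.isndfd_48 is not None]
        x, y = zip(*pairs)
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(x, y, color="k")
        ax.plot(sorted(x), self.calibration.predict(sorted(x)),
                label=str(self.calibration))
        ax.set_xlabel("IVNDFD-48 (%)")
        ax.set_ylabel("ISNDFD-48 (%)")
        ax.legend(fontsize=8)
        return ax
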