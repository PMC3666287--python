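"""Model precision via simple linear regression.

The precision of each summative TDN variant is judged by ordinary least
squares of its predicted TDN (y) on observed 48-h in vitro true DM
digestibility (x) across feeds: a model whose ranking of feeds tracks the
fermentation assay closely earns a high coefficient of determination.
A second regression calibrates the in situ NDF degradability assay
against the in vitro one.

The regression is computed from centered sums (slope = Sxy/Sxx,
intercept = ybar - slope*xbar, R^2 = Sxy^2/(Sxx*Syy)) so the numerical
contract is explicit and environment-independent; standard errors use the
usual residual-variance formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .feed_data import FeedTable
from .summative import METHOD_ORDER, DndfMethod, TDNPrediction

__all__ = [
    "RegressionFit",
    "PrecisionReport",
    "fit_simple_regression",
    "evaluate_models",
    "calibrate_ndfd",
]


@dataclass(frozen=True)
class RegressionFit:
    """Simple-linear-regression estimates and diagnostics.

    ``stderr_intercept``/``stderr_slope`` are NaN when n == 2 (zero
    residual degrees of freedom).
    """

    intercept: float
    slope: float
    r_squared: float
    n: int
    stderr_intercept: float = float("nan")
    stderr_slope: float = float("nan")
    residual_sd: float = float("nan")

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def __str__(self) -> str:
        return (f"y = {self.intercept:+.3f} + {self.slope:.4f} x "
                f"(R^2 = {self.r_squared:.2f}, n = {self.n})")


def fit_simple_regression(x: Sequence[float],
                          y: Sequence[float]) -> RegressionFit:
    """OLS of y on x with intercept, from centered sums.

    Raises ``ValueError`` on length mismatch, fewer than two points, or
    constant x (undefined slope).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError(
            f"x and y must be equal-length 1-d sequences "
            f"(got {xa.shape} and {ya.shape})")
    n = xa.size
    if n < 2:
        raise ValueError(f"need at least 2 points, got {n}")
    dx = xa - xa.mean()
    dy = ya - ya.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    sxy = float(dx @ dy)
    if sxx == 0.0:
        raise ValueError("x is constant; slope undefined")
    slope = sxy / sxx
    intercept = float(ya.mean()) - slope * float(xa.mean())
    r2 = 1.0 if syy == 0.0 else sxy * sxy / (sxx * syy)
    sse = syy - slope * sxy
    if n > 2:
        s2 = max(0.0, sse) / (n - 2)
        se_slope = math.sqrt(s2 / sxx)
        se_int = math.sqrt(s2 * (1.0 / n + xa.mean() ** 2 / sxx))
        resid_sd = math.sqrt(s2)
    else:
        se_slope = se_int = resid_sd = float("nan")
    return RegressionFit(intercept=intercept, slope=slope,
                         r_squared=min(1.0, max(0.0, r2)), n=n,
                         stderr_intercept=se_int, stderr_slope=se_slope,
                         residual_sd=resid_sd)


@dataclass
class PrecisionReport:
    """Per-method regression of predicted TDN on observed IVTDMD-48."""

    fits: dict[DndfMethod, RegressionFit] = field(default_factory=dict)

    def __getitem__(self, method: DndfMethod) -> RegressionFit:
        return self.fits[method]

    def __iter__(self):
        return iter(self.fits.items())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"method": m.value, "intercept": f.intercept,
                 "slope": f.slope, "r_squared": f.r_squared, "n": f.n}
                for m, f in self.fits.items()]
        return pd.DataFrame(rows, columns=["method", "intercept", "slope",
                                           "r_squared", "n"])


def evaluate_models(table: FeedTable,
                    predictions: Sequence[TDNPrediction]
                    ) -> PrecisionReport:
    """Regress each method's predicted TDN on observed IVTDMD-48.

    Every feed in ``table`` must carry ``ivtdmd_48`` and a prediction for
    every method present in ``predictions``; the pairing is by feed_id, so
    the result is invariant to row order.
    """
    observed: dict[str, float] = {}
    for comp, degr in table:
        if degr is None or degr.ivtdmd_48 is None:
            raise ValueError(
                f"{comp.feed_id!r}: ivtdmd_48 required for model "
                "evaluation")
        observed[comp.feed_id] = degr.ivtdmd_48

    by_method: dict[DndfMethod, dict[str, float]] = {}
    for p in predictions:
        by_method.setdefault(p.method, {})[p.feed_id] = p.tdn_1x

    report = PrecisionReport()
    feed_ids = sorted(observed)
    for method in METHOD_ORDER:
        if method not in by_method:
            continue
        preds = by_method[method]
        missing = [f for f in feed_ids if f not in preds]
        if missing:
            raise ValueError(
                f"method {method.value}: missing predictions for "
                f"{missing}")
        x = [observed[f] for f in feed_ids]
        y = [preds[f] for f in feed_ids]
        report.fits[method] = fit_simple_regression(x, y)
    return report


def calibrate_ndfd(table: FeedTable) -> RegressionFit:
    """OLS of in situ on in vitro 48-h NDF degradability across feeds."""
    pairs = [(d.ivndfd_48, d.isndfd_48) for _, d in table
             if d is not None and d.ivndfd_48 is not None
             and d.isndfd_48 is not None]
    if len(pairs) < 2:
        raise ValueError(
            f"need at least 2 feeds with both ivndfd_48 and isndfd_48, "
            f"got {len(pairs)}")
    x, y = zip(*pairs)
    return fit_simple_regression(x, y)
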