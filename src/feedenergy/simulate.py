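"""Seeded synthetic feed tables and fixture verification.

The generator produces feed tables that satisfy every structural
invariant of :mod:`feedenergy.feed_data` by construction: component
fractions close to 100 via the NFC-by-difference identity, NDICP below
NDF, lignin below the protein-free NDF mass.  Default parameter ranges
emulate the variability of the bundled twelve-feed table (CP 4.3-17.7%,
NDF 25.9-77.9% of DM, and so on), so synthetic tables exercise the same
regime as the real one.

Chemistry and degradability are linked through the surface law: the
"true" 48-h NDF degradability of a synthetic feed is the value that makes
the degradability-driven dNDF equal the chemistry-driven (surface-law)
one.  ``degradability_mode`` controls what is observed:

``surface_law_exact``
    assays report the true value exactly (useful for equivalence tests);
``surface_law_noisy``
    independent truncated-Gaussian observation noise of sd ``noise_sd``
    is added to each assay (clipped to [0, 100], not resampled);
``independent``
    assay values are drawn uniformly from the ``ndfd`` range, severing
    the chemistry link.

The observed in vitro true DM digestibility is generated as a
true-digestibility proxy: the sum of the digestible fractions
dCP + 2.25*dFA + dNFC + dNDF (no endogenous-loss subtraction), clipped to
[0, 100], plus the mode's observation noise.  In the surface-law modes
dNDF is the chemistry-implied value; in ``independent`` mode it follows
the drawn in vitro NDF degradability.  This proxy is a modelling
convenience for exercising the evaluation pipeline, not an assay model.

Randomness: one integer seed; each field draws from its own sub-stream
keyed by a CRC-32 of the field name (so later additions cannot shift
existing draws), in the documented field order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .energy import tdn_3x
from .evaluation import calibrate_ndfd, evaluate_models
from .feed_data import (DegradabilityRecord, FeedComposition, FeedTable,
                        load_example_feeds, load_reference_tables)
from .summative import (METHOD_ORDER, MissingDegradabilityError,
                        digestible_cp, digestible_fa, digestible_nfc,
                        dndf_surface_law, predict_tdn)

__all__ = [
    "SyntheticConfig",
    "generate_feed_table",
    "regenerate_fixture_checks",
    "FixtureCheckReport",
    "DEFAULT_RANGES",
    "NDFD_CALIBRATION_REFERENCE",
]

DEGRADABILITY_MODES = ("surface_law_exact", "surface_law_noisy",
                       "independent")

#: default per-field (min, max) draws, chosen to emulate the bundled table
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "dm": (74.0, 96.5),
    "cp": (4.3, 17.7),
    "ee": (0.8, 3.5),
    "ash": (3.5, 15.0),
    "ndf": (25.9, 77.9),
    "ndicp_ratio": (0.04, 0.15),     # NDICP as a fraction of NDF
    "lignin_ratio": (0.08, 0.26),    # lignin / (NDF - NDICP)
    "adicp_ratio": (0.20, 0.70),     # ADICP as a fraction of NDICP
    "ndfd": (5.0, 95.0),             # only used in independent mode
}

_RATIO_FIELDS = ("ndicp_ratio", "lignin_ratio", "adicp_ratio")

#: field-stream draw order (documented; new fields append, never reorder)
_FIELD_ORDER = ("feed_class", "dm", "cp", "ee", "ash", "ndicp_ratio",
                "ndf", "lignin_ratio", "adicp_ratio", "ivndfd_noise",
                "isndfd_noise", "ivtdmd_noise", "ivndfd_indep",
                "isndfd_indep")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic feed-table generator."""

    seed: int
    n_feeds: int = 12
    forage_fraction: float = 8.0 / 12.0
    ranges: dict[str, tuple[float, float]] = dc_field(
        default_factory=lambda: dict(DEFAULT_RANGES))
    degradability_mode: str = "surface_law_noisy"
    noise_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.n_feeds < 1:
            raise ValueError(f"n_feeds={self.n_feeds} must be >= 1")
        if not 0.0 <= self.forage_fraction <= 1.0:
            raise ValueError("forage_fraction must be in [0, 1]")
        if self.degradability_mode not in DEGRADABILITY_MODES:
            raise ValueError(
                f"degradability_mode={self.degradability_mode!r} not in "
                f"{DEGRADABILITY_MODES}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        merged = dict(DEFAULT_RANGES)
        merged.update(self.ranges)
        self.ranges = merged
        for name, (lo, hi) in self.ranges.items():
            upper = 1.0 if name in _RATIO_FIELDS else 100.0
            if not (0.0 <= lo <= hi <= upper):
                raise ValueError(
                    f"range {name}=({lo}, {hi}) must satisfy "
                    f"0 <= min <= max <= {upper}")
        if self.ranges["cp"][0] <= 0:
            raise ValueError("cp range must exclude 0 (digestible CP "
                             "is undefined at cp=0)")
        if self.ranges["ndicp_ratio"][1] >= 1.0 \
                or self.ranges["lignin_ratio"][1] >= 1.0:
            raise ValueError("ndicp_ratio and lignin_ratio maxima must "
                             "be < 1")


def _stream(seed: int, name: str) -> np.random.Generator:
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed,
                                                        spawn_key=(key,)))


def _uniform(cfg: SyntheticConfig, name: str, n: int) -> np.ndarray:
    lo, hi = cfg.ranges[name]
    return _stream(cfg.seed, name).uniform(lo, hi, size=n)


def generate_feed_table(config: SyntheticConfig) -> FeedTable:
    """Generate a validated synthetic feed table.

    NDF is drawn last among the composition fields so it can be capped at
    the value keeping NFC non-negative given the already-drawn CP, EE and
    ash; a configuration whose NDF minimum exceeds that cap for some row
    is reported as infeasible.
    """
    n = config.n_feeds
    is_forage = _stream(config.seed, "feed_class").random(n) \
        < config.forage_fraction
    dm = _uniform(config, "dm", n)
    cp = _uniform(config, "cp", n)
    ee = _uniform(config, "ee", n)
    ash = _uniform(config, "ash", n)
    ndicp_ratio = _uniform(config, "ndicp_ratio", n)

    ndf_lo, ndf_hi = config.ranges["ndf"]
    budget = 100.0 - cp - ee - ash          # room for (NDF - NDICP) + NFC
    cap = np.minimum(ndf_hi, budget / (1.0 - ndicp_ratio))
    if np.any(cap < ndf_lo):
        bad = int(np.argmax(cap < ndf_lo))
        raise ValueError(
            "infeasible ranges: NDF minimum "
            f"{ndf_lo} exceeds the feasible cap {cap[bad]:.2f} implied by "
            "the cp/ee/ash draws; shrink those ranges or lower the NDF "
            "minimum")
    u = _stream(config.seed, "ndf").random(n)
    ndf = ndf_lo + u * (cap - ndf_lo)
    ndicp = ndicp_ratio * ndf
    lignin = _uniform(config, "lignin_ratio", n) * (ndf - ndicp)
    adicp = _uniform(config, "adicp_ratio", n) * ndicp
    nfc = 100.0 - cp - (ndf - ndicp) - ee - ash

    # chemistry-implied truth for the degradability assays
    d_ndf_true = np.array([dndf_surface_law(ndf[i], ndicp[i], lignin[i])
                           for i in range(n)])
    ndfd_true = 100.0 * d_ndf_true / ndf

    mode = config.degradability_mode
    if mode == "independent":
        ivndfd = _stream(config.seed, "ivndfd_indep").uniform(
            *config.ranges["ndfd"], size=n)
        isndfd = _stream(config.seed, "isndfd_indep").uniform(
            *config.ranges["ndfd"], size=n)
        d_ndf_obs = ivndfd / 100.0 * ndf
    else:
        ivndfd = ndfd_true.copy()
        isndfd = ndfd_true.copy()
        d_ndf_obs = d_ndf_true
    classes = np.where(is_forage, "forage", "concentrate")
    proxy = np.array([
        digestible_cp(cp[i], adicp[i], classes[i])
        + 2.25 * digestible_fa(ee[i])
        + digestible_nfc(nfc[i])
        + d_ndf_obs[i]
        for i in range(n)])
    ivtdmd = proxy
    if mode == "surface_law_noisy" and config.noise_sd > 0:
        sd = config.noise_sd
        ivndfd = ivndfd + sd * _stream(config.seed,
                                       "ivndfd_noise").standard_normal(n)
        isndfd = isndfd + sd * _stream(config.seed,
                                       "isndfd_noise").standard_normal(n)
        ivtdmd = ivtdmd + sd * _stream(config.seed,
                                       "ivtdmd_noise").standard_normal(n)
    ivndfd = np.clip(ivndfd, 0.0, 100.0)
    isndfd = np.clip(isndfd, 0.0, 100.0)
    ivtdmd = np.clip(ivtdmd, 0.0, 100.0)

    rows = []
    for i in range(n):
        comp = FeedComposition(
            feed_id=f"synthetic-{i:03d}",
            feed_class=str(classes[i]),
            dm=float(dm[i]), cp=float(cp[i]), ee=float(ee[i]),
            ndf=float(ndf[i]), adf=float(0.6 * ndf[i]),
            lignin=float(lignin[i]), ndicp=float(ndicp[i]),
            adicp=float(adicp[i]), nfc=float(nfc[i]), ash=float(ash[i]))
        degr = DegradabilityRecord(
            feed_id=comp.feed_id,
            ivtdmd_48=float(ivtdmd[i]),
            ivndfd_48=float(ivndfd[i]),
            isndfd_48=float(isndfd[i]))
        rows.append((comp, degr))
    return FeedTable(rows)


NDFD_CALIBRATION_REFERENCE = {"slope": 0.8313, "intercept": 15.475,
                              "r_squared": 0.94}


@dataclass
class FixtureCheckReport:
    """Per-cell deviations of recomputed results from the published ones."""

    tdn_deviation: pd.DataFrame          # feeds x methods, computed - published
    precision: pd.DataFrame              # per method: computed, published, dev
    calibration: pd.DataFrame            # NDFD calibration: computed vs published
    energy_deviation: pd.DataFrame       # per feed: tdn_3x computed - published

    @property
    def max_abs_tdn_deviation(self) -> pd.Series:
        return self.tdn_deviation.abs().max()

    def summary(self) -> str:
        lines = ["fixture verification",
                 "  max |TDN deviation| by method:"]
        for name, v in self.max_abs_tdn_deviation.items():
            lines.append(f"    {name:12s} {v:.3f}")
        lines.append("  precision (R^2 computed vs published):")
        for name, row in self.precision.iterrows():
            lines.append(f"    {name:12s} {row['r_squared']:.3f} vs "
                         f"{row['r_squared_published']:.2f}")
        lines.append(
            "  max |TDN_3x deviation|: "
            f"{self.energy_deviation['deviation'].abs().max():.3f}")
        return "\n".join(lines)


def regenerate_fixture_checks(table: FeedTable | None = None
                              ) -> FixtureCheckReport:
    """Recompute every published result table from the bundled fixture
    (or a caller-supplied table with the same feeds) and report per-cell
    deviations.

    A method whose required degradability field is absent is reported as
    all-NaN rather than failing the whole check.
    """
    if table is None:
        table = load_example_feeds()
    refs = load_reference_tables()

    ref_tdn = refs["tdn"].set_index("feed_id")
    dev = pd.DataFrame(index=ref_tdn.index,
                       columns=[m.name for m in METHOD_ORDER],
                       dtype=float)
    predictions = []
    for method in METHOD_ORDER:
        for comp, degr in table:
            try:
                p = predict_tdn(comp, degr, method)
            except MissingDegradabilityError:
                continue
            predictions.append(p)
            if comp.feed_id in dev.index:
                dev.loc[comp.feed_id, method.name] = \
                    p.tdn_1x - ref_tdn.loc[comp.feed_id, method.name]

    ref_prec = refs["precision"]
    try:
        report = evaluate_models(table, predictions)
        prec_rows = {}
        for method, fit in report:
            pub = ref_prec.loc[method.name]
            prec_rows[method.name] = {
                "intercept": fit.intercept, "slope": fit.slope,
                "r_squared": fit.r_squared,
                "intercept_published": pub["intercept"],
                "slope_published": pub["slope"],
                "r_squared_published": pub["r_squared"],
            }
        precision = pd.DataFrame.from_dict(prec_rows, orient="index")
    except ValueError:
        precision = pd.DataFrame()

    try:
        cal = calibrate_ndfd(table)
        calibration = pd.DataFrame({
            "computed": [cal.slope, cal.intercept, cal.r_squared],
            "published": [NDFD_CALIBRATION_REFERENCE["slope"],
                          NDFD_CALIBRATION_REFERENCE["intercept"],
                          NDFD_CALIBRATION_REFERENCE["r_squared"]],
        }, index=["slope", "intercept", "r_squared"])
    except ValueError:
        calibration = pd.DataFrame()

    ref_energy = refs["energy"].set_index("feed_id")
    computed_3x = ref_energy["tdn_1x"].map(tdn_3x)
    energy = pd.DataFrame({
        "tdn_1x": ref_energy["tdn_1x"],
        "tdn_3x": computed_3x,
        "tdn_3x_published": ref_energy["tdn_3x"],
        "deviation": computed_3x - ref_energy["tdn_3x"],
    })
    return FixtureCheckReport(tdn_deviation=dev, precision=precision,
                              calibration=calibration,
                              energy_deviation=energy)
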