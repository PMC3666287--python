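"""Feed chemistry and ruminal degradability tables.

All composition fields are percentages of dry matter (DM) except ``dm``
itself, which is percent as-fed.  The non-fiber carbohydrate (NFC) fraction
is defined by difference,

    NFC = 100 - [CP + (NDF - NDICP) + EE + Ash],

so a composition that carries both ``nfc`` and ``ash`` must satisfy that
identity within a small tolerance.  Ash is frequently unreported in feed
tables; :func:`derive_ash` recovers it from NFC by the same identity.

The bundled twelve-feed example table (eight tropical forages, four
byproducts) ships as two CSV files under ``feedenergy/data`` and is loaded
with :func:`load_example_feeds`.  Three cells of the published source were
corrected during transcription; each corrected row documents the published
value in its ``note`` column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "FeedComposition",
    "DegradabilityRecord",
    "FeedTable",
    "FeedValidationError",
    "compute_nfc",
    "derive_ash",
    "read_feed_table",
    "write_feed_table",
    "load_example_feeds",
]

#: tolerance (percentage points) for the NFC-by-difference consistency check
NFC_TOLERANCE = 0.15

#: a 72-h degradability may fall below its 48-h value by at most this much
HORIZON_TOLERANCE = 0.5

COMPOSITION_COLUMNS = [
    "feed_id", "feed_class", "dm", "cp", "ee", "ndf", "adf",
    "lignin", "ndicp", "adicp", "nfc", "ash", "fap",
]
DEGRADABILITY_COLUMNS = [
    "feed_id", "ivtdmd_48", "ivtdmd_72", "ivndfd_48", "ivndfd_72",
    "isdmd_48", "isndfd_48",
]

_MANDATORY_COMPOSITION = ["feed_id", "feed_class", "cp", "ee", "ndf",
                          "lignin", "ndicp", "adicp"]
_MANDATORY_DEGRADABILITY = ["feed_id"]

FEED_CLASSES = ("forage", "concentrate")


class FeedValidationError(ValueError):
    """Raised when a feed row violates a hard structural invariant."""

    def __init__(self, message: str, feed_id: str | None = None):
        self.feed_id = feed_id
        super().__init__(message if feed_id is None
                         else f"{feed_id!r}: {message}")


def _check_fraction(name: str, value: float | None, feed_id: str | None,
                    upper: float = 100.0) -> None:
    if value is None:
        return
    if not np.isfinite(value) or value < 0 or value > upper:
        raise FeedValidationError(
            f"{name}={value} outside [0, {upper}]", feed_id)


@dataclass
class FeedComposition:
    """Proximate and detergent-fiber chemistry of one feed (% of DM).

    Parameters
    ----------
    feed_id : str
        Unique label.
    feed_class : str
        ``"forage"`` or ``"concentrate"``; selects the digestible-CP form.
    dm : float
        Dry matter, % as-fed.
    cp, ee, ndf, adf, lignin, ndicp, adicp : float
        Crude protein, ether extract, neutral/acid detergent fiber, lignin
        and the detergent-insoluble CP fractions, all % of DM.
    nfc : float, optional
        Non-fiber carbohydrates by difference.  Derived from ash when absent.
    ash : float, optional
        Derived from ``nfc`` when absent (see :func:`derive_ash`).
    fap : float
        Processing adjustment factor on NFC digestibility; 1.0 for
        unprocessed feeds.
    """

    feed_id: str
    feed_class: str
    dm: float
    cp: float
    ee: float
    ndf: float
    adf: float
    lignin: float
    ndicp: float
    adicp: float
    nfc: float | None = None
    ash: float | None = None
    fap: float = 1.0
    note: str = ""

    def __post_init__(self) -> None:
        fid = self.feed_id
        if self.feed_class not in FEED_CLASSES:
            raise FeedValidationError(
                f"feed_class={self.feed_class!r} not in {FEED_CLASSES}", fid)
        for name in ("cp", "ee", "ndf", "adf", "lignin", "ndicp", "adicp",
                     "nfc", "ash"):
            _check_fraction(name, getattr(self, name), fid)
        _check_fraction("dm", self.dm, fid)
        if self.fap <= 0:
            raise FeedValidationError(f"fap={self.fap} must be > 0", fid)
        if self.ndicp >= self.ndf:
            raise FeedValidationError(
                f"ndicp={self.ndicp} must be < ndf={self.ndf}", fid)
        if self.lignin >= self.ndf - self.ndicp:
            raise FeedValidationError(
                f"lignin={self.lignin} must be < ndf-ndicp="
                f"{self.ndf - self.ndicp}", fid)
        # soft checks: published data occasionally violate these
        if self.adf > self.ndf:
            warnings.warn(f"{fid!r}: adf ({self.adf}) > ndf ({self.ndf}); "
                          "keeping row as published data may be noisy",
                          stacklevel=2)
        if self.adicp > self.ndicp:
            warnings.warn(f"{fid!r}: adicp ({self.adicp}) > ndicp "
                          f"({self.ndicp})", stacklevel=2)
        if self.nfc is not None and self.ash is not None:
            implied = 100.0 - (self.cp + (self.ndf - self.ndicp)
                               + self.ee + self.ash)
            if abs(self.nfc - implied) > NFC_TOLERANCE:
                raise FeedValidationError(
                    f"nfc={self.nfc} inconsistent with composition "
                    f"(implies {implied:.3f})", fid)


def compute_nfc(comp: FeedComposition) -> float:
    """Non-fiber carbohydrates by difference, % of DM.

    Requires ``ash``.  May be negative for pathological inputs; a warning
    is issued in that case and the value returned as computed.
    """
    if comp.ash is None:
        raise FeedValidationError("ash required to compute nfc", comp.feed_id)
    nfc = 100.0 - (comp.cp + (comp.ndf - comp.ndicp) + comp.ee + comp.ash)
    if nfc < 0:
        warnings.warn(f"{comp.feed_id!r}: computed nfc is negative "
                      f"({nfc:.3f})", stacklevel=2)
    return nfc


def derive_ash(comp: FeedComposition) -> float:
    """Ash recovered from NFC by inverting the by-difference identity."""
    if comp.nfc is None:
        raise FeedValidationError("nfc required to derive ash", comp.feed_id)
    ash = 100.0 - comp.cp - (comp.ndf - comp.ndicp) - comp.ee - comp.nfc
    if ash < 0:
        warnings.warn(f"{comp.feed_id!r}: derived ash is negative "
                      f"({ash:.3f})", stacklevel=2)
    return ash


@dataclass
class DegradabilityRecord:
    """Ruminal degradability observations for one feed (all %).

    ``ivtdmd`` is in vitro true DM digestibility, ``ivndfd``/``isndfd``
    the in vitro / in situ NDF degradabilities, at 48 or 72 h of
    fermentation.  Any field other than ``feed_id`` may be missing.
    """

    feed_id: str
    ivtdmd_48: float | None = None
    ivtdmd_72: float | None = None
    ivndfd_48: float | None = None
    ivndfd_72: float | None = None
    isdmd_48: float | None = None
    isndfd_48: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        for name in ("ivtdmd_48", "ivtdmd_72", "ivndfd_48", "ivndfd_72",
                     "isdmd_48", "isndfd_48"):
            _check_fraction(name, getattr(self, name), self.feed_id)
        for assay in ("ivtdmd", "ivndfd"):
            lo, hi = (getattr(self, f"{assay}_48"),
                      getattr(self, f"{assay}_72"))
            if lo is not None and hi is not None \
                    and hi < lo - HORIZON_TOLERANCE:
                raise FeedValidationError(
                    f"{assay}_72={hi} < {assay}_48={lo} - "
                    f"{HORIZON_TOLERANCE}", self.feed_id)


@dataclass
class FeedTable:
    """Ordered pairing of composition and degradability rows by feed_id."""

    rows: list[tuple[FeedComposition, DegradabilityRecord | None]] = \
        field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for comp, _ in self.rows:
            if comp.feed_id in seen:
                raise FeedValidationError("duplicate feed_id", comp.feed_id)
            seen.add(comp.feed_id)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[
            tuple[FeedComposition, DegradabilityRecord | None]]:
        return iter(self.rows)

    @property
    def feed_ids(self) -> list[str]:
        return [c.feed_id for c, _ in self.rows]

    def composition(self, feed_id: str) -> FeedComposition:
        for comp, _ in self.rows:
            if comp.feed_id == feed_id:
                return comp
        raise KeyError(feed_id)

    def degradability(self, feed_id: str) -> DegradabilityRecord | None:
        for comp, degr in self.rows:
            if comp.feed_id == feed_id:
                return degr
        raise KeyError(feed_id)

    def subset(self, feed_ids: Iterable[str]) -> "FeedTable":
        wanted = list(feed_ids)
        return FeedTable([r for r in self.rows if r[0].feed_id in wanted])

    def to_dataframes(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (composition, degradability) frames in CSV column order."""
        comp = pd.DataFrame(
            [{c: getattr(cmp, c) for c in COMPOSITION_COLUMNS + ["note"]}
             for cmp, _ in self.rows],
            columns=COMPOSITION_COLUMNS + ["note"])
        degr = pd.DataFrame(
            [{c: getattr(d, c) for c in DEGRADABILITY_COLUMNS + ["note"]}
             for _, d in self.rows if d is not None],
            columns=DEGRADABILITY_COLUMNS + ["note"])
        return comp, degr


def _optional(row: pd.Series, name: str) -> float | None:
    if name not in row or pd.isna(row[name]):
        return None
    return float(row[name])


def _require_columns(df: pd.DataFrame, names: Iterable[str],
                     path: str | Path) -> None:
    missing = [c for c in names if c not in df.columns]
    if missing:
        raise FeedValidationError(
            f"{path}: missing mandatory column(s) {missing}")


def _read_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"feed_id": str, "note": str})
    numeric = [c for c in df.columns
               if c not in ("feed_id", "feed_class", "note")]
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise FeedValidationError(
                f"{path}: non-numeric value in column {col!r}: {exc}"
            ) from exc
    return df


def read_feed_table(composition_path: str | Path,
                    degradability_path: str | Path | None = None
                    ) -> FeedTable:
    """Read and validate a feed table from CSV.

    Rows violating a hard invariant are reported together with row-level
    context in a single :class:`FeedValidationError`; soft anomalies
    (``adf > ndf``, ``adicp > ndicp``) only warn.  When ``ash`` is absent
    it is derived from ``nfc`` (and vice versa) so downstream models always
    see both.
    """
    comp_df = _read_csv(composition_path)
    _require_columns(comp_df, _MANDATORY_COMPOSITION, composition_path)

    degr_by_id: dict[str, DegradabilityRecord] = {}
    problems: list[str] = []
    if degradability_path is not None:
        degr_df = _read_csv(degradability_path)
        _require_columns(degr_df, _MANDATORY_DEGRADABILITY,
                         degradability_path)
        for _, row in degr_df.iterrows():
            fid = str(row["feed_id"])
            try:
                rec = DegradabilityRecord(
                    feed_id=fid,
                    **{c: _optional(row, c)
                       for c in DEGRADABILITY_COLUMNS[1:]},
                    note=str(row.get("note") or ""))
            except FeedValidationError as exc:
                problems.append(str(exc))
                continue
            if fid in degr_by_id:
                problems.append(f"{fid!r}: duplicate feed_id in "
                                "degradability table")
            degr_by_id[fid] = rec

    rows: list[tuple[FeedComposition, DegradabilityRecord | None]] = []
    seen: set[str] = set()
    for _, row in comp_df.iterrows():
        fid = str(row["feed_id"])
        if fid in seen:
            problems.append(f"{fid!r}: duplicate feed_id")
            continue
        seen.add(fid)
        try:
            comp = FeedComposition(
                feed_id=fid,
                feed_class=str(row["feed_class"]),
                dm=_optional(row, "dm") or 0.0,
                cp=float(row["cp"]), ee=float(row["ee"]),
                ndf=float(row["ndf"]),
                adf=_optional(row, "adf") or 0.0,
                lignin=float(row["lignin"]),
                ndicp=float(row["ndicp"]), adicp=float(row["adicp"]),
                nfc=_optional(row, "nfc"), ash=_optional(row, "ash"),
                fap=_optional(row, "fap") or 1.0,
                note=str(row.get("note") or ""))
        except FeedValidationError as exc:
            problems.append(str(exc))
            continue
        if comp.ash is None and comp.nfc is not None:
            comp = replace(comp, ash=derive_ash(comp))
        elif comp.nfc is None and comp.ash is not None:
            comp = replace(comp, nfc=compute_nfc(comp))
        rows.append((comp, degr_by_id.get(fid)))

    orphans = set(degr_by_id) - seen
    if orphans:
        problems.append(f"degradability rows without composition: "
                        f"{sorted(orphans)}")
    if problems:
        raise FeedValidationError(
            "invalid feed table:\n  " + "\n  ".join(problems))
    return FeedTable(rows)


def write_feed_table(table: FeedTable, composition_path: str | Path,
                     degradability_path: str | Path) -> None:
    """Write a feed table to the two-file CSV layout read back by
    :func:`read_feed_table`."""
    comp, degr = table.to_dataframes()
    comp.to_csv(composition_path, index=False)
    degr.to_csv(degradability_path, index=False)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("feedenergy").joinpath("data", name)))


def load_example_feeds() -> FeedTable:
    """The bundled twelve-feed table (eight tropical forages grazed by
    goats plus four agro-industrial byproducts)."""
    with warnings.catch_warnings():
        # the discarded-sesame row has adf > ndf as published
        warnings.simplefilter("ignore")
        return read_feed_table(_data_path("feed_composition.csv"),
                               _data_path("feed_degradability.csv"))


def load_reference_tables() -> dict[str, pd.DataFrame]:
    """Published TDN prediction, precision-regression and energy tables
    used by the fixture-verification report."""
    return {
        "tdn": pd.read_csv(_data_path("reference_tdn.csv")),
        "precision": pd.read_csv(_data_path("reference_precision.csv"),
                                 index_col="method"),
        "energy": pd.read_csv(_data_path("reference_energy.csv")),
    }
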