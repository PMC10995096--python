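"""Packaged study tables and typed record loaders.

The package ships four small delimited-text tables that together contain
every numeric input of the study:

* ``table2`` — the 29-indicator evaluation system with AHP weights (percent),
* ``table3`` — the 17 socio-economic / ecological input columns, 2015-2022,
* ``table5`` — green and water class-level landscape indices, 2015-2022,
* ``table6`` — the true landscape-quality composite index (LQCI) per year,
  the two model outputs reported alongside it, and the quality level.

Tables are stored as UTF-8 CSV with a header row, numeric cells as printed.
``table5`` is a best-effort reconstruction: in the source the twelve numeric
columns of each row are run together and a few digit boundaries are ambiguous
(the table is internally inconsistent regardless, e.g. patch counts that do
not match the printed densities for the 55.47 km^2 study area), so it is
treated strictly as fixture input, never as a numeric target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "Indicator",
    "YearRecord",
    "GWLIRecord",
    "LQCITruthRecord",
    "load_fixture",
    "load_table",
    "table3_matrix",
    "FixtureError",
    "TABLE_IDS",
]

TABLE_IDS = ("table2", "table3", "table5", "table6")

_LAYERS = ("SEI", "EEI", "LPCI")
_LEVELS = ("I", "II", "III", "IV")


class FixtureError(RuntimeError):
    """A packaged fixture is missing or does not parse."""


@dataclass(frozen=True)
class Indicator:
    """One row of the 29-indicator evaluation system.

    ``weight`` is in percent as printed, so the maximum attainable composite
    index equals the sum of the printed weights (~55.9), matching the scale
    of the truth series in ``table6``.  ``polarity`` defaults to benefit for
    every indicator; the source states no cost directions.
    """

    id: int
    code: str           # unique short key (NP_G vs NP_W etc.)
    abbrev: str         # abbreviation as printed (may repeat across groups)
    name: str
    layer: str          # SEI | EEI | LPCI
    group: str          # "", "vegetation" or "water"
    weight: float       # percent
    polarity: str = "benefit"

    def __post_init__(self) -> None:
        if self.layer not in _LAYERS:
            raise FixtureError(f"unknown layer {self.layer!r}")
        if self.weight <= 0:
            raise FixtureError(f"indicator {self.code}: weight must be > 0")
        if self.polarity not in ("benefit", "cost"):
            raise FixtureError(f"indicator {self.code}: bad polarity")

    @property
    def key(self) -> str:
        """Human-readable unique key, e.g. ``"NP (vegetation)"``."""
        return f"{self.abbrev} ({self.group})" if self.group else self.abbrev


@dataclass(frozen=True)
class YearRecord:
    """Raw values of the 17 model-input columns for one calendar year."""

    year: int
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.values.items():
            if not pd.notna(v) or v in (float("inf"), float("-inf")):
                raise FixtureError(f"{self.year}/{k}: non-finite value")


@dataclass(frozen=True)
class GWLIRecord:
    """Class-level landscape indices for one (year, class) pair."""

    year: int
    klass: str          # "green" | "water"
    np: int
    pd: float
    lpi: float
    lsi: float
    area_mn: float
    ai: float

    def __post_init__(self) -> None:
        if self.klass not in ("green", "water"):
            raise FixtureError(f"bad class {self.klass!r}")
        if self.np < 0:
            raise FixtureError("np must be >= 0")


@dataclass(frozen=True)
class LQCITruthRecord:
    """Truth composite index, both model outputs, and the printed level."""

    year: int
    truth_lqci: float
    bp_pred: float
    gabp_pred: float
    level: str

    def __post_init__(self) -> None:
        if self.level not in _LEVELS:
            raise FixtureError(f"bad level {self.level!r}")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("lqci").joinpath("data", name)))


def load_table(table_id: str) -> pd.DataFrame:
    """Load one packaged table as a DataFrame, cells as printed."""
    if table_id not in TABLE_IDS:
        raise FixtureError(f"unknown table id {table_id!r}; expected one of {TABLE_IDS}")
    path = _data_path(f"{table_id}.csv")
    if not path.exists():
        raise FixtureError(f"fixture file missing: {path}")
    try:
        df = pd.read_csv(path, keep_default_na=False, na_values=[])
    except Exception as exc:  # pragma: no cover - corrupt install
        raise FixtureError(f"fixture {table_id} failed to parse: {exc}") from exc
    return df


def load_fixture(table_id: str):
    """Parse a packaged table into typed records.

    Returns a list of :class:`Indicator`, :class:`YearRecord`,
    :class:`GWLIRecord` or :class:`LQCITruthRecord` depending on
    ``table_id``.  Round-trips losslessly to delimited text via
    :func:`serialize_records`.
    """
    df = load_table(table_id)
    if table_id == "table2":
        return [
            Indicator(
                id=int(r.id), code=r.code, abbrev=r.abbrev, name=r.name,
                layer=r.layer, group=r.group, weight=float(r.weight_percent),
            )
            for r in df.itertuples(index=False)
        ]
    if table_id == "table3":
        cols = [c for c in df.columns if c != "Year"]
        recs = [
            YearRecord(year=int(row["Year"]),
                       values={c: float(row[c]) for c in cols})
            for _, row in df.iterrows()
        ]
        years = [r.year for r in recs]
        if years != list(range(min(years), max(years) + 1)):
            raise FixtureError("table3 years are not contiguous")
        return recs
    if table_id == "table5":
        return [
            GWLIRecord(year=int(r.year), klass=str(r.klass), np=int(r.np),
                       pd=float(r.pd), lpi=float(r.lpi), lsi=float(r.lsi),
                       area_mn=float(r.area_mn), ai=float(r.ai))
            for r in df.rename(columns={"class": "klass"}).itertuples(index=False)
        ]
    # table6
    return [
        LQCITruthRecord(year=int(r.year), truth_lqci=float(r.truth_lqci),
                        bp_pred=float(r.bp_pred), gabp_pred=float(r.gabp_pred),
                        level=str(r.level))
        for r in df.itertuples(index=False)
    ]


def serialize_records(records: Iterable, table_id: str) -> str:
    """Render typed records back to the exact CSV text of their table."""
    records = list(records)
    if table_id == "table2":
        df = pd.DataFrame(
            [(r.id, r.code, r.abbrev, r.name, r.layer, r.group, r.weight)
             for r in records],
            columns=["id", "code", "abbrev", "name", "layer", "group",
                     "weight_percent"],
        )
    elif table_id == "table3":
        cols = list(records[0].values)
        df = pd.DataFrame(
            [[r.year] + [r.values[c] for c in cols] for r in records],
            columns=["Year"] + cols,
        )
    elif table_id == "table5":
        df = pd.DataFrame(
            [(r.year, r.klass, r.np, r.pd, r.lpi, r.lsi, r.area_mn, r.ai)
             for r in records],
            columns=["year", "class", "np", "pd", "lpi", "lsi", "area_mn", "ai"],
        )
    elif table_id == "table6":
        df = pd.DataFrame(
            [(r.year, r.truth_lqci, r.bp_pred, r.gabp_pred, r.level)
             for r in records],
            columns=["year", "truth_lqci", "bp_pred", "gabp_pred", "level"],
        )
    else:
        raise FixtureError(f"unknown table id {table_id!r}")
    return df.to_csv(index=False)


def table3_matrix() -> tuple[list[int], list[str], "pd.DataFrame"]:
    """The 8x17 raw input matrix: (years, column names, DataFrame).

    The DataFrame is indexed by year with the 17 columns in printed order —
    the direct input to normalization and the network.
    """
    recs = load_fixture("table3")
    cols = list(recs[0].values)
    df = pd.DataFrame([[r.values[c] for c in cols] for r in recs],
                      index=[r.year for r in recs], columns=cols)
    df.index.name = "Year"
    return [r.year for r in recs], cols, df
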