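"""Panel data model, I/O, validation and packaged fixtures.

The substrate of every analysis stage is a balanced long-format panel:
one row per (unit, year) with a constant region label per unit and an
arbitrary set of numeric value columns (raw financial fields, computed
indicators, covariates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RESERVED_COLUMNS = ("unit", "region", "year")

REGIONS = ("east", "central", "west")


class PanelError(ValueError):
    """Raised when a panel violates the balanced-panel contract."""


@dataclass
class PanelDataset:
    """Balanced unit x year panel.

    Parameters
    ----------
    data
        Long-format frame with columns ``unit``, ``region``, ``year`` and
        one numeric column per value field.

    Invariants (enforced by :meth:`validate`):

    * every unit appears in every year exactly once (balanced);
    * years form a contiguous integer range;
    * the region label is constant within each unit.
    """

    data: pd.DataFrame
    completeness: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def units(self) -> list[str]:
        return sorted(self.data["unit"].unique().tolist())

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique().tolist())

    @property
    def value_fields(self) -> list[str]:
        return [c for c in self.data.columns if c not in RESERVED_COLUMNS]

    @property
    def regions(self) -> pd.Series:
        """unit -> region, ordered by unit id."""
        s = self.data.drop_duplicates("unit").set_index("unit")["region"]
        return s.loc[self.units]

    def __len__(self) -> int:
        return len(self.data)

    def validate(self) -> None:
        df = self.data
        missing = [c for c in RESERVED_COLUMNS if c not in df.columns]
        if missing:
            raise PanelError(f"missing required column(s): {missing}")
        dup = df.duplicated(subset=["unit", "year"])
        if dup.any():
            row = df.loc[dup.idxmax()]
            raise PanelError(
                f"duplicate (unit, year) record: ({row['unit']}, {row['year']})"
            )
        years = sorted(df["year"].unique())
        if [int(y) for y in years] != list(range(int(years[0]), int(years[-1]) + 1)):
            raise PanelError(f"years are not a contiguous range: {years}")
        counts = df.groupby("unit")["year"].agg(["count", "nunique"])
        bad = counts[counts["count"] != len(years)]
        if len(bad):
            unit = bad.index[0]
            have = set(df.loc[df["unit"] == unit, "year"])
            gap = sorted(set(int(y) for y in years) - {int(y) for y in have})
            raise PanelError(f"unbalanced panel: unit {unit!r} missing year(s) {gap}")
        nreg = df.groupby("unit")["region"].nunique()
        if (nreg > 1).any():
            unit = nreg[nreg > 1].index[0]
            raise PanelError(f"region label varies within unit {unit!r}")

    # -- access ------------------------------------------------------------

    def wide(self, fld: str) -> pd.DataFrame:
        """Return one value field as a units x years matrix."""
        return self.data.pivot(index="unit", columns="year", values=fld).loc[self.units]

    def cross_section(self, year: int) -> pd.DataFrame:
        cs = self.data[self.data["year"] == year].set_index("unit")
        return cs.loc[self.units]

    def with_fields(self, new: pd.DataFrame) -> "PanelDataset":
        """Return a copy with extra value columns joined on (unit, year)."""
        merged = self.data.merge(new, on=["unit", "year"], how="left", validate="1:1")
        return PanelDataset(merged)


def read_panel(path: str | Path, schema: Sequence[str] | None = None) -> PanelDataset:
    """Read a comma-delimited long-format panel file.

    ``schema``, if given, lists the value fields that must be present;
    extras are kept.  Non-numeric entries in value columns raise with the
    offending row number (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    missing = [c for c in RESERVED_COLUMNS if c not in df.columns]
    if missing:
        raise PanelError(f"{path}: missing required column(s): {missing}")
    if schema is not None:
        absent = [c for c in schema if c not in df.columns]
        if absent:
            raise PanelError(f"{path}: schema field(s) not in file: {absent}")
    for col in df.columns:
        if col in ("unit", "region"):
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            rownum = int(bad.idxmax()) + 1
            raise PanelError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r} at data row {rownum}"
            )
        df[col] = coerced
    df["year"] = df["year"].astype(int)
    return PanelDataset(df)


def write_panel(panel: PanelDataset, path: str | Path) -> None:
    panel.data.to_csv(path, index=False)


def impute_missing(panel: PanelDataset, method: str = "linear_interpolation") -> PanelDataset:
    """Fill missing values within each unit's time series.

    Interior gaps are linearly interpolated along the year axis; boundary
    gaps carry the nearest observed value.  A completeness report (fraction
    of observed cells per unit and field) is attached to the result.
    """
    if method != "linear_interpolation":
        raise ValueError(f"unknown imputation method {method!r}")
    df = panel.data.sort_values(["unit", "year"]).reset_index(drop=True)
    fields = [c for c in df.columns if c not in RESERVED_COLUMNS]
    completeness = (
        df.groupby("unit")[fields].apply(lambda g: g.notna().mean()) if fields else None
    )
    for fld in fields:
        wide = df.pivot(index="year", columns="unit", values=fld)
        all_missing = wide.isna().all(axis=0)
        if all_missing.any():
            unit = all_missing.idxmax()
            raise PanelError(f"all values missing for unit {unit!r}, field {fld!r}")
        filled = wide.interpolate(method="linear", limit_direction="both", axis=0)
        long = filled.reset_index().melt(id_vars="year", var_name="unit", value_name=fld)
        df = df.drop(columns=fld).merge(long, on=["unit", "year"], validate="1:1")
    out = PanelDataset(df)
    out.completeness = completeness
    return out


@dataclass(frozen=True)
class AdjacencyStructure:
    """Undirected contiguity graph over an ordered list of units."""

    units: tuple[str, ...]
    edges: frozenset[frozenset]

    def __post_init__(self) -> None:
        known = set(self.units)
        for e in self.edges:
            pair = tuple(e)
            if len(pair) != 2:
                raise ValueError(f"self-edge or malformed edge: {sorted(e)}")
            for u in pair:
                if u not in known:
                    raise ValueError(f"edge endpoint {u!r} not among units")

    @classmethod
    def from_edge_list(
        cls, pairs: Iterable[tuple[str, str]], units: Sequence[str] | None = None
    ) -> "AdjacencyStructure":
        pairs = list(pairs)
        if units is None:
            units = sorted({u for p in pairs for u in p})
        edges = frozenset(frozenset(p) for p in pairs if p[0] != p[1])
        if any(a == b for a, b in pairs):
            raise ValueError("self-edges are not allowed")
        return cls(tuple(units), edges)

    def neighbors(self, unit: str) -> list[str]:
        return sorted(
            next(iter(e - {unit})) for e in self.edges if unit in e
        )

    def degree(self, unit: str) -> int:
        return sum(1 for e in self.edges if unit in e)


def read_adjacency(path: str | Path, units: Sequence[str] | None = None) -> AdjacencyStructure:
    """Read a two-column (tab/whitespace) edge-list text file; '#' comments."""
    pairs: list[tuple[str, str]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}: malformed edge line {line!r}")
        pairs.append((parts[0].strip(), parts[1].strip()))
    return AdjacencyStructure.from_edge_list(pairs, units)


# -- packaged fixtures -----------------------------------------------------

def _data_path(name: str):
    return resources.files("fsispace.data").joinpath(name)


def load_table2_fixture() -> pd.DataFrame:
    """Published province-level sustainability index and LISA diagnostics.

    31 rows: province, region (east/central/west), composite index,
    LISA quadrant label, local Moran's I, significance (p), and the
    spatial-neighbor mean of the index.
    """
    with resources.as_file(_data_path("table2_clusters.csv")) as p:
        df = pd.read_csv(p)
    assert len(df) == 31
    return df


def load_china_adjacency() -> AdjacencyStructure:
    """First-order contiguity among the 31 mainland provinces.

    Hainan (an island) carries a declared link to Guangdong so that no
    row of the resulting weight matrix is empty.
    """
    order = load_table2_fixture()["province"].tolist()
    with resources.as_file(_data_path("china_adjacency.txt")) as p:
        return read_adjacency(p, units=order)


def load_table3_effects() -> dict:
    """Published spatial-model coefficient table (OLS/SAR/SEM/SDM + effects)."""
    with resources.as_file(_data_path("table3_effects.json")) as p:
        return json.loads(Path(p).read_text())
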