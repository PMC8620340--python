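"""Data model and I/O for river-monitoring panels and objective configurations.

A monitoring panel is a long-format table of annual measurements: one value per
(station, year, parameter).  Objectives attach a regulatory limit (pass/fail
semantics), a standard value ``S`` and an ideal value ``V0`` to each parameter,
which together drive every index computation downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

#: Canonical parameter labels, in the conventional reporting order.
PARAMETERS = [
    "temperature",
    "pH",
    "EC",
    "DO",
    "BOD",
    "nitrate_nitrite",
    "FC",
    "TC",
]

#: Parameters constrained to be nonnegative.
NONNEGATIVE = {"EC", "BOD", "nitrate_nitrite", "FC", "TC"}


class PanelError(ValueError):
    """Raised when a panel or objective file violates its contract."""


@dataclass(frozen=True)
class ObjectiveSpec:
    """Regulatory objective, standard and ideal value for one parameter.

    Parameters
    ----------
    parameter : str
        Parameter label.
    direction : {"upper_limit", "lower_limit", "range"}
        How the objective is violated.  ``lower_limit`` encodes the dissolved
        oxygen convention (a measurement *below* the objective fails);
        ``upper_limit`` is the usual concentration cap; ``range`` requires the
        value to lie inside ``[objective_low, objective_high]``.
    objective_low, objective_high : float or None
        The bound(s).  ``upper_limit`` uses ``objective_high``, ``lower_limit``
        uses ``objective_low``, ``range`` uses both.
    standard_S : float
        Standard value ``S`` anchoring the weighted sub-index scale.
    ideal_V0 : float
        Ideal value ``V0`` (sub-index zero point; 7.0 for pH, 14.6 mg/L for
        DO, 0 for concentration-type parameters).
    include_in_ccme, include_in_bc, include_in_weighted : bool
        Whether the parameter participates in each index.
    """

    parameter: str
    direction: str
    objective_low: float | None = None
    objective_high: float | None = None
    standard_S: float = float("nan")
    ideal_V0: float = 0.0
    include_in_ccme: bool = True
    include_in_bc: bool = True
    include_in_weighted: bool = True

    def __post_init__(self) -> None:
        if self.direction not in {"upper_limit", "lower_limit", "range"}:
            raise PanelError(f"unknown direction {self.direction!r}")
        if self.direction == "upper_limit" and self.objective_high is None:
            raise PanelError(f"{self.parameter}: upper_limit needs objective_high")
        if self.direction == "lower_limit" and self.objective_low is None:
            raise PanelError(f"{self.parameter}: lower_limit needs objective_low")
        if self.direction == "range":
            if self.objective_low is None or self.objective_high is None:
                raise PanelError(
                    f"{self.parameter}: range objective needs both bounds"
                )
            if not self.objective_low < self.objective_high:
                raise PanelError(
                    f"{self.parameter}: range bounds must satisfy low < high"
                )
        if not np.isnan(self.standard_S) and self.standard_S == self.ideal_V0:
            raise PanelError(
                f"{self.parameter}: standard_S equals ideal_V0 "
                "(weighted sub-index denominator would be zero)"
            )

    def meets(self, value: float) -> bool:
        """True if ``value`` satisfies the objective (boundary inclusive)."""
        if self.direction == "upper_limit":
            return value <= self.objective_high
        if self.direction == "lower_limit":
            return value >= self.objective_low
        return self.objective_low <= value <= self.objective_high


@dataclass
class MonitoringPanel:
    """Station x year x parameter observation table.

    ``data`` is a long-format DataFrame with columns
    ``station``, ``year``, ``parameter``, ``value`` and at most one row per
    key triple.  Missing measurements are simply absent rows (never zeros).
    Station order is first-appearance order; years are sorted ascending.
    """

    data: pd.DataFrame
    stations: list[str] = field(default_factory=list)
    periods: list[int] = field(default_factory=list)
    parameters: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data
        required = {"station", "year", "parameter", "value"}
        if not required.issubset(df.columns):
            raise PanelError(f"panel frame must have columns {sorted(required)}")
        dup = df.duplicated(subset=["station", "year", "parameter"])
        if dup.any():
            key = df.loc[dup.idxmax(), ["station", "year", "parameter"]]
            raise PanelError(
                "duplicate measurement for "
                f"(station={key['station']}, year={key['year']}, "
                f"parameter={key['parameter']})"
            )
        df = df.dropna(subset=["value"]).copy()
        df["year"] = df["year"].astype(int)
        bad_ph = df[(df["parameter"] == "pH") & ~df["value"].between(0, 14)]
        if len(bad_ph):
            raise PanelError("pH values must lie in [0, 14]")
        neg = df[df["parameter"].isin(NONNEGATIVE) & (df["value"] < 0)]
        if len(neg):
            p = neg.iloc[0]
            raise PanelError(
                f"negative value for {p['parameter']} at "
                f"({p['station']}, {p['year']})"
            )
        if not self.stations:
            self.stations = list(dict.fromkeys(df["station"]))
        if not self.periods:
            self.periods = sorted(df["year"].unique().tolist())
        if self.periods != sorted(set(self.periods)):
            raise PanelError("periods must be strictly increasing")
        if not self.parameters:
            seen = list(dict.fromkeys(df["parameter"]))
            self.parameters = [p for p in PARAMETERS if p in seen] + [
                p for p in seen if p not in PARAMETERS
            ]
        self.data = df.reset_index(drop=True)

    # -- slicing -----------------------------------------------------------

    def station_slice(self, station: str) -> pd.DataFrame:
        """All years of one station (the per-station index slice)."""
        if station not in self.stations:
            raise PanelError(f"unknown station {station!r}")
        return self.data[self.data["station"] == station].copy()

    def year_slice(self, year: int) -> pd.DataFrame:
        """All stations in one year (the per-year index slice)."""
        if year not in self.periods:
            raise PanelError(f"unknown year {year!r}")
        return self.data[self.data["year"] == year].copy()

    def series(self, station: str, parameter: str) -> pd.Series:
        """One parameter's annual series at one station, indexed by year."""
        sub = self.data[
            (self.data["station"] == station) & (self.data["parameter"] == parameter)
        ]
        return sub.set_index("year")["value"].sort_index()

    def wide(self, station: str | None = None) -> pd.DataFrame:
        """Year x parameter table (one station) or station-year rows (all)."""
        df = self.station_slice(station) if station else self.data
        return df.pivot_table(
            index=["station", "year"], columns="parameter", values="value",
            aggfunc="first",
        ).reindex(columns=self.parameters)


# ---------------------------------------------------------------------------
# readers / writers


def read_panel(path: str | Path, layout: str = "long") -> MonitoringPanel:
    """Read a monitoring panel CSV in ``long`` or ``wide`` layout.

    Long layout needs columns ``station, year, parameter, value``; wide layout
    needs ``station, year`` plus one column per parameter.  Blank cells become
    absent entries.  Unknown parameter labels are retained with a warning.
    """
    path = Path(path)
    if layout not in {"long", "wide"}:
        raise PanelError(f"unknown layout {layout!r}")
    raw = pd.read_csv(path)
    if layout == "wide":
        id_cols = ["station", "year"]
        if not set(id_cols).issubset(raw.columns):
            raise PanelError("wide layout requires station and year columns")
        raw = raw.melt(id_vars=id_cols, var_name="parameter", value_name="value")
        raw = raw.dropna(subset=["value"])
    missing = {"station", "year", "parameter", "value"} - set(raw.columns)
    if missing:
        raise PanelError(f"long layout missing columns {sorted(missing)}")
    values = pd.to_numeric(raw["value"], errors="coerce")
    bad = values.isna() & raw["value"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise PanelError(f"non-numeric value cell at data row {row + 1}")
    raw = raw.assign(value=values)
    unknown = sorted(set(raw["parameter"]) - set(PARAMETERS))
    if unknown:
        warnings.warn(f"unknown parameter labels retained: {unknown}", stacklevel=2)
    return MonitoringPanel(raw[["station", "year", "parameter", "value"]])


def read_objectives(path: str | Path | None = None) -> list[ObjectiveSpec]:
    """Read objective specs from YAML; ``None`` loads the shipped defaults.

    The shipped defaults are guideline-derived assumptions (CPCB/BIS bathing
    and drinking-water limits), not values printed by any single study.
    """
    if path is None:
        text = (
            resources.files("riverwqi.data")
            .joinpath("objectives_default.yaml")
            .read_text()
        )
        blocks = yaml.safe_load(text)
    else:
        with open(path) as fh:
            blocks = yaml.safe_load(fh)
    if isinstance(blocks, dict):
        blocks = blocks.get("objectives", blocks)
    specs = []
    for block in blocks:
        specs.append(
            ObjectiveSpec(
                parameter=block["parameter"],
                direction=block["direction"],
                objective_low=block.get("objective_low"),
                objective_high=block.get("objective_high"),
                standard_S=float(block["standard_S"]),
                ideal_V0=float(block.get("ideal_V0", 0.0)),
                include_in_ccme=bool(block.get("include_in_ccme", True)),
                include_in_bc=bool(block.get("include_in_bc", True)),
                include_in_weighted=bool(block.get("include_in_weighted", True)),
            )
        )
    return specs


def write_panel(panel: MonitoringPanel, path: str | Path) -> None:
    """Write a panel as a long-layout CSV (full float precision)."""
    panel.data.to_csv(path, index=False)


def write_results_table(
    rows: pd.DataFrame | Sequence[dict], path: str | Path, decimals: int = 2
) -> None:
    """Write a results table as CSV, formatting float columns to ``decimals``."""
    df = pd.DataFrame(rows)
    if df.empty:
        raise PanelError("refusing to write an empty results table")
    df = df.copy()
    for col in df.columns:
        if pd.api.types.is_float_dtype(df[col]):
            df[col] = df[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.{decimals}f}"
            )
    df.to_csv(path, index=False)


def specs_by_parameter(specs: Iterable[ObjectiveSpec]) -> dict[str, ObjectiveSpec]:
    return {s.parameter: s for s in specs}
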