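"""Data model and CSV I/O for continuous-luminescence plate time series.

The canonical exchange format is a long (tidy) CSV with one row per
(well, timepoint): ``cell_line, drug, concentration_M, replicate, time_h,
rlu[, count]``.  Instrument export dialects vary, so column names and unit
multipliers are remapped through a :class:`PlateSchema`, optionally loaded
from a YAML config.

Time is always hours and concentration always molar once inside the data
model; readers apply the schema's multipliers on the way in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PlateIOError",
    "SchemaError",
    "PlateValidationError",
    "PlateSchema",
    "WellTimeSeries",
    "PlateDataset",
    "RESULT_COLUMNS",
    "RATE_COLUMNS",
    "read_plate",
    "write_plate",
    "read_result_table",
    "write_result_table",
    "validate_result_table",
    "read_rate_table",
    "write_rate_table",
    "load_schema",
]


class PlateIOError(Exception):
    """Base class for plate I/O failures."""


class SchemaError(PlateIOError):
    """A required column is missing or the schema config is malformed."""


class PlateValidationError(PlateIOError):
    """Parsed data violates a data-model invariant."""


# Default drug labels that mark vehicle-control wells regardless of the
# concentration column (DMSO / PBS vehicles are common in screening exports).
DEFAULT_CONTROL_ALIASES = ("control", "vehicle", "dmso", "pbs")


@dataclass(frozen=True)
class PlateSchema:
    """Column-name mapping and unit multipliers for a long-format plate CSV."""

    cell_line: str = "cell_line"
    drug: str = "drug"
    concentration: str = "concentration_M"
    replicate: str = "replicate"
    time: str = "time_h"
    rlu: str = "rlu"
    count: str = "count"
    time_to_hours: float = 1.0
    concentration_to_molar: float = 1.0
    control_aliases: tuple[str, ...] = DEFAULT_CONTROL_ALIASES

    @property
    def required(self) -> tuple[str, ...]:
        return (
            self.cell_line,
            self.drug,
            self.concentration,
            self.replicate,
            self.time,
            self.rlu,
        )


def load_schema(path: str | Path) -> PlateSchema:
    """Load a :class:`PlateSchema` from a YAML config file.

    Recognized keys: ``columns`` (mapping of field name -> CSV column name),
    ``time_to_hours``, ``concentration_to_molar``, ``control_aliases``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise SchemaError(f"schema config {path!s} must be a mapping")
    kwargs: dict = dict(raw.get("columns", {}))
    unknown = set(kwargs) - {
        "cell_line", "drug", "concentration", "replicate", "time", "rlu", "count",
    }
    if unknown:
        raise SchemaError(f"unknown schema columns: {sorted(unknown)}")
    for key in ("time_to_hours", "concentration_to_molar"):
        if key in raw:
            kwargs[key] = float(raw[key])
    if "control_aliases" in raw:
        kwargs["control_aliases"] = tuple(str(a).lower() for a in raw["control_aliases"])
    return PlateSchema(**kwargs)


@dataclass
class WellTimeSeries:
    """One well/condition's luminescence (and optionally count) trajectory.

    Attributes
    ----------
    cell_line, drug : str
        Condition labels.  Controls carry ``concentration == 0``.
    concentration : float
        Drug concentration in molar; 0 for vehicle controls.
    replicate : int
        Replicate index, 1-based.
    times : ndarray
        Sampling times in hours, strictly increasing, length >= 2.
    rlu : ndarray
        Relative luminescence units, nonnegative, same length as ``times``.
    counts : ndarray or None
        Optional direct cell counts (nonnegative integers), same length.
    """

    cell_line: str
    drug: str
    concentration: float
    replicate: int
    times: np.ndarray
    rlu: np.ndarray
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rlu = np.asarray(self.rlu, dtype=float)
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=float)
        self.validate()

    @property
    def key(self) -> tuple[str, str, float, int]:
        return (self.cell_line, self.drug, float(self.concentration), int(self.replicate))

    @property
    def is_control(self) -> bool:
        return self.concentration == 0.0

    def validate(self) -> None:
        label = f"{self.cell_line}/{self.drug}/{self.concentration:g}/rep{self.replicate}"
        if self.times.ndim != 1 or len(self.times) < 2:
            raise PlateValidationError(f"well {label}: need at least 2 timepoints")
        if len(self.rlu) != len(self.times):
            raise PlateValidationError(f"well {label}: rlu length != times length")
        if not np.all(np.isfinite(self.times)):
            raise PlateValidationError(f"well {label}: non-finite time")
        if np.any(np.diff(self.times) <= 0):
            raise PlateValidationError(
                f"well {label}: times not strictly increasing (duplicate or "
                "out-of-order timepoints)"
            )
        if not np.all(np.isfinite(self.rlu)) or np.any(self.rlu < 0):
            raise PlateValidationError(f"well {label}: RLU must be finite and >= 0")
        if not np.isfinite(self.concentration) or self.concentration < 0:
            raise PlateValidationError(f"well {label}: concentration must be finite and >= 0")
        if int(self.replicate) < 1:
            raise PlateValidationError(f"well {label}: replicate must be >= 1")
        if self.counts is not None:
            if len(self.counts) != len(self.times):
                raise PlateValidationError(f"well {label}: counts length != times length")
            if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
                raise PlateValidationError(f"well {label}: counts must be finite and >= 0")


@dataclass
class PlateDataset:
    """A collection of :class:`WellTimeSeries` plus free-form metadata."""

    wells: list[WellTimeSeries] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set = set()
        for w in self.wells:
            if w.key in seen:
                raise PlateValidationError(f"duplicate well key {w.key}")
            seen.add(w.key)
        control_free = sorted(
            cl for cl in {w.cell_line for w in self.wells}
            if not any(w.is_control for w in self.wells if w.cell_line == cl)
        )
        if control_free:
            self.metadata["control_free_cell_lines"] = control_free

    def cell_lines(self) -> list[str]:
        return sorted({w.cell_line for w in self.wells})

    def controls(self, cell_line: str) -> list[WellTimeSeries]:
        return [w for w in self.wells if w.cell_line == cell_line and w.is_control]

    def condition(
        self, cell_line: str, drug: str, concentration: float
    ) -> list[WellTimeSeries]:
        return [
            w for w in self.wells
            if w.cell_line == cell_line and w.drug == drug
            and w.concentration == concentration
        ]


def read_plate(path: str | Path, schema: PlateSchema | None = None) -> PlateDataset:
    """Read a long-format plate CSV into a validated :class:`PlateDataset`.

    Rows are grouped by (cell_line, drug, concentration, replicate) and
    sorted by time within each well.  Drug labels matching the schema's
    control aliases are coerced to concentration 0.
    """
    schema = schema or PlateSchema()
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    has_counts = schema.count in df.columns and df[schema.count].notna().any()

    conc = df[schema.concentration].astype(float) * schema.concentration_to_molar
    is_alias = df[schema.drug].astype(str).str.lower().isin(schema.control_aliases)
    conc = conc.where(~is_alias, 0.0)

    work = pd.DataFrame(
        {
            "cell_line": df[schema.cell_line].astype(str),
            "drug": df[schema.drug].astype(str),
            "concentration": conc,
            "replicate": df[schema.replicate].astype(int),
            "time": df[schema.time].astype(float) * schema.time_to_hours,
            "rlu": df[schema.rlu].astype(float),
        }
    )
    if has_counts:
        work["count"] = df[schema.count].astype(float)

    wells: list[WellTimeSeries] = []
    for (cl, drug, c, rep), grp in work.groupby(
        ["cell_line", "drug", "concentration", "replicate"], sort=True
    ):
        grp = grp.sort_values("time")
        counts = None
        if has_counts and grp["count"].notna().all():
            counts = grp["count"].to_numpy()
        wells.append(
            WellTimeSeries(
                cell_line=cl,
                drug=drug,
                concentration=float(c),
                replicate=int(rep),
                times=grp["time"].to_numpy(),
                rlu=grp["rlu"].to_numpy(),
                counts=counts,
            )
        )
    return PlateDataset(wells=wells, metadata={"source": str(path)})


def write_plate(dataset: PlateDataset, path: str | Path,
                schema: PlateSchema | None = None) -> None:
    """Write a :class:`PlateDataset` back to the long CSV format."""
    schema = schema or PlateSchema()
    any_counts = any(w.counts is not None for w in dataset.wells)
    rows = []
    for w in dataset.wells:
        for i, t in enumerate(w.times):
            row = {
                schema.cell_line: w.cell_line,
                schema.drug: w.drug,
                schema.concentration: w.concentration / schema.concentration_to_molar,
                schema.replicate: w.replicate,
                schema.time: t / schema.time_to_hours,
                schema.rlu: w.rlu[i],
            }
            if any_counts:
                row[schema.count] = w.counts[i] if w.counts is not None else np.nan
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_shortest)


def _shortest(x: float) -> str:
    """Shortest decimal string that round-trips the float exactly."""
    return repr(float(x))


# --- result tables -----------------------------------------------------------

#: Fitted dose-response parameter table: one row per (cell_line, drug,
#: data_type) with the Hill coefficient, maximal response (lower asymptote),
#: EC50 in molar, and residual sum of squares of the fit.
RESULT_COLUMNS = (
    "cell_line", "drug", "data_type", "hill_coef", "max_resp", "ec50_M", "residuals",
)

#: Per-condition extracted-rate table.
RATE_COLUMNS = (
    "cell_line", "drug", "concentration_M", "replicate", "channel",
    "rate", "r2", "slice_start_h", "slice_end_h", "n_points",
)


def validate_result_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"result table missing column(s) {missing}")
    keys = table[["cell_line", "drug", "data_type"]].apply(tuple, axis=1)
    dup = keys[keys.duplicated()]
    if len(dup):
        raise PlateValidationError(f"duplicate result rows for {sorted(set(dup))}")
    return table.loc[:, list(RESULT_COLUMNS)]


def write_result_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the fitted-parameter table with full float precision."""
    validate_result_table(table).to_csv(path, index=False, float_format=_shortest)


def read_result_table(path: str | Path) -> pd.DataFrame:
    return validate_result_table(pd.read_csv(path, float_precision="round_trip"))


def write_rate_table(table: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in RATE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"rate table missing column(s) {missing}")
    table.loc[:, list(RATE_COLUMNS)].to_csv(path, index=False, float_format=_shortest)


def read_rate_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in RATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"rate table missing column(s) {missing}")
    return df
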