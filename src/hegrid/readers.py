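"""CSV ingest for CGM and glucometer export tables.

The generic dialect is a four-column CSV: ``patient_id, timestamp, glucose,
unit`` with ISO 8601 timestamps and per-row units (mmol/L or mg/dL). Device
export dialects — header junk rows, fixed units, event/calibration rows to
drop — are registered by name in :data:`DIALECTS`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .pairing import IngestError, validate_readings
from .units import MMOLL, convert_units, normalize_unit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Dialect:
    """Column mapping for one CSV flavour."""

    name: str
    patient_col: str = "patient_id"
    time_col: str = "timestamp"
    value_col: str = "glucose"
    unit: str | None = None          # fixed unit; None = per-row "unit" column
    unit_col: str = "unit"
    skiprows: int = 0
    keep_rows: dict = field(default_factory=dict)  # column -> required value


DIALECTS: dict[str, Dialect] = {
    "generic": Dialect(name="generic"),
    # minimal Dexcom-style export: leading device-info rows, mg/dL, and
    # calibration/alert rows flagged in an "Event Type" column
    "dexcom": Dialect(
        name="dexcom",
        patient_col="Patient ID",
        time_col="Timestamp",
        value_col="Glucose Value (mg/dL)",
        unit="mg/dL",
        keep_rows={"Event Type": "EGV"},
    ),
}


def register_dialect(dialect: Dialect) -> None:
    DIALECTS[dialect.name] = dialect


def read_readings_csv(path, source: str, dialect: str = "generic") -> pd.DataFrame:
    """Read a reading table, normalise units/time, validate and sort.

    Rows not matching a dialect's ``keep_rows`` filter (calibration, alerts)
    are dropped with a logged count; unparseable timestamps raise with the
    offending rows named.
    """
    if dialect not in DIALECTS:
        raise IngestError(f"unknown CSV dialect {dialect!r}; registered: {sorted(DIALECTS)}")
    d = DIALECTS[dialect]
    path = Path(path)
    raw = pd.read_csv(path, skiprows=d.skiprows)
    for col, required in d.keep_rows.items():
        if col in raw.columns:
            n0 = len(raw)
            raw = raw[raw[col] == required]
            if len(raw) < n0:
                logger.info("%s: dropped %d non-measurement row(s)", path.name, n0 - len(raw))
    needed = [d.patient_col, d.time_col, d.value_col]
    missing = [c for c in needed if c not in raw.columns]
    if missing:
        raise IngestError(f"{path.name}: missing column(s) {missing} for dialect {d.name!r}")
    ts = pd.to_datetime(raw[d.time_col], errors="coerce")
    bad = ts.isna()
    if bad.any():
        rows = raw.index[bad].tolist()[:10]
        raise IngestError(f"{path.name}: unparseable timestamp(s) at row(s) {rows}")
    values = pd.to_numeric(raw[d.value_col], errors="coerce")
    if values.isna().any():
        rows = raw.index[values.isna()].tolist()[:10]
        raise IngestError(f"{path.name}: non-numeric glucose at row(s) {rows}")
    if d.unit is not None:
        values = convert_units(values, d.unit, MMOLL)
    else:
        if d.unit_col not in raw.columns:
            raise IngestError(f"{path.name}: no unit column {d.unit_col!r} and no fixed unit")
        units = raw[d.unit_col].map(normalize_unit)
        factor = units.map(lambda u: 1.0 if u == MMOLL else 1.0 / convert_units(1.0, MMOLL, "mg/dL"))
        values = values * factor
    df = pd.DataFrame(
        {
            "patient_id": raw[d.patient_col].astype(str),
            "timestamp": ts,
            "value": values.astype(float),
            "source": source,
        }
    )
    return validate_readings(df, source=source)


def read_cgm_csv(path, dialect: str = "generic") -> pd.DataFrame:
    return read_readings_csv(path, source="CGM", dialect=dialect)


def read_smbg_csv(path, dialect: str = "generic") -> pd.DataFrame:
    return read_readings_csv(path, source="SMBG", dialect=dialect)


def write_readings_csv(df: pd.DataFrame, path) -> None:
    """Write a reading table in the generic dialect (mmol/L)."""
    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "timestamp": pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S"),
            "glucose": df["value"],
            "unit": MMOLL,
        }
    )
    out.to_csv(path, index=False)
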