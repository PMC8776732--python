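"""Data schema, time grid and readers/writers for sensor-network soil moisture.

The central in-memory object is the *sensor table*: a :class:`pandas.DataFrame`
whose index is a strictly increasing, minute-resolution ``DatetimeIndex``
(naive timestamps with a fixed local offset — the loggers step at fixed
intervals and observing DST would create phantom gaps or duplicates) and whose
columns are sensor ids holding volumetric water content (VWC, m3/m3).  Missing
cells are ``NaN``.

Sensor identity lives in :class:`SensorMeta` records.  The default network is
three replicate probes in each of five microsites: *Stipa* tussocks, *Retama*
shrubs, and open areas with low/medium/high biocrust cover (BSCl/BSCm/BSCh).
Wide-format column names follow ``<microsite>_<replicate>`` (e.g. ``Stipa_1``)
so a wide CSV is self-describing.

Supported on-disk formats:

* long CSV  — header ``timestamp,sensor_id,vwc`` (optionally ``,quality``);
  empty vwc field = missing.
* wide CSV  — header ``timestamp,<sensor_1>,...,<sensor_k>``.
* SQLite    — tables ``sensors(sensor_id, microsite, replicate)``,
  ``records(timestamp, sensor_id, vwc, quality)`` and
  ``weather(date, tmean, precip, rh, solar)``; missing = SQL NULL.
* XLSX      — one sheet per table, same columns as the long CSV.

Timestamps serialize as ISO 8601 to the minute (``YYYY-MM-DD HH:MM``).
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ChronologyError, DuplicateRecordError, RecordFormatError

#: Closed enumeration of the five microsite classes.
MICROSITES = ("Stipa", "Retama", "BSCl", "BSCm", "BSCh")

TIME_FORMAT = "%Y-%m-%d %H:%M"

WEATHER_FIELDS = ("tmean", "precip", "rh", "solar")


@dataclass(frozen=True, order=True)
class SensorMeta:
    """Identity of one probe: unique id, microsite class, replicate index."""

    sensor_id: str
    microsite: str
    replicate: int

    def __post_init__(self) -> None:
        if self.microsite not in MICROSITES:
            raise ValueError(
                f"unknown microsite {self.microsite!r}; expected one of {MICROSITES}"
            )
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")


def default_network(n_replicates: int = 3) -> list[SensorMeta]:
    """The standard network: ``n_replicates`` probes in each of the five microsites."""
    return [
        SensorMeta(f"{m}_{r}", m, r)
        for m in MICROSITES
        for r in range(1, n_replicates + 1)
    ]


def meta_from_ids(sensor_ids: Iterable[str]) -> list[SensorMeta]:
    """Parse ``<microsite>_<replicate>`` sensor ids into metadata records."""
    out = []
    for sid in sensor_ids:
        parts = str(sid).rsplit("_", 1)
        if len(parts) != 2 or parts[0] not in MICROSITES or not parts[1].isdigit():
            raise RecordFormatError(
                f"sensor id {sid!r} does not follow '<microsite>_<replicate>' "
                f"(microsites: {', '.join(MICROSITES)}); supply metadata explicitly"
            )
        out.append(SensorMeta(sid, parts[0], int(parts[1])))
    return out


def meta_frame(meta: Sequence[SensorMeta]) -> pd.DataFrame:
    """Metadata records as a DataFrame indexed by sensor_id."""
    return pd.DataFrame(
        {
            "sensor_id": [m.sensor_id for m in meta],
            "microsite": [m.microsite for m in meta],
            "replicate": [m.replicate for m in meta],
        }
    ).set_index("sensor_id")


# ---------------------------------------------------------------------------
# time grid
# ---------------------------------------------------------------------------

def build_time_grid(
    start,
    end,
    switch,
    cadence1: int = 120,
    cadence2: int = 150,
) -> pd.DatetimeIndex:
    """Logger time grid with a one-off cadence change.

    Regular ``cadence1``-minute steps run from ``start`` up to (excluding)
    ``switch``; from ``switch`` the grid continues in ``cadence2``-minute
    steps through ``end`` (inclusive).  Each segment steps cumulatively from
    its own origin — there is no per-day reset, so a 150-min cadence drifts
    across day boundaries exactly as the loggers do.

    Parameters
    ----------
    start, end, switch
        Anything :func:`pandas.Timestamp` accepts; must satisfy
        ``start < switch <= end``.
    cadence1, cadence2
        Step lengths in minutes; positive integers dividing 1440.
    """
    start, end, switch = (pd.Timestamp(t) for t in (start, end, switch))
    if not (start < switch <= end):
        raise ChronologyError(
            f"require start < switch <= end, got {start} / {switch} / {end}"
        )
    for c in (cadence1, cadence2):
        # 150 min does not divide the day; cadences may drift across midnight
        if not (isinstance(c, (int, np.integer)) and 0 < c <= 1440):
            raise ValueError(f"cadence must be a positive integer of minutes <= 1440, got {c}")
    seg1 = pd.date_range(start, switch, freq=f"{cadence1}min", inclusive="left")
    seg2 = pd.date_range(switch, end, freq=f"{cadence2}min")
    grid = seg1.append(seg2)
    grid.name = "timestamp"
    return grid


def empty_table(grid: pd.DatetimeIndex, meta: Sequence[SensorMeta]) -> pd.DataFrame:
    """All-missing sensor table on the given grid."""
    return pd.DataFrame(
        np.nan, index=grid, columns=[m.sensor_id for m in meta], dtype=float
    )


def validate_table(table: pd.DataFrame) -> None:
    """Check the sensor-table invariants; raise ``ValueError`` on violation."""
    if not isinstance(table.index, pd.DatetimeIndex):
        raise ValueError("sensor table index must be a DatetimeIndex")
    if not table.index.is_unique:
        raise ValueError("sensor table timestamps must be unique")
    if not table.index.is_monotonic_increasing:
        raise ValueError("sensor table timestamps must be increasing")
    vals = table.to_numpy(dtype=float)
    if np.isinf(vals).any():
        raise ValueError("sensor table cells must be finite or missing")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _parse_timestamps(raw: pd.Series) -> pd.DatetimeIndex:
    parsed = pd.to_datetime(raw, format=TIME_FORMAT, errors="coerce")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise RecordFormatError(
            f"unparseable timestamp {raw.iloc[row]!r} at data row {row + 1} "
            f"(expected {TIME_FORMAT.replace('%', '')!s} i.e. 'YYYY-MM-DD HH:MM')"
        )
    if parsed.isna().any():
        row = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise RecordFormatError(f"empty timestamp at data row {row + 1}")
    return pd.DatetimeIndex(parsed)


def _check_duplicates(frame: pd.DataFrame) -> None:
    dup = frame.duplicated(subset=["timestamp", "sensor_id"])
    if dup.any():
        first = frame.loc[dup].iloc[0]
        raise DuplicateRecordError(
            f"duplicate record for sensor {first['sensor_id']!r} at "
            f"{pd.Timestamp(first['timestamp']).strftime(TIME_FORMAT)}"
        )


def _long_to_table(frame: pd.DataFrame) -> pd.DataFrame:
    _check_duplicates(frame)
    table = frame.pivot(index="timestamp", columns="sensor_id", values="vwc")
    table = table.sort_index()
    table.index.name = "timestamp"
    table.columns.name = None
    return table.astype(float)


def read_records(
    path,
    fmt: str = "csv",
    layout: str = "long",
    meta: Sequence[SensorMeta] | None = None,
    with_quality: bool = False,
):
    """Read a sensor table from ``csv`` or ``sqlite``.

    The table's timestamps are the sorted union of those present in the file;
    grid cells absent from the file are missing.  Returns ``(table, meta)``,
    or ``(table, meta, quality)`` when ``with_quality`` is set (``quality`` is
    ``None`` if the file carries no quality column).

    Raises
    ------
    DuplicateRecordError
        If the same (timestamp, sensor) pair occurs twice.
    RecordFormatError
        On an unparseable timestamp (the message names the row).
    """
    path = Path(path)
    quality = None
    if fmt == "csv":
        raw = pd.read_csv(path, dtype={"timestamp": str})
        if layout == "long":
            required = {"timestamp", "sensor_id", "vwc"}
            if not required.issubset(raw.columns):
                raise RecordFormatError(
                    f"long CSV must have columns {sorted(required)}, got {list(raw.columns)}"
                )
            raw = raw.assign(timestamp=_parse_timestamps(raw["timestamp"]))
            table = _long_to_table(raw[["timestamp", "sensor_id", "vwc"]])
            if "quality" in raw.columns:
                quality = raw.pivot(
                    index="timestamp", columns="sensor_id", values="quality"
                ).sort_index()
                quality.columns.name = None
                quality = quality.reindex(columns=table.columns).astype(float)
        elif layout == "wide":
            if "timestamp" not in raw.columns:
                raise RecordFormatError("wide CSV must have a 'timestamp' column")
            idx = _parse_timestamps(raw["timestamp"])
            if idx.duplicated().any():
                first = idx[idx.duplicated()][0]
                raise DuplicateRecordError(
                    f"duplicate timestamp {first.strftime(TIME_FORMAT)} in wide CSV"
                )
            table = raw.drop(columns="timestamp").astype(float)
            table.index = idx
            table.index.name = "timestamp"
            table = table.sort_index()
        else:
            raise ValueError(f"unknown layout {layout!r}")
    elif fmt == "sqlite":
        with sqlite3.connect(path) as con:
            raw = pd.read_sql(
                "SELECT timestamp, sensor_id, vwc, quality FROM records", con
            )
            try:
                sensors = pd.read_sql(
                    "SELECT sensor_id, microsite, replicate FROM sensors", con
                )
            except pd.errors.DatabaseError:
                sensors = None
        raw = raw.assign(timestamp=_parse_timestamps(raw["timestamp"]))
        table = _long_to_table(raw[["timestamp", "sensor_id", "vwc"]])
        if raw["quality"].notna().any():
            quality = raw.pivot(
                index="timestamp", columns="sensor_id", values="quality"
            ).sort_index()
            quality.columns.name = None
            quality = quality.reindex(columns=table.columns).astype(float)
        if meta is None and sensors is not None and len(sensors):
            meta = [
                SensorMeta(r.sensor_id, r.microsite, int(r.replicate))
                for r in sensors.itertuples()
            ]
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if meta is None:
        meta = meta_from_ids(table.columns)
    else:
        meta = [m for m in meta if m.sensor_id in set(table.columns)]
    validate_table(table)
    if with_quality:
        return table, meta, quality
    return table, meta


def read_weather(path, fmt: str = "csv") -> pd.DataFrame:
    """Read a daily-weather table (columns date, tmean, precip, rh, solar)."""
    if fmt == "csv":
        raw = pd.read_csv(path)
    elif fmt == "sqlite":
        with sqlite3.connect(path) as con:
            raw = pd.read_sql("SELECT * FROM weather", con)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    raw["date"] = pd.to_datetime(raw["date"], format="%Y-%m-%d")
    weather = raw.set_index("date").reindex(columns=list(WEATHER_FIELDS)).astype(float)
    validate_weather(weather)
    return weather


def validate_weather(weather: pd.DataFrame) -> None:
    if not weather.index.is_unique:
        raise ValueError("weather days must be unique")
    if (weather.get("precip", pd.Series(dtype=float)).dropna() < 0).any():
        raise ValueError("precip must be >= 0")
    rh = weather.get("rh", pd.Series(dtype=float)).dropna()
    if ((rh < 0) | (rh > 100)).any():
        raise ValueError("rh must lie in [0, 100]")


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _table_to_long(table: pd.DataFrame, quality: pd.DataFrame | None) -> pd.DataFrame:
    long = table.stack(future_stack=True).rename("vwc").reset_index()
    long.columns = ["timestamp", "sensor_id", "vwc"]
    if quality is not None:
        qlong = quality.stack(future_stack=True).rename("quality").reset_index()
        long["quality"] = qlong["quality"].to_numpy()
    long["timestamp"] = long["timestamp"].dt.strftime(TIME_FORMAT)
    return long


def write_dataset(
    table: pd.DataFrame,
    out_dir,
    formats: Sequence[str] = ("csv",),
    quality: pd.DataFrame | None = None,
    weather: pd.DataFrame | None = None,
    meta: Sequence[SensorMeta] | None = None,
    layout: str = "long",
    stem: str = "records",
) -> dict[str, Path]:
    """Write the dataset in each requested format (``csv``, ``sqlite``, ``xlsx``).

    Missing cells serialize as empty CSV fields / SQL NULL so that a
    write→read round trip through :func:`read_records` reproduces the table
    cell-for-cell, including the missingness mask.  Returns a mapping
    format → main artifact path.
    """
    validate_table(table)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if meta is None:
        meta = meta_from_ids(table.columns)
    paths: dict[str, Path] = {}

    for fmt in formats:
        if fmt == "csv":
            path = out_dir / f"{stem}.csv"
            if layout == "long":
                _table_to_long(table, quality).to_csv(path, index=False, na_rep="")
            elif layout == "wide":
                wide = table.copy()
                wide.index = wide.index.strftime(TIME_FORMAT)
                wide.index.name = "timestamp"
                wide.to_csv(path, na_rep="")
                if quality is not None:
                    qw = quality.copy()
                    qw.index = qw.index.strftime(TIME_FORMAT)
                    qw.index.name = "timestamp"
                    qw.to_csv(out_dir / f"{stem}_quality.csv", na_rep="")
            else:
                raise ValueError(f"unknown layout {layout!r}")
            if weather is not None:
                _write_weather_csv(weather, out_dir / "weather.csv")
            paths["csv"] = path
        elif fmt == "sqlite":
            path = out_dir / f"{stem}.sqlite"
            _write_sqlite(path, table, quality, weather, meta)
            paths["sqlite"] = path
        elif fmt == "xlsx":
            path = out_dir / f"{stem}.xlsx"
            _write_xlsx(path, table, quality, weather, meta)
            paths["xlsx"] = path
        else:
            raise ValueError(f"unknown format {fmt!r}")
    return paths


def _write_weather_csv(weather: pd.DataFrame, path: Path) -> None:
    out = weather.copy()
    out.index = out.index.strftime("%Y-%m-%d")
    out.index.name = "date"
    out.to_csv(path, na_rep="")


def _write_sqlite(path, table, quality, weather, meta) -> None:
    path = Path(path)
    if path.exists():
        path.unlink()
    long = _table_to_long(table, quality)
    if "quality" not in long.columns:
        long["quality"] = np.nan
    with sqlite3.connect(path) as con:
        con.execute(
            "CREATE TABLE sensors (sensor_id TEXT PRIMARY KEY, microsite TEXT, replicate INTEGER)"
        )
        con.execute(
            "CREATE TABLE records (timestamp TEXT, sensor_id TEXT, vwc REAL, "
            "quality REAL, PRIMARY KEY (timestamp, sensor_id))"
        )
        con.execute(
            "CREATE TABLE weather (date TEXT PRIMARY KEY, tmean REAL, precip REAL, "
            "rh REAL, solar REAL)"
        )
        con.executemany(
            "INSERT INTO sensors VALUES (?, ?, ?)",
            [(m.sensor_id, m.microsite, m.replicate) for m in meta],
        )
        rows = [
            (t, s, None if pd.isna(v) else float(v), None if pd.isna(q) else float(q))
            for t, s, v, q in long[["timestamp", "sensor_id", "vwc", "quality"]].itertuples(
                index=False
            )
        ]
        con.executemany("INSERT INTO records VALUES (?, ?, ?, ?)", rows)
        if weather is not None:
            wrows = [
                (d.strftime("%Y-%m-%d"),)
                + tuple(None if pd.isna(x) else float(x) for x in row)
                for d, row in zip(weather.index, weather.to_numpy())
            ]
            con.executemany("INSERT INTO weather VALUES (?, ?, ?, ?, ?)", wrows)
        con.commit()


def _write_xlsx(path, table, quality, weather, meta) -> None:
    long = _table_to_long(table, quality)
    with pd.ExcelWriter(path, engine="openpyxl") as xl:
        long.to_excel(xl, sheet_name="records", index=False)
        meta_frame(meta).reset_index().to_excel(xl, sheet_name="sensors", index=False)
        if weather is not None:
            out = weather.copy()
            out.index = out.index.strftime("%Y-%m-%d")
            out.index.name = "date"
            out.reset_index().to_excel(xl, sheet_name="weather", index=False)


# ---------------------------------------------------------------------------
# weather join
# ---------------------------------------------------------------------------

def attach_weather(table: pd.DataFrame, weather: pd.DataFrame) -> pd.DataFrame:
    """Annotate every sub-daily record with its calendar day's weather.

    Returns a long-format frame ``timestamp, sensor_id, vwc, tmean, precip,
    rh, solar``.  Days absent from ``weather`` yield missing weather fields;
    VWC cells are never created, removed or altered.
    """
    validate_table(table)
    validate_weather(weather)
    long = table.stack(future_stack=True).rename("vwc").reset_index()
    long.columns = ["timestamp", "sensor_id", "vwc"]
    days = long["timestamp"].dt.normalize()
    annot = weather.reindex(columns=list(WEATHER_FIELDS)).reindex(days)
    for field in WEATHER_FIELDS:
        long[field] = annot[field].to_numpy()
    return long
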