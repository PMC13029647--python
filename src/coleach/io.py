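"""Delimited-text I/O for reactor series, count series and abundance tables.

CSV (UTF-8, "." decimal separator) is the single interchange format — the
domain's data volumes are tiny.  Column conventions:

* reactor time series: ``time_days, pH, Eh_mV, fe2_gL, fe3_gL, fetot_gL,
  cells_1e7_mL`` plus optional per-metal columns ``<metal>_gL`` (e.g.
  ``cu_gL``); optional columns may be absent.
* cell-count series: ``time_days, count_1e7_per_mL, reactor``.
* abundance tables: wide, metadata columns ``sample_id, day, reactor,
  pcb_gL`` plus one column per genus.

Floats are written with 12 significant digits, so a write/read round trip
is identity to ~1e-9 relative precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .community import AbundanceTable, METADATA_COLUMNS
from .growth import CellCountSeries
from .metrics import ReactorTimeSeries

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_counts",
    "write_counts",
    "read_abundance",
    "write_abundance",
]

_FLOAT_FMT = "%.12g"

_TS_FIELDS = {
    "pH": "pH",
    "Eh_mV": "Eh",
    "fe2_gL": "fe2",
    "fe3_gL": "fe3",
    "fetot_gL": "fe_total",
    "cells_1e7_mL": "cells",
}
_CONC_COLS = ("fe2_gL", "fe3_gL", "fetot_gL", "cells_1e7_mL")


def read_timeseries(path: str | Path, reactor_id: str = "") -> ReactorTimeSeries:
    """Read a reactor time series from CSV.

    Unknown ``*_gL`` columns are preserved as metal concentrations.  Raises
    ``ValueError`` naming the offending row for non-monotone time or
    negative concentrations; an fe2 + fe3 vs fe_total mismatch beyond
    tolerance only warns.
    """
    df = pd.read_csv(path)
    if "time_days" not in df.columns:
        raise ValueError(f"{path}: missing required column 'time_days'")
    t = df["time_days"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if len(bad):
        raise ValueError(
            f"{path}: time_days not strictly increasing at row {bad[0] + 1} "
            f"(value {t[bad[0] + 1]} after {t[bad[0]]})"
        )
    for col in df.columns:
        if col in _CONC_COLS or (col.endswith("_gL") and col not in _TS_FIELDS):
            vals = df[col].to_numpy(dtype=float)
            neg = np.flatnonzero(vals < 0)
            if len(neg):
                raise ValueError(
                    f"{path}: negative concentration in column {col!r} at row "
                    f"{neg[0]} (value {vals[neg[0]]})"
                )
    kwargs = {
        field: df[col].to_numpy(dtype=float)
        for col, field in _TS_FIELDS.items()
        if col in df.columns
    }
    metals = {
        col[:-3]: df[col].to_numpy(dtype=float)
        for col in df.columns
        if col.endswith("_gL") and col not in _TS_FIELDS and col != "pcb_gL"
    }
    return ReactorTimeSeries(times=t, metals=metals, reactor_id=reactor_id, **kwargs)


def write_timeseries(series: ReactorTimeSeries, path: str | Path) -> None:
    data: dict[str, np.ndarray] = {"time_days": series.times}
    for col, field in _TS_FIELDS.items():
        v = getattr(series, field)
        if v is not None:
            data[col] = v
    for metal, v in series.metals.items():
        data[f"{metal}_gL"] = v
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_counts(path: str | Path) -> dict[str, CellCountSeries]:
    """Read cell-count series from CSV; returns one series per reactor label."""
    df = pd.read_csv(path)
    needed = {"time_days", "count_1e7_per_mL", "reactor"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = {}
    for reactor, group in df.groupby("reactor"):
        group = group.sort_values("time_days")
        out[str(reactor)] = CellCountSeries(
            times=group["time_days"].to_numpy(dtype=float),
            counts=group["count_1e7_per_mL"].to_numpy(dtype=float),
            reactor_id=str(reactor),
        )
    return out


def write_counts(series_map: dict[str, CellCountSeries], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "time_days": s.times,
                "count_1e7_per_mL": s.counts,
                "reactor": name,
            }
        )
        for name, s in series_map.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_abundance(path: str | Path) -> AbundanceTable:
    """Read a wide abundance table from CSV; validation happens on construction."""
    return AbundanceTable(pd.read_csv(path))


def write_abundance(table: AbundanceTable, path: str | Path) -> None:
    cols = METADATA_COLUMNS + table.genera
    table.data[cols].to_csv(path, index=False, float_format=_FLOAT_FMT)
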