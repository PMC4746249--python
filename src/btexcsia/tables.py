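"""Delimited time-series input/output.

The package's exchange format is a UTF-8 delimited table (tab or comma,
sniffed from the header) with the required header names

    time_days, compound, conc, conc_control, conc_internal_std,
    delta13C_permil, delta2H_permil

Optional columns may be left empty.  Lines starting with ``#`` are comments.
Delta uncertainties are not part of the schema; readers attach the default
reproducibilities (see :data:`btexcsia.isotope_core.DEFAULT_DELTA_SIGMA`).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional

import pandas as pd

from .isotope_core import DeltaValue, IsotopeSeries, Measurement

__all__ = [
    "REQUIRED_COLUMNS",
    "SchemaError",
    "read_timeseries",
    "write_timeseries",
    "attach_internal_standard",
]

REQUIRED_COLUMNS = (
    "time_days",
    "compound",
    "conc",
    "conc_control",
    "conc_internal_std",
    "delta13C_permil",
    "delta2H_permil",
)


class SchemaError(ValueError):
    """Input table does not conform to the delimited schema."""


def _opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_timeseries(path) -> tuple[dict[str, IsotopeSeries], dict[str, IsotopeSeries]]:
    """Read a delimited time-series table into per-compound series.

    Returns ``(live, control)`` mappings compound -> :class:`IsotopeSeries`.
    The control mapping holds one series per compound that has any
    ``conc_control`` entries (control flask concentration stored as ``conc``).
    Raises :class:`SchemaError` naming the offending row/column on malformed
    input.
    """
    path = Path(path)
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except (pd.errors.EmptyDataError, pd.errors.ParserError, csv.Error) as exc:
        raise SchemaError(f"{path}: empty or unparseable input file: {exc}") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")

    live: dict[str, IsotopeSeries] = {}
    control: dict[str, IsotopeSeries] = {}
    for compound, group in df.groupby("compound", sort=False):
        group = group.sort_values("time_days")
        live_ms: list[Measurement] = []
        ctrl_ms: list[Measurement] = []
        for idx, row in group.iterrows():
            try:
                t = float(row["time_days"])
                conc = float(row["conc"])
                d13 = _opt(row["delta13C_permil"])
                d2 = _opt(row["delta2H_permil"])
                m = Measurement(
                    time=t,
                    compound=str(compound),
                    conc=conc,
                    conc_control=_opt(row["conc_control"]),
                    conc_internal_std=_opt(row["conc_internal_std"]),
                    delta13C=DeltaValue("C", d13) if d13 is not None else None,
                    delta2H=DeltaValue("H", d2) if d2 is not None else None,
                )
            except (TypeError, ValueError) as exc:
                raise SchemaError(
                    f"{path}: row {idx} (compound {compound!r}): {exc}"
                ) from exc
            live_ms.append(m)
            if m.conc_control is not None:
                ctrl_ms.append(
                    Measurement(time=t, compound=str(compound), conc=m.conc_control)
                )
        try:
            live[str(compound)] = IsotopeSeries(str(compound), live_ms)
        except ValueError as exc:
            raise SchemaError(f"{path}: compound {compound!r}: {exc}") from exc
        if ctrl_ms:
            control[str(compound)] = IsotopeSeries(str(compound), ctrl_ms)
    return live, control


def write_timeseries(
    live: dict[str, IsotopeSeries],
    path,
    control: Optional[dict[str, IsotopeSeries]] = None,
    sep: str = "\t",
) -> None:
    """Write per-compound live (and optional control) series to one table.

    Control concentrations are merged into the ``conc_control`` column by
    exact time match.
    """
    rows = []
    for compound, series in live.items():
        ctrl = (control or {}).get(compound)
        ctrl_by_time = {m.time: m.conc for m in ctrl.measurements} if ctrl else {}
        for m in series.measurements:
            rows.append(
                {
                    "time_days": m.time,
                    "compound": compound,
                    "conc": m.conc,
                    "conc_control": (
                        m.conc_control
                        if m.conc_control is not None
                        else ctrl_by_time.get(m.time)
                    ),
                    "conc_internal_std": m.conc_internal_std,
                    "delta13C_permil": m.delta13C.value if m.delta13C else None,
                    "delta2H_permil": m.delta2H.value if m.delta2H else None,
                }
            )
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(
        path, sep=sep, index=False
    )


def attach_internal_standard(
    series_map: dict[str, IsotopeSeries], internal_std_compound: str
) -> dict[str, IsotopeSeries]:
    """Fill ``conc_internal_std`` from the named compound's own series.

    For every measurement of every other compound, the internal-standard
    concentration at the exactly matching time is attached (in place).  Times
    without a matching internal-standard sample are left untouched.
    """
    if internal_std_compound not in series_map:
        raise KeyError(
            f"internal standard {internal_std_compound!r} not among compounds "
            f"{sorted(series_map)}"
        )
    is_by_time = {
        m.time: m.conc for m in series_map[internal_std_compound].measurements
    }
    for series in series_map.values():
        for m in series.measurements:
            if m.time in is_by_time:
                m.conc_internal_std = is_by_time[m.time]
    return series_map
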