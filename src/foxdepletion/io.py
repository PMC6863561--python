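"""Reading gamekeeper diary records and aggregating to the two-weekly grid.

Daily diaries record, per estate and date, the lamping hours, foxes seen,
and foxes culled by method (lamping, snare/other, cub at earth). These are
aggregated into the two-weekly :class:`~foxdepletion.model_core.EstateSeries`
the model consumes: hours and detections summed per step, culls converted to
densities by the estate area, and every step in the series span present
(zeros, not gaps, where nothing was recorded).

Input dialect: comma-separated with ISO dates and header columns ``date,
estate, hours, seen, lamping_cull, other_cull, cub_cull``. A column-mapping
dict adapts other headers.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calendars import STEPS_PER_YEAR, step_of_date
from .model_core import EstateSeries

__all__ = [
    "DailyRecord",
    "ReadReport",
    "read_daily",
    "aggregate",
    "write_series",
    "read_series",
    "cull_totals",
]

MANDATORY = ("date", "estate", "hours", "seen", "lamping_cull", "other_cull",
             "cub_cull")


@dataclass(frozen=True)
class DailyRecord:
    date: _dt.date
    estate: str
    hours: float
    seen: int
    lamping_cull: int
    other_cull: int
    cub_cull: int


@dataclass
class ReadReport:
    records: list
    errors: list  # (row_number, message)


def read_daily(
    path,
    column_map: dict | None = None,
    strict: bool = False,
) -> ReadReport:
    """Parse a daily diary CSV into validated records.

    Unknown columns are ignored; missing mandatory columns are a hard
    error. Malformed rows (bad dates, negative hours or counts) are
    collected into the error report with their row numbers; ``strict=True``
    raises instead.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")

    records: list[DailyRecord] = []
    errors: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            date = _dt.date.fromisoformat(str(getattr(row, "date")))
            hours = float(getattr(row, "hours"))
            counts = {
                name: int(getattr(row, name))
                for name in ("seen", "lamping_cull", "other_cull", "cub_cull")
            }
            if hours < 0:
                raise ValueError(f"negative hours ({hours})")
            bad = [k for k, v in counts.items() if v < 0]
            if bad:
                raise ValueError(f"negative counts in {bad}")
            records.append(
                DailyRecord(date=date, estate=str(getattr(row, "estate")),
                            hours=hours, **counts)
            )
        except (ValueError, TypeError) as exc:
            if strict:
                raise ValueError(f"row {i}: {exc}") from exc
            errors.append((i, str(exc)))
    return ReadReport(records=records, errors=errors)


def aggregate(
    records: list,
    area_km2: float,
    steps_per_year: int = STEPS_PER_YEAR,
    estate: str | None = None,
) -> EstateSeries:
    """Sum daily records onto the two-weekly grid for one estate.

    Hours and detections are summed per step; culls are divided by the
    estate area to densities. The series spans the first to last record
    date, padded to whole steps, with zero-filled steps where no records
    fall. Totals (hours, detections, culls) are conserved exactly.
    """
    if steps_per_year != STEPS_PER_YEAR:
        raise ValueError("only the 26-step two-weekly grid is supported")
    if area_km2 <= 0:
        raise ValueError("area_km2 must be positive")
    if estate is not None:
        records = [r for r in records if r.estate == estate]
    if not records:
        raise ValueError("no records to aggregate")
    estates = {r.estate for r in records}
    if len(estates) > 1:
        raise ValueError(
            f"records span multiple estates {sorted(estates)}; pass estate="
        )

    keyed = [(step_of_date(r.date), r) for r in records]
    (y0, s0) = min(k for k, _ in keyed)
    (y1, s1) = max(k for k, _ in keyed)
    n = (y1 - y0) * STEPS_PER_YEAR + (s1 - s0) + 1
    idx = np.arange(n)
    years = y0 + (idx + s0 - 1) // STEPS_PER_YEAR
    steps = (idx + s0 - 1) % STEPS_PER_YEAR + 1

    E = np.zeros(n)
    Y = np.zeros(n, dtype=np.int64)
    L = np.zeros(n)
    S = np.zeros(n)
    C = np.zeros(n)
    for (y, s), r in keyed:
        j = (y - y0) * STEPS_PER_YEAR + (s - s0)
        E[j] += r.hours
        Y[j] += r.seen
        L[j] += r.lamping_cull / area_km2
        S[j] += r.other_cull / area_km2
        C[j] += r.cub_cull / area_km2
    return EstateSeries(E=E, Y=Y, L=L, S=S, C_obs=C, area=area_km2,
                        years=years, steps=steps,
                        estate=next(iter(estates)))


_SERIES_COLUMNS = ("year", "step", "E", "Y", "L", "S", "C_obs")


def write_series(series: EstateSeries, path) -> None:
    """Write an EstateSeries to delimited text (the same format read back)."""
    df = pd.DataFrame(
        {
            "year": series.years,
            "step": series.steps,
            "E": series.E,
            "Y": series.Y,
            "L": series.L,
            "S": series.S,
            "C_obs": series.C_obs,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# estate={series.estate or 'unknown'} area_km2={series.area}\n")
        df.to_csv(fh, index=False)


def read_series(path) -> EstateSeries:
    """Read a series written by :func:`write_series`."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError("series file must start with a '# estate=... area_km2=...' line")
        meta = dict(item.split("=", 1) for item in header[1:].split())
        df = pd.read_csv(fh)
    missing = [c for c in _SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"series file missing columns: {missing}")
    return EstateSeries(
        E=df["E"].to_numpy(), Y=df["Y"].to_numpy(), L=df["L"].to_numpy(),
        S=df["S"].to_numpy(), C_obs=df["C_obs"].to_numpy(),
        area=float(meta["area_km2"]),
        years=df["year"].to_numpy(), steps=df["step"].to_numpy(),
        estate=meta.get("estate", ""),
    )


def cull_totals(series_list: list) -> dict:
    """Total foxes culled by channel across estates (counts, via estate areas).

    Returns lamping, other, cub and overall counts, rounded to integers;
    with complete diary data these reproduce the raw record totals because
    aggregation conserves culls exactly.
    """
    lamp = sum(float(np.sum(s.L)) * s.area for s in series_list)
    other = sum(float(np.sum(s.S)) * s.area for s in series_list)
    cubs = sum(float(np.sum(s.C_obs)) * s.area for s in series_list)
    return {
        "lamping": int(round(lamp)),
        "other": int(round(other)),
        "cubs": int(round(cubs)),
        "total": int(round(lamp + other + cubs)),
    }
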