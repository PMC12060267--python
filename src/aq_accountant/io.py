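"""Validated CSV I/O for the pipeline's daily tables."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("aq_accountant")

NA_MARKERS = {"", "NA", "NaN", "nan", "-999", "-999.0"}


class TableIOError(ValueError):
    """Schema or content failure while reading a daily table."""


def read_timeseries_csv(
    path,
    required_columns=None,
    date_col: str = "date",
    index_by_date: bool = True,
) -> pd.DataFrame:
    """Read a daily CSV with ISO-8601 dates and numeric value columns.

    Duplicate dates are rejected (naming the date); values matching NA
    markers become missing with a logged count; any other non-numeric
    cell is reported with its row number.
    """
    path = Path(path)
    if not path.exists():
        raise TableIOError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    missing = [c for c in ([date_col] + list(required_columns or [])) if c not in cols]
    if missing:
        raise TableIOError(f"{path.name}: header lacks required columns {missing}")
    try:
        dates = pd.to_datetime(df[date_col], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise TableIOError(f"{path.name}: unparseable ISO-8601 dates ({exc})") from exc
    if index_by_date:
        dup = dates[dates.duplicated()]
        if len(dup):
            raise TableIOError(
                f"{path.name}: duplicated date(s): "
                + ", ".join(d.date().isoformat() for d in dup.unique()[:5])
            )
    out = {date_col: dates}
    n_missing = 0
    for c in cols:
        if c == date_col:
            continue
        raw = df[c]
        if raw.str.match(r"^[A-Za-z_]").all() and not raw.isin(NA_MARKERS).any():
            out[c] = raw  # label column (e.g. sector, pollutant)
            continue
        is_na = raw.isin(NA_MARKERS)
        n_missing += int(is_na.sum())
        vals = pd.to_numeric(raw.where(~is_na), errors="coerce")
        bad = vals.isna() & ~is_na
        if bad.any():
            rows = [str(i + 2) for i in np.flatnonzero(bad)[:5]]  # +2: header + 1-based
            raise TableIOError(
                f"{path.name}: column {c!r} has non-numeric values at file row(s) "
                + ", ".join(rows)
            )
        out[c] = vals
    if n_missing:
        log.info("%s: %d missing value(s) read as NaN", path.name, n_missing)
    res = pd.DataFrame(out)
    if index_by_date:
        res = res.set_index(date_col)
        res.index = pd.DatetimeIndex(res.index)
    res.attrs["n_missing"] = n_missing
    return res


def write_timeseries_csv(df: pd.DataFrame, path, date_col: str = "date") -> None:
    df = df.copy()
    if isinstance(df.index, pd.DatetimeIndex):
        df.index = df.index.strftime("%Y-%m-%d")
        df.index.name = date_col
        df.to_csv(path)
    else:
        df.to_csv(path, index=False)
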