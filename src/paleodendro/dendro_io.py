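"""Reading and writing ring-width series in standard dendro interchange formats.

Two formats are supported:

* Tucson/decadal RWL — the fixed-layout exchange format used by the ITRDB
  and most measurement software.  Both common dialects are handled: widths
  in units of 0.01 mm with the ``999`` end-of-series marker, and widths in
  0.001 mm with the ``-9999`` marker.  The dialect is detected per series
  from its terminator and recorded as the series' measurement precision.
* Long-form CSV with columns ``series_id, tree_id, radius_id, year, width_mm``.

The year axis of fossil material is *relative* (chronology-internal,
"floating"): year numbers order rings within a chronology but carry no
calendar meaning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RingWidthSeries",
    "read_rwl",
    "write_rwl",
    "read_series_csv",
    "write_series_csv",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_json",
]


class DendroIOError(ValueError):
    """Raised for malformed ring-width files."""


@dataclass
class RingWidthSeries:
    """One measured radial transect of annual ring widths.

    Parameters
    ----------
    series_id, tree_id, radius_id
        Identifiers; ``series_id`` must be unique within a collection.
    first_year
        Relative year of the first ring.  The axis is contiguous: ring ``i``
        belongs to year ``first_year + i``.
    widths
        Ring widths in mm, strictly positive and finite.
    precision
        Measurement resolution in mm (0.001 for caliper measurements read
        to thousandths of a millimetre).
    """

    series_id: str
    tree_id: str
    radius_id: str
    first_year: int
    widths: np.ndarray
    precision: float = 0.001

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.ndim != 1 or self.widths.size < 1:
            raise DendroIOError(f"series {self.series_id!r}: needs >= 1 width")
        if not np.all(np.isfinite(self.widths)) or np.any(self.widths <= 0):
            raise DendroIOError(
                f"series {self.series_id!r}: widths must be positive and finite"
            )
        self.first_year = int(self.first_year)

    def __len__(self) -> int:
        return self.widths.size

    @property
    def last_year(self) -> int:
        return self.first_year + len(self) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self))

    def shifted(self, lag: int) -> "RingWidthSeries":
        """Copy of the series with the year axis shifted by ``lag``."""
        return replace(self, first_year=self.first_year + lag,
                       widths=self.widths.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RingWidthSeries):
            return NotImplemented
        return (
            self.series_id == other.series_id
            and self.tree_id == other.tree_id
            and self.radius_id == other.radius_id
            and self.first_year == other.first_year
            and len(self) == len(other)
            and np.allclose(self.widths, other.widths,
                            atol=max(self.precision, other.precision) / 2, rtol=0)
        )


# ---------------------------------------------------------------------------
# Tucson / decadal RWL
# ---------------------------------------------------------------------------

_STOP_001 = -9999   # terminator in the 0.001 mm dialect
_STOP_01 = 999      # terminator in the 0.01 mm dialect


def read_rwl(path: str | Path) -> list[RingWidthSeries]:
    """Parse a Tucson/decadal RWL file into a list of series.

    Each line carries an 8-character series id, the (relative) year of the
    first value on the line, and up to ten 6-character integer widths.  The
    series terminator identifies the dialect: ``999`` means widths are in
    units of 0.01 mm, ``-9999`` means 0.001 mm.  Both dialects may coexist
    in one file; the detected precision is recorded per series.
    """
    path = Path(path)
    raw: dict[str, list[tuple[int, list[int]]]] = {}
    order: list[str] = []
    last_sid: str | None = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        sid = line[:8].strip()
        rest = line[8:]
        try:
            year = int(rest[:4])
            fields = rest[4:].split()
            values = [int(v) for v in fields]
        except ValueError as exc:
            raise DendroIOError(
                f"{path.name}:{lineno}: malformed decade row: {line!r}"
            ) from exc
        if not sid:
            raise DendroIOError(f"{path.name}:{lineno}: missing series id")
        if sid not in raw:
            raw[sid] = []
            order.append(sid)
        elif sid != last_sid:
            raise DendroIOError(
                f"{path.name}:{lineno}: duplicate series id {sid!r}"
            )
        raw[sid].append((year, values))
        last_sid = sid

    out: list[RingWidthSeries] = []
    for sid in order:
        rows = raw[sid]
        values: list[int] = []
        first_year = rows[0][0]
        expect = first_year
        for year, vals in rows:
            if year != expect:
                raise DendroIOError(
                    f"{path.name}: series {sid!r}: decade row year {year} "
                    f"does not continue from year {expect}"
                )
            values.extend(vals)
            expect = year + len(vals)
        if not values:
            raise DendroIOError(f"{path.name}: series {sid!r}: empty")
        stop = values[-1]
        if stop == _STOP_001:
            scale, precision = 1000.0, 0.001
        elif stop == _STOP_01:
            scale, precision = 100.0, 0.01
        else:
            raise DendroIOError(
                f"{path.name}: series {sid!r}: missing terminator "
                f"(expected {_STOP_01} or {_STOP_001}, got {stop})"
            )
        widths = np.asarray(values[:-1], dtype=float) / scale
        out.append(
            RingWidthSeries(
                series_id=sid, tree_id=sid, radius_id="1",
                first_year=first_year, widths=widths, precision=precision,
            )
        )
    return out


def write_rwl(series: list[RingWidthSeries] | RingWidthSeries,
              path: str | Path) -> None:
    """Write series to Tucson RWL, choosing the dialect from each precision.

    Series with precision <= 0.001 mm are written in thousandths with the
    ``-9999`` terminator; anything coarser in hundredths with ``999``.
    The terminator value itself is never emitted as data (widths are
    strictly positive, so collision is impossible).
    """
    if isinstance(series, RingWidthSeries):
        series = [series]
    path = Path(path)
    lines: list[str] = []
    for s in series:
        if s.precision <= 0.0015:
            scale, stop = 1000.0, _STOP_001
        else:
            scale, stop = 100.0, _STOP_01
        values = [int(round(w * scale)) for w in s.widths] + [stop]
        sid = s.series_id[:8]
        year = s.first_year
        i = 0
        while i < len(values):
            # a decade row runs to the next multiple of ten on the year axis
            row_len = 10 - (year % 10 + 10) % 10
            row_vals = values[i:i + row_len]
            lines.append(
                f"{sid:<8s}{year:4d}" + "".join(f"{v:6d}" for v in row_vals)
            )
            i += len(row_vals)
            year += len(row_vals)
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Long-form CSV
# ---------------------------------------------------------------------------

_CSV_COLS = ["series_id", "tree_id", "radius_id", "year", "width_mm"]


def read_series_csv(path: str | Path) -> list[RingWidthSeries]:
    """Read long-form CSV (series_id, tree_id, radius_id, year, width_mm)."""
    df = pd.read_csv(path, dtype={"series_id": str, "tree_id": str,
                                  "radius_id": str})
    missing = [c for c in _CSV_COLS if c not in df.columns]
    if missing:
        raise DendroIOError(f"{path}: missing columns {missing}")
    bad = df.index[~np.isfinite(df.width_mm) | (df.width_mm <= 0)]
    if len(bad):
        raise DendroIOError(
            f"{path}: non-positive width at data row {int(bad[0]) + 2}"
        )
    out = []
    for sid, grp in df.groupby("series_id", sort=False):
        grp = grp.sort_values("year")
        years = grp.year.to_numpy()
        if len(years) > 1 and not np.all(np.diff(years) == 1):
            gap = int(years[np.flatnonzero(np.diff(years) != 1)[0]])
            raise DendroIOError(
                f"{path}: series {sid!r}: year axis not contiguous after "
                f"year {gap}"
            )
        out.append(
            RingWidthSeries(
                series_id=str(sid),
                tree_id=str(grp.tree_id.iloc[0]),
                radius_id=str(grp.radius_id.iloc[0]),
                first_year=int(years[0]),
                widths=grp.width_mm.to_numpy(),
            )
        )
    return out


def write_series_csv(series: list[RingWidthSeries] | RingWidthSeries,
                     path: str | Path) -> None:
    if isinstance(series, RingWidthSeries):
        series = [series]
    rows = []
    for s in series:
        for year, width in zip(s.years, s.widths):
            rows.append((s.series_id, s.tree_id, s.radius_id, int(year),
                         float(width)))
    pd.DataFrame(rows, columns=_CSV_COLS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Derived products
# ---------------------------------------------------------------------------

def write_matrix_csv(matrix: np.ndarray, row_labels: np.ndarray,
                     col_labels: np.ndarray, path: str | Path,
                     row_name: str = "period_yr") -> None:
    """Write a (period x time) matrix as CSV with labelled axes."""
    df = pd.DataFrame(matrix, index=np.asarray(row_labels),
                      columns=np.asarray(col_labels))
    df.index.name = row_name
    df.to_csv(path)


def read_matrix_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(), df.index.to_numpy(float), df.columns.to_numpy(float)


def write_json(obj: dict, path: str | Path) -> None:
    """Write a JSON document for derived products (chronology summaries etc.)."""

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
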