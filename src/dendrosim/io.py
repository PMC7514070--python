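"""Reading and writing ring-width data.

Supports the decadal Tucson (RWL) format in its two dominant dialects
(end-of-series sentinel ``999`` with widths in 1/100 mm, or ``-9999`` with
widths in 1/1000 mm), a long CSV alternative, single-column length pools,
and site metadata tables.  Widths are held internally in millimetres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: minimum usable historical-series length, in years
MIN_SERIES_LENGTH = 50


class RWLParseError(ValueError):
    """Raised when an RWL file cannot be parsed; carries the line number."""


@dataclass
class RingWidthSeries:
    """One cross-dated ring-width measurement series.

    Years are calendar years and must be gap-free: ``widths[i]`` is the ring
    formed in year ``first_year + i``.  Widths are in millimetres, positive.
    """

    series_id: str
    site_id: str
    first_year: int
    widths: np.ndarray

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.size == 0:
            raise ValueError(f"series {self.series_id!r}: no ring widths")
        if not np.all(np.isfinite(self.widths)):
            raise ValueError(f"series {self.series_id!r}: non-finite widths")
        if np.any(self.widths <= 0):
            raise ValueError(f"series {self.series_id!r}: non-positive widths")

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.widths) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def __len__(self) -> int:
        return len(self.widths)


@dataclass
class SiteDataset:
    """All measurement series of one site plus its contrast attributes."""

    site_id: str
    series: list[RingWidthSeries]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.series:
            raise ValueError(f"site {self.site_id!r}: no series")
        bad = [s.series_id for s in self.series if s.site_id != self.site_id]
        if bad:
            raise ValueError(
                f"site {self.site_id!r}: series {bad} carry a different site_id"
            )

    def __len__(self) -> int:
        return len(self.series)


@dataclass
class SeriesLengthPool:
    """Empirical pool of historical series lengths (years), all >= 50."""

    lengths: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=int)
        if self.lengths.size == 0:
            raise ValueError("length pool is empty")
        if np.any(self.lengths < MIN_SERIES_LENGTH):
            raise ValueError(
                f"length pool contains lengths < {MIN_SERIES_LENGTH}"
            )

    def __len__(self) -> int:
        return len(self.lengths)


# ---------------------------------------------------------------------------
# Tucson / RWL
# ---------------------------------------------------------------------------

_SENTINEL_100 = 999      # 1/100 mm dialect
_SENTINEL_1000 = -9999   # 1/1000 mm dialect


def _detect_scale(text: str) -> float:
    """Return the width divisor of the dialect used in ``text``."""
    for line in text.splitlines():
        if "-9999" in line.split():
            return 1000.0
    return 100.0


def read_rwl(path: str | Path, site_id: str | None = None) -> list[RingWidthSeries]:
    """Read a decadal Tucson RWL file.

    The unit convention is auto-detected: the ``-9999`` sentinel implies
    1/1000 mm, otherwise 1/100 mm is assumed.  ``site_id`` (default: the
    file stem) is attached to every series.
    """
    path = Path(path)
    text = path.read_text()
    scale = _detect_scale(text)
    sentinel = _SENTINEL_1000 if scale == 1000.0 else _SENTINEL_100

    if site_id is None:
        site_id = path.stem

    out: list[RingWidthSeries] = []
    open_series: dict[str, tuple[int, list[float]]] = {}
    seen: set[str] = set()

    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        tokens = raw.split()
        if len(tokens) < 3:
            raise RWLParseError(f"{path}:{lineno}: expected id, year and values")
        sid = tokens[0]
        try:
            year = int(tokens[1])
            values = [int(t) for t in tokens[2:]]
        except ValueError as exc:
            raise RWLParseError(f"{path}:{lineno}: non-numeric token ({exc})") from None

        if sid in seen:
            raise RWLParseError(
                f"{path}:{lineno}: data for finished series {sid!r} (duplicate years)"
            )
        if sid not in open_series:
            open_series[sid] = (year, [])
        first_year, widths = open_series[sid]
        expected = first_year + len(widths)
        if year != expected:
            raise RWLParseError(
                f"{path}:{lineno}: series {sid!r} continues at year {year}, "
                f"expected {expected} (gap or duplicate year)"
            )
        done = False
        for v in values:
            if v == sentinel:
                done = True
                break
            widths.append(v / scale)
        if done:
            seen.add(sid)
            del open_series[sid]
            try:
                out.append(RingWidthSeries(sid, site_id, first_year, np.array(widths)))
            except ValueError as exc:
                raise RWLParseError(f"{path}:{lineno}: {exc}") from None

    if open_series:
        unterminated = ", ".join(sorted(open_series))
        raise RWLParseError(f"{path}: series without end sentinel: {unterminated}")
    return out


def write_rwl(series_list: list[RingWidthSeries], path: str | Path,
              precision: float = 0.01) -> None:
    """Write series to a decadal Tucson RWL file.

    ``precision`` selects the dialect: 0.01 mm (sentinel 999) or
    0.001 mm (sentinel -9999).  Widths are rounded to the dialect precision,
    so the round trip is exact only for widths already on that grid.
    """
    if precision == 0.01:
        scale, sentinel = 100, _SENTINEL_100
    elif precision == 0.001:
        scale, sentinel = 1000, _SENTINEL_1000
    else:
        raise ValueError("precision must be 0.01 or 0.001")

    lines: list[str] = []
    for s in series_list:
        if not -999 <= s.first_year <= s.last_year <= 9999:
            raise ValueError(
                f"series {s.series_id!r}: years outside the writable range")
        ints = np.rint(s.widths * scale).astype(int)
        if np.any(ints <= 0):
            raise ValueError(
                f"series {s.series_id!r}: width rounds to <= 0 at this precision"
            )
        if np.any(ints == sentinel):
            raise ValueError(
                f"series {s.series_id!r}: width {sentinel / scale} mm collides "
                "with the end-of-series sentinel; use the 0.001 mm dialect"
            )
        values = list(ints) + [sentinel]
        year = s.first_year
        i = 0
        while i < len(values):
            # fill to the end of the current decade
            n = 10 - (year % 10)
            chunk = values[i:i + n]
            cells = "".join(f"{v:6d}" for v in chunk)
            # width-5 year field guarantees a separator after long ids
            lines.append(f"{s.series_id:<8s}{year:5d}{cells}")
            i += len(chunk)
            year += len(chunk)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# CSV long format
# ---------------------------------------------------------------------------

def read_csv_long(path: str | Path) -> list[RingWidthSeries]:
    """Read ring widths from long CSV: series_id, site_id, year, width."""
    df = pd.read_csv(path)
    required = {"series_id", "site_id", "year", "width"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for (sid, site), grp in df.groupby(["series_id", "site_id"], sort=False):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy(dtype=int)
        if np.unique(years).size != years.size:
            raise ValueError(f"{path}: duplicate years in series {sid!r}")
        if np.any(np.diff(years) != 1):
            raise ValueError(f"{path}: gap in series {sid!r}")
        out.append(RingWidthSeries(str(sid), str(site), int(years[0]),
                                   grp["width"].to_numpy(dtype=float)))
    return out


def write_csv_long(series_list: list[RingWidthSeries], path: str | Path) -> None:
    frames = [
        pd.DataFrame({
            "series_id": s.series_id,
            "site_id": s.site_id,
            "year": s.years,
            "width": s.widths,
        })
        for s in series_list
    ]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["series_id", "site_id", "year", "width"])
    df.to_csv(path, index=False)


def group_by_site(series_list: list[RingWidthSeries],
                  meta: dict[str, dict] | None = None) -> list[SiteDataset]:
    """Assemble per-site datasets from a flat series list."""
    by_site: dict[str, list[RingWidthSeries]] = {}
    for s in series_list:
        by_site.setdefault(s.site_id, []).append(s)
    meta = meta or {}
    return [SiteDataset(site, ser, dict(meta.get(site, {})))
            for site, ser in by_site.items()]


# ---------------------------------------------------------------------------
# Length pool & metadata
# ---------------------------------------------------------------------------

def read_length_pool(path: str | Path,
                     min_length: int = MIN_SERIES_LENGTH) -> SeriesLengthPool:
    """Read a series-length pool (one integer per row); drops lengths < 50."""
    raw = pd.read_csv(path, header=None).iloc[:, 0].to_numpy(dtype=int)
    kept = raw[raw >= min_length]
    n_dropped = raw.size - kept.size
    if n_dropped:
        logger.info("length pool %s: dropped %d lengths < %d",
                    path, n_dropped, min_length)
    if kept.size == 0:
        raise ValueError(f"{path}: no lengths >= {min_length} remain")
    return SeriesLengthPool(kept)


def write_length_pool(pool: SeriesLengthPool, path: str | Path) -> None:
    pd.Series(pool.lengths).to_csv(path, index=False, header=False)


def read_site_metadata(path: str | Path) -> dict[str, dict]:
    """Read site metadata CSV (site_id, elevation_band, watershed)."""
    df = pd.read_csv(path)
    required = {"site_id", "elevation_band", "watershed"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    valid = {"low", "medium", "high"}
    out = {}
    for _, row in df.iterrows():
        band = str(row["elevation_band"])
        if band not in valid:
            raise ValueError(f"{path}: elevation_band {band!r} not in {sorted(valid)}")
        out[str(row["site_id"])] = {
            "elevation_band": band,
            "watershed": str(row["watershed"]),
        }
    return out


def write_site_metadata(meta: dict[str, dict], path: str | Path) -> None:
    rows = [{"site_id": k, **v} for k, v in meta.items()]
    pd.DataFrame(rows).to_csv(path, index=False)
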