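"""Site and satellite AOD ingestion.

Covers the three standard preprocessing steps upstream of fusion:

* spectral interpolation of sun-photometer AOD from 440 and 675 nm to the
  satellite reference wavelength of 550 nm via the two-point Angstrom
  power law,
* aggregation of instantaneous site records to daily means, and
* binning of satellite swath pixels onto the regular analysis grid.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grid import MISSING, RETRIEVED, DailyGridField, GridSpec

__all__ = [
    "SiteAodRecord",
    "SwathPixel",
    "InvalidRecordError",
    "angstrom_interpolate_550",
    "daily_mean_site_aod",
    "grid_swath",
]

log = logging.getLogger(__name__)

_WL_440 = 440.0
_WL_675 = 675.0
_WL_550 = 550.0


class InvalidRecordError(ValueError):
    """Raised for a spectrally invalid AOD record (non-positive anchor AOD)."""


@dataclass
class SiteAodRecord:
    """One instantaneous multi-wavelength site AOD observation."""

    timestamp: _dt.datetime
    aod_440: float
    aod_675: float
    aod_550: float | None = None  # derived; absent before interpolation


@dataclass
class SwathPixel:
    """One satellite level-2 pixel: location and 550 nm AOD."""

    lat: float
    lon: float
    aod_550: float
    timestamp: _dt.datetime | None = None


def angstrom_interpolate_550(aod_440: float, aod_675: float) -> float:
    """Interpolate AOD to 550 nm from the 440 and 675 nm anchors.

    Log AOD is linear in log wavelength through the two anchor points
    (a single power law): the Angstrom exponent is
    ``alpha = -ln(aod_440 / aod_675) / ln(440 / 675)`` and the result is
    ``aod_440 * (550 / 440) ** (-alpha)``.

    Both inputs must be strictly positive; otherwise the spectrum has no
    power-law representation and :class:`InvalidRecordError` is raised.
    Accepts scalars or same-shape arrays.
    """
    a440 = np.asarray(aod_440, dtype=float)
    a675 = np.asarray(aod_675, dtype=float)
    if np.any(~(a440 > 0)) or np.any(~(a675 > 0)):
        raise InvalidRecordError("anchor AODs must be strictly positive")
    alpha = -np.log(a440 / a675) / np.log(_WL_440 / _WL_675)
    out = a440 * (_WL_550 / _WL_440) ** (-alpha)
    if np.isscalar(aod_440) and np.isscalar(aod_675):
        return float(out)
    return out


def interpolate_records(records: Iterable[SiteAodRecord]) -> list[SiteAodRecord]:
    """Fill ``aod_550`` on each record; skip invalid ones with a logged count."""
    out: list[SiteAodRecord] = []
    n_skipped = 0
    for rec in records:
        try:
            a550 = angstrom_interpolate_550(rec.aod_440, rec.aod_675)
        except InvalidRecordError:
            n_skipped += 1
            continue
        out.append(SiteAodRecord(rec.timestamp, rec.aod_440, rec.aod_675, a550))
    if n_skipped:
        log.info("interpolate_records: skipped %d invalid record(s)", n_skipped)
    return out


def daily_mean_site_aod(
    records: Sequence[SiteAodRecord],
    min_obs: int = 1,
    time_window: tuple[_dt.time, _dt.time] | None = None,
) -> pd.Series:
    """Daily-mean 550 nm site AOD.

    Records without ``aod_550`` are interpolated first (invalid ones
    skipped).  ``time_window=(start, end)`` restricts to records whose
    time-of-day lies in the closed window — e.g. an overpass window —
    before averaging; default uses the whole day.  Dates with fewer than
    ``min_obs`` valid records are absent from the result.

    Returns a Series indexed by ``datetime.date`` with the daily means.
    """
    if min_obs < 1:
        raise ValueError("min_obs must be >= 1")
    recs = [r for r in records if r.aod_550 is not None]
    missing_550 = [r for r in records if r.aod_550 is None]
    if missing_550:
        recs.extend(interpolate_records(missing_550))
    if time_window is not None:
        t0, t1 = time_window
        recs = [r for r in recs if t0 <= r.timestamp.time() <= t1]
    if not recs:
        return pd.Series(dtype=float, name="aod550")
    df = pd.DataFrame(
        {"date": [r.timestamp.date() for r in recs],
         "aod550": [r.aod_550 for r in recs]}
    )
    grouped = df.groupby("date")["aod550"].agg(["mean", "count"])
    keep = grouped[grouped["count"] >= min_obs]["mean"]
    keep.name = "aod550"
    return keep


def grid_swath(
    pixels: Sequence[SwathPixel], grid: GridSpec, date
) -> DailyGridField:
    """Bin swath pixels to the analysis grid for one day.

    Each pixel goes to the half-open cell containing its center; pixels
    outside the domain are dropped (logged).  A cell's value is the
    unweighted mean of its pixels; cells with no pixels are missing.
    """
    sums = np.zeros(grid.shape)
    counts = np.zeros(grid.shape, dtype=int)
    n_dropped = 0
    for px in pixels:
        if px.aod_550 < 0:
            raise ValueError("pixel AOD must be non-negative")
        cell = grid.cell_of(px.lat, px.lon)
        if cell is None:
            n_dropped += 1
            continue
        sums[cell] += px.aod_550
        counts[cell] += 1
    if n_dropped:
        log.info("grid_swath %s: dropped %d pixel(s) outside domain",
                 date, n_dropped)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    flags = np.where(counts > 0, RETRIEVED, MISSING).astype(np.int8)
    return DailyGridField(date, values, flags)
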