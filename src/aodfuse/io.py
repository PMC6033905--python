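"""Plain-text readers and writers for all pipeline artifacts.

Every artifact is a delimited text file (CSV) or a YAML sidecar:

* site AOD records:   date,time,aod_440,aod_675 (AERONET-like all-points)
* daily site AOD:     date,aod550
* grid AOD fields:    date,row,col,aod,flag   (long format, present cells)
* grid spec sidecar:  YAML with lon/lat extent and cell size
* regression map:     season,row,col,slope,intercept,r,n
* PM2.5 records:      date[,time],site_id,lat,lon,pm25
* collocated panel:   site,day,pm,aod,source
* mixed-model fit:    JSON

Day labels may be calendar dates or plain integers (synthetic scenes);
readers preserve whichever the file carries.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fusion import SeasonalRegressionMap
from .grid import FLAG_CODES, FLAG_NAMES, MISSING, DailyGridField, GridSpec
from .ingest import SiteAodRecord, interpolate_records
from .mixedlm import MixedModelFit
from .pm25 import CollocatedPanel

log = logging.getLogger(__name__)

#: AERONET level-2.0 all-points column names -> our reader layout
AERONET_COLUMN_MAP = {
    "Date(dd:mm:yyyy)": "date",
    "Time(hh:mm:ss)": "time",
    "AOD_440nm": "aod_440",
    "AOD_675nm": "aod_675",
}


def _parse_day(value):
    """Day label: int if it looks like one, else a datetime.date."""
    s = str(value)
    try:
        return int(s)
    except ValueError:
        return pd.Timestamp(s).date()


# ---------------------------------------------------------------- site AOD

def read_site_records(path, column_map: dict | None = None) -> list[SiteAodRecord]:
    """Read instantaneous site AOD records (date,time,aod_440,aod_675).

    ``column_map`` renames source columns first (see AERONET_COLUMN_MAP);
    records failing spectral validity are skipped with a logged count by
    the downstream interpolation.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    recs = []
    for rec in df.itertuples(index=False):
        ts = pd.Timestamp(f"{rec.date} {rec.time}").to_pydatetime()
        recs.append(SiteAodRecord(ts, float(rec.aod_440), float(rec.aod_675)))
    return interpolate_records(recs)


def write_site_daily(series: pd.Series, path) -> None:
    df = pd.DataFrame({"date": series.index, "aod550": series.to_numpy()})
    df.to_csv(path, index=False)


def read_site_daily(path) -> pd.Series:
    df = pd.read_csv(path)
    idx = [_parse_day(d) for d in df["date"]]
    return pd.Series(df["aod550"].to_numpy(float), index=idx, name="aod550")


# -------------------------------------------------------------- grid fields

def write_gridspec(grid: GridSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(grid.to_dict(), sort_keys=True))


def read_gridspec(path) -> GridSpec:
    return GridSpec.from_dict(yaml.safe_load(Path(path).read_text()))


def write_grid_fields(fields: list[DailyGridField], path) -> None:
    """Long-format date,row,col,aod,flag; one row per present cell.

    All-missing days are kept via a sentinel row (row=col=-1, empty aod)
    so the day list round-trips.
    """
    rows = []
    for f in fields:
        rr, cc = np.nonzero(f.present)
        if rr.size == 0:
            rows.append((f.date, -1, -1, np.nan, "missing"))
            continue
        for r, c in zip(rr, cc):
            rows.append((f.date, int(r), int(c), f.values[r, c],
                         FLAG_NAMES[int(f.flags[r, c])]))
    pd.DataFrame(rows, columns=["date", "row", "col", "aod", "flag"]).to_csv(
        path, index=False
    )


def read_grid_fields(path, grid: GridSpec) -> list[DailyGridField]:
    df = pd.read_csv(path)
    fields = []
    for date_val, g in df.groupby("date", sort=True):
        date = _parse_day(date_val)
        values = np.full(grid.shape, np.nan)
        flags = np.full(grid.shape, MISSING, dtype=np.int8)
        for rec in g.itertuples(index=False):
            if int(rec.row) < 0:
                continue  # all-missing sentinel
            values[int(rec.row), int(rec.col)] = float(rec.aod)
            flags[int(rec.row), int(rec.col)] = FLAG_CODES[str(rec.flag)]
        fields.append(DailyGridField(date, values, flags))
    fields.sort(key=lambda f: f.date)
    return fields


# ----------------------------------------------------------- regression map

def write_regression_map(rmap: SeasonalRegressionMap, path) -> None:
    rmap.to_frame().to_csv(path, index=False)


def read_regression_map(path, grid: GridSpec) -> SeasonalRegressionMap:
    return SeasonalRegressionMap.from_frame(pd.read_csv(path), grid)


# ------------------------------------------------------------------- PM2.5

def read_pm(path, min_hours: int = 1):
    """Read monitor PM2.5 (date[,time],site_id,lat,lon,pm25).

    Hourly files (with a ``time`` column) are averaged to daily means per
    site; dates with fewer than ``min_hours`` hourly values are dropped.
    Returns ``(pm_daily, site_coords)`` with columns
    (date, site_id, pm25) and (site_id, lat, lon).
    """
    df = pd.read_csv(path)
    df["date"] = [_parse_day(d) for d in df["date"]]
    if "time" in df.columns:
        g = df.groupby(["date", "site_id"])["pm25"].agg(["mean", "count"])
        g = g[g["count"] >= min_hours]
        pm_daily = g["mean"].rename("pm25").reset_index()
    else:
        pm_daily = df[["date", "site_id", "pm25"]].copy()
    coords = df[["site_id", "lat", "lon"]].drop_duplicates("site_id")
    return pm_daily, coords.reset_index(drop=True)


def write_panel(panel: CollocatedPanel, path) -> None:
    panel.records.to_csv(path, index=False)


def read_panel(path, site_cells: dict | None = None) -> CollocatedPanel:
    df = pd.read_csv(path)
    df["day"] = [_parse_day(d) for d in df["day"]]
    if site_cells is None:
        # pseudo-site ids of the form r{row}c{col} carry their own cell
        site_cells = {}
        for s in df["site"].unique():
            s = str(s)
            if s.startswith("r") and "c" in s:
                try:
                    r, c = s[1:].split("c")
                    site_cells[s] = (int(r), int(c))
                except ValueError:
                    pass
    return CollocatedPanel(df, site_cells)


# --------------------------------------------------------- mixed-model fit

def write_fit(fit: MixedModelFit, path) -> None:
    d = {
        "alpha": fit.alpha, "beta": fit.beta,
        "alpha_se": fit.alpha_se, "beta_se": fit.beta_se,
        "Sigma": np.asarray(fit.Sigma).tolist(),
        "sigma_s_sq": fit.sigma_s_sq, "sigma_sq": fit.sigma_sq,
        "u": fit.u.tolist(), "v": fit.v.tolist(), "s": fit.s.tolist(),
        "day_labels": [str(d_) for d_ in fit.day_labels],
        "site_labels": [str(s_) for s_ in fit.site_labels],
        "n_days": fit.n_days, "n_sites": fit.n_sites, "n_obs": fit.n_obs,
        "converged": fit.converged, "loglik": fit.loglik,
        "message": fit.message,
        "site_cells": [list(c) if c is not None else None
                       for c in (fit.site_cells or [])],
    }
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))


def read_fit(path) -> MixedModelFit:
    d = json.loads(Path(path).read_text())
    return MixedModelFit(
        alpha=d["alpha"], beta=d["beta"],
        alpha_se=d["alpha_se"], beta_se=d["beta_se"],
        Sigma=np.asarray(d["Sigma"]),
        sigma_s_sq=d["sigma_s_sq"], sigma_sq=d["sigma_sq"],
        u=np.asarray(d["u"]), v=np.asarray(d["v"]), s=np.asarray(d["s"]),
        day_labels=np.asarray([_parse_day(x) for x in d["day_labels"]]),
        site_labels=np.asarray(d["site_labels"]),
        n_days=d["n_days"], n_sites=d["n_sites"], n_obs=d["n_obs"],
        converged=d["converged"], loglik=d["loglik"], message=d["message"],
        site_cells=[tuple(c) if c is not None else None
                    for c in d.get("site_cells", [])] or None,
    )
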