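"""Meteorological season assignment.

Seasons follow the standard meteorological convention: spring = MAM,
summer = JJA, autumn = SON, winter = DJF.  A December day belongs to the
winter labelled by its own year, so "winter of 2013" spans December 2013
through February 2014.
"""

from __future__ import annotations

import datetime as _dt

SEASONS = ("spring", "summer", "autumn", "winter")

_MONTH_SEASON = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
    12: "winter", 1: "winter", 2: "winter",
}


def season_of(date) -> str:
    """Season label for a date (or anything with a ``month`` attribute)."""
    return _MONTH_SEASON[date.month]


def winter_year(date) -> int:
    """Label year of the winter containing ``date`` (Dec keeps its own year)."""
    if date.month == 12:
        return date.year
    if date.month in (1, 2):
        return date.year - 1
    raise ValueError(f"{date} is not a winter date")


def winter_dates(year: int):
    """All dates of the winter labelled ``year`` (Dec year .. Feb year+1)."""
    d = _dt.date(year, 12, 1)
    end = _dt.date(year + 1, 3, 1)
    out = []
    while d < end:
        out.append(d)
        d += _dt.timedelta(days=1)
    return out
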