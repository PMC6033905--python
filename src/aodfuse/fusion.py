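"""Site-to-grid AOD fusion.

The spatial representativeness of a fixed ground site is captured by a
per-cell, per-season ordinary least-squares regression of gridded
satellite AOD (response) on the site AOD (predictor), together with the
Pearson correlation r of the daily pairs.  Cells whose seasonal r passes
a threshold (default r >= 0.5) are eligible for gap-filling: on days when
the satellite retrieval is missing but the site observed, the cell gets
``slope * site_aod + intercept`` (floored at 0) with a ``filled`` source
flag.  Retrieved values are never altered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .grid import FILLED, MISSING, RETRIEVED, DailyGridField, GridSpec
from .seasons import SEASONS, season_of

__all__ = [
    "FusionConfig",
    "SeasonFit",
    "SeasonalRegressionMap",
    "EvalMetrics",
    "fit_regression_map",
    "fill_missing",
    "sampling_ratio",
    "evaluate_against_reference",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FusionConfig:
    """Fusion stage settings.

    r_threshold: minimum signed Pearson r for a (cell, season) to fill.
    min_pairs:   minimum daily pairs for a regression fit to be kept;
                 fits on fewer pairs are statistically meaningless and
                 are suppressed.
    season_of:   date -> season label; default meteorological seasons.
    """

    r_threshold: float = 0.5
    min_pairs: int = 10
    season_of: Callable[[object], str] = season_of

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_threshold <= 1.0:
            raise ValueError("r_threshold must be in [0, 1]")
        if self.min_pairs < 2:
            raise ValueError("min_pairs must be >= 2")


@dataclass
class SeasonFit:
    """Per-cell OLS fit arrays for one season (NaN where no fit)."""

    slope: np.ndarray
    intercept: np.ndarray
    r: np.ndarray
    n_pairs: np.ndarray  # int array; counts are kept even where no fit


@dataclass
class SeasonalRegressionMap:
    """Per-cell, per-season link between site AOD and grid AOD."""

    grid: GridSpec
    seasons: dict[str, SeasonFit] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table season,row,col,slope,intercept,r,n."""
        rows = []
        for season, fit in self.seasons.items():
            nr, nc = fit.slope.shape
            for i in range(nr):
                for j in range(nc):
                    rows.append(
                        (season, i, j, fit.slope[i, j], fit.intercept[i, j],
                         fit.r[i, j], int(fit.n_pairs[i, j]))
                    )
        return pd.DataFrame(
            rows, columns=["season", "row", "col", "slope", "intercept", "r", "n"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, grid: GridSpec) -> "SeasonalRegressionMap":
        out = cls(grid)
        for season, g in df.groupby("season"):
            fit = SeasonFit(
                slope=np.full(grid.shape, np.nan),
                intercept=np.full(grid.shape, np.nan),
                r=np.full(grid.shape, np.nan),
                n_pairs=np.zeros(grid.shape, dtype=int),
            )
            idx = (g["row"].to_numpy(int), g["col"].to_numpy(int))
            fit.slope[idx] = g["slope"].to_numpy(float)
            fit.intercept[idx] = g["intercept"].to_numpy(float)
            fit.r[idx] = g["r"].to_numpy(float)
            fit.n_pairs[idx] = g["n"].to_numpy(int)
            out.seasons[str(season)] = fit
        return out


def fit_regression_map(
    site_daily: pd.Series,
    grid_daily: Sequence[DailyGridField],
    config: FusionConfig = FusionConfig(),
) -> SeasonalRegressionMap:
    """Fit per-cell seasonal OLS of retrieved grid AOD on site AOD.

    For each cell and season, the days where BOTH the site daily AOD and
    that cell's *retrieved* AOD exist form the pairs; slope, intercept and
    Pearson r come from the standard normal equations.  Strata with fewer
    than ``min_pairs`` pairs, or with zero variance in either variable,
    carry no fit (NaN) but keep their pair count.
    """
    if len(grid_daily) == 0:
        raise ValueError("no grid fields supplied")
    grid = _infer_gridspec(grid_daily)
    shape = grid_daily[0].values.shape

    by_season: dict[str, list[DailyGridField]] = {}
    for f in grid_daily:
        by_season.setdefault(config.season_of(f.date), []).append(f)

    out = SeasonalRegressionMap(grid)
    for season, fields in by_season.items():
        dates = [f.date for f in fields]
        x_all = np.array(
            [site_daily.get(d, np.nan) for d in dates], dtype=float
        )
        has_site = ~np.isnan(x_all)
        Y = np.stack([f.values for f in fields])           # (days, nr, nc)
        retrieved = np.stack([f.retrieved for f in fields])
        valid = retrieved & has_site[:, None, None]
        Yv = np.where(valid, Y, 0.0)
        xv = np.where(has_site, x_all, 0.0)[:, None, None]

        n = valid.sum(axis=0).astype(float)
        sx = (xv * valid).sum(axis=0)
        sy = Yv.sum(axis=0)
        sxx = (xv ** 2 * valid).sum(axis=0)
        sxy = (xv * Yv).sum(axis=0)
        syy = (Yv ** 2).sum(axis=0)

        with np.errstate(invalid="ignore", divide="ignore"):
            var_x = n * sxx - sx ** 2
            var_y = n * syy - sy ** 2
            cov = n * sxy - sx * sy
            slope = cov / var_x
            intercept = (sy - slope * sx) / n
            r = cov / np.sqrt(var_x * var_y)

        ok = (n >= config.min_pairs) & (var_x > 0) & (var_y > 0)
        n_degenerate = int(((n >= config.min_pairs) & ~ok).sum())
        if n_degenerate:
            log.info(
                "fit_regression_map[%s]: %d cell(s) with zero-variance "
                "stratum, no fit", season, n_degenerate,
            )
        fit = SeasonFit(
            slope=np.where(ok, slope, np.nan),
            intercept=np.where(ok, intercept, np.nan),
            r=np.where(ok, np.clip(r, -1.0, 1.0), np.nan),
            n_pairs=n.astype(int),
        )
        assert fit.slope.shape == shape
        out.seasons[season] = fit
    return out


def fill_missing(
    grid_daily: DailyGridField,
    site_value: float | None,
    rmap: SeasonalRegressionMap,
    config: FusionConfig = FusionConfig(),
) -> DailyGridField:
    """Fill one day's missing cells from the site AOD where r passes.

    Retrieved cells are returned unchanged.  A missing cell is filled with
    ``slope * site_value + intercept`` (floored at 0, flag ``filled``) iff
    its season's fitted r >= r_threshold and a site value exists for the
    day.  Absent site value is a no-op.
    """
    out = grid_daily.copy()
    if site_value is None or (isinstance(site_value, float) and np.isnan(site_value)):
        log.info("fill_missing %s: no site value, field unchanged", grid_daily.date)
        return out
    season = config.season_of(grid_daily.date)
    fit = rmap.seasons.get(season)
    if fit is None:
        log.info("fill_missing %s: no fitted map for season %s", grid_daily.date, season)
        return out
    with np.errstate(invalid="ignore"):
        eligible = (
            (grid_daily.flags == MISSING)
            & ~np.isnan(fit.slope)
            & (fit.r >= config.r_threshold)
        )
    pred = fit.slope * float(site_value) + fit.intercept
    n_floored = int(np.sum(eligible & (pred < 0)))
    if n_floored:
        log.info("fill_missing %s: floored %d negative prediction(s) to 0",
                 grid_daily.date, n_floored)
    out.values[eligible] = np.maximum(pred[eligible], 0.0)
    out.flags[eligible] = FILLED
    return out


def sampling_ratio(
    fields: Sequence[DailyGridField], include_filled: bool = True
) -> np.ndarray:
    """Per-cell fraction of days with an AOD value.

    ``include_filled=False`` counts retrieved cells only (pre-fusion
    coverage); the default counts retrieved and filled cells (post-fusion
    coverage).
    """
    if len(fields) == 0:
        raise ValueError("no fields supplied")
    if include_filled:
        counts = np.sum([f.present for f in fields], axis=0)
    else:
        counts = np.sum([f.retrieved for f in fields], axis=0)
    return counts / float(len(fields))


@dataclass
class EvalMetrics:
    """Agreement metrics between predicted and reference values.

    mpe is the mean absolute difference (the satellite-validation usage of
    "mean prediction error"), rmse the root mean square error, both in the
    units of the inputs.  envelope_fraction is the fraction of pairs with
    ``|pred - ref| <= 0.05 + 0.20 * ref`` — the expected satellite AOD
    retrieval uncertainty over land — and is only meaningful in AOD units
    (None for PM2.5 comparisons).
    """

    r: float
    mpe: float
    rmse: float
    n: int
    envelope_fraction: float | None = None


def evaluate_against_reference(
    predicted, reference, envelope: bool = True
) -> EvalMetrics:
    """Pearson r, MPE, RMSE (and the AOD error-envelope fraction) of pairs."""
    pred = np.asarray(predicted, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("predicted and reference must have equal length")
    if pred.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = pred - ref
    mpe = float(np.mean(np.abs(diff)))
    rmse = float(np.sqrt(np.mean(diff ** 2)))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = float(np.corrcoef(pred, ref)[0, 1])  # nan if either side constant
    env = None
    if envelope:
        # boundary inclusive
        env = float(np.mean(np.abs(diff) <= 0.05 + 0.20 * ref))
    return EvalMetrics(r=r, mpe=mpe, rmse=rmse, n=int(pred.size),
                       envelope_fraction=env)


def _infer_gridspec(fields: Sequence[DailyGridField]) -> GridSpec:
    """Placeholder GridSpec matching the field shape (indices only).

    Regression maps only need cell indices; a caller with a real GridSpec
    should attach it via SeasonalRegressionMap(grid=...).
    """
    nr, nc = fields[0].values.shape
    return GridSpec(0.0, nc * 0.1, 0.0, nr * 0.1, 0.1)
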