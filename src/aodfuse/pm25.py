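"""PM2.5 estimation from gridded AOD via the day/site mixed model.

Monitors are collocated with the analysis grid (monitors sharing a cell
are merged into one pseudo-site whose daily PM2.5 is the mean of the
member values), the mixed model is fitted by REML, PM2.5 fields are
predicted with day-specific effects, and spatial generalisation is
assessed by leave-one-site-out cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fusion import EvalMetrics, evaluate_against_reference
from .grid import FLAG_NAMES, DailyGridField, GridSpec
from .mixedlm import IdentifiabilityError, MixedModelFit, fit_day_site_lmm

__all__ = [
    "CollocatedPanel",
    "collocate",
    "fit_mixed_model",
    "predict_pm",
    "loso_cross_validate",
    "LosoResult",
    "compare_histograms",
]

log = logging.getLogger(__name__)


@dataclass
class CollocatedPanel:
    """Long-format (site, day, PM2.5, AOD) records feeding the mixed model.

    ``records`` has columns site (pseudo-site id), day (day label),
    pm (ug m^-3), aod (dimensionless) and source ('retrieved'|'filled').
    At most one record per (site, day); pm and aod are non-negative.
    ``site_cells`` maps pseudo-site id -> (row, col) of its grid cell.
    """

    records: pd.DataFrame
    site_cells: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        req = {"site", "day", "pm", "aod", "source"}
        missing = req - set(self.records.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        if self.records.duplicated(["site", "day"]).any():
            raise ValueError("panel has more than one record per (site, day)")
        if len(self.records):
            if (self.records["pm"] < 0).any() or (self.records["aod"] < 0).any():
                raise ValueError("pm and aod must be non-negative")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sites(self) -> np.ndarray:
        return np.asarray(sorted(self.records["site"].unique()))

    @property
    def days(self) -> np.ndarray:
        return np.asarray(sorted(self.records["day"].unique()))

    def drop_site(self, site) -> "CollocatedPanel":
        return CollocatedPanel(
            self.records[self.records["site"] != site].reset_index(drop=True),
            self.site_cells,
        )

    def codes(self):
        """(y, x, day_idx, site_idx, day_labels, site_labels) dense coding."""
        day_labels = self.days
        site_labels = self.sites
        day_map = {d: j for j, d in enumerate(day_labels)}
        site_map = {s: i for i, s in enumerate(site_labels)}
        df = self.records
        return (
            df["pm"].to_numpy(float),
            df["aod"].to_numpy(float),
            df["day"].map(day_map).to_numpy(int),
            df["site"].map(site_map).to_numpy(int),
            day_labels,
            site_labels,
        )


def collocate(
    pm_daily: pd.DataFrame,
    site_coords: pd.DataFrame,
    fields: list[DailyGridField],
    grid: GridSpec,
) -> CollocatedPanel:
    """Pair monitor PM2.5 with the AOD of the containing grid cell.

    ``pm_daily`` has columns date, site_id, pm25; ``site_coords`` has
    site_id, lat, lon.  Monitors are mapped to cells with the half-open
    convention; those outside the domain are excluded (logged).  Monitors
    sharing a cell become one pseudo-site ``r{row}c{col}`` whose daily PM
    is the mean of member values available that day.  A record is emitted
    only when both the merged PM and the cell AOD exist; the AOD source
    flag (retrieved/filled) is propagated.
    """
    cell_of_site: dict[object, tuple[int, int]] = {}
    n_outside = 0
    for rec in site_coords.itertuples(index=False):
        cell = grid.cell_of(float(rec.lat), float(rec.lon))
        if cell is None:
            n_outside += 1
            log.info("collocate: monitor %r outside domain, excluded", rec.site_id)
            continue
        cell_of_site[rec.site_id] = cell
    if n_outside:
        log.info("collocate: excluded %d monitor(s) outside domain", n_outside)

    pm = pm_daily[pm_daily["site_id"].isin(cell_of_site)].copy()
    pm["cell"] = pm["site_id"].map(cell_of_site)
    # merge monitors sharing a cell: daily mean over available members
    merged = pm.groupby(["date", "cell"], as_index=False)["pm25"].mean()

    field_by_date = {f.date: f for f in fields}
    rows = []
    for rec in merged.itertuples(index=False):
        fld = field_by_date.get(rec.date)
        if fld is None:
            continue
        r, c = rec.cell
        if not fld.present[r, c]:
            continue
        rows.append(
            (f"r{r}c{c}", rec.date, rec.pm25, fld.values[r, c],
             FLAG_NAMES[int(fld.flags[r, c])])
        )
    records = pd.DataFrame(rows, columns=["site", "day", "pm", "aod", "source"])
    site_cells = {f"r{r}c{c}": (r, c) for (r, c) in
                  {cell for cell in cell_of_site.values()}}
    return CollocatedPanel(records, site_cells)


def fit_mixed_model(
    panel: CollocatedPanel,
    include_day: bool = True,
    include_site: bool = True,
) -> MixedModelFit:
    """REML fit of the day/site crossed mixed model to a collocated panel.

    ``include_day=False`` / ``include_site=False`` force the respective
    variance components to zero (with both off the fit is pooled OLS) —
    used for reduction checks and degenerate panels.
    """
    if len(panel) == 0:
        raise IdentifiabilityError("empty panel")
    y, x, day_idx, site_idx, day_labels, site_labels = panel.codes()
    fit = fit_day_site_lmm(
        y, x, day_idx, site_idx,
        day_labels=day_labels, site_labels=site_labels,
        include_day=include_day, include_site=include_site,
    )
    fit.site_cells = [panel.site_cells.get(s) for s in site_labels]
    return fit


def predict_pm(
    fit: MixedModelFit,
    fld: DailyGridField,
    day=None,
    new_day: bool = False,
) -> np.ndarray:
    """Per-cell PM2.5 prediction for one day's AOD field.

    For a training day (``day`` in the fit) the day-specific effects are
    applied: PM = (alpha + u_j) + (beta + v_j) * AOD.  Site random
    intercepts are added only at cells hosting a known site; elsewhere the
    population level (0) is used.  For an unseen day pass ``new_day=True``
    to use u_j = v_j = 0 (population-level day; predictions carry wider
    uncertainty).  Missing AOD yields missing PM; negative predictions are
    floored at 0 (counted in the log).
    """
    if day is None:
        day = fld.date
    if fit.has_day(day):
        u_j, v_j = fit.day_effects(day)
    elif new_day:
        u_j, v_j = 0.0, 0.0
    else:
        raise KeyError(
            f"day {day!r} not in the training set; pass new_day=True for a "
            "population-level (u_j = v_j = 0) prediction"
        )
    pm = (fit.alpha + u_j) + (fit.beta + v_j) * fld.values
    if fit.site_cells:
        for i, cell in enumerate(fit.site_cells):
            if cell is not None:
                pm[cell] += fit.s[i]
    n_neg = int(np.nansum(pm < 0))
    if n_neg:
        log.info("predict_pm %s: floored %d negative prediction(s)", day, n_neg)
    with np.errstate(invalid="ignore"):
        pm = np.where(pm < 0, 0.0, pm)
    return pm


@dataclass
class LosoResult:
    """Leave-one-site-out cross-validation output."""

    predictions: pd.DataFrame       # site, day, obs, pred, fold
    metrics: EvalMetrics            # pooled daily-record metrics
    site_summary: pd.DataFrame      # per-site n, obs/pred means, mpe, rmse
    site_mean_metrics: EvalMetrics | None  # metrics on per-site mean levels
    failed_folds: list


def loso_cross_validate(panel: CollocatedPanel) -> LosoResult:
    """Leave-one-site-out CV of the mixed model.

    Each site is held out in turn; the model is refitted on the remaining
    sites and the held-out site's records are predicted with the refitted
    day effects and s_k = 0 (the prior mean of an unseen site's
    intercept).  Held-out days absent from a fold's training data get
    population-level day effects.  Pooled record-level metrics and
    per-site summaries are returned; folds whose refit fails are excluded
    from the pool and reported.
    """
    sites = panel.sites
    if sites.size < 3:
        raise IdentifiabilityError("leave-one-site-out CV needs >= 3 sites")
    rows = []
    failed = []
    for k, site in enumerate(sites):
        train = panel.drop_site(site)
        held = panel.records[panel.records["site"] == site]
        try:
            fit = fit_mixed_model(train)
        except (IdentifiabilityError, np.linalg.LinAlgError) as exc:
            log.warning("loso fold %r failed: %s", site, exc)
            failed.append((site, str(exc)))
            continue
        for rec in held.itertuples(index=False):
            if fit.has_day(rec.day):
                u_j, v_j = fit.day_effects(rec.day)
            else:
                u_j, v_j = 0.0, 0.0
            pred = (fit.alpha + u_j) + (fit.beta + v_j) * rec.aod
            rows.append((site, rec.day, rec.pm, max(pred, 0.0), k))
    preds = pd.DataFrame(rows, columns=["site", "day", "obs", "pred", "fold"])
    if len(preds) < 2:
        raise IdentifiabilityError("too few held-out predictions pooled")
    metrics = evaluate_against_reference(
        preds["pred"].to_numpy(), preds["obs"].to_numpy(), envelope=False
    )
    summ = (
        preds.groupby("site")
        .apply(
            lambda g: pd.Series(
                {
                    "n": len(g),
                    "obs_mean": g["obs"].mean(),
                    "pred_mean": g["pred"].mean(),
                    "mpe": (g["pred"] - g["obs"]).abs().mean(),
                    "rmse": np.sqrt(((g["pred"] - g["obs"]) ** 2).mean()),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    site_mean_metrics = None
    if len(summ) >= 2:
        site_mean_metrics = evaluate_against_reference(
            summ["pred_mean"].to_numpy(), summ["obs_mean"].to_numpy(),
            envelope=False,
        )
    return LosoResult(preds, metrics, summ, site_mean_metrics, failed)


def compare_histograms(
    obs, pred, bin_width: float = 10.0
) -> tuple[float, float]:
    """Compare two PM2.5 samples as relative-frequency histograms.

    Both samples are binned on the shared range [0, max of both] with the
    given width into percent-frequency vectors; returns ``(r_hist,
    mad_hist)`` — the Pearson correlation of the two vectors and the mean
    absolute difference in percent frequency over bins.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.size == 0 or pred.size == 0:
        raise ValueError("empty input sample")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = min(0.0, obs.min(), pred.min())
    hi = max(obs.max(), pred.max())
    n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    # make the last edge inclusive of the max value
    edges[-1] = max(edges[-1], hi)
    f_obs = np.histogram(obs, bins=edges)[0] / obs.size * 100.0
    f_pred = np.histogram(pred, bins=edges)[0] / pred.size * 100.0
    mad = float(np.mean(np.abs(f_obs - f_pred)))
    if n_bins < 2 or np.std(f_obs) == 0 or np.std(f_pred) == 0:
        r = 1.0 if mad == 0 else np.nan
    else:
        r = float(np.corrcoef(f_obs, f_pred)[0, 1])
    return r, mad
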