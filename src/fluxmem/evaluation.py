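"""Metrics and the four-scale decomposition of NEE predictive skill.

Skill is read at four scales, each from the same monthly prediction table:

* seasonal cycle        - the raw monthly (obs, pred) pairs;
* seasonal anomalies    - monthly value minus that site's calendar-month mean
                          (obs and pred each centered on their own means);
* interannual anomalies - site-year mean minus the site's mean of annual
                          means, only for sites with >= 3 complete years;
* across-site           - one (mean obs, mean pred) pair per site.

Metrics: Nash-Sutcliffe efficiency (NSE), squared Pearson correlation (R2),
RMSE and MAE.  With ensemble predictions the primary report is the mean +/- sd
of per-member metrics; metrics of the ensemble-mean prediction are also
emitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

SCALES = ["seasonal_cycle", "seasonal_anomalies", "across_site", "interannual_anomalies"]


class UndefinedMetricError(ValueError):
    pass


def nse(obs: np.ndarray, pred: np.ndarray) -> float:
    """Nash-Sutcliffe efficiency: 1 - SSE / SS_about_obs_mean; 1 is perfect."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.size < 2:
        raise UndefinedMetricError("NSE needs at least 2 observations")
    denom = np.sum((obs - obs.mean()) ** 2)
    if denom == 0:
        raise UndefinedMetricError("NSE undefined for zero-variance observations")
    return float(1.0 - np.sum((pred - obs) ** 2) / denom)


def metric_suite(obs: np.ndarray, pred: np.ndarray) -> dict[str, float]:
    """NSE, R2 (squared Pearson correlation), RMSE and MAE."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    err = pred - obs
    so, sp = obs.std(), pred.std()
    if so > 0 and sp > 0:
        r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    else:
        r2 = np.nan
    return {
        "nse": nse(obs, pred),
        "r2": r2,
        "rmse": float(np.sqrt(np.mean(err**2))),
        "mae": float(np.mean(np.abs(err))),
    }


def complete_years(site_rows: pd.DataFrame) -> list[int]:
    """Years in which all 12 calendar months carry an observation."""
    counts = site_rows.groupby("year")["month"].nunique()
    return sorted(int(y) for y, c in counts.items() if c == 12)


def hemisphere_align(month: int | np.ndarray, latitude: float) -> int | np.ndarray:
    """Shift southern-hemisphere months by 6 so seasons line up across sites."""
    if np.ndim(month) == 0:
        return int((int(month) - 1 + 6) % 12 + 1) if latitude < 0 else int(month)
    month = np.asarray(month)
    return np.where(latitude < 0, (month - 1 + 6) % 12 + 1, month)


@dataclass
class Decomposition:
    """Paired (obs, pred) vectors per scale, plus bookkeeping."""

    pairs: dict[str, tuple[np.ndarray, np.ndarray]]
    eligible_sites: list[str]
    excluded_sites: list[str]


def decompose(
    table: pd.DataFrame,
    pred_col: str = "pred",
    min_complete_years: int = 3,
) -> Decomposition:
    """Split a (site_id, year, month, obs, pred) table into the four scales.

    Anomaly scales only use sites with at least ``min_complete_years``
    complete years of observations; everything else is reported per scale
    from all observed rows.
    """
    t = table.dropna(subset=["obs", pred_col])
    pairs: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    pairs["seasonal_cycle"] = (t["obs"].to_numpy(), t[pred_col].to_numpy())

    site_means = t.groupby("site_id")[["obs", pred_col]].mean()
    pairs["across_site"] = (
        site_means["obs"].to_numpy(), site_means[pred_col].to_numpy()
    )

    eligible, excluded = [], []
    for sid, grp in t.groupby("site_id"):
        if len(complete_years(grp)) >= min_complete_years:
            eligible.append(str(sid))
        else:
            excluded.append(str(sid))

    el = t[t["site_id"].isin(eligible)]
    if len(el):
        cm = el.groupby(["site_id", "month"])[["obs", pred_col]].transform("mean")
        pairs["seasonal_anomalies"] = (
            (el["obs"] - cm["obs"]).to_numpy(),
            (el[pred_col] - cm[pred_col]).to_numpy(),
        )
        cy = {s: complete_years(g) for s, g in el.groupby("site_id")}
        rows_o, rows_p = [], []
        for sid, grp in el.groupby("site_id"):
            g = grp[grp["year"].isin(cy[str(sid)])]
            ann = g.groupby("year")[["obs", pred_col]].mean()
            rows_o.append(ann["obs"].to_numpy() - ann["obs"].mean())
            rows_p.append(ann[pred_col].to_numpy() - ann[pred_col].mean())
        pairs["interannual_anomalies"] = (
            np.concatenate(rows_o), np.concatenate(rows_p)
        )
    else:
        pairs["seasonal_anomalies"] = (np.array([]), np.array([]))
        pairs["interannual_anomalies"] = (np.array([]), np.array([]))
    return Decomposition(pairs=pairs, eligible_sites=eligible, excluded_sites=excluded)


def scale_metrics(
    table: pd.DataFrame,
    member_cols: Optional[Sequence[str]] = None,
    min_complete_years: int = 3,
) -> dict[str, dict[str, float]]:
    """Per-scale metrics; with member columns, mean +/- sd over members.

    Returns {scale: {nse_mean, nse_sd, r2_mean, ..., n, nse_of_mean, ...}}.
    Scales without enough data come back as None (the report's "NA").
    """
    out: dict[str, dict[str, float]] = {}
    cols = list(member_cols) if member_cols else ["pred"]
    per_member: dict[str, list[dict[str, float]]] = {s: [] for s in SCALES}
    n_pairs: dict[str, int] = {}
    for c in cols:
        dec = decompose(table, pred_col=c, min_complete_years=min_complete_years)
        for s in SCALES:
            o, p = dec.pairs[s]
            n_pairs[s] = len(o)
            if len(o) >= 2 and np.sum((o - o.mean()) ** 2) > 0:
                per_member[s].append(metric_suite(o, p))
    mean_dec = decompose(table, pred_col="pred", min_complete_years=min_complete_years)
    for s in SCALES:
        if not per_member[s]:
            out[s] = None
            continue
        rec: dict[str, float] = {"n": n_pairs[s]}
        for m in ("nse", "r2", "rmse", "mae"):
            vals = np.array([d[m] for d in per_member[s]])
            rec[f"{m}_mean"] = float(np.mean(vals))
            rec[f"{m}_sd"] = float(np.std(vals))
        o, p = mean_dec.pairs[s]
        if len(o) >= 2 and np.sum((o - o.mean()) ** 2) > 0:
            rec["nse_of_mean"] = nse(o, p)
        out[s] = rec
    return out


def residual_seasonal_curve(
    table: pd.DataFrame,
    site_latitudes: dict[str, float],
    member_cols: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Mean seasonal curve of site-centered residuals.

    Residual per (site i, month j) = [obs_ij - mean(obs_i)] - [pred_ij -
    mean(pred_i)]; averaged by hemisphere-aligned calendar month across
    sites.  Returns a 12-row frame with mean and (ensemble) sd.
    """
    cols = list(member_cols) if member_cols else ["pred"]
    t = table.dropna(subset=["obs"] + cols).copy()
    lat = t["site_id"].map(site_latitudes).to_numpy()
    t["aligned_month"] = np.where(
        lat < 0, (t["month"].to_numpy() - 1 + 6) % 12 + 1, t["month"].to_numpy()
    )
    curves = []
    for c in cols:
        cen = t.groupby("site_id")[["obs", c]].transform("mean")
        resid = (t["obs"] - cen["obs"]) - (t[c] - cen[c])
        curves.append(resid.groupby(t["aligned_month"]).mean())
    stacked = pd.concat(curves, axis=1)
    out = pd.DataFrame(
        {
            "month": stacked.index.astype(int),
            "residual_mean": stacked.mean(axis=1).to_numpy(),
            "residual_sd": stacked.std(axis=1, ddof=0).to_numpy() if len(cols) > 1 else 0.0,
        }
    ).reset_index(drop=True)
    return out


def stratified_report(
    table: pd.DataFrame,
    site_strata: pd.DataFrame,
    by: Sequence[str] = ("pft", "climate_class"),
    member_cols: Optional[Sequence[str]] = None,
    min_complete_years: int = 3,
) -> dict[str, dict[str, dict]]:
    """Per-stratum scale metrics: {stratifier: {stratum: {scale: metrics|None}}}.

    Strata with no eligible anomaly sites report None for the anomaly scales
    rather than a number.
    """
    merged = table.merge(site_strata, on="site_id", how="left")
    report: dict[str, dict[str, dict]] = {"all": {"all": scale_metrics(
        table, member_cols=member_cols, min_complete_years=min_complete_years
    )}}
    for key in by:
        report[key] = {}
        for stratum, grp in merged.groupby(key):
            report[key][str(stratum)] = scale_metrics(
                grp, member_cols=member_cols, min_complete_years=min_complete_years
            )
    return report
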