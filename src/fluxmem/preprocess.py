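"""Data preparation: reflectance gap-filling, climate down-scaling, QC filter.

Reflectance records are irregular (clouds), but the sequence model needs
complete monthly predictor matrices.  Gaps are filled in two stages:

* stage 1 - inside the coverage window of a co-located auxiliary reflectance
  product (MODIS-like), each band is regressed on the auxiliary bands with a
  random forest trained on months where both are observed;
* stage 2 - all remaining gaps over the full record are filled from climate
  (tair, precip, rg, vpd, rpot), plant functional type, calendar month and
  latitude with a global random forest per band.

Candidate predictors for each stage pass through a shadow-feature selection
(each candidate duplicated as a within-column permutation; candidates whose
tree importance beats the best shadow in most repeats are kept).

Climate gaps are filled by regressing the gappy site series on the three
nearest gridded neighbor series and picking, per site and variable, the model
family with the highest Nash-Sutcliffe efficiency on held-out months (lowest
RMSE for precipitation).

Provenance flags partition every reflectance cell into observed / stage1 /
stage2; observed values are never overwritten.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import LinearRegression

from .synthgen import BANDS, SiteRecord, potential_radiation

OBSERVED, STAGE1, STAGE2 = 0, 1, 2


class InsufficientDataError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


@dataclass
class FeatureSelection:
    selected: list[str]
    none_significant: bool
    hit_fraction: dict[str, float] = field(default_factory=dict)


def select_features(
    candidates: pd.DataFrame,
    target: np.ndarray | pd.Series,
    seed: int,
    n_repeats: int = 20,
    confirm_fraction: float = 0.8,
    min_rows: int = 50,
    n_estimators: int = 50,
) -> FeatureSelection:
    """Shadow-feature (Boruta-style) predictor screening.

    Each candidate column is duplicated as a within-column permutation
    ("shadow").  Over ``n_repeats`` refits of a random-forest regressor, a
    candidate is confirmed when its importance exceeds the maximum shadow
    importance in at least ``confirm_fraction`` of repeats.  Always returns at
    least one predictor: when nothing is confirmed the top-ranked candidate is
    returned and flagged.
    """
    y = np.asarray(target, dtype=float)
    ok = np.isfinite(y) & np.isfinite(candidates.to_numpy(dtype=float)).all(axis=1)
    if ok.sum() < min_rows:
        raise InsufficientDataError(
            f"feature selection needs >= {min_rows} complete rows; got {int(ok.sum())}"
        )
    Xc = candidates.loc[ok].to_numpy(dtype=float)
    y = y[ok]
    names = list(candidates.columns)
    k = len(names)
    rng = np.random.default_rng(seed)
    hits = np.zeros(k)
    imp_sum = np.zeros(k)
    for r in range(n_repeats):
        shadows = np.column_stack([rng.permutation(Xc[:, j]) for j in range(k)])
        Xfull = np.hstack([Xc, shadows])
        rf = RandomForestRegressor(
            n_estimators=n_estimators, random_state=int(rng.integers(2**31)), n_jobs=1
        )
        rf.fit(Xfull, y)
        imp = rf.feature_importances_
        max_shadow = imp[k:].max()
        hits += imp[:k] > max_shadow
        imp_sum += imp[:k]
    frac = hits / n_repeats
    selected = [names[j] for j in range(k) if frac[j] >= confirm_fraction]
    none_significant = not selected
    if none_significant:
        selected = [names[int(np.argmax(imp_sum))]]
    return FeatureSelection(
        selected=selected,
        none_significant=none_significant,
        hit_fraction={names[j]: float(frac[j]) for j in range(k)},
    )


def _ensure_provenance(panel: pd.DataFrame) -> pd.DataFrame:
    out = panel.copy()
    for b in BANDS:
        col = f"{b}_src"
        if col not in out.columns:
            src = np.where(out[b].notna(), OBSERVED, -1)
            out[col] = src
    return out


def gapfill_stage1(
    panel: pd.DataFrame,
    aux: pd.DataFrame,
    seed: int,
    n_estimators: int = 100,
    run_feature_selection: bool = False,
) -> pd.DataFrame:
    """Fill reflectance gaps inside the auxiliary product's coverage window.

    Per band, a random forest is trained on months where both the band and
    the auxiliary bands are observed; gaps within coverage are predicted from
    the auxiliaries.  Fills carry provenance flag 1.
    """
    out = _ensure_provenance(panel)
    aux_cols = [c for c in aux.columns if c.startswith("aux_")]
    merged = out.merge(aux, on=["year", "month"], how="left")
    cover = merged[aux_cols].notna().all(axis=1).to_numpy()
    rng = np.random.default_rng(seed)
    for b in BANDS:
        obs = merged[b].notna().to_numpy()
        train = obs & cover
        gaps = (~obs) & cover
        if not gaps.any():
            continue
        if train.sum() < 5:
            warnings.warn(
                f"stage 1 skipped for band {b}: no usable overlap with auxiliaries"
            )
            continue
        cols = aux_cols
        if run_feature_selection and train.sum() >= 50:
            cols = select_features(
                merged.loc[train, aux_cols], merged.loc[train, b],
                seed=int(rng.integers(2**31)),
            ).selected
        rf = RandomForestRegressor(
            n_estimators=n_estimators, random_state=int(rng.integers(2**31)), n_jobs=1
        )
        rf.fit(merged.loc[train, cols], merged.loc[train, b])
        pred = rf.predict(merged.loc[gaps, cols])
        idx = out.index[gaps]
        out.loc[idx, b] = pred
        out.loc[idx, f"{b}_src"] = STAGE1
    return out


def gapfill_stage2(
    panels: dict[str, pd.DataFrame],
    sites: Sequence[SiteRecord],
    seed: int,
    n_estimators: int = 100,
) -> dict[str, pd.DataFrame]:
    """Fill all remaining reflectance gaps over the full record.

    A single global model per band uses climate + rpot + PFT (one-hot) +
    calendar month (cyclic sin/cos) + latitude; trained on every observed
    month across sites.  Fills carry provenance flag 2; afterwards no
    reflectance gap remains.
    """
    site_map = {s.site_id: s for s in sites}
    frames = []
    for sid, panel in panels.items():
        p = _ensure_provenance(panel)
        panels[sid] = p
        s = site_map[sid]
        f = p[["year", "month", "tair", "precip", "rg", "vpd"]].copy()
        if "rpot" in p.columns:
            f["rpot"] = p["rpot"]
        else:
            f["rpot"] = potential_radiation(s.latitude, p["month"].to_numpy())
        f["latitude"] = s.latitude
        f["month_sin"] = np.sin(2 * np.pi * p["month"] / 12.0)
        f["month_cos"] = np.cos(2 * np.pi * p["month"] / 12.0)
        for pft in ("deciduous", "evergreen", "mixed", "savanna"):
            f[f"pft_{pft}"] = float(s.pft == pft)
        f["site_id"] = sid
        f["_row"] = np.arange(len(p))
        for b in BANDS:
            f[b] = p[b].to_numpy()
        frames.append(f)
    table = pd.concat(frames, ignore_index=True)
    feat_cols = [
        "tair", "precip", "rg", "vpd", "rpot", "latitude",
        "month_sin", "month_cos",
        "pft_deciduous", "pft_evergreen", "pft_mixed", "pft_savanna",
    ]
    rng = np.random.default_rng(seed)
    for b in BANDS:
        obs = table[b].notna()
        gaps = ~obs
        if not gaps.any():
            continue
        if obs.sum() == 0:
            raise InsufficientDataError(
                f"stage 2 needs at least one observed month for band {b}"
            )
        rf = RandomForestRegressor(
            n_estimators=n_estimators, random_state=int(rng.integers(2**31)), n_jobs=1
        )
        rf.fit(table.loc[obs, feat_cols], table.loc[obs, b])
        pred = rf.predict(table.loc[gaps, feat_cols])
        filled = table.loc[gaps, ["site_id", "_row"]].copy()
        filled["value"] = pred
        for sid, grp in filled.groupby("site_id"):
            panels[sid].loc[panels[sid].index[grp["_row"].to_numpy()], b] = grp["value"].to_numpy()
            panels[sid].loc[panels[sid].index[grp["_row"].to_numpy()], f"{b}_src"] = STAGE2
    return panels


@dataclass
class DownscaleSelection:
    site_id: str
    variable: str
    candidate_scores: dict[str, float]
    chosen_family: str
    low_skill: bool = False


_FAMILY_ORDER = ["linear", "kernel_ridge", "neighbor_mean"]


def _fit_family(name: str, Xtr: np.ndarray, ytr: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    if name == "linear":
        m = LinearRegression().fit(Xtr, ytr)
        return m.predict
    if name == "kernel_ridge":
        m = KernelRidge(alpha=1.0, kernel="rbf", gamma=1.0 / Xtr.shape[1]).fit(
            (Xtr - Xtr.mean(0)) / (Xtr.std(0) + 1e-12), ytr
        )
        mu, sd = Xtr.mean(0), Xtr.std(0) + 1e-12
        return lambda X: m.predict((X - mu) / sd)
    if name == "neighbor_mean":
        return lambda X: X.mean(axis=1)
    raise ConfigurationError(f"unknown model family {name!r}")


def downscale_climate(
    site_obs: np.ndarray | pd.Series,
    neighbor_series: np.ndarray,
    variable: str,
    site_id: str = "",
    families: Sequence[str] = tuple(_FAMILY_ORDER),
    seed: int = 0,
    min_overlap: int = 24,
    holdout_frac: float = 0.2,
) -> tuple[DownscaleSelection, np.ndarray]:
    """Gap-fill a site climate series from 3 gridded neighbor series.

    Candidate families are fit on the observed overlap and scored on a
    held-out 20% of overlap months; the family with the highest NSE wins
    (lowest RMSE for precipitation).  Family order never affects the choice:
    ties break by fixed family-name order.
    """
    y = np.asarray(site_obs, dtype=float)
    X = np.asarray(neighbor_series, dtype=float)
    if X.shape[0] != len(y):
        raise ConfigurationError("neighbor series must align with the site series")
    obs = np.isfinite(y)
    if obs.sum() < min_overlap:
        warnings.warn(
            f"overlap too short for {site_id}/{variable}; series passed through"
        )
        sel = DownscaleSelection(site_id, variable, {}, "passthrough", low_skill=True)
        return sel, y
    rng = np.random.default_rng(seed)
    idx = np.flatnonzero(obs)
    held = rng.permutation(len(idx))[: max(1, int(round(holdout_frac * len(idx))))]
    test_idx = idx[held]
    train_idx = np.setdiff1d(idx, test_idx)

    use_rmse = variable == "precip"
    scores: dict[str, float] = {}
    preds: dict[str, np.ndarray] = {}
    for name in sorted(families, key=_FAMILY_ORDER.index):
        predict = _fit_family(name, X[train_idx], y[train_idx])
        ptest = predict(X[test_idx])
        if use_rmse:
            scores[name] = float(np.sqrt(np.mean((ptest - y[test_idx]) ** 2)))
        else:
            denom = np.sum((y[test_idx] - y[test_idx].mean()) ** 2)
            scores[name] = float(1.0 - np.sum((ptest - y[test_idx]) ** 2) / denom) if denom > 0 else -np.inf
        preds[name] = predict(X)

    if use_rmse:
        chosen = min(scores, key=lambda k: (scores[k], _FAMILY_ORDER.index(k)))
        low_skill = False
    else:
        chosen = max(scores, key=lambda k: (scores[k], -_FAMILY_ORDER.index(k)))
        # NSE near zero is indistinguishable from predicting the mean
        low_skill = scores[chosen] < 0.1
    filled = y.copy()
    filled[~obs] = preds[chosen][~obs]
    sel = DownscaleSelection(site_id, variable, scores, chosen, low_skill=low_skill)
    return sel, filled


def qc_filter(panel: pd.DataFrame, threshold: float = 0.8) -> pd.DataFrame:
    """Mask NEE at months whose quality fraction is not strictly above threshold.

    Retention follows the "more than 80% good data" rule: a month survives iff
    nee_quality > threshold.  Idempotent.
    """
    if not (0.0 < threshold <= 1.0):
        raise ConfigurationError("qc threshold must lie in (0, 1]")
    if "nee_quality" not in panel.columns:
        raise ConfigurationError("panel lacks an nee_quality column")
    out = panel.copy()
    drop = ~(out["nee_quality"] > threshold)
    out.loc[drop, "nee"] = np.nan
    return out


def preprocess_dataset(
    panels: dict[str, pd.DataFrame],
    sites: Sequence[SiteRecord],
    aux: Optional[dict[str, pd.DataFrame]] = None,
    seed: int = 0,
    qc_threshold: float = 0.8,
    n_estimators: int = 100,
) -> dict[str, pd.DataFrame]:
    """Run stage-1 + stage-2 gap-filling and the QC filter over a dataset."""
    rng = np.random.default_rng(seed)
    out: dict[str, pd.DataFrame] = {}
    for s in sites:
        p = panels[s.site_id]
        if aux is not None and s.site_id in aux:
            p = gapfill_stage1(
                p, aux[s.site_id], seed=int(rng.integers(2**31)), n_estimators=n_estimators
            )
        else:
            p = _ensure_provenance(p)
        out[s.site_id] = p
    needs_stage2 = any(out[s.site_id][list(BANDS)].isna().any().any() for s in sites)
    if needs_stage2:
        out = gapfill_stage2(out, sites, seed=int(rng.integers(2**31)), n_estimators=n_estimators)
    return {sid: qc_filter(p, threshold=qc_threshold) for sid, p in out.items()}
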