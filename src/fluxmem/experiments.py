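"""Entire-site cross-validation and the altered-forcings experiment.

Cross-validation assigns whole sites to folds (default K=10), so a model is
never evaluated on months from a site it has seen during training.  For each
fold, the standardizer, (optional) hyperparameter search and ensemble are fit
on the other K-1 folds and predictions are made for the held-out fold.

The altered-forcings experiment reuses the fold model for which a site was in
the test fold, and measures how much held-out predictions move when the
actual predictor anomalies of the n preceding years are hidden (replaced by
their mean seasonal cycle).  A model that ignores the past is flat in n; a
model exploiting memory rises from n=0 to n=1 and plateaus once n exceeds the
memory horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .seqmodel import (
    Hyperparams,
    PREDICTORS,
    SequenceSample,
    Standardizer,
    TrainedEnsemble,
    fit_ensemble,
    grid_search,
    train_static_baseline,
)
from .setups import SCENARIOS, SetupVariant, TimeIndex, make_altered_forcings
from .synthgen import SiteRecord


@dataclass
class FoldAssignment:
    """site_id -> fold index in {1..K}; balanced to within one site."""

    folds: dict[str, int]
    k: int
    seed: int

    def sites_in(self, fold: int) -> list[str]:
        return [s for s, f in self.folds.items() if f == fold]

    def sites_not_in(self, fold: int) -> list[str]:
        return [s for s, f in self.folds.items() if f != fold]


def assign_folds(
    sites: Sequence[SiteRecord | str],
    k: int = 10,
    seed: int = 0,
    stratify_by_climate: bool = False,
) -> FoldAssignment:
    """Random balanced partition of sites into K folds."""
    ids = [s if isinstance(s, str) else s.site_id for s in sites]
    if k > len(ids):
        raise ValueError(f"cannot split {len(ids)} sites into {k} folds")
    rng = np.random.default_rng(seed)
    folds: dict[str, int] = {}
    if stratify_by_climate and not isinstance(sites[0], str):
        groups: dict[str, list[str]] = {}
        for s in sites:
            groups.setdefault(s.climate_class, []).append(s.site_id)
        counter = 0
        for cls in sorted(groups):
            for sid in rng.permutation(groups[cls]):
                folds[str(sid)] = counter % k + 1
                counter += 1
    else:
        for i, sid in enumerate(rng.permutation(ids)):
            folds[str(sid)] = i % k + 1
    return FoldAssignment(folds=folds, k=k, seed=seed)


@dataclass
class ModelConfig:
    """How each fold's model is fit."""

    hp: Optional[Hyperparams] = None            # fixed hyperparameters ...
    grid: Optional[list[Hyperparams]] = None    # ... or a per-fold grid search
    n_members: int = 50
    rf_estimators: int = 200

    def resolve(self, train: list[SequenceSample], seed: int) -> Hyperparams:
        if self.grid:
            return grid_search(train, self.grid, seed=seed)
        return self.hp if self.hp is not None else Hyperparams()


@dataclass
class CVResult:
    """Concatenated held-out predictions plus the per-fold models."""

    setup: str
    table: pd.DataFrame                 # site_id, year, month, obs, pred, pred_sd, fold
    member_cols: list[str]
    fold_models: dict[int, object]      # TrainedEnsemble or (rf, feature order)
    provenance: dict[int, dict]         # fold -> {train_sites, eval/test sites, hp}
    folds: FoldAssignment


def _predict_rf(model, samples: Sequence[SequenceSample]) -> np.ndarray:
    X = np.concatenate([s.X for s in samples], axis=0)
    return model.predict(X).reshape(len(samples), -1)


def run_cross_validation(
    variant: SetupVariant,
    folds: FoldAssignment,
    index: TimeIndex,
    model_config: ModelConfig,
    seed: int = 0,
) -> CVResult:
    """Fit on K-1 folds, predict the held-out fold; every site is test once."""
    by_id = {s.site_id: s for s in variant.samples}
    rows = []
    fold_models: dict[int, object] = {}
    provenance: dict[int, dict] = {}
    member_cols: list[str] = []
    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.generate_state(folds.k)

    for fold in range(1, folds.k + 1):
        test_ids = folds.sites_in(fold)
        train_ids = folds.sites_not_in(fold)
        train = [by_id[s] for s in train_ids]
        test = [by_id[s] for s in test_ids]
        if not test:
            continue
        n_obs = sum(s.mask.sum() for s in test)
        if n_obs == 0:
            provenance[fold] = {"train_sites": train_ids, "test_sites": test_ids, "skipped": True}
            continue
        fseed = int(fold_seeds[fold - 1])

        if variant.name == "RF":
            Xtr = np.concatenate([s.X[s.mask] for s in train], axis=0)
            ytr = np.concatenate([s.y[s.mask] for s in train])
            rf = train_static_baseline(
                Xtr, ytr, seed=fseed, n_estimators=model_config.rf_estimators
            )
            preds = _predict_rf(rf, test)[None, :, :]  # (1, S, T)
            fold_models[fold] = rf
            hp_used = None
        else:
            hp_used = model_config.resolve(train, seed=fseed)
            ens = fit_ensemble(
                train, hp_used, n_members=model_config.n_members, seed=fseed
            )
            preds = ens.predict(test)  # (M, S, T)
            fold_models[fold] = ens

        m = preds.shape[0]
        member_cols = [f"pred_m{j}" for j in range(m)]
        for si, s in enumerate(test):
            obs_rows = np.flatnonzero(s.mask)
            for r in obs_rows:
                rec = {
                    "site_id": s.site_id,
                    "year": int(index.years[r]),
                    "month": int(index.months[r]),
                    "obs": float(s.y[r]),
                    "pred": float(preds[:, si, r].mean()),
                    "pred_sd": float(preds[:, si, r].std(ddof=0)),
                    "setup": variant.name,
                    "fold": fold,
                }
                for j in range(m):
                    rec[f"pred_m{j}"] = float(preds[j, si, r])
                rows.append(rec)
        provenance[fold] = {
            "train_sites": sorted(train_ids),
            "test_sites": sorted(test_ids),
            "hp": hp_used,
        }

    table = pd.DataFrame(rows)
    return CVResult(
        setup=variant.name, table=table, member_cols=member_cols,
        fold_models=fold_models, provenance=provenance, folds=folds,
    )


def _site_fold_model(cv: CVResult, site_id: str):
    fold = cv.folds.folds[site_id]
    return cv.fold_models.get(fold)


def run_altered_forcings(
    variant: SetupVariant,
    sites: Sequence[SiteRecord],
    cv: CVResult,
    index: TimeIndex,
    n_years_list: Sequence[int] = (1, 2, 3, 4, 5),
    scenarios: Sequence[str] = ("all",),
) -> pd.DataFrame:
    """Absolute deviation of held-out predictions under altered past forcings.

    For each site, target year i, horizon n and scenario, predictors in years
    i-1..i-n are replaced by their MSC and the site's own test-fold ensemble
    re-predicts year i.  Output rows: scenario, n_years, site_id, pft,
    latitude, year, month (hemisphere-aligned), abs_dev (ensemble mean of
    |altered - unaltered|), pred_sd (ensemble sd of the unaltered prediction).
    """
    site_map = {s.site_id: s for s in sites}
    by_id = {s.site_id: s for s in variant.samples}
    rows = []
    years_all = np.unique(index.years)
    for sid, sample in by_id.items():
        model = _site_fold_model(cv, sid)
        if model is None or not isinstance(model, TrainedEnsemble):
            continue
        site = site_map[sid]
        base = model.predict([sample])[:, 0, :]  # (M, T)
        base_sd = base.std(axis=0, ddof=0)
        for scenario in scenarios:
            if scenario not in SCENARIOS:
                raise ValueError(f"unknown scenario {scenario!r}")
            for n in n_years_list:
                for year in years_all:
                    alt = make_altered_forcings(sample, index, int(year), int(n), scenario)
                    if alt is None:
                        continue  # altered span precedes the panel
                    pred = model.predict([alt])[:, 0, :]
                    in_year = index.years == year
                    dev = np.abs(pred - base)[:, in_year].mean(axis=0)  # per month
                    months = index.months[in_year]
                    for mth, d, bsd in zip(months, dev, base_sd[in_year]):
                        am = int((mth - 1 + 6) % 12 + 1) if site.latitude < 0 else int(mth)
                        rows.append(
                            {
                                "scenario": scenario,
                                "n_years": int(n),
                                "site_id": sid,
                                "pft": site.pft,
                                "latitude": site.latitude,
                                "year": int(year),
                                "month": am,
                                "abs_dev": float(d),
                                "pred_sd": float(bsd),
                            }
                        )
    return pd.DataFrame(rows)


def altered_forcings_curves(
    deviations: pd.DataFrame,
    pft_groups: dict[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Aggregate deviations per scenario, horizon, forest group and month."""
    if pft_groups is None:
        pft_groups = {"deciduous": ["deciduous"], "evergreen": ["evergreen"]}
    rows = []
    for group, pfts in pft_groups.items():
        sub = deviations[deviations["pft"].isin(pfts)]
        if not len(sub):
            continue
        agg = sub.groupby(["scenario", "n_years", "month"])["abs_dev"].mean().reset_index()
        agg["group"] = group
        rows.append(agg)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
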