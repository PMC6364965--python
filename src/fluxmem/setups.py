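"""Factorial model set-ups: predictor transformations over a common dataset.

Five variants isolate where the temporal information lives:

* ``LSTM``        - full reflectance + climate sequences (reference);
* ``LSTM_perm``   - timesteps randomly permuted within each site, destroying
                    temporal order while keeping every instantaneous
                    (predictors, target) pair;
* ``LSTM_msc``    - each reflectance band replaced by its mean seasonal cycle
                    (per-calendar-month mean over all years), climate intact;
* ``LSTM_annual`` - each reflectance band replaced by its calendar-year mean,
                    climate intact;
* ``RF``          - same rows as ``LSTM`` handed to a static regressor.

Plus the altered-forcings counterfactual: when predicting year i, predictor
values in years i-1 ... i-n are replaced by their mean seasonal cycle, so the
model cannot draw on the actual anomalies of the n preceding years.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .seqmodel import PREDICTORS, SequenceSample

VARIANTS = ["LSTM", "LSTM_perm", "LSTM_msc", "LSTM_annual", "RF"]
BAND_IDX = list(range(7))      # reflectance columns within PREDICTORS
CLIMATE_IDX = list(range(7, 11))


@dataclass
class SetupVariant:
    name: str
    samples: list[SequenceSample]
    permutation_seed: Optional[int] = None


def compute_msc(series: np.ndarray, months: np.ndarray) -> np.ndarray:
    """Per-calendar-month mean over all years; returns 12 values (Jan..Dec)."""
    series = np.asarray(series, dtype=float)
    months = np.asarray(months)
    if len(series) < 12:
        raise ValueError("mean seasonal cycle needs at least 12 months")
    out = np.empty(12)
    for m in range(1, 13):
        sel = months == m
        if not sel.any():
            raise ValueError(f"calendar month {m} entirely missing")
        out[m - 1] = series[sel].mean()
    return out


def _tile_msc(msc: np.ndarray, months: np.ndarray) -> np.ndarray:
    return msc[np.asarray(months) - 1]


def _months_years(sample: SequenceSample, panel_index) -> tuple[np.ndarray, np.ndarray]:
    years, months = panel_index
    return np.asarray(years), np.asarray(months)


@dataclass
class TimeIndex:
    """Shared (year, month) axis of a fixed panel period."""

    years: np.ndarray
    months: np.ndarray

    @classmethod
    def from_period(cls, start_year: int, end_year: int) -> "TimeIndex":
        n_years = end_year - start_year + 1
        return cls(
            years=np.repeat(np.arange(start_year, end_year + 1), 12),
            months=np.tile(np.arange(1, 13), n_years),
        )


def make_full_variant(samples: Sequence[SequenceSample]) -> SetupVariant:
    return SetupVariant("LSTM", [copy.deepcopy(s) for s in samples])


def make_msc_variant(samples: Sequence[SequenceSample], index: TimeIndex) -> SetupVariant:
    """Replace each band by its MSC tiled over the years; climate untouched."""
    out = []
    for s in samples:
        X = s.X.copy()
        for j in BAND_IDX:
            X[:, j] = _tile_msc(compute_msc(s.X[:, j], index.months), index.months)
        out.append(SequenceSample(s.site_id, X, s.y.copy(), s.mask.copy()))
    return SetupVariant("LSTM_msc", out)


def make_annual_variant(samples: Sequence[SequenceSample], index: TimeIndex) -> SetupVariant:
    """Replace each band by its calendar-year mean; climate untouched."""
    out = []
    for s in samples:
        X = s.X.copy()
        for year in np.unique(index.years):
            rows = index.years == year
            for j in BAND_IDX:
                X[rows, j] = s.X[rows, j].mean()
        out.append(SequenceSample(s.site_id, X, s.y.copy(), s.mask.copy()))
    return SetupVariant("LSTM_annual", out)


def make_permuted_variant(samples: Sequence[SequenceSample], seed: int) -> SetupVariant:
    """Jointly permute (X row, y, mask) within each site.

    One random permutation of timestep indices per site (seeded per site from
    ``seed``), so the multiset of instantaneous triples is exactly preserved
    while realistic temporal sequences are destroyed.
    """
    out = []
    ss = np.random.SeedSequence(seed)
    site_seeds = ss.generate_state(len(samples))
    for s, site_seed in zip(samples, site_seeds):
        rng = np.random.default_rng(site_seed)
        perm = rng.permutation(len(s.y))
        out.append(
            SequenceSample(s.site_id, s.X[perm].copy(), s.y[perm].copy(), s.mask[perm].copy())
        )
    return SetupVariant("LSTM_perm", out, permutation_seed=seed)


def make_rf_variant(samples: Sequence[SequenceSample]) -> SetupVariant:
    """The static baseline consumes the identical rows; tagged for dispatch."""
    return SetupVariant("RF", [copy.deepcopy(s) for s in samples])


def materialize(
    name: str, samples: Sequence[SequenceSample], index: TimeIndex, seed: int = 0
) -> SetupVariant:
    if name == "LSTM":
        return make_full_variant(samples)
    if name == "LSTM_perm":
        return make_permuted_variant(samples, seed)
    if name == "LSTM_msc":
        return make_msc_variant(samples, index)
    if name == "LSTM_annual":
        return make_annual_variant(samples, index)
    if name == "RF":
        return make_rf_variant(samples)
    raise ValueError(f"unknown setup variant {name!r}")


SCENARIOS = ("all", "climate_only", "reflectance_only")


def make_altered_forcings(
    sample: SequenceSample,
    index: TimeIndex,
    target_year: int,
    n_years: int,
    scenario: str = "all",
) -> Optional[SequenceSample]:
    """Counterfactual predictors for predicting ``target_year``.

    Values in years ``target_year-1 .. target_year-n_years`` are replaced by
    their mean seasonal cycle (reflectance bands, climate, or both depending
    on scenario); earlier years and the target year itself keep actual
    values.  Returns None (with a warning upstream) when the altered span
    would start before the panel.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if n_years < 0:
        raise ValueError("n_years must be >= 0")
    if n_years == 0:
        return copy.deepcopy(sample)
    if target_year - n_years < int(index.years.min()):
        return None
    cols: list[int] = []
    if scenario in ("all", "reflectance_only"):
        cols += BAND_IDX
    if scenario in ("all", "climate_only"):
        cols += CLIMATE_IDX
    X = sample.X.copy()
    altered = (index.years >= target_year - n_years) & (index.years < target_year)
    for j in cols:
        msc = compute_msc(sample.X[:, j], index.months)
        X[altered, j] = _tile_msc(msc, index.months[altered])
    return SequenceSample(sample.site_id, X, sample.y.copy(), sample.mask.copy())
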