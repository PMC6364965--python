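"""Shared fixtures.

The expensive fixtures (cross-validated LSTM ensembles on the 40-site memory
benchmark) are session-scoped and shared by the acceptance tests so each
training run happens once.  Problem sizes: 40 sites x 20-year panels, 3-fold
entire-site CV, ensembles of 5, 150 full-batch Adam iterations at the fixed
point of the hyperparameter grid (hidden 10, lr 0.01, dropout 0).
"""

from __future__ import annotations

import numpy as np
import pytest

from fluxmem.evaluation import scale_metrics
from fluxmem.experiments import ModelConfig, assign_folds, run_cross_validation
from fluxmem.seqmodel import Hyperparams, build_samples
from fluxmem.setups import TimeIndex, materialize
from fluxmem.synthgen import GeneratorConfig, generate_dataset

MASTER_SEEDS = (0, 1, 2, 3, 4)
CI_HP = Hyperparams(
    learning_rate=0.01, hidden_units=10, dropout=0.0, patience=500, max_iterations=150
)
K_FOLDS = 3
N_MEMBERS = 5


def memory_config(master_seed: int, **overrides) -> GeneratorConfig:
    """The 40-site / 20-year benchmark with pool decay 0.2 (half-life ~3.1 mo)."""
    kw = dict(
        n_sites=40, period=(1996, 2015), master_seed=master_seed,
        gap_rate_reflectance=0.0,
    )
    kw.update(overrides)
    return GeneratorConfig(**kw)


def run_variant_cv(ds, variant_name: str, seed: int, keep_models: bool = False):
    samples = build_samples(ds.panels, qc_threshold=0.8)
    index = TimeIndex.from_period(*ds.config.period)
    variant = materialize(variant_name, samples, index, seed=seed)
    folds = assign_folds(ds.sites, k=K_FOLDS, seed=seed)
    mc = ModelConfig(hp=CI_HP, n_members=N_MEMBERS, rf_estimators=200)
    cv = run_cross_validation(variant, folds, index, mc, seed=seed)
    metrics = scale_metrics(cv.table, member_cols=cv.member_cols)
    if not keep_models:
        cv.fold_models = {}
    return cv, metrics


@pytest.fixture(scope="session")
def tiny_dataset():
    """8 sites x 10 years: cheap, for structural tests."""
    return generate_dataset(GeneratorConfig(n_sites=8, period=(2000, 2009), master_seed=11))


@pytest.fixture(scope="session")
def memory_study():
    """Per-master-seed CV metrics for LSTM / LSTM_perm / LSTM_msc / RF.

    Returns {seed: {"metrics": {variant: scale_metrics}, "cv": {variant: CVResult}}}
    with fold models retained only for seed 0's reference LSTM (reused by the
    altered-forcings experiment).
    """
    out = {}
    for seed in MASTER_SEEDS:
        ds = generate_dataset(memory_config(seed))
        entry = {"metrics": {}, "cv": {}, "dataset": ds if seed == 0 else None}
        for name in ("LSTM", "LSTM_perm", "LSTM_msc", "RF"):
            keep = seed == 0 and name == "LSTM"
            cv, m = run_variant_cv(ds, name, seed=seed, keep_models=keep)
            entry["metrics"][name] = m
            entry["cv"][name] = cv
        out[seed] = entry
    return out


@pytest.fixture(scope="session")
def tiny_samples():
    """Six short synthetic sequences with partial observation masks."""
    rng = np.random.default_rng(42)
    from fluxmem.seqmodel import SequenceSample

    samples = []
    for i in range(6):
        T = 60
        X = rng.normal(size=(T, 11))
        y = X[:, 3] - 0.5 * X[:, 9] + 0.1 * rng.normal(size=T)
        mask = rng.random(T) < 0.7
        mask[:2] = True
        samples.append(SequenceSample(f"s{i}", X, y, mask))
    return samples
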