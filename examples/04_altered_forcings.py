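"""How far back does the model actually look?  The altered-forcings probe.

For each target year, predictor values in the n preceding years are replaced
by their mean seasonal cycle and the held-out ensemble re-predicts the year.
The deviation from the unaltered prediction measures how much the model uses
those years.  With a pool half-life of ~3 months the curve should rise from
n=0 to n=1 and then plateau.
"""

from fluxmem.experiments import (
    ModelConfig, assign_folds, run_altered_forcings, run_cross_validation,
)
from fluxmem.seqmodel import Hyperparams, build_samples
from fluxmem.setups import TimeIndex, materialize
from fluxmem.synthgen import GeneratorConfig, generate_dataset, memory_half_life

cfg = GeneratorConfig(n_sites=16, period=(1996, 2015), gap_rate_reflectance=0.0,
                      master_seed=2)
ds = generate_dataset(cfg)
samples = build_samples(ds.panels, qc_threshold=0.8)
index = TimeIndex.from_period(*cfg.period)
variant = materialize("LSTM", samples, index, seed=2)
folds = assign_folds(ds.sites, k=3, seed=2)
mc = ModelConfig(hp=Hyperparams(hidden_units=10, learning_rate=0.01,
                                max_iterations=150), n_members=3)
cv = run_cross_validation(variant, folds, index, mc, seed=2)

dev = run_altered_forcings(variant, ds.sites, cv, index,
                           n_years_list=(1, 2, 3, 4, 5), scenarios=("all",))
curve = dev.groupby("n_years")["abs_dev"].mean()
print(f"generator memory half-life: {memory_half_life(cfg.pool_decay):.1f} months")
print("mean |prediction deviation| (gC m-2 d-1) by years of altered forcings:")
for n, v in curve.items():
    print(f"  n={n}: {v:.4f}")
print("\nA rise at n=1 followed by a plateau means the model draws on the "
      "previous year but gains little from earlier years - matching the "
      "generator's short memory horizon.")
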