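"""Two-stage reflectance gap-filling, checked against withheld truth.

Stage 1 fills gaps inside the auxiliary (MODIS-like) coverage window from
co-located auxiliary bands; stage 2 fills everything that remains from
climate + potential radiation + PFT + month + latitude.  Provenance flags
record where each value came from.
"""

import numpy as np

from fluxmem.preprocess import OBSERVED, STAGE1, STAGE2, preprocess_dataset
from fluxmem.synthgen import BANDS, GeneratorConfig, generate_dataset

cfg = GeneratorConfig(
    n_sites=5, period=(1996, 2015), gap_rate_reflectance=0.3,
    tropical_gap_multiplier=1.0, master_seed=3,
)
ds = generate_dataset(cfg)
filled = preprocess_dataset(
    {sid: p.copy() for sid, p in ds.panels.items()}, ds.sites, aux=ds.aux, seed=0
)

for b in ("red", "nir", "tir"):
    src = np.concatenate([p[f"{b}_src"].to_numpy() for p in filled.values()])
    errs = []
    for sid, p in filled.items():
        s1 = p[f"{b}_src"].to_numpy() == STAGE1
        truth = ds.truth[sid][f"{b}_withheld"].to_numpy()
        errs.append(p[b].to_numpy()[s1] - truth[s1])
    rmse = np.sqrt(np.mean(np.concatenate(errs) ** 2))
    print(f"{b:5s}: {np.mean(src == OBSERVED):.0%} observed, "
          f"{np.mean(src == STAGE1):.0%} stage-1, {np.mean(src == STAGE2):.0%} stage-2; "
          f"stage-1 fill RMSE vs withheld truth = {rmse:.4f}")
print("\n(RMSE well below each band's seasonal spread: gaps are recoverable "
      "from the auxiliary product inside its coverage window.)")
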