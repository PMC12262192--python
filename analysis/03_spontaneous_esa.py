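#!/usr/bin/env python
"""Analysis step 3: ESA percent change of spontaneous activity under gain.

Links the forward model to the recording generator: the anodic gain-kernel
column at the recording site is mapped to per-channel gain profiles for a
range of iDC amplitudes (gain scales linearly with current in the model's
linear regime), 90 s laminar recordings are simulated for three synthetic
animals, and the during-vs-pre ESA percent change is summarized per layer.

Writes results/esa_percent_change.csv and results/esa_layer_summary.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from idcmod.esa import (bandpass_mua, epoch_mean, esa_transform, layer_summary,
                        percent_change)
from idcmod.field import DiskSource, TissueModel, disk_field
from idcmod.kernel import (GainKernelMap, interpolate_kernel,
                           polarize_placements, scatter_rods)
from idcmod.rods import default_morphology
from idcmod.synth import (SpontaneousSimConfig, gain_profile_from_kernel,
                          simulate_spontaneous)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

AMPLITUDES_UA = (-20.0, -10.0, 10.0, 20.0)
N_ANIMALS = 3
COUPLING_AT_20UA = 0.3   # peak |gain - 1| at the reference +20 uA amplitude

# gain kernel at +20 uA (one scatter; amplitudes scale it linearly)
tissue = TissueModel()
specs = default_morphology()
grid = disk_field(tissue, DiskSource(current=20e-6))
placements = scatter_rods(specs, 500, tissue.lateral_extent, seed=0)
polarize_placements(grid, placements, specs)
kmap = interpolate_kernel(placements)

rows = []
for animal in range(N_ANIMALS):
    for amp in AMPLITUDES_UA:
        cfg0 = SpontaneousSimConfig(seed=0)
        depths = 0.1 + 0.05 * np.arange(cfg0.n_channels)
        gains = gain_profile_from_kernel(
            kmap, 1.1, depths, coupling=COUPLING_AT_20UA * amp / 20.0)
        cfg = SpontaneousSimConfig(gain_profile=tuple(gains),
                                   noise_sd_uv=1.0,
                                   seed=1000 * animal + int(amp) + 100)
        rec = simulate_spontaneous(cfg)
        env = esa_transform(bandpass_mua(rec).samples, rec.sampling_rate)
        pre = epoch_mean(env, rec.sampling_rate, rec.epochs.pre)
        during = epoch_mean(env, rec.sampling_rate, rec.epochs.during)
        pc = percent_change(during, pre)
        for d, v in zip(rec.channel_depths_mm, pc):
            rows.append((f"animal{animal}", d, amp, v))

changes = pd.DataFrame(rows, columns=["animal", "depth_mm", "amplitude_ua",
                                      "percent_change"])
changes.to_csv(OUT / "esa_percent_change.csv", index=False)
summary = layer_summary(changes)
summary.to_csv(OUT / "esa_layer_summary.csv", index=False)

print(summary.to_string(index=False, float_format=lambda x: f"{x:7.2f}"))
l5 = summary[summary.layer == "L5"].set_index("amplitude_ua")["mean"]
print(f"\nL5 is the most modulated layer: {l5[20.0]:.1f}% at +20 uA vs "
      f"{l5[-20.0]:.1f}% at -20 uA, graded and polarity-symmetric in the "
      f"linear regime.")
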