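#!/usr/bin/env python
"""Analysis step 4: evoked-response heatmaps and MSE gain-shift matrices.

Simulates foot-stimulation evoked recordings over the default intensity
family for odd/even baseline cycles and for +-iDC gain conditions
(anodic gain 1.3, cathodic 0.75), builds trial-averaged 32 x 40 ESA
heatmaps, and computes the three MSE matrices plus their above/below
diagonal summaries.

Writes results/mse_matrix_{baseline,anodic,cathodic}.csv and
results/mse_diagonal_summary.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from idcmod.esa import bandpass_mua
from idcmod.evoked import diagonal_shift_summary, extract_evoked, mse_matrix
from idcmod.synth import DEFAULT_INTENSITIES_MA, EvokedSimConfig, simulate_evoked

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def family(gain, seed0):
    maps = []
    for k, intensity in enumerate(DEFAULT_INTENSITIES_MA):
        cfg = EvokedSimConfig(intensity_ma=intensity, gain=gain, seed=seed0 + k)
        maps.append(extract_evoked(bandpass_mua(simulate_evoked(cfg))))
    return maps


odd = family(1.0, 0)
even = family(1.0, 100)
anodic = family(1.3, 200)
cathodic = family(0.75, 300)

summary = []
for label, queries in (("baseline", even), ("anodic", anodic),
                       ("cathodic", cathodic)):
    m = mse_matrix(odd, queries)
    df = pd.DataFrame(m.values, index=m.row_labels, columns=m.col_labels)
    df.to_csv(OUT / f"mse_matrix_{label}.csv")
    above, below = diagonal_shift_summary(m)
    argmins = m.values.argmin(axis=0)
    shift = float(np.mean(argmins - np.arange(len(argmins))))
    summary.append((label, above, below, shift))
    print(f"{label:9s} per-column argmin rows {argmins} "
          f"(mean shift {shift:+.1f}); above/below diagonal MSE "
          f"{above:.1f} / {below:.1f} uV^2")

pd.DataFrame(summary, columns=["condition", "mse_above_diag_uv2",
                               "mse_below_diag_uv2",
                               "mean_argmin_shift"]).to_csv(
    OUT / "mse_diagonal_summary.csv", index=False)
print("\nBaseline minima sit on the diagonal (reproducible responses); "
      "anodic gain shifts them below it (responses resemble stronger "
      "stimuli), cathodic gain above it.")
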