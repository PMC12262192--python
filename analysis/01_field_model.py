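#!/usr/bin/env python
"""Forward model, step 1: disk-source field and per-type rod polarization.

Computes the extracellular potential of the 0.25 mm iDC catheter disk at
+-20 uA on the 2.2 x 2.2 mm cross-section, then the mirror-estimate soma
polarization of every default rod type at the catheter offsets used in the
lateral-resolution experiment (0.20, 0.55, 0.90, 1.25 mm).

Writes results/field_summary.csv and results/soma_polarization.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from idcmod.field import DiskSource, TissueModel, disk_field
from idcmod.rods import default_morphology, soma_polarization_profile

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

tissue = TissueModel()
specs = default_morphology()
offsets_mm = np.array([0.20, 0.55, 0.90, 1.25])

RECORDING_LATERAL = 1.6  # fixed recording site; the catheter disk is moved

rows, tables = [], []
for current_ua in (20.0, -20.0):
    grid = disk_field(tissue, DiskSource(current=current_ua * 1e-6))
    v = grid.potentials
    rows.append({
        "current_ua": current_ua,
        "v_max_mv": 1e3 * v.max(), "v_min_mv": 1e3 * v.min(),
        "v_surface_center_mv": 1e3 * v[np.argmin(np.abs(grid.lateral_axis - 1.1)), 0],
        "v_at_1mm_depth_mv": 1e3 * v[np.argmin(np.abs(grid.lateral_axis - 1.1)),
                                     np.argmin(np.abs(grid.depth_axis - 1.0))],
    })
    # emulate the lateral-resolution sweep: shift the disk, keep the rods put
    for offset in offsets_mm:
        shifted = disk_field(tissue, DiskSource(
            center_lateral=RECORDING_LATERAL - offset,
            current=current_ua * 1e-6))
        prof = soma_polarization_profile(shifted, specs, [RECORDING_LATERAL])
        prof["offset_mm"] = offset
        prof["current_ua"] = current_ua
        prof["soma_delta_vm_mv"] = 1e3 * prof["soma_delta_vm"]
        tables.append(prof[["current_ua", "type_name", "offset_mm",
                            "soma_delta_vm_mv"]])

pd.DataFrame(rows).to_csv(OUT / "field_summary.csv", index=False)
soma = pd.concat(tables, ignore_index=True)
soma.to_csv(OUT / "soma_polarization.csv", index=False)

near = soma[(soma.current_ua == 20.0) & (soma.offset_mm == 0.20)]
far = soma[(soma.current_ua == 20.0) & (soma.offset_mm == 1.25)]
print("Anodic +20 uA, catheter 0.20 mm from the rods:")
print(near.sort_values("soma_delta_vm_mv", ascending=False)
      .to_string(index=False))
top = near.loc[near.soma_delta_vm_mv.idxmax(), "type_name"]
print(f"\nLargest somatic depolarization: {top} "
      f"(long somatodendritic axis spanning the field gradient).")
ratio = (far.set_index("type_name").soma_delta_vm_mv
         / near.set_index("type_name").soma_delta_vm_mv)
print(f"At 1.25 mm offset the soma polarization has fallen to "
      f"{ratio.abs().median():.0%} (median across types) of its 0.20 mm "
      f"value: millimetre-scale focality.")
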