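"""Neuron-rod abstraction and the mirror estimate of membrane polarization.

Each neuron type is reduced to a vertical rod spanning its dendritic extent,
with a discrete soma depth approximating the electrotonic center (and the
colocalized axon initial segment).  For a rod exposed to an extracellular
potential profile Ve(z), the mirror estimate of the membrane potential change
is

    dVm(z) = mean_z'[Ve(z')] - Ve(z)

the DC analog of the extracellular activation function: compartments where
the local potential is below the rod mean depolarize, and vice versa.

The packaged morphology table (depths in mm from the pia) holds this
artifact's default rod geometries and relative densities for eight excitatory
and two inhibitory types of rat S1; the values approximate the anatomical
literature and are configurable via CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .field import FieldGrid

__all__ = [
    "NeuronRodSpec",
    "RodPolarization",
    "LAYER_BANDS",
    "default_morphology",
    "load_morphology",
    "mirror_estimate",
    "soma_polarization_profile",
]

#: Laminar depth bands in mm from the pia, used for layer labels.
LAYER_BANDS: dict[str, tuple[float, float]] = {
    "L1": (0.0, 0.15),
    "L2/3": (0.15, 0.75),
    "L4": (0.75, 1.10),
    "L5": (1.10, 1.55),
    "L6": (1.55, 2.00),
}


@dataclass(frozen=True)
class NeuronRodSpec:
    type_name: str
    dendrite_top_depth: float
    dendrite_bottom_depth: float
    soma_depth: float
    relative_density: float = 1.0
    cell_class: str = "excitatory"

    def __post_init__(self) -> None:
        if not self.dendrite_top_depth < self.dendrite_bottom_depth:
            raise ValueError(f"{self.type_name}: top depth must be above bottom depth")
        if not (self.dendrite_top_depth <= self.soma_depth <= self.dendrite_bottom_depth):
            raise ValueError(f"{self.type_name}: soma must lie within the rod span")
        if self.relative_density < 0:
            raise ValueError(f"{self.type_name}: relative_density must be >= 0")
        if self.cell_class not in ("excitatory", "inhibitory"):
            raise ValueError(f"{self.type_name}: unknown cell_class {self.cell_class!r}")


@dataclass
class RodPolarization:
    """Mirror-estimate polarization profile along one rod."""

    type_name: str
    depth_samples: np.ndarray  # mm
    delta_vm: np.ndarray       # volts
    soma_delta_vm: float       # volts
    source_current: float      # amperes


def load_morphology(path) -> list[NeuronRodSpec]:
    """Read a morphology table (CSV with the packaged schema) into specs."""
    df = pd.read_csv(path)
    required = {"type_name", "top_mm", "bottom_mm", "soma_mm",
                "relative_density", "cell_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"morphology table missing columns: {sorted(missing)}")
    return [
        NeuronRodSpec(r.type_name, r.top_mm, r.bottom_mm, r.soma_mm,
                      r.relative_density, r.cell_class)
        for r in df.itertuples()
    ]


def default_morphology() -> list[NeuronRodSpec]:
    """The packaged default rod geometry / density table."""
    with resources.files("idcmod.data").joinpath("morphology.csv").open() as f:
        return load_morphology(f)


def _interpolator(fieldgrid: FieldGrid) -> RegularGridInterpolator:
    return RegularGridInterpolator(
        (fieldgrid.lateral_axis, fieldgrid.depth_axis),
        fieldgrid.potentials, method="linear", bounds_error=True,
    )


def _check_inside(fieldgrid: FieldGrid, lateral: float, spec: NeuronRodSpec) -> None:
    lat0, lat1 = fieldgrid.lateral_axis[0], fieldgrid.lateral_axis[-1]
    dep0, dep1 = fieldgrid.depth_axis[0], fieldgrid.depth_axis[-1]
    if not (lat0 <= lateral <= lat1):
        raise ValueError(f"rod lateral position {lateral} mm outside grid "
                         f"[{lat0}, {lat1}] mm")
    for name, z in (("top", spec.dendrite_top_depth),
                    ("bottom", spec.dendrite_bottom_depth)):
        if not (dep0 <= z <= dep1):
            raise ValueError(f"rod {name} depth {z} mm outside grid "
                             f"[{dep0}, {dep1}] mm")


def _rod_depth_samples(spec: NeuronRodSpec, step: float) -> np.ndarray:
    n = max(int(round((spec.dendrite_bottom_depth - spec.dendrite_top_depth) / step)), 1) + 1
    return np.linspace(spec.dendrite_top_depth, spec.dendrite_bottom_depth, n)


def mirror_estimate(fieldgrid: FieldGrid, rod_lateral: float,
                    spec: NeuronRodSpec, step: float | None = None) -> RodPolarization:
    """Mirror-estimate polarization of one rod at a given lateral position.

    The rod is sampled at the field grid spacing (bilinear interpolation of
    Ve) unless ``step`` overrides it.
    """
    _check_inside(fieldgrid, rod_lateral, spec)
    if step is None:
        step = float(np.diff(fieldgrid.depth_axis).min())
    z = _rod_depth_samples(spec, step)
    interp = _interpolator(fieldgrid)
    ve = interp(np.column_stack([np.full_like(z, rod_lateral), z]))
    v_mean = ve.mean()
    delta = v_mean - ve
    ve_soma = float(interp([[rod_lateral, spec.soma_depth]])[0])
    current = fieldgrid.source.current if fieldgrid.source is not None else np.nan
    return RodPolarization(
        type_name=spec.type_name,
        depth_samples=z,
        delta_vm=delta,
        soma_delta_vm=float(v_mean - ve_soma),
        source_current=current,
    )


def soma_polarization_profile(fieldgrid: FieldGrid, specs, lateral_positions) -> pd.DataFrame:
    """Soma mirror-estimate polarization per (type, lateral position).

    Returns a DataFrame with columns type_name, lateral_mm, soma_delta_vm
    (volts); one row per combination, empty if ``specs`` is empty.
    """
    lateral_positions = np.atleast_1d(np.asarray(lateral_positions, dtype=float))
    specs = list(specs)
    rows = []
    if len(specs) == 0:
        return pd.DataFrame(columns=["type_name", "lateral_mm", "soma_delta_vm"])
    interp = _interpolator(fieldgrid)
    step = float(np.diff(fieldgrid.depth_axis).min())
    for spec in specs:
        z = _rod_depth_samples(spec, step)
        for x in lateral_positions:
            _check_inside(fieldgrid, x, spec)
            ve = interp(np.column_stack([np.full_like(z, x), z]))
            ve_soma = float(interp([[x, spec.soma_depth]])[0])
            rows.append((spec.type_name, float(x), float(ve.mean() - ve_soma)))
    return pd.DataFrame(rows, columns=["type_name", "lateral_mm", "soma_delta_vm"])


def soma_polarization_at(fieldgrid: FieldGrid, spec: NeuronRodSpec,
                         laterals: np.ndarray) -> np.ndarray:
    """Vectorized soma mirror estimate of one rod type at many laterals."""
    laterals = np.asarray(laterals, dtype=float)
    interp = _interpolator(fieldgrid)
    step = float(np.diff(fieldgrid.depth_axis).min())
    z = _rod_depth_samples(spec, step)
    pts = np.stack(np.meshgrid(laterals, z, indexing="ij"), axis=-1).reshape(-1, 2)
    ve = interp(pts).reshape(laterals.size, z.size)
    ve_soma = interp(np.column_stack([laterals, np.full_like(laterals, spec.soma_depth)]))
    return ve.mean(axis=1) - ve_soma
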