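"""Population gain kernel: scattered rods, Gaussian-weighted soma polarization.

Rods of each type are scattered laterally across the cross-section in
proportion to their relative densities, their soma mirror-estimate
polarizations are computed on a field, and the excitatory soma values are
summed with spatial Gaussian weighting onto a fine grid:

    S(x, y) = sum_i exp(-((x - x_i)^2 + (y - y_i)^2) / (2 sigma^2)) dVm_i

S approximates how an iDC field scales local population excitability — the
"gain kernel".  It is a polarization score in volt-weighted units, not a
firing rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field import FieldGrid
from .rods import NeuronRodSpec, soma_polarization_at

__all__ = [
    "RodPlacement",
    "GainKernelMap",
    "PackingError",
    "scatter_rods",
    "polarize_placements",
    "interpolate_kernel",
    "kernel_lateral_profile",
]


class PackingError(RuntimeError):
    """Raised when rods cannot be placed subject to the spacing constraint."""


@dataclass
class RodPlacement:
    type_name: str
    lateral_position: float  # mm
    soma_depth: float        # mm
    cell_class: str = "excitatory"
    soma_delta_vm: float = np.nan  # volts, filled by polarize_placements


@dataclass
class GainKernelMap:
    values: np.ndarray       # (n_lateral, n_depth)
    lateral_axis: np.ndarray  # mm
    depth_axis: np.ndarray    # mm
    sigma_spatial: float = 0.1
    seed: int | None = None


def _largest_remainder_counts(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` among categories by largest-remainder rounding."""
    w = np.asarray(weights, dtype=float)
    if total == 0 or w.sum() == 0:
        return np.zeros(w.size, dtype=int)
    quota = total * w / w.sum()
    counts = np.floor(quota).astype(int)
    rem = quota - counts
    short = total - counts.sum()
    # stable tie-break: larger remainder first, then original order
    order = np.lexsort((np.arange(w.size), -rem))
    counts[order[:short]] += 1
    return counts


def scatter_rods(specs, total_count: int, lateral_extent: float,
                 min_spacing: float = 0.005, seed: int | None = None,
                 max_attempts: int = 100_000) -> list[RodPlacement]:
    """Scatter ``total_count`` rods laterally in proportion to type densities.

    Per-type counts follow largest-remainder rounding of the density shares.
    The minimum lateral gap is enforced *within each type* (rods of distinct
    types occupy distinct rows of the cross-section and cannot collide);
    rejection sampling is capped at ``max_attempts`` per type.  Identical
    seeds give identical placements.
    """
    specs = list(specs)
    if total_count < 0:
        raise ValueError("total_count must be >= 0")
    if min_spacing < 0:
        raise ValueError("min_spacing must be >= 0")
    densities = np.array([s.relative_density for s in specs], dtype=float)
    counts = _largest_remainder_counts(densities, total_count)
    for spec, n in zip(specs, counts):
        if n * min_spacing >= lateral_extent:
            raise PackingError(
                f"{n} rods of {spec.type_name} at >= {min_spacing} mm gaps "
                f"cannot fit in {lateral_extent} mm")
    rng = np.random.default_rng(seed)
    placements: list[RodPlacement] = []
    for spec, n in zip(specs, counts):
        xs: list[float] = []
        attempts = 0
        while len(xs) < n:
            x = float(rng.uniform(0.0, lateral_extent))
            if all(abs(x - other) >= min_spacing for other in xs):
                xs.append(x)
            attempts += 1
            if attempts > max_attempts:
                raise PackingError(
                    f"failed to place {n} rods of {spec.type_name} within "
                    f"{max_attempts} attempts")
        placements.extend(
            RodPlacement(spec.type_name, x, spec.soma_depth, spec.cell_class)
            for x in xs
        )
    return placements


def polarize_placements(fieldgrid: FieldGrid, placements, specs) -> list[RodPlacement]:
    """Fill ``soma_delta_vm`` of each placement from the field (in place)."""
    by_name = {s.type_name: s for s in specs}
    groups: dict[str, list[RodPlacement]] = {}
    for p in placements:
        groups.setdefault(p.type_name, []).append(p)
    for name, group in groups.items():
        spec = by_name[name]
        laterals = np.array([p.lateral_position for p in group])
        vals = soma_polarization_at(fieldgrid, spec, laterals)
        for p, v in zip(group, vals):
            p.soma_delta_vm = float(v)
    return list(placements)


def interpolate_kernel(placements, lateral_extent: float = 2.2,
                       depth_extent: float = 2.2, n_grid: int = 200,
                       sigma: float = 0.1, seed: int | None = None,
                       excitatory_only: bool = True) -> GainKernelMap:
    """Gaussian-weighted sum of soma polarizations on an ``n_grid``^2 map.

    Only excitatory somas contribute by default (inhibitory rods are placed
    and polarized for reporting but carry near-zero net weight in the
    population score).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    lat = np.linspace(0.0, lateral_extent, n_grid)
    dep = np.linspace(0.0, depth_extent, n_grid)
    vals = np.zeros((n_grid, n_grid))
    use = [p for p in placements
           if not excitatory_only or p.cell_class == "excitatory"]
    if use:
        xi = np.array([p.lateral_position for p in use])
        yi = np.array([p.soma_depth for p in use])
        wi = np.array([p.soma_delta_vm for p in use])
        # (L, D, N) weights are large; accumulate over placements in chunks
        dx2 = (lat[:, None] - xi[None, :]) ** 2          # (L, N)
        dy2 = (dep[:, None] - yi[None, :]) ** 2          # (D, N)
        ex = np.exp(-dx2 / (2 * sigma**2))
        ey = np.exp(-dy2 / (2 * sigma**2))
        vals = np.einsum("ln,dn,n->ld", ex, ey, wi)
    return GainKernelMap(values=vals, lateral_axis=lat, depth_axis=dep,
                         sigma_spatial=sigma, seed=seed)


def kernel_lateral_profile(kmap: GainKernelMap, depth_band: tuple[float, float],
                           center_lateral: float = 1.1) -> tuple[np.ndarray, np.ndarray]:
    """Band-mean of S per lateral column vs signed distance from the source.

    Returns ``(signed_distance_mm, band_mean)``.
    """
    lo, hi = depth_band
    mask = (kmap.depth_axis >= lo) & (kmap.depth_axis <= hi)
    if not mask.any():
        raise ValueError(f"depth band {depth_band} contains no grid rows")
    profile = kmap.values[:, mask].mean(axis=1)
    return kmap.lateral_axis - center_lateral, profile
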