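"""Extracellular potential of a pia-mounted disk current source.

The tissue is modelled as an isotropic conductive half-space bounded by the
pia.  A point source carrying current ``I`` in such a half-space produces a
hemispherically spreading potential

    V(r) = rho * I / (2 * pi * r)

with ``rho`` the tissue resistivity.  A disk electrode is represented as a
lattice of point sources clipped to the disk, each carrying an equal share of
the total current, and the potential on a 2-D cortical cross-section through
the disk center is obtained by superposition.

Units are fixed throughout: millimetres, amperes, ohm·millimetres, volts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TissueModel",
    "DiskSource",
    "FieldGrid",
    "point_source_potential",
    "disk_field",
]


@dataclass(frozen=True)
class TissueModel:
    """Geometry and resistivity of the modelled cortical cross-section.

    Parameters
    ----------
    resistivity : float
        Tissue resistivity in ohm·mm.  The default, 5e3 ohm·mm, is the
        in vivo value used throughout.
    lateral_extent, depth_extent : float
        Size of the cross-section in mm (pia at depth 0, depth positive
        downward).
    grid_spacing : float
        Node spacing of the evaluation grid in mm.
    """

    resistivity: float = 5e3
    lateral_extent: float = 2.2
    depth_extent: float = 2.2
    grid_spacing: float = 0.01

    def __post_init__(self) -> None:
        if self.resistivity <= 0:
            raise ValueError("resistivity must be positive")
        if self.lateral_extent <= 0 or self.depth_extent <= 0:
            raise ValueError("extents must be positive")
        if not (0 < self.grid_spacing <= min(self.lateral_extent, self.depth_extent)):
            raise ValueError("grid_spacing must be positive and <= both extents")

    @property
    def lateral_axis(self) -> np.ndarray:
        n = int(round(self.lateral_extent / self.grid_spacing)) + 1
        return np.linspace(0.0, self.lateral_extent, n)

    @property
    def depth_axis(self) -> np.ndarray:
        n = int(round(self.depth_extent / self.grid_spacing)) + 1
        return np.linspace(0.0, self.depth_extent, n)


@dataclass(frozen=True)
class DiskSource:
    """Disk electrode on the pial surface (depth 0).

    ``current`` is signed: positive is anodic, negative cathodic.
    The default diameter (0.25 mm) matches the iDC microcatheter tip.
    """

    center_lateral: float = 1.1
    diameter: float = 0.25
    current: float = 20e-6
    lattice_pitch: float = 0.0125  # pitch of the point-source lattice, mm

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.lattice_pitch <= 0:
            raise ValueError("lattice_pitch must be positive")
        if not np.isfinite(self.current):
            raise ValueError("current must be finite")

    def lattice_points(self) -> np.ndarray:
        """(M, 2) array of point-source positions (lateral, transverse) on
        the pia plane, clipped to the disk; each carries current / M."""
        r = self.diameter / 2.0
        # integer-indexed lattice keeps the point set exactly mirror-symmetric
        n = int(np.floor(r / self.lattice_pitch))
        offs = np.arange(-n, n + 1) * self.lattice_pitch
        gx, gy = np.meshgrid(offs, offs, indexing="ij")
        inside = gx**2 + gy**2 <= r**2
        pts = np.column_stack([gx[inside] + self.center_lateral, gy[inside]])
        return pts


@dataclass
class FieldGrid:
    """Extracellular potential sampled on a (lateral, depth) grid."""

    potentials: np.ndarray  # volts, shape (n_lateral, n_depth)
    lateral_axis: np.ndarray  # mm
    depth_axis: np.ndarray  # mm
    source: DiskSource | None = None
    tissue: TissueModel | None = None

    def __post_init__(self) -> None:
        if self.potentials.shape != (self.lateral_axis.size, self.depth_axis.size):
            raise ValueError("potentials shape must match axis lengths")


def point_source_potential(resistivity: float, current: float, distance):
    """Potential (V) of a point source in a conductive half-space.

    ``distance`` may be a scalar or array of distances in mm (> 0).
    """
    if resistivity <= 0:
        raise ValueError("resistivity must be positive")
    distance = np.asarray(distance, dtype=float)
    if np.any(distance <= 0):
        raise ValueError("distance must be positive (singularity handled upstream)")
    out = resistivity * current / (2.0 * np.pi * distance)
    return out if out.ndim else float(out)


def disk_field(tissue: TissueModel, source: DiskSource) -> FieldGrid:
    """Superpose point-source contributions of the disk onto the grid.

    The cross-section is the vertical plane through the disk center; the
    lattice points off that plane contribute through their full 3-D distance.
    Distances are clamped below at half the grid spacing so pial nodes under
    the disk stay finite.
    """
    if source.diameter >= tissue.lateral_extent:
        raise ValueError("disk diameter must be smaller than the lateral extent")
    lat = tissue.lateral_axis
    dep = tissue.depth_axis
    pts = source.lattice_points()  # (M, 2): lateral, transverse
    m = pts.shape[0]
    i_each = source.current / m

    # distance from node (x, 0, z) to source (sx, sy, 0)
    dx = lat[:, None] - pts[None, :, 0]          # (L, M)
    d2_lat = dx**2 + pts[None, :, 1] ** 2        # (L, M)
    z2 = dep**2                                  # (D,)
    dmin = tissue.grid_spacing / 2.0

    v = np.zeros((lat.size, dep.size))
    if source.current != 0.0:
        coef = tissue.resistivity * i_each / (2.0 * np.pi)
        for j in range(m):  # loop sources to bound memory at (L, D) per step
            r = np.sqrt(d2_lat[:, j, None] + z2[None, :])
            np.maximum(r, dmin, out=r)
            v += coef / r
    return FieldGrid(potentials=v, lateral_axis=lat, depth_axis=dep,
                     source=source, tissue=tissue)
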