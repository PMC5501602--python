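"""Canonical axisymmetric bioreactor + scaffold geometry.

The perfusion chamber is modeled as a coaxial stack (bottom to top):
inlet tube -> bottom plenum -> porous scaffold disc -> top plenum ->
outlet tube.  The scaffold is a salt-leached silk-fibroin disc, 8 mm in
diameter and 3 mm in height, press-fit into the chamber (scaffold radius
equal to the chamber radius by default, so the highest shear stresses
develop against the chamber wall).  All lengths are in meters.

The chamber and tube dimensions are canonical reconstructions: the tube
radius follows from requiring the pump flow rate Q and the mean inlet
velocity v to be consistent through v = Q / (pi r^2) for both the low
(0.2 ml/min, 1e-3 m/s) and high (12 ml/min, 6.1e-2 m/s) operating points,
which both give a tube diameter of about 2.05 mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = [
    "GeometryError",
    "DomainLabel",
    "BioreactorGeometry",
    "FlowBoundaryCondition",
    "DomainGrid",
    "build_geometry",
    "inlet_velocity_from_flow_rate",
    "rasterize",
    "straight_tube_grid",
    "porous_column_grid",
]

ML_PER_MIN = 1e-6 / 60.0  # m^3/s per ml/min


class GeometryError(ValueError):
    """Invalid geometry parameters or rasterization request."""


class DomainLabel(IntEnum):
    """Per-cell domain classification of the axisymmetric grid."""

    SOLID = 0  # outside the fluid (chamber wall, beyond tube radius, ...)
    FREE = 1  # free media flow (tubes and plenums)
    POROUS = 2  # Brinkman porous flow (scaffold disc)


@dataclass(frozen=True)
class BioreactorGeometry:
    """Parametric axisymmetric description of the perfusion chamber.

    Defaults are the canonical reconstruction; every length is
    overridable (e.g. from a TOML config).
    """

    scaffold_radius: float = 4.0e-3
    scaffold_height: float = 3.0e-3
    chamber_radius: float = 4.0e-3
    tube_radius: float = 1.025e-3
    tube_length: float = 10.0e-3
    plenum_height_bottom: float = 5.0e-3
    plenum_height_top: float = 5.0e-3

    def __post_init__(self) -> None:
        for name in (
            "scaffold_radius",
            "scaffold_height",
            "chamber_radius",
            "tube_radius",
            "tube_length",
            "plenum_height_bottom",
            "plenum_height_top",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise GeometryError(f"{name} must be a positive finite length, got {v!r}")
        if self.scaffold_radius > self.chamber_radius:
            raise GeometryError(
                f"scaffold_radius ({self.scaffold_radius}) exceeds "
                f"chamber_radius ({self.chamber_radius})"
            )
        if self.tube_radius >= self.chamber_radius:
            raise GeometryError("tube_radius must be smaller than chamber_radius")

    # -- axial landmarks (z = 0 at the inlet-tube mouth, flow in +z) --------
    @property
    def z_scaffold_bottom(self) -> float:
        return self.tube_length + self.plenum_height_bottom

    @property
    def z_scaffold_top(self) -> float:
        return self.z_scaffold_bottom + self.scaffold_height

    @property
    def total_height(self) -> float:
        return self.z_scaffold_top + self.plenum_height_top + self.tube_length

    def scaffold_volume(self) -> float:
        """Analytic scaffold cylinder volume (m^3)."""
        return float(np.pi * self.scaffold_radius**2 * self.scaffold_height)

    def wall_radius_at(self, z: float) -> float:
        """Radius of the fluid envelope at axial position z."""
        if z < self.tube_length or z > self.total_height - self.tube_length:
            return self.tube_radius
        return self.chamber_radius


def build_geometry(**params: float) -> BioreactorGeometry:
    """Construct a :class:`BioreactorGeometry`, filling canonical defaults."""
    return BioreactorGeometry(**params)


def inlet_velocity_from_flow_rate(flow_rate: float, tube_radius: float) -> float:
    """Mean inlet velocity (m/s) for a pump flow rate Q (m^3/s): v = Q/(pi r^2)."""
    if flow_rate < 0:
        raise ValueError(f"flow rate must be non-negative, got {flow_rate!r}")
    if tube_radius <= 0:
        raise ValueError(f"tube_radius must be positive, got {tube_radius!r}")
    return float(flow_rate / (np.pi * tube_radius**2))


@dataclass(frozen=True)
class FlowBoundaryCondition:
    """Inlet/outlet/wall specification of the flow problem.

    ``inlet_velocity`` is the mean (superficial) velocity in the inlet
    tube; the outlet is held at zero reference pressure and every other
    boundary is a no-slip wall.  ``profile`` selects the inlet shape:
    ``"parabolic"`` (fully developed laminar tube flow, the default) or
    ``"plug"``.  Either profile is discretely renormalized so the revolved
    inlet flux equals exactly ``inlet_velocity * pi * inlet_radius**2``.
    """

    inlet_velocity: float
    profile: str = "parabolic"

    def __post_init__(self) -> None:
        if self.inlet_velocity < 0:
            raise ValueError("inlet_velocity must be non-negative")
        if self.profile not in ("parabolic", "plug"):
            raise ValueError(f"unknown inlet profile {self.profile!r}")

    @classmethod
    def from_flow_rate(cls, flow_rate: float, tube_radius: float, profile: str = "parabolic"
                       ) -> "FlowBoundaryCondition":
        return cls(inlet_velocity_from_flow_rate(flow_rate, tube_radius), profile=profile)


@dataclass(frozen=True)
class DomainGrid:
    """Uniform staggered-grid discretization of the (r, z) half-plane.

    ``labels`` has shape (nr, nz) indexed [i_radial, j_axial]; cell centers
    sit at r = (i+0.5)*dr, z = (j+0.5)*dz.  A cell center exactly on a
    free/porous interface is porous; a center exactly on the fluid/solid
    envelope is solid.
    """

    dr: float
    dz: float
    labels: np.ndarray  # (nr, nz) of DomainLabel values
    inlet_radius: float
    geometry: BioreactorGeometry | None = None

    def __post_init__(self) -> None:
        if self.dr <= 0 or self.dz <= 0:
            raise GeometryError("grid spacings must be positive")
        if self.labels.ndim != 2:
            raise GeometryError("labels must be a 2-D (nr, nz) array")

    @property
    def nr(self) -> int:
        return self.labels.shape[0]

    @property
    def nz(self) -> int:
        return self.labels.shape[1]

    @property
    def r_centers(self) -> np.ndarray:
        return (np.arange(self.nr) + 0.5) * self.dr

    @property
    def r_faces(self) -> np.ndarray:
        return np.arange(self.nr + 1) * self.dr

    @property
    def z_centers(self) -> np.ndarray:
        return (np.arange(self.nz) + 0.5) * self.dz

    def cell_volumes(self) -> np.ndarray:
        """Revolved cell volumes 2*pi*r*dr*dz, shape (nr, nz)."""
        return (2.0 * np.pi * self.r_centers * self.dr * self.dz)[:, None] * np.ones(
            (1, self.nz)
        )

    def region_volume(self, label: DomainLabel) -> float:
        return float(self.cell_volumes()[self.labels == label].sum())

    @property
    def fluid(self) -> np.ndarray:
        return self.labels != DomainLabel.SOLID


def rasterize(geom: BioreactorGeometry, spacing: float) -> DomainGrid:
    """Label a uniform (r, z) grid with the free / porous / solid partition.

    Cell classification is by the cell-center point-in-region test, with
    half-open conventions: a center on the porous interface is porous, a
    center on the solid envelope is solid.
    """
    if spacing <= 0:
        raise GeometryError("spacing must be positive")
    features = (
        geom.tube_radius,
        geom.scaffold_radius,
        geom.chamber_radius,
        geom.scaffold_height,
        geom.tube_length,
        geom.plenum_height_bottom,
        geom.plenum_height_top,
    )
    if spacing >= min(features):
        raise GeometryError(
            f"spacing {spacing} must be smaller than every geometric feature "
            f"(smallest: {min(features)})"
        )
    nr = int(np.ceil(geom.chamber_radius / spacing - 1e-12))
    nz = int(np.ceil(geom.total_height / spacing - 1e-12))
    rc = (np.arange(nr) + 0.5) * spacing
    zc = (np.arange(nz) + 0.5) * spacing
    R, Z = np.meshgrid(rc, zc, indexing="ij")

    in_tube_z = (Z < geom.tube_length) | (Z > geom.total_height - geom.tube_length)
    wall_r = np.where(in_tube_z, geom.tube_radius, geom.chamber_radius)
    fluid = (R < wall_r) & (Z < geom.total_height)

    porous = (
        fluid
        & (Z >= geom.z_scaffold_bottom)
        & (Z <= geom.z_scaffold_top)
        & (R <= geom.scaffold_radius)
    )
    labels = np.where(porous, DomainLabel.POROUS, np.where(fluid, DomainLabel.FREE, DomainLabel.SOLID))
    return DomainGrid(spacing, spacing, labels.astype(np.int8), geom.tube_radius, geom)


def straight_tube_grid(radius: float, length: float, spacing: float) -> DomainGrid:
    """All-free straight tube, for analytic (Poiseuille) validation."""
    if spacing <= 0 or spacing >= radius:
        raise GeometryError("spacing must be positive and smaller than the tube radius")
    nr = int(np.ceil(radius / spacing - 1e-12))
    nz = int(np.ceil(length / spacing - 1e-12))
    labels = np.full((nr, nz), DomainLabel.FREE, dtype=np.int8)
    rc = (np.arange(nr) + 0.5) * spacing
    labels[rc >= radius, :] = DomainLabel.SOLID
    return DomainGrid(spacing, spacing, labels, radius, None)


def porous_column_grid(radius: float, length: float, spacing: float) -> DomainGrid:
    """All-porous column, for analytic (Darcy) validation."""
    grid = straight_tube_grid(radius, length, spacing)
    labels = grid.labels.copy()
    labels[labels == DomainLabel.FREE] = DomainLabel.POROUS
    return DomainGrid(spacing, spacing, labels, radius, None)
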