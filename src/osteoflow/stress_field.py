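"""Scalar shear-stress fields and their revolution onto 3-D voxel lattices.

The stimulus acting on cells is summarized as the viscous stress magnitude
tau = mu * gamma_dot with shear rate gamma_dot = sqrt(2 D:D), D being the
symmetric strain-rate tensor of the volume-averaged velocity field.  In
axisymmetric (r, z) coordinates

    D_rr = du_r/dr,  D_tt = u_r/r,  D_zz = du_z/dz,
    D_rz = (du_r/dz + du_z/dr) / 2,

so gamma_dot = sqrt(2 (D_rr^2 + D_tt^2 + D_zz^2 + 2 D_rz^2)).  tau is
evaluated at cell centers; the off-diagonal derivative lives naturally at
grid corners on the staggered mesh and is averaged back to centers.

Because the field is axisymmetric it can be revolved about the bioreactor
axis and sampled at every voxel center of a micro-CT lattice, which is how
simulated stresses are paired with measured mineralization voxel-by-voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .flow_solver import FlowSolution
from .geometry import DomainGrid, DomainLabel

__all__ = [
    "ShearStressField",
    "VoxelFieldSample",
    "shear_stress",
    "max_in_region",
    "revolve_to_voxels",
    "sample_scaffold_volume",
]


@dataclass
class ShearStressField:
    """Cell-centered shear stress tau (Pa) on the simulation grid."""

    tau: np.ndarray  # (nr, nz), Pa; 0 in solid cells
    grid: DomainGrid
    inlet_velocity: float
    viscosity: float


@dataclass
class VoxelFieldSample:
    """tau revolved onto a 3-D voxel lattice aligned with micro-CT volumes.

    ``valid`` flags voxels whose centers fall inside the fluid domain;
    invalid voxels hold NaN rather than a silent zero.
    """

    tau: np.ndarray  # (nx, ny, nz) Pa, NaN where invalid
    voxel_size: float  # m, isotropic
    origin: np.ndarray  # (3,) position of the (0,0,0) voxel corner, m
    valid: np.ndarray  # (nx, ny, nz) bool


def shear_stress(solution: FlowSolution, viscosity: float | None = None) -> ShearStressField:
    """Compute tau = mu * sqrt(2 D:D) at cell centers of a converged solution."""
    if not solution.converged:
        raise ValueError("shear stress requires a converged flow solution")
    mu = solution.fluid_props.viscosity if viscosity is None else viscosity
    g = solution.grid
    dr, dz = g.dr, g.dz
    ur, uz = solution.u_r, solution.u_z  # (nr+1, nz), (nr, nz+1)
    rc = g.r_centers

    d_rr = (ur[1:, :] - ur[:-1, :]) / dr
    d_zz = (uz[:, 1:] - uz[:, :-1]) / dz
    d_tt = 0.5 * (ur[1:, :] + ur[:-1, :]) / rc[:, None]

    # corner values of du_r/dz and du_z/dr, shape (nr+1, nz+1)
    ur_pad = np.pad(ur, ((0, 0), (1, 1)), mode="edge")
    dur_dz = (ur_pad[:, 1:] - ur_pad[:, :-1]) / dz  # (nr+1, nz+1)
    uz_pad = np.pad(uz, ((1, 1), (0, 0)), mode="edge")
    duz_dr = (uz_pad[1:, :] - uz_pad[:-1, :]) / dr  # (nr+1, nz+1)
    d_rz_corner = 0.5 * (dur_dz + duz_dr)
    d_rz = 0.25 * (
        d_rz_corner[:-1, :-1] + d_rz_corner[1:, :-1]
        + d_rz_corner[:-1, 1:] + d_rz_corner[1:, 1:]
    )

    gamma = np.sqrt(2.0 * (d_rr**2 + d_tt**2 + d_zz**2 + 2.0 * d_rz**2))
    tau = mu * gamma
    tau[~g.fluid] = 0.0
    return ShearStressField(tau, g, solution.bc.inlet_velocity, mu)


def max_in_region(
    field: ShearStressField,
    label: DomainLabel | None = None,
    cross_section: str | None = None,
) -> float:
    """Maximum tau over a labeled region, optionally restricted to the
    mid-height horizontal plane (``"horizontal_mid"``) or the vertical
    mid cross-section (``"vertical_mid"``, which for an axisymmetric field
    is the full (r, z) plane)."""
    g = field.grid
    mask = g.fluid if label is None else g.labels == int(label)
    if cross_section == "horizontal_mid":
        rows = np.nonzero(mask.any(axis=0))[0]
        if len(rows) == 0:
            raise ValueError("region is empty")
        j_mid = int(rows[len(rows) // 2])
        plane = np.zeros_like(mask)
        plane[:, j_mid] = True
        mask = mask & plane
    elif cross_section not in (None, "vertical_mid"):
        raise ValueError(f"unknown cross-section selector {cross_section!r}")
    if not mask.any():
        raise ValueError("region is empty")
    return float(field.tau[mask].max())


def revolve_to_voxels(
    field: ShearStressField,
    voxel_size: float,
    shape: tuple[int, int, int],
    origin: np.ndarray | tuple[float, float, float],
) -> VoxelFieldSample:
    """Sample the axisymmetric tau field at every voxel center of a lattice.

    The lattice x/y axes are perpendicular to, and its z axis parallel to,
    the bioreactor axis, which passes through (x, y) = (0, 0) of the
    lattice frame; ``origin`` places the corner of voxel (0, 0, 0) in that
    frame, with z measured in simulation coordinates (z = 0 at the inlet
    mouth).  tau is interpolated bilinearly in (r, z) between cell centers
    (clamped to the nearest cell within half a cell of the grid edge);
    voxels whose centers fall outside the fluid domain are flagged invalid.
    """
    g = field.grid
    origin = np.asarray(origin, dtype=float)
    nx, ny, nz = shape
    x = origin[0] + (np.arange(nx) + 0.5) * voxel_size
    y = origin[1] + (np.arange(ny) + 0.5) * voxel_size
    z = origin[2] + (np.arange(nz) + 0.5) * voxel_size
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    R = np.hypot(X, Y)

    # fractional cell-center indices
    ci = R / g.dr - 0.5
    cj = Z / g.dz - 0.5
    coords = np.stack([ci.ravel(), cj.ravel()])
    tau = ndimage.map_coordinates(field.tau, coords, order=1, mode="nearest").reshape(shape)

    inside = (
        (R <= g.nr * g.dr) & (Z >= 0.0) & (Z <= g.nz * g.dz)
    )
    ni = np.clip(np.rint(ci).astype(int), 0, g.nr - 1)
    nj = np.clip(np.rint(cj).astype(int), 0, g.nz - 1)
    valid = inside & (g.labels[ni, nj] != DomainLabel.SOLID)
    if not valid.any():
        raise ValueError("voxel lattice lies entirely outside the fluid domain")
    tau = np.where(valid, tau, np.nan)
    return VoxelFieldSample(tau, float(voxel_size), origin, valid)


def sample_scaffold_volume(field: ShearStressField, voxel_size: float) -> VoxelFieldSample:
    """Convenience: revolve tau onto a lattice that just covers the scaffold disc."""
    geom = field.grid.geometry
    if geom is None:
        raise ValueError("grid carries no bioreactor geometry")
    n_xy = int(np.ceil(2 * geom.scaffold_radius / voxel_size))
    n_z = int(np.ceil(geom.scaffold_height / voxel_size))
    origin = np.array([
        -0.5 * n_xy * voxel_size,
        -0.5 * n_xy * voxel_size,
        geom.z_scaffold_bottom,
    ])
    return revolve_to_voxels(field, voxel_size, (n_xy, n_xy, n_z), origin)
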