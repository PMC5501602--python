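"""Steady incompressible flow through the coupled free/porous domains.

The bioreactor (free media flow) and the scaffold (porous media flow) are
handled with a single-field Brinkman-penalization formulation: one
momentum equation everywhere, with the Darcy drag term -(mu/k)*u switched
on in porous cells,

    0 = -grad p + mu * Lap(u) - chi * (mu/k) * u - rho (u . grad) u,
    div u = 0,

discretized with staggered (MAC) axisymmetric finite volumes on a uniform
(r, z) grid.  Momentum and continuity are assembled into one sparse
saddle-point system and solved directly (sparse LU); the stiff drag
coefficient (mu/k ~ 4e7 s^-1 Pa s/m^2) is therefore fully implicit and
discrete mass conservation holds to solver precision in every fluid cell.
Convective inertia is relinearized by Picard iteration with first-order
upwinding; with ``include_inertia=False`` the operator is linear
(Stokes-Brinkman) and the solution scales exactly with the inlet velocity.

Boundary conditions: developed (or plug) inlet profile at the bottom tube
mouth, zero reference pressure at the top outlet face, no-slip on every
wall (normal velocities vanish on fluid/solid faces; tangential no-slip is
imposed through mirror ghosts, second-order at walls that fall on faces).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import (
    BioreactorGeometry,
    DomainGrid,
    DomainLabel,
    FlowBoundaryCondition,
    rasterize,
)

__all__ = [
    "FluidProps",
    "PorousProps",
    "FlowSolution",
    "RefinementReport",
    "FlowNonConvergenceError",
    "RefinementError",
    "MassBalance",
    "solve_flow",
    "refine_until_converged",
    "mass_balance",
]


@dataclass(frozen=True)
class FluidProps:
    """Newtonian fluid properties; defaults are water at 37 degC."""

    density: float = 993.0  # kg/m^3
    viscosity: float = 6.91e-4  # Pa s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


@dataclass(frozen=True)
class PorousProps:
    """Scaffold porous-medium properties (salt-leached silk fibroin)."""

    porosity: float = 0.55
    permeability: float = 1.76e-11  # m^2

    def __post_init__(self) -> None:
        if not 0.0 < self.porosity < 1.0:
            raise ValueError("porosity must be in (0, 1)")
        if self.permeability <= 0:
            raise ValueError("permeability must be positive")


class FlowNonConvergenceError(RuntimeError):
    """Picard iteration diverged or failed to meet tolerance."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class RefinementError(RuntimeError):
    """Mesh-refinement sweep did not meet the convergence criterion."""

    def __init__(self, message: str, report: "RefinementReport"):
        super().__init__(message)
        self.report = report


@dataclass
class FlowSolution:
    """Staggered velocity/pressure fields with domain masks and diagnostics.

    ``u_r`` has shape (nr+1, nz) on radial faces, ``u_z`` shape (nr, nz+1)
    on axial faces, ``p`` shape (nr, nz) at cell centers (NaN in solid
    cells, referenced to zero at the outlet).
    """

    grid: DomainGrid
    u_r: np.ndarray
    u_z: np.ndarray
    p: np.ndarray
    fluid_props: FluidProps
    porous_props: PorousProps
    bc: FlowBoundaryCondition
    diagnostics: dict = field(default_factory=dict)
    converged: bool = True

    def center_velocity(self) -> tuple[np.ndarray, np.ndarray]:
        """Velocity components interpolated to cell centers, (nr, nz)."""
        ur_c = 0.5 * (self.u_r[:-1, :] + self.u_r[1:, :])
        uz_c = 0.5 * (self.u_z[:, :-1] + self.u_z[:, 1:])
        return ur_c, uz_c

    def speed(self) -> np.ndarray:
        ur_c, uz_c = self.center_velocity()
        s = np.hypot(ur_c, uz_c)
        s[~self.grid.fluid] = 0.0
        return s

    def max_speed(self, label: DomainLabel | None = None) -> float:
        s = self.speed()
        mask = self.grid.fluid if label is None else self.grid.labels == label
        if not mask.any():
            raise ValueError("region is empty")
        return float(s[mask].max())

    def mean_speed(self, label: DomainLabel | None = None) -> float:
        """Volume-weighted mean velocity magnitude over a domain."""
        s = self.speed()
        mask = self.grid.fluid if label is None else self.grid.labels == label
        if not mask.any():
            raise ValueError("region is empty")
        w = self.grid.cell_volumes()[mask]
        return float((s[mask] * w).sum() / w.sum())

    def divergence(self) -> np.ndarray:
        """Discrete divergence in every fluid cell (1/s); ~0 when converged."""
        g = self.grid
        rf, rc = g.r_faces, g.r_centers
        div = (
            (rf[1:, None] * self.u_r[1:, :] - rf[:-1, None] * self.u_r[:-1, :])
            / (rc[:, None] * g.dr)
            + (self.u_z[:, 1:] - self.u_z[:, :-1]) / g.dz
        )
        div[~g.fluid] = 0.0
        return div

    def inlet_flux(self) -> float:
        g = self.grid
        return float((2 * np.pi * g.r_centers * g.dr * self.u_z[:, 0]).sum())

    def outlet_flux(self) -> float:
        g = self.grid
        return float((2 * np.pi * g.r_centers * g.dr * self.u_z[:, -1]).sum())


@dataclass
class RefinementReport:
    """Record of a mesh-refinement convergence sweep."""

    spacings: list[float]
    mean_free: list[float]
    mean_porous: list[float]
    rel_change_free: list[float]
    rel_change_porous: list[float]
    criterion: float
    converged: bool


@dataclass(frozen=True)
class MassBalance:
    imbalance: float  # |flux_in - flux_out| / flux_in
    inlet_flux: float  # m^3/s
    outlet_flux: float  # m^3/s


# ----------------------------------------------------------------------
# assembly
# ----------------------------------------------------------------------


class _Discretization:
    """Index maps and constant (Stokes) operator for a labeled grid."""

    def __init__(self, grid: DomainGrid, fluid: FluidProps, porous: PorousProps,
                 bc: FlowBoundaryCondition):
        self.grid = grid
        self.mu = fluid.viscosity
        self.rho = fluid.density
        self.k = porous.permeability
        nr, nz = grid.nr, grid.nz
        self.nr, self.nz = nr, nz
        self.dr, self.dz = grid.dr, grid.dz
        F = grid.fluid
        self.F = F
        self.chi = (grid.labels == DomainLabel.POROUS).astype(float)

        FP = np.zeros((nr + 2, nz + 2), dtype=bool)
        FP[1:-1, 1:-1] = F

        # unknown maps (-1 = not an unknown)
        self.ur_unk = FP[:-1, 1:-1] & FP[1:, 1:-1]  # (nr+1, nz)
        self.uz_unk = FP[1:-1, :-1] & FP[1:-1, 1:]  # (nr, nz+1)
        self.uz_unk[:, nz] = F[:, nz - 1]  # outlet faces are unknowns
        self.inlet = F[:, 0]  # Dirichlet inlet faces at j = 0

        self.iur = -np.ones((nr + 1, nz), dtype=np.int64)
        self.iur[self.ur_unk] = np.arange(int(self.ur_unk.sum()))
        self.n_ur = int(self.ur_unk.sum())
        self.iuz = -np.ones((nr, nz + 1), dtype=np.int64)
        self.iuz[self.uz_unk] = self.n_ur + np.arange(int(self.uz_unk.sum()))
        self.n_uz = int(self.uz_unk.sum())
        self.ip = -np.ones((nr, nz), dtype=np.int64)
        self.ip[F] = self.n_ur + self.n_uz + np.arange(int(F.sum()))
        self.n_p = int(F.sum())
        self.n = self.n_ur + self.n_uz + self.n_p

        self.v_prof = self._inlet_profile(bc)
        self._stokes = None  # cached (rows, cols, vals, rhs)

    # -- inlet profile, renormalized to the exact nominal flux -----------
    def _inlet_profile(self, bc: FlowBoundaryCondition) -> np.ndarray:
        g = self.grid
        rc = g.r_centers
        v = np.zeros(self.nr)
        if bc.inlet_velocity == 0 or not self.inlet.any():
            return v
        r_in = g.inlet_radius
        if bc.profile == "parabolic":
            v[self.inlet] = np.maximum(2.0 * bc.inlet_velocity * (1.0 - (rc[self.inlet] / r_in) ** 2), 0.0)
        else:  # plug
            v[self.inlet] = bc.inlet_velocity
        flux = (2 * np.pi * rc * g.dr * v).sum()
        target = bc.inlet_velocity * np.pi * r_in**2
        if flux <= 0:
            raise FlowNonConvergenceError("inlet carries no discrete flux; grid too coarse")
        v *= target / flux
        return v

    # -- Stokes (constant) part ------------------------------------------
    def stokes_system(self):
        if self._stokes is not None:
            return self._stokes
        mu, dr, dz = self.mu, self.dr, self.dz
        nr, nz = self.nr, self.nz
        rf = self.grid.r_faces
        rc = self.grid.r_centers
        chi, k = self.chi, self.k
        rows, cols, vals = [], [], []
        rhs = np.zeros(self.n)

        def add(r, c, v):
            rows.append(np.asarray(r, dtype=np.int64))
            cols.append(np.asarray(c, dtype=np.int64))
            vals.append(np.asarray(v, dtype=float))

        # ---------------- r-momentum -----------------------------------
        I, J = np.nonzero(self.ur_unk)
        row = self.iur[I, J]
        diag = np.zeros(len(row))

        c_p = mu / dr**2 * rf[I + 1] / rc[I]
        c_m = mu / dr**2 * rf[I - 1] / rc[I - 1]
        diag += -mu / dr**2 * (rf[I] / rc[I] + rf[I] / rc[I - 1])
        nb = self.iur[I + 1, J]
        m = nb >= 0
        add(row[m], nb[m], c_p[m])  # fixed radial faces carry u_r = 0
        nb = self.iur[I - 1, J]
        m = nb >= 0
        add(row[m], nb[m], c_m[m])

        cz = mu / dz**2
        diag += -2.0 * cz
        # axial neighbor above
        top = J == nz - 1
        nb = self.iur[I, np.minimum(J + 1, nz - 1)]
        m = (~top) & (nb >= 0)
        add(row[m], nb[m], np.full(m.sum(), cz))
        diag[(~top) & (nb < 0)] += -cz  # wall halfway above: mirror ghost
        diag[top] += cz  # outlet plane: zero-gradient ghost
        # axial neighbor below
        bot = J == 0
        nb = self.iur[I, np.maximum(J - 1, 0)]
        m = (~bot) & (nb >= 0)
        add(row[m], nb[m], np.full(m.sum(), cz))
        diag[(~bot) & (nb < 0)] += -cz
        diag[bot] += -cz  # inlet plane: u_r = 0 Dirichlet, mirror ghost

        diag += -(mu / k) * 0.5 * (chi[I - 1, J] + chi[I, J])
        add(row, row, diag)
        add(row, self.ip[I, J], np.full(len(row), -1.0 / dr))
        add(row, self.ip[I - 1, J], np.full(len(row), 1.0 / dr))

        # ---------------- z-momentum (interior) -------------------------
        interior = self.uz_unk.copy()
        interior[:, nz] = False
        Iz, Jz = np.nonzero(interior)
        rowz = self.iuz[Iz, Jz]
        diag = np.zeros(len(rowz))

        c_p = mu * rf[Iz + 1] / (rc[Iz] * dr**2)
        c_m = mu * rf[Iz] / (rc[Iz] * dr**2)
        diag += -(c_p + c_m)
        outer = Iz + 1 > nr - 1
        nb = self.iuz[np.minimum(Iz + 1, nr - 1), Jz]
        m = (~outer) & (nb >= 0)
        add(rowz[m], nb[m], c_p[m])
        diag[outer | ((~outer) & (nb < 0))] += -c_p[outer | ((~outer) & (nb < 0))]  # wall mirror
        inner = Iz == 0  # c_m = 0 on the axis, no neighbor term
        nb = self.iuz[np.maximum(Iz - 1, 0), Jz]
        m = (~inner) & (nb >= 0)
        add(rowz[m], nb[m], c_m[m])
        mm = (~inner) & (nb < 0)
        diag[mm] += -c_m[mm]

        czz = mu / dz**2
        diag += -2.0 * czz
        nb = self.iuz[Iz, Jz + 1]
        m = nb >= 0
        add(rowz[m], nb[m], np.full(m.sum(), czz))  # fixed faces carry u_z = 0
        below_inlet = (Jz - 1 == 0) & self.inlet[Iz]
        nb = self.iuz[Iz, Jz - 1]
        m = (nb >= 0) & ~below_inlet
        add(rowz[m], nb[m], np.full(m.sum(), czz))
        np.add.at(rhs, rowz[below_inlet], -czz * self.v_prof[Iz[below_inlet]])

        diag += -(mu / k) * 0.5 * (chi[Iz, Jz - 1] + chi[Iz, Jz])
        add(rowz, rowz, diag)
        add(rowz, self.ip[Iz, Jz], np.full(len(rowz), -1.0 / dz))
        add(rowz, self.ip[Iz, Jz - 1], np.full(len(rowz), 1.0 / dz))

        # ---------------- z-momentum (outlet faces, p = 0 reference) ----
        Io = np.nonzero(self.uz_unk[:, nz])[0]
        rowo = self.iuz[Io, nz]
        diag = np.zeros(len(rowo))
        c_p = mu * rf[Io + 1] / (rc[Io] * dr**2)
        c_m = mu * rf[Io] / (rc[Io] * dr**2)
        diag += -(c_p + c_m)
        outer = Io + 1 > nr - 1
        nb = self.iuz[np.minimum(Io + 1, nr - 1), np.full(len(Io), nz)]
        m = (~outer) & (nb >= 0)
        add(rowo[m], nb[m], c_p[m])
        mm = outer | ((~outer) & (nb < 0))
        diag[mm] += -c_p[mm]
        inner = Io == 0
        nb = self.iuz[np.maximum(Io - 1, 0), np.full(len(Io), nz)]
        m = (~inner) & (nb >= 0)
        add(rowo[m], nb[m], c_m[m])
        mm = (~inner) & (nb < 0)
        diag[mm] += -c_m[mm]
        # zero-gradient ghost above; diffusion from the face below
        diag += -czz
        nb = self.iuz[Io, nz - 1]
        m = nb >= 0
        add(rowo[m], nb[m], np.full(m.sum(), czz))
        diag += -(mu / k) * chi[Io, nz - 1]
        add(rowo, rowo, diag)
        add(rowo, self.ip[Io, nz - 1], np.full(len(rowo), 2.0 / dz))

        # ---------------- continuity ------------------------------------
        Ic, Jc = np.nonzero(self.F)
        rowc = self.ip[Ic, Jc]
        nb = self.iur[Ic + 1, Jc]
        m = nb >= 0
        add(rowc[m], nb[m], (rf[Ic + 1] / (rc[Ic] * dr))[m])
        nb = self.iur[Ic, Jc]
        m = nb >= 0
        add(rowc[m], nb[m], (-rf[Ic] / (rc[Ic] * dr))[m])
        nb = self.iuz[Ic, Jc + 1]
        m = nb >= 0
        add(rowc[m], nb[m], np.full(m.sum(), 1.0 / dz))
        at_inlet = (Jc == 0) & self.inlet[Ic]
        nb = self.iuz[Ic, Jc]
        m = (nb >= 0) & ~at_inlet
        add(rowc[m], nb[m], np.full(m.sum(), -1.0 / dz))
        np.add.at(rhs, rowc[at_inlet], self.v_prof[Ic[at_inlet]] / dz)

        self._stokes = (np.concatenate(rows), np.concatenate(cols),
                        np.concatenate(vals), rhs)
        return self._stokes

    # -- convective (Picard) part ----------------------------------------
    def convection_system(self, ur: np.ndarray, uz: np.ndarray):
        """First-order upwind linearization of rho (u*.grad)u; returns COO triplets + rhs."""
        rho, dr, dz = self.rho, self.dr, self.dz
        nr, nz = self.nr, self.nz
        rows, cols, vals = [], [], []
        rhs = np.zeros(self.n)

        def add(r, c, v):
            rows.append(np.asarray(r, dtype=np.int64))
            cols.append(np.asarray(c, dtype=np.int64))
            vals.append(np.asarray(v, dtype=float))

        # ---- u_r faces --------------------------------------------------
        I, J = np.nonzero(self.ur_unk)
        row = self.iur[I, J]
        a_r = ur[I, J]
        a_z = 0.25 * (uz[I - 1, J] + uz[I, J] + uz[I - 1, J + 1] + uz[I, J + 1])
        diag = np.zeros(len(row))

        pos = a_r >= 0
        diag += np.where(pos, -rho * a_r / dr, rho * a_r / dr)
        nb = self.iur[I - 1, J]
        m = pos & (nb >= 0)
        add(row[m], nb[m], (rho * a_r / dr)[m])
        nb = self.iur[I + 1, J]
        m = (~pos) & (nb >= 0)
        add(row[m], nb[m], (-rho * a_r / dr)[m])

        pos = a_z >= 0
        diag += np.where(pos, -rho * a_z / dz, rho * a_z / dz)
        nb = self.iur[I, np.maximum(J - 1, 0)]
        m = pos & (J > 0) & (nb >= 0)
        add(row[m], nb[m], (rho * a_z / dz)[m])
        nb = self.iur[I, np.minimum(J + 1, nz - 1)]
        m = (~pos) & (J < nz - 1) & (nb >= 0)
        add(row[m], nb[m], (-rho * a_z / dz)[m])
        add(row, row, diag)

        # ---- u_z faces (interior) ---------------------------------------
        interior = self.uz_unk.copy()
        interior[:, nz] = False
        Iz, Jz = np.nonzero(interior)
        rowz = self.iuz[Iz, Jz]
        a_z = uz[Iz, Jz]
        a_r = 0.25 * (ur[Iz, Jz - 1] + ur[Iz + 1, Jz - 1] + ur[Iz, Jz] + ur[Iz + 1, Jz])
        diag = np.zeros(len(rowz))

        pos = a_z >= 0
        diag += np.where(pos, -rho * a_z / dz, rho * a_z / dz)
        below_inlet = (Jz - 1 == 0) & self.inlet[Iz]
        nb = self.iuz[Iz, Jz - 1]
        m = pos & (nb >= 0) & ~below_inlet
        add(rowz[m], nb[m], (rho * a_z / dz)[m])
        mk = pos & below_inlet
        np.add.at(rhs, rowz[mk], -(rho * a_z / dz)[mk] * self.v_prof[Iz[mk]])
        nb = self.iuz[Iz, Jz + 1]
        m = (~pos) & (nb >= 0)
        add(rowz[m], nb[m], (-rho * a_z / dz)[m])

        pos = a_r >= 0
        diag += np.where(pos, -rho * a_r / dr, rho * a_r / dr)
        nb = self.iuz[np.maximum(Iz - 1, 0), Jz]
        m = pos & (Iz > 0) & (nb >= 0)
        add(rowz[m], nb[m], (rho * a_r / dr)[m])
        nb = self.iuz[np.minimum(Iz + 1, nr - 1), Jz]
        m = (~pos) & (Iz < nr - 1) & (nb >= 0)
        add(rowz[m], nb[m], (-rho * a_r / dr)[m])
        add(rowz, rowz, diag)

        # ---- outlet faces: axial upwind only ----------------------------
        Io = np.nonzero(self.uz_unk[:, nz])[0]
        rowo = self.iuz[Io, nz]
        a_z = uz[Io, nz]
        pos = a_z >= 0
        diag = np.where(pos, -rho * a_z / dz, 0.0)  # backflow: zero-gradient
        nb = self.iuz[Io, nz - 1]
        m = pos & (nb >= 0)
        add(rowo[m], nb[m], (rho * a_z / dz)[m])
        add(rowo, rowo, diag)

        if rows:
            return np.concatenate(rows), np.concatenate(cols), np.concatenate(vals), rhs
        return (np.zeros(0, np.int64), np.zeros(0, np.int64), np.zeros(0), rhs)

    # -- helpers -----------------------------------------------------------
    def unpack(self, x: np.ndarray):
        ur = np.zeros((self.nr + 1, self.nz))
        ur[self.ur_unk] = x[: self.n_ur]
        uz = np.zeros((self.nr, self.nz + 1))
        uz[self.uz_unk] = x[self.n_ur : self.n_ur + self.n_uz]
        uz[self.inlet, 0] = self.v_prof[self.inlet]
        p = np.full((self.nr, self.nz), np.nan)
        p[self.F] = x[self.n_ur + self.n_uz :]
        return ur, uz, p


def _solve_linear(disc: _Discretization, conv=None) -> np.ndarray:
    r, c, v, rhs = disc.stokes_system()
    rhs = rhs.copy()
    if conv is not None:
        rc_, cc_, vc_, rhs_c = conv
        r = np.concatenate([r, rc_])
        c = np.concatenate([c, cc_])
        v = np.concatenate([v, vc_])
        rhs += rhs_c
    A = sp.coo_matrix((v, (r, c)), shape=(disc.n, disc.n)).tocsc()
    x = spla.spsolve(A, rhs)
    if not np.all(np.isfinite(x)):
        raise FlowNonConvergenceError("direct solve returned non-finite values")
    return x


def solve_flow(
    grid: DomainGrid,
    fluid: FluidProps | None = None,
    porous: PorousProps | None = None,
    bc: FlowBoundaryCondition | None = None,
    *,
    include_inertia: bool = True,
    tol: float = 1e-8,
    max_iter: int = 60,
    relax: float = 0.85,
) -> FlowSolution:
    """Solve steady Stokes-Brinkman (optionally Navier-Stokes-Brinkman) flow.

    Parameters
    ----------
    grid
        Labeled domain grid from :func:`osteoflow.geometry.rasterize`.
    fluid, porous
        Material properties; defaults are water at 37 degC and the silk
        scaffold (porosity 0.55, permeability 1.76e-11 m^2).
    bc
        Inlet boundary condition (mean velocity + profile).
    include_inertia
        Include rho(u.grad)u by Picard relinearization (default).  With
        ``False`` the problem is linear and solved in one sparse LU pass.
    tol
        Convergence tolerance: relative Picard update for the inertial
        solve; the linear systems themselves are solved directly.
    max_iter
        Maximum Picard iterations before a non-convergence error.
    """
    fluid = fluid or FluidProps()
    porous = porous or PorousProps()
    if bc is None:
        raise ValueError("a FlowBoundaryCondition is required")
    disc = _Discretization(grid, fluid, porous, bc)

    x = _solve_linear(disc)
    ur, uz, p = disc.unpack(x)
    diagnostics = {"include_inertia": include_inertia, "iterations": 0,
                   "picard_change": 0.0, "n_unknowns": disc.n}

    if include_inertia and bc.inlet_velocity > 0:
        scale = max(float(np.abs(uz).max()), 1e-300)
        prev_change = np.inf
        growth = 0
        for it in range(1, max_iter + 1):
            conv = disc.convection_system(ur, uz)
            x_new = _solve_linear(disc, conv)
            ur_n, uz_n, p_n = disc.unpack(x_new)
            change = max(np.abs(ur_n - ur).max(), np.abs(uz_n - uz).max()) / scale
            ur = relax * ur_n + (1 - relax) * ur
            uz = relax * uz_n + (1 - relax) * uz
            p = p_n
            diagnostics["iterations"] = it
            diagnostics["picard_change"] = change
            if change < max(tol, 1e-12):
                break
            if change > prev_change:
                growth += 1
                if growth >= 6:
                    raise FlowNonConvergenceError(
                        f"Picard iteration diverging (change {change:.3e} after {it} iterations)",
                        diagnostics,
                    )
            else:
                growth = 0
            prev_change = change
        else:
            raise FlowNonConvergenceError(
                f"Picard iteration did not converge in {max_iter} iterations "
                f"(last relative change {diagnostics['picard_change']:.3e})",
                diagnostics,
            )

    sol = FlowSolution(grid, ur, uz, p, fluid, porous, bc, diagnostics, converged=True)
    div = np.abs(sol.divergence())
    vref = max(float(np.abs(uz).max()), 1e-300)
    diagnostics["max_divergence"] = float(div.max())
    diagnostics["rel_divergence"] = float(div.max() * grid.dz / vref)
    return sol


def refine_until_converged(
    geom: BioreactorGeometry,
    fluid: FluidProps | None = None,
    porous: PorousProps | None = None,
    bc: FlowBoundaryCondition | None = None,
    initial_spacing: float = 205e-6,
    criterion: float = 0.02,
    max_levels: int = 8,
    **solve_opts,
) -> tuple[FlowSolution, RefinementReport]:
    """Halve the grid spacing until the volume-weighted mean velocity
    magnitude changes by less than ``criterion`` in both the free and the
    porous domain between consecutive levels (the mesh-sensitivity rule
    used for the bioreactor model, default 2%)."""
    report = RefinementReport([], [], [], [], [], criterion, False)
    solution = None
    for level in range(max_levels):
        h = initial_spacing / 2**level
        grid = rasterize(geom, h)
        solution = solve_flow(grid, fluid, porous, bc, **solve_opts)
        report.spacings.append(h)
        report.mean_free.append(solution.mean_speed(DomainLabel.FREE))
        report.mean_porous.append(solution.mean_speed(DomainLabel.POROUS))
        if level > 0:
            prev_f, cur_f = report.mean_free[-2:]
            prev_p, cur_p = report.mean_porous[-2:]
            ch_f = abs(cur_f - prev_f) / abs(prev_f) if prev_f else np.inf
            ch_p = abs(cur_p - prev_p) / abs(prev_p) if prev_p else np.inf
            report.rel_change_free.append(ch_f)
            report.rel_change_porous.append(ch_p)
            if ch_f < criterion and ch_p < criterion:
                report.converged = True
                return solution, report
    raise RefinementError(
        f"mean velocity not converged to {criterion:.2%} after {max_levels} levels",
        report,
    )


def mass_balance(solution: FlowSolution) -> MassBalance:
    """Relative inlet/outlet flux imbalance of a converged solution."""
    fin = solution.inlet_flux()
    fout = solution.outlet_flux()
    if fin == 0.0:
        if solution.max_speed() > 0:
            raise ValueError("zero inlet flux with a nonzero velocity field")
        return MassBalance(0.0, 0.0, 0.0)
    return MassBalance(abs(fin - fout) / abs(fin), fin, fout)
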