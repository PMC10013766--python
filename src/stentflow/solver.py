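"""Steady incompressible Navier–Stokes on the stented-ureter mesh.

Taylor–Hood (P2 velocity / P1 pressure) discretization; no-slip walls, a
fully developed (parabolic) inlet profile and a traction-free outlet that
pins the static pressure to ~0 there.  The nonlinear system is solved by a
Picard start and Newton finish with sparse-direct (SuperLU) linear solves;
the contract is a nonlinear-residual reduction by ``rel_tol`` (default
1e-8).  There is no randomness anywhere in the solve.

Internally the solver works in mm, s and kinematic pressure (mm^2/s^2),
which keeps matrix entries O(1) at urinary-flow scales; pressures are
reported in Pa using the fluid density.  At the study's Reynolds number
(~10) the steady solution is unique and Newton converges in a handful of
iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import simpson

from .fem import TaylorHood, p2_basis
from .geometry import Domain2D, Mesh2D, generate_mesh

__all__ = [
    "FluidProps",
    "BoundaryConditions",
    "FlowField",
    "ConvergenceReport",
    "solve_steady_flow",
    "convergence_study",
]


@dataclass(frozen=True)
class FluidProps:
    """Newtonian fluid; SI units (kg/m^3, m^2/s)."""

    density_rho: float = 1000.0
    kinematic_viscosity_nu: float = 1.005e-6

    def __post_init__(self) -> None:
        if self.density_rho <= 0 or self.kinematic_viscosity_nu <= 0:
            raise ValueError("fluid properties must be positive")

    @property
    def dynamic_viscosity_mu(self) -> float:
        """mu = rho * nu (Pa s)."""
        return self.density_rho * self.kinematic_viscosity_nu

    @property
    def nu_mm2(self) -> float:
        """Kinematic viscosity in mm^2/s (solver units)."""
        return self.kinematic_viscosity_nu * 1e6


@dataclass(frozen=True)
class BoundaryConditions:
    """Inlet mean velocity (mm/s, parabolic profile across the cone mouth),
    outlet static pressure (Pa), no-slip on all walls."""

    inlet_mean_velocity: float = 0.235
    outlet_pressure: float = 0.0

    def inlet_profile(self, r: np.ndarray, half_width: float) -> np.ndarray:
        """Fully developed 2D channel profile with the prescribed mean."""
        r = np.asarray(r, dtype=float)
        return 1.5 * self.inlet_mean_velocity * (1.0 - (r / half_width) ** 2)


class FlowField:
    """Discrete steady velocity/pressure solution with point evaluation.

    ``velocity(x, r)`` evaluates the P2 interpolant at arbitrary fluid
    points (mm/s); ``pressure(x, r)`` the P1 pressure in Pa.  Carries the
    mesh, fluid, boundary conditions and residual history.
    """

    def __init__(self, mesh: Mesh2D, th: TaylorHood, ux: np.ndarray,
                 uy: np.ndarray, p_kin: np.ndarray, fluid: FluidProps,
                 bc: BoundaryConditions, residuals: List[float]):
        self.mesh = mesh
        self.th = th
        self.ux = ux
        self.uy = uy
        self.p_kin = p_kin
        self.fluid = fluid
        self.bc = bc
        self.residuals = residuals
        self._trifinder = None

    # ---- point evaluation ----------------------------------------------------
    def _finder(self):
        if self._trifinder is None:
            from matplotlib.tri import Triangulation

            tri = Triangulation(self.mesh.points[:, 0], self.mesh.points[:, 1],
                                self.mesh.triangles)
            self._trifinder = (tri, tri.get_trifinder())
        return self._trifinder

    def _locate(self, x: np.ndarray, r: np.ndarray) -> np.ndarray:
        _, finder = self._finder()
        e = finder(x, r)
        if np.any(e < 0):
            # nudge points that sit exactly on a boundary edge/corner
            miss = np.flatnonzero(e < 0)
            eps = 1e-9 * max(1.0, float(np.abs(x).max()))
            for dx in (eps, -eps):
                for dr in (eps, -eps, 0.0):
                    still = miss[e[miss] < 0]
                    if len(still) == 0:
                        break
                    e[still] = finder(x[still] + dx, r[still] + dr)
            if np.any(e < 0):
                i = int(np.flatnonzero(e < 0)[0])
                raise ValueError(
                    f"point (x={x[i]:.6g}, r={r[i]:.6g}) mm is outside the fluid"
                )
        return e

    def velocity(self, x, r) -> Tuple[np.ndarray, np.ndarray]:
        """(U, V) in mm/s at points (x, r); raises if a point is in solid."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        r = np.atleast_1d(np.asarray(r, dtype=float))
        x, r = np.broadcast_arrays(x, r)
        e = self._locate(x, r)
        tris = self.th.triangles[e]
        v0 = self.th.points[tris[:, 0]]
        J = np.stack([self.th.points[tris[:, 1]] - v0,
                      self.th.points[tris[:, 2]] - v0], axis=2)
        rhs = np.stack([x - v0[:, 0], r - v0[:, 1]], axis=1)
        det = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        xi = (J[:, 1, 1] * rhs[:, 0] - J[:, 0, 1] * rhs[:, 1]) / det
        eta = (-J[:, 1, 0] * rhs[:, 0] + J[:, 0, 0] * rhs[:, 1]) / det
        N, _ = p2_basis(np.column_stack([xi, eta]))
        dofs = self.th.p2_element_dofs()[e]
        U = np.einsum("ki,ki->k", N, self.ux[dofs])
        V = np.einsum("ki,ki->k", N, self.uy[dofs])
        return U, V

    def pressure(self, x, r) -> np.ndarray:
        """Static pressure in Pa (P1 interpolant)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        r = np.atleast_1d(np.asarray(r, dtype=float))
        x, r = np.broadcast_arrays(x, r)
        e = self._locate(x, r)
        tris = self.th.triangles[e]
        v0 = self.th.points[tris[:, 0]]
        J = np.stack([self.th.points[tris[:, 1]] - v0,
                      self.th.points[tris[:, 2]] - v0], axis=2)
        rhs = np.stack([x - v0[:, 0], r - v0[:, 1]], axis=1)
        det = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        xi = (J[:, 1, 1] * rhs[:, 0] - J[:, 0, 1] * rhs[:, 1]) / det
        eta = (-J[:, 1, 0] * rhs[:, 0] + J[:, 0, 0] * rhs[:, 1]) / det
        lam = np.column_stack([1 - xi - eta, xi, eta])
        q = np.einsum("ki,ki->k", lam, self.p_kin[tris])
        return self.fluid.density_rho * q * 1e-6  # (kg/m^3)(mm^2/s^2) -> Pa

    # ---- integral diagnostics ------------------------------------------------
    def _vertical_flux(self, x: float, r_lo: float, r_hi: float,
                       n: int = 401) -> float:
        rr = np.linspace(r_lo, r_hi, n)
        U, _ = self.velocity(np.full(n, x), rr)
        return float(simpson(U, x=rr))

    def cross_section_flux(self, x: float, n: int = 401) -> float:
        """Integral of U over all fluid bands of the section (mm^2/s)."""
        dom = self.mesh.domain
        levels = [float(dom.f_bot(np.array([x]))[0])]
        if dom.stent is not None and dom.stent_x_min < x < dom.stent_x_max:
            levels += [dom.stent_bottom, dom.lumen_bottom, dom.lumen_top,
                       dom.stent_top]
        levels += [float(dom.f_top(np.array([x]))[0])]
        levels = sorted(set(levels))
        total = 0.0
        for lo, hi in zip(levels[:-1], levels[1:]):
            mid = 0.5 * (lo + hi)
            if dom.in_fluid(np.array([x]), np.array([mid]))[0]:
                total += self._vertical_flux(x, lo, hi, n)
        return total

    def inlet_flux(self, n: int = 801) -> float:
        dom = self.mesh.domain
        x = dom.x_min + 1e-9
        return self._vertical_flux(x, float(dom.f_bot(np.array([x]))[0]) + 1e-9,
                                   float(dom.f_top(np.array([x]))[0]) - 1e-9, n)

    def outlet_flux(self, n: int = 801) -> float:
        dom = self.mesh.domain
        x = dom.x_max - 1e-9
        return self._vertical_flux(x, float(dom.f_bot(np.array([x]))[0]) + 1e-9,
                                   float(dom.f_top(np.array([x]))[0]) - 1e-9, n)

    def mass_imbalance(self) -> float:
        """|inlet flux - outlet flux| / inlet flux."""
        qi = self.inlet_flux()
        if qi == 0.0:
            return 0.0
        return abs(qi - self.outlet_flux()) / abs(qi)

    def divergence_l1(self) -> float:
        """Sum over elements of integral |div u| (mm^2/s)."""
        return float(self.th.element_divergence(self.ux, self.uy).sum())

    def no_slip_error(self) -> float:
        """Max |velocity| on wall dofs (solver-tolerance check), mm/s."""
        dofs = _facet_p2_dofs(self.th, self.mesh,
                              self.mesh.wall_tags())
        if len(dofs) == 0:
            return 0.0
        return float(np.max(np.hypot(self.ux[dofs], self.uy[dofs])))

    def stent_tip_shear(self, x: float = 0.0, delta: float = 0.01) -> float:
        """Wall shear mu dU/dr (Pa) on the stent outer surface at given x."""
        dom = self.mesh.domain
        assert dom.stent is not None
        r0 = dom.stent_top
        rr = np.array([r0, r0 + delta, r0 + 2 * delta])
        U, _ = self.velocity(np.full(3, x), rr)
        dudr = (-3 * U[0] + 4 * U[1] - U[2]) / (2 * delta)
        return self.fluid.dynamic_viscosity_mu * dudr


def _facet_p2_dofs(th: TaylorHood, mesh: Mesh2D,
                   tags: Sequence[str]) -> np.ndarray:
    """Scalar-P2 dof indices (vertices + midsides) on the tagged facets."""
    pairs = [mesh.facets[t] for t in tags if len(mesh.facets[t])]
    if not pairs:
        return np.empty(0, dtype=np.int64)
    pairs = np.concatenate(pairs)
    verts = np.unique(pairs)
    eidx = th.edge_index(pairs)
    return np.unique(np.concatenate([verts, th.n_vertices + eidx]))


def _momentum_matrix(th: TaylorHood, nu: float, conv: Optional[sp.csr_array]):
    A = nu * th.scalar_stiffness()
    if conv is not None:
        A = A + conv
    return A


def solve_steady_flow(mesh: Mesh2D, fluid: FluidProps, bc: BoundaryConditions,
                      rel_tol: float = 1e-8, max_iter: int = 25,
                      n_picard: int = 1) -> FlowField:
    """Solve the steady Navier–Stokes equations on ``mesh``.

    Picard iterations (``n_picard``, counting the initial Stokes solve)
    followed by Newton until the nonlinear residual of the free dofs has
    dropped by ``rel_tol`` relative to its value after the Stokes solve.
    Raises ``RuntimeError`` with the residual history on non-convergence.
    """
    th = TaylorHood.build(mesh.points, mesh.triangles)
    dom = mesh.domain
    nu = fluid.nu_mm2

    # Reynolds sanity: the model is laminar and steady
    D = dom.ureter.diameter_D
    uc_est = 1.5 * bc.inlet_mean_velocity * dom.ureter.cone_mouth_width / D
    Re = uc_est * D / nu
    if Re > 100:
        warnings.warn(f"channel Reynolds number ~{Re:.0f} > 100; the steady "
                      "laminar model may not be meaningful", stacklevel=2)

    nv2, np1 = th.nv2, th.np1
    ndof = 2 * nv2 + np1
    coords = th.p2_dof_coords()

    wall_dofs = _facet_p2_dofs(th, mesh, mesh.wall_tags())
    inlet_dofs = _facet_p2_dofs(th, mesh, ["inlet"])
    half_w = 0.5 * dom.ureter.cone_mouth_width

    dirichlet = np.zeros(ndof, dtype=bool)
    values = np.zeros(ndof)
    for d in (wall_dofs, inlet_dofs):
        dirichlet[d] = True
        dirichlet[nv2 + d] = True
    values[inlet_dofs] = bc.inlet_profile(coords[inlet_dofs, 1], half_w)
    free = ~dirichlet

    K = th.scalar_stiffness()
    Bx, By = th.divergence_blocks()
    Z = sp.csr_array((np1, np1))

    def full_matrix(conv, newton_blocks=None):
        A = nu * K + conv if conv is not None else nu * K
        Axx, Axy, Ayx, Ayy = A, None, None, A
        if newton_blocks is not None:
            Axx = A + newton_blocks["xx"]
            Axy = newton_blocks["xy"]
            Ayx = newton_blocks["yx"]
            Ayy = A + newton_blocks["yy"]
        if Axy is None:
            Axy = sp.csr_array((nv2, nv2))
            Ayx = sp.csr_array((nv2, nv2))
        return sp.bmat([[Axx, Axy, -Bx.T],
                        [Ayx, Ayy, -By.T],
                        [Bx, By, Z]], format="csr")

    def residual(U):
        ux, uy = U[:nv2], U[nv2:2 * nv2]
        uq, _ = th.quad_velocity(ux, uy)
        conv = th.convection(uq)
        S = full_matrix(conv)
        return S @ U, conv

    def solve_dirichlet(S, rhs):
        """Solve S U = rhs with prescribed values on Dirichlet dofs."""
        U = np.zeros(ndof)
        U[dirichlet] = values[dirichlet]
        b = rhs - S @ U
        Sff = S[free][:, free].tocsc()
        U[free] = spla.spsolve(Sff, b[free])
        return U

    # --- initial (Stokes) solve ----------------------------------------------
    U = solve_dirichlet(full_matrix(None), np.zeros(ndof))
    R, conv = residual(U)
    res0 = np.linalg.norm(R[free])
    history = [res0]
    scale = max(res0, 1e-14)
    if bc.inlet_mean_velocity == 0.0:
        scale = 1e-14  # zero-flow case: Stokes solve is already exact

    it = 0
    while history[-1] > rel_tol * scale and it < max_iter:
        it += 1
        if it < n_picard:  # Picard: solve with frozen convection
            S = full_matrix(conv)
            U = solve_dirichlet(S, np.zeros(ndof))
        else:              # Newton
            ux, uy = U[:nv2], U[nv2:2 * nv2]
            uq, gq = th.quad_velocity(ux, uy)
            J = full_matrix(th.convection(uq), th.newton_blocks(gq))
            dU = np.zeros(ndof)
            Jff = J[free][:, free].tocsc()
            dU[free] = spla.spsolve(Jff, -R[free])
            U = U + dU
        R, conv = residual(U)
        history.append(np.linalg.norm(R[free]))

    if history[-1] > rel_tol * scale:
        raise RuntimeError(
            f"nonlinear solver did not converge in {max_iter} iterations; "
            f"residual history: {history}"
        )

    return FlowField(mesh=mesh, th=th, ux=U[:nv2], uy=U[nv2:2 * nv2],
                     p_kin=U[2 * nv2:], fluid=fluid, bc=bc,
                     residuals=[float(h) for h in history])


@dataclass
class ConvergenceReport:
    """Mesh-convergence metrics: the relative change between successive mesh
    levels of the global mass imbalance, the first-side-hole flux and the
    stent-outer-wall shear at x=0 (centerline velocity instead for unstented
    domains).  ``uncertainty`` is the max metric on the finest pair."""

    levels: List[Tuple[float, float]]
    n_elements: List[int]
    metrics: Dict[str, List[float]]
    rel_changes: Dict[str, List[float]] = field(default_factory=dict)
    uncertainty: float = float("nan")

    def finalize(self) -> "ConvergenceReport":
        self.rel_changes = {}
        worst = 0.0
        for name, vals in self.metrics.items():
            if name == "imbalance":
                # already a relative mass-defect; contributes its own value
                self.rel_changes[name] = list(vals)
                worst = max(worst, vals[-1])
                continue
            ch = [abs(b - a) / max(abs(b), 1e-300)
                  for a, b in zip(vals[:-1], vals[1:])]
            self.rel_changes[name] = ch
            if ch:
                worst = max(worst, ch[-1])
        self.uncertainty = worst
        return self


def convergence_study(domain: Domain2D, fluid: FluidProps,
                      bc: BoundaryConditions,
                      mesh_levels: Sequence[Tuple[float, float]],
                      rel_tol: float = 1e-8) -> ConvergenceReport:
    """Solve on successively refined meshes and report metric changes.

    ``mesh_levels`` is a list of ``(h_global, h_sh)`` from coarse to fine.
    """
    if len(mesh_levels) < 2:
        raise ValueError("need at least two mesh levels")
    from . import postprocess  # local import; postprocess is solver-agnostic

    report = ConvergenceReport(levels=list(mesh_levels), n_elements=[],
                               metrics={})
    stented = domain.stent is not None and len(domain.stent.side_holes) > 0
    names = ["imbalance"] + (
        ["sh1_flux", "tip_shear"] if stented else ["centerline_u"]
    )
    for n in names:
        report.metrics[n] = []

    for h_global, h_sh in mesh_levels:
        mesh = generate_mesh(domain, h_global=h_global, h_sh=h_sh)
        fld = solve_steady_flow(mesh, fluid, bc, rel_tol=rel_tol)
        report.n_elements.append(mesh.n_elements)
        report.metrics["imbalance"].append(fld.mass_imbalance())
        if stented:
            sh1 = domain.stent.side_holes[0]
            res = postprocess.sh_flux(fld, sh1)
            report.metrics["sh1_flux"].append(res.flux_Q_SH)
            report.metrics["tip_shear"].append(fld.stent_tip_shear())
        else:
            u, _ = fld.velocity(0.5 * domain.ureter.length_L, 0.0)
            report.metrics["centerline_u"].append(float(u[0]))
    return report.finalize()
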