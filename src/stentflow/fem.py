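"""Mixed P2/P1 (Taylor–Hood) finite elements on triangles.

Minimal, vectorized building blocks for the steady incompressible
Navier–Stokes solver: quadratic velocity / linear pressure shape functions,
a degree-5 triangle quadrature, unique-edge numbering for the P2 midside
nodes, and assembly of the Stokes, convection and Newton matrices in sparse
COO form.  Velocity degrees of freedom are blocked per component:
``[u_x (nv2), u_y (nv2), p (np1)]`` with ``nv2 = n_vertices + n_edges``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import scipy.sparse as sp

# degree-5, 7-point symmetric triangle rule (barycentric points, weights sum 1/2)
_A1 = 0.0597158717897698
_B1 = 0.4701420641051151
_A2 = 0.7974269853530873
_B2 = 0.1012865073234563
_QP = np.array([
    [1 / 3, 1 / 3],
    [_A1, _B1], [_B1, _A1], [_B1, _B1],
    [_A2, _B2], [_B2, _A2], [_B2, _B2],
])
_QW = 0.5 * np.array([
    0.225,
    0.1323941527885062, 0.1323941527885062, 0.1323941527885062,
    0.1259391805448271, 0.1259391805448271, 0.1259391805448271,
])


def p2_basis(xi: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """P2 shape values and reference gradients at points ``xi`` (n, 2).

    Local ordering: vertices 0,1,2 then midsides of edges (0,1), (1,2), (2,0).
    Returns ``N`` (n, 6) and ``dN`` (n, 6, 2).
    """
    xi = np.atleast_2d(xi)
    l1 = 1.0 - xi[:, 0] - xi[:, 1]
    l2 = xi[:, 0]
    l3 = xi[:, 1]
    N = np.stack([
        l1 * (2 * l1 - 1), l2 * (2 * l2 - 1), l3 * (2 * l3 - 1),
        4 * l1 * l2, 4 * l2 * l3, 4 * l3 * l1,
    ], axis=1)
    # gradients wrt (xi, eta); dl1 = (-1,-1), dl2 = (1,0), dl3 = (0,1)
    z = np.zeros_like(l1)
    dN = np.empty((len(l1), 6, 2))
    dN[:, 0, 0] = -(4 * l1 - 1); dN[:, 0, 1] = -(4 * l1 - 1)
    dN[:, 1, 0] = 4 * l2 - 1;    dN[:, 1, 1] = z
    dN[:, 2, 0] = z;             dN[:, 2, 1] = 4 * l3 - 1
    dN[:, 3, 0] = 4 * (l1 - l2); dN[:, 3, 1] = -4 * l2
    dN[:, 4, 0] = 4 * l3;        dN[:, 4, 1] = 4 * l2
    dN[:, 5, 0] = -4 * l3;       dN[:, 5, 1] = 4 * (l1 - l3)
    return N, dN


def p1_basis(xi: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """P1 shape values (n, 3) and constant reference gradients (3, 2)."""
    xi = np.atleast_2d(xi)
    N = np.column_stack([1.0 - xi[:, 0] - xi[:, 1], xi[:, 0], xi[:, 1]])
    dN = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
    return N, dN


@dataclass
class TaylorHood:
    """Dof structures and precomputed element data for one mesh."""

    points: np.ndarray          # (nv, 2)
    triangles: np.ndarray       # (ne, 3)
    edges: np.ndarray           # (ned, 2) unique vertex pairs (sorted)
    tri_edges: np.ndarray       # (ne, 3) edge index per local edge
    detJ: np.ndarray            # (ne,)
    grad2: np.ndarray           # (ne, nq, 6, 2) physical P2 gradients
    grad1: np.ndarray           # (ne, 3, 2) physical P1 gradients (constant)

    @classmethod
    def build(cls, points: np.ndarray, triangles: np.ndarray) -> "TaylorHood":
        tris = np.asarray(triangles, dtype=np.int64)
        local = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
        local_sorted = np.sort(local, axis=1)
        edges, inv = np.unique(local_sorted, axis=0, return_inverse=True)
        tri_edges = inv.reshape(3, -1).T.copy()

        p = np.asarray(points, dtype=float)
        v0 = p[tris[:, 0]]
        J = np.stack([p[tris[:, 1]] - v0, p[tris[:, 2]] - v0], axis=2)  # (ne,2,2)
        detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        if np.any(detJ <= 0):
            raise ValueError("mesh contains non-CCW or degenerate triangles")
        invJT = np.empty_like(J)
        invJT[:, 0, 0] = J[:, 1, 1]
        invJT[:, 0, 1] = -J[:, 1, 0]
        invJT[:, 1, 0] = -J[:, 0, 1]
        invJT[:, 1, 1] = J[:, 0, 0]
        invJT /= detJ[:, None, None]

        _, dN2 = p2_basis(_QP)                    # (nq, 6, 2)
        grad2 = np.einsum("eab,qib->eqia", invJT, dN2)
        _, dN1 = p1_basis(_QP)
        grad1 = np.einsum("eab,ib->eia", invJT, dN1)
        return cls(points=p, triangles=tris, edges=edges, tri_edges=tri_edges,
                   detJ=detJ, grad2=grad2, grad1=grad1)

    # ---- dof bookkeeping -----------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.points)

    @property
    def nv2(self) -> int:
        """Scalar P2 dofs (vertices + edge midpoints)."""
        return len(self.points) + len(self.edges)

    @property
    def np1(self) -> int:
        return len(self.points)

    @property
    def n_dofs(self) -> int:
        return 2 * self.nv2 + self.np1

    def p2_element_dofs(self) -> np.ndarray:
        """(ne, 6) scalar-P2 dof indices per element."""
        return np.concatenate(
            [self.triangles, self.n_vertices + self.tri_edges], axis=1
        )

    def p2_dof_coords(self) -> np.ndarray:
        """Coordinates of all scalar P2 dofs (vertices then edge midpoints)."""
        mid = 0.5 * (self.points[self.edges[:, 0]] + self.points[self.edges[:, 1]])
        return np.concatenate([self.points, mid])

    def edge_index(self, pairs: np.ndarray) -> np.ndarray:
        """Global edge index for vertex pairs (k, 2); raises if absent."""
        pairs = np.sort(np.asarray(pairs, dtype=np.int64), axis=1)
        nv = self.n_vertices
        keys = self.edges[:, 0] * nv + self.edges[:, 1]
        order = np.argsort(keys)
        want = pairs[:, 0] * nv + pairs[:, 1]
        pos = np.searchsorted(keys[order], want)
        if np.any(pos >= len(keys)) or np.any(keys[order][pos] != want):
            raise KeyError("facet pair is not a mesh edge")
        return order[pos]

    # ---- assembly ------------------------------------------------------------
    def _coo(self, rows_loc, cols_loc, vals) -> sp.csr_array:
        ne = len(self.triangles)
        ni, nj = vals.shape[1], vals.shape[2]
        r = np.repeat(rows_loc, nj, axis=1).ravel()
        c = np.tile(cols_loc, (1, ni)).ravel()
        return sp.coo_array((vals.ravel(), (r, c)),
                            shape=(self._shape_r, self._shape_c)).tocsr()

    def scalar_stiffness(self) -> sp.csr_array:
        """(grad phi_i, grad phi_j) on scalar P2 space."""
        w = (_QW[None, :] * self.detJ[:, None])
        K = np.einsum("eq,eqia,eqja->eij", w, self.grad2, self.grad2)
        d = self.p2_element_dofs()
        self._shape_r = self._shape_c = self.nv2
        return self._coo(d, d, K)

    def p2_mass(self) -> sp.csr_array:
        N2, _ = p2_basis(_QP)
        w = (_QW[None, :] * self.detJ[:, None])
        M = np.einsum("eq,qi,qj->eij", w, N2, N2)
        d = self.p2_element_dofs()
        self._shape_r = self._shape_c = self.nv2
        return self._coo(d, d, M)

    def divergence_blocks(self) -> Tuple[sp.csr_array, sp.csr_array]:
        """Bx, By with B[q, j] = int psi_q d(phi_j)/dx_a (P1 row, P2 col)."""
        N1, _ = p1_basis(_QP)
        w = (_QW[None, :] * self.detJ[:, None])
        d2 = self.p2_element_dofs()
        d1 = self.triangles
        self._shape_r, self._shape_c = self.np1, self.nv2
        Bx = self._coo(d1, d2, np.einsum("eq,qi,eqja->eij",
                                         w, N1, self.grad2[..., 0:1]))
        By = self._coo(d1, d2, np.einsum("eq,qi,eqja->eij",
                                         w, N1, self.grad2[..., 1:2]))
        return Bx, By

    def quad_velocity(self, ux: np.ndarray, uy: np.ndarray):
        """Velocity and its gradient at quadrature points.

        Returns ``(u, gradu)`` with ``u`` (ne, nq, 2) and ``gradu``
        (ne, nq, 2, 2) where ``gradu[..., a, b] = d u_a / d x_b``.
        """
        N2, _ = p2_basis(_QP)
        d = self.p2_element_dofs()
        ue = np.stack([ux[d], uy[d]], axis=-1)          # (ne, 6, 2)
        u = np.einsum("qi,eic->eqc", N2, ue)
        gradu = np.einsum("eic,eqia->eqca", ue, self.grad2)
        return u, gradu

    def convection(self, u_quad: np.ndarray) -> sp.csr_array:
        """N(ub)[i, j] = int (ub . grad phi_j) phi_i on scalar P2."""
        N2, _ = p2_basis(_QP)
        w = (_QW[None, :] * self.detJ[:, None])
        adv = np.einsum("eqa,eqja->eqj", u_quad, self.grad2)
        C = np.einsum("eq,qi,eqj->eij", w, N2, adv)
        d = self.p2_element_dofs()
        self._shape_r = self._shape_c = self.nv2
        return self._coo(d, d, C)

    def newton_blocks(self, gradu_quad: np.ndarray):
        """D_ab[i, j] = int phi_j (d ub_a / d x_b) phi_i for a,b in {x,y}."""
        N2, _ = p2_basis(_QP)
        w = (_QW[None, :] * self.detJ[:, None])
        d = self.p2_element_dofs()
        self._shape_r = self._shape_c = self.nv2
        out = {}
        for a, na in ((0, "x"), (1, "y")):
            for b, nb in ((0, "x"), (1, "y")):
                D = np.einsum("eq,qi,qj,eq->eij", w, N2, N2,
                              gradu_quad[:, :, a, b])
                out[na + nb] = self._coo(d, d, D)
        return out

    def element_divergence(self, ux: np.ndarray, uy: np.ndarray) -> np.ndarray:
        """Per-element integral of |div u| (mm^2/s); a discrete mass check."""
        _, gradu = self.quad_velocity(ux, uy)
        div = gradu[:, :, 0, 0] + gradu[:, :, 1, 1]
        w = (_QW[None, :] * self.detJ[:, None])
        return np.einsum("eq,eq->e", w, np.abs(div))
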