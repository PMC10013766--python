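"""Analytic reference flows and perturbed fixtures.

Every post-processing and lumped-model operation in this package can be
exercised against a field whose fluxes and shear rates are known in closed
form, without running the finite-element solver.  A :class:`ReferenceField`
exposes the same ``velocity(x, r)`` contract as a solved
:class:`~stentflow.solver.FlowField`, plus a dictionary of exact
functionals.

The only random source in the package is :func:`perturb_profile`, which is
seeded and deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Tuple

import numpy as np

from .postprocess import Profile

__all__ = [
    "ReferenceField",
    "pipe_poiseuille_profile",
    "plane_poiseuille_field",
    "annular_poiseuille_profile",
    "crossflow_patch",
    "perturb_profile",
]


@dataclass
class ReferenceField:
    """Closed-form (U, V) field with exact functionals attached.

    ``exact`` holds the closed-form values the fixture guarantees, e.g.
    ``flux`` (streamwise, mm^2/s), ``wall_shear_rate`` (1/s) or
    ``transverse_flux`` (mm^2/s).  Each must match high-resolution
    quadrature of the pointwise field.
    """

    kind: str
    u_fn: Callable[[np.ndarray, np.ndarray], np.ndarray]
    v_fn: Callable[[np.ndarray, np.ndarray], np.ndarray]
    exact: Dict[str, float]
    params: Dict[str, float] = field(default_factory=dict)
    seed: Optional[int] = None

    def velocity(self, x, r) -> Tuple[np.ndarray, np.ndarray]:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        r = np.atleast_1d(np.asarray(r, dtype=float))
        x, r = np.broadcast_arrays(x, r)
        return self.u_fn(x, r), self.v_fn(x, r)


def pipe_poiseuille_profile(Uc: float, D: float,
                            r_points: np.ndarray) -> Profile:
    """Theoretical Poiseuille profile U*(r) = Uc (1 - (2r/D)^2), V* = 0.

    ``r_points`` must lie in [-D/2, D/2] (mm); used as the reference in the
    base-flow error metrics.
    """
    r = np.asarray(r_points, dtype=float)
    if np.any(np.abs(r) > D / 2 + 1e-12):
        raise ValueError("r_points outside the pipe radius")
    u = Uc * (1.0 - (2.0 * r / D) ** 2)
    return Profile(coords=r, u=u, v=np.zeros_like(u), Uc=Uc)


def plane_poiseuille_field(Uc: float, D: float) -> ReferenceField:
    """Plane channel flow between r = ±D/2; exact flux (2/3) Uc D.

    ``wall_shear_rate`` = 4 Uc / D is |dU/dr| at the walls (multiply by mu
    for a stress).
    """
    if Uc < 0 or D <= 0:
        raise ValueError("need Uc >= 0 and D > 0")

    def u_fn(x, r):
        return Uc * (1.0 - (2.0 * r / D) ** 2)

    def v_fn(x, r):
        return np.zeros_like(np.asarray(x, dtype=float))

    return ReferenceField(
        kind="plane_poiseuille", u_fn=u_fn, v_fn=v_fn,
        exact={"flux": 2.0 / 3.0 * Uc * D, "wall_shear_rate": 4.0 * Uc / D},
        params={"Uc": Uc, "D": D},
    )


def annular_poiseuille_profile(dpdx: float, mu: float, D: float, Do: float,
                               r_points: np.ndarray) -> Profile:
    """Axial velocity of pressure-driven flow in a coaxial annulus (SI).

    u(r) = G/(4 mu) [Ro^2 - r^2 - (Ro^2 - Ri^2) ln(Ro/r) / ln(Ro/Ri)] with
    G = -dp/dx, Ri = Do/2, Ro = D/2.  ``r_points`` are radial coordinates
    with Ri <= |r| <= Ro.  The quadrature 2 pi int u r dr over the annulus
    is the independent oracle for the closed-form bulk flow rate.
    """
    if not 0 < Do < D:
        raise ValueError("need 0 < Do < D")
    Ro, Ri = D / 2.0, Do / 2.0
    r = np.abs(np.asarray(r_points, dtype=float))
    if np.any(r < Ri - 1e-15) or np.any(r > Ro + 1e-15):
        raise ValueError("r_points outside the annulus")
    G = -dpdx
    u = G / (4.0 * mu) * (
        Ro ** 2 - r ** 2 - (Ro ** 2 - Ri ** 2) * np.log(Ro / r) / np.log(Ro / Ri)
    )
    return Profile(coords=np.asarray(r_points, dtype=float), u=u,
                   v=np.zeros_like(u), Uc=float(np.max(np.abs(u))) or 1.0)


def crossflow_patch(Q_target: float, width: float,
                    x_center: float) -> ReferenceField:
    """Compactly supported transverse flow with an exact window integral.

    V(x) is a raised-cosine bump on [x_c - w/2, x_c + w/2] whose integral
    over x is exactly ``Q_target`` (mm^2/s); U = 0.  The compact support
    makes window-overlap behaviour exactly testable.
    """
    if width <= 0:
        raise ValueError("width must be > 0")

    def v_fn(x, r):
        xi = (np.asarray(x, dtype=float) - x_center) / width
        out = np.zeros_like(xi)
        m = np.abs(xi) < 0.5
        out[m] = (Q_target / width) * (1.0 + np.cos(2.0 * np.pi * xi[m]))
        return out

    def u_fn(x, r):
        return np.zeros_like(np.asarray(x, dtype=float))

    return ReferenceField(
        kind="crossflow_patch", u_fn=u_fn, v_fn=v_fn,
        exact={"transverse_flux": Q_target},
        params={"Q_target": Q_target, "width": width, "x_center": x_center},
    )


def perturb_profile(profile: Profile, sigma: float, seed: int) -> Profile:
    """Add i.i.d. N(0, (sigma Uc)^2) noise to both components; seeded."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0.0:
        return Profile(coords=profile.coords.copy(), u=profile.u.copy(),
                       v=profile.v.copy(), Uc=profile.Uc)
    rng = np.random.default_rng(seed)
    s = sigma * profile.Uc
    return Profile(
        coords=profile.coords.copy(),
        u=profile.u + rng.normal(0.0, s, profile.u.shape),
        v=profile.v + rng.normal(0.0, s, profile.v.shape),
        Uc=profile.Uc,
    )
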