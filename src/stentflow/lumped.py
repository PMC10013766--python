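"""Zero-dimensional hydraulics of the stented ureter and design numbers.

The large-scale behaviour of a stented ureter is well captured by treating
the stent–ureter gap as a coaxial annulus.  This module provides the
analytic annular flow rate, the geometry factor zeta that makes the laminar
Darcy law f = 64 zeta / Re_Dh exact for that annulus (hydraulic diameter
Dh = D - Do), minor-loss coefficients for the sudden contraction/expansion
at the stent lumen inlet/outlet, the pigtail inlet-loss scaling K ~ s/Ds,
and the dimensionless numbers used to design a flow bench (Reynolds number
matching, tracer particle response time and Stokes number).

All functions are pure and work in SI units; convenience converters for mm
and ml/min are provided at the interface.  Degenerate geometries (Do -> 0,
Ds -> D) are handled by explicit limits rather than evaluating singular
expressions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "LumpedCase",
    "DesignNumbers",
    "annular_bracket",
    "annular_flow_rate",
    "friction_zeta",
    "friction_factor",
    "pressure_loss",
    "loss_coefficients",
    "stent_size_sweep",
    "pigtail_loss_scale",
    "design_numbers",
    "match_experiment_flow",
    "mm",
    "ml_per_min",
]

#: Default empirical constant for the sudden-contraction coefficient Kc;
#: standard textbook value ~0.42 for an abrupt circular contraction.
CONTRACTION_CONSTANT = 0.42


def mm(value: float) -> float:
    """Convert mm to m."""
    return value * 1e-3


def ml_per_min(q_m3s: float) -> float:
    """Convert m^3/s to ml/min."""
    return q_m3s * 6e7


@dataclass(frozen=True)
class LumpedCase:
    """Inputs of the 0D hydraulic network (SI units)."""

    D: float                    # ureter diameter, m
    Do: float                   # stent outer diameter, m
    L: float                    # conduit length, m
    mu: float                   # dynamic viscosity, Pa s
    rho: float                  # density, kg/m^3
    mean_velocity: float        # annular mean velocity U-bar, m/s
    Ds: Optional[float] = None  # stent lumen diameter, m
    K: Tuple[float, ...] = field(default_factory=tuple)  # minor losses
    contraction_c: float = CONTRACTION_CONSTANT
    protrusion_s: float = 0.0   # pigtail/tip protrusion, m

    def __post_init__(self) -> None:
        if not 0 < self.Do < self.D:
            raise ValueError("need 0 < Do < D")
        if self.Ds is not None and not 0 < self.Ds < self.D:
            raise ValueError("need 0 < Ds < D")
        if self.L <= 0 or self.mu <= 0 or self.rho <= 0:
            raise ValueError("L, mu, rho must be positive")
        if any(k < 0 for k in self.K):
            raise ValueError("minor-loss coefficients must be >= 0")

    @property
    def Dh(self) -> float:
        """Hydraulic diameter of the annulus, D - Do."""
        return self.D - self.Do

    @property
    def annulus_area(self) -> float:
        return math.pi * (self.D ** 2 - self.Do ** 2) / 4.0


@dataclass(frozen=True)
class DesignNumbers:
    """Dimensionless design numbers for a flow bench."""

    reynolds: float
    particle_response_time: float  # s
    stokes: float
    flow_rate: float               # m^3/s
    centerline_velocity: float     # m/s


def annular_bracket(D: float, Do: float) -> float:
    """Geometry bracket D^4 - Do^4 - (D^2 - Do^2)^2 / ln(D/Do).

    Returns D^4 (the Hagen–Poiseuille limit) for Do = 0.
    """
    if Do < 0 or Do >= D:
        raise ValueError("need 0 <= Do < D")
    if Do == 0.0:
        return D ** 4
    return D ** 4 - Do ** 4 - (D ** 2 - Do ** 2) ** 2 / math.log(D / Do)


def annular_flow_rate(D: float, Do: float, dpdx: float, mu: float) -> float:
    """Bulk flow rate of laminar flow in a coaxial annulus.

    Q = pi/(128 mu) (-dp/dx) [D^4 - Do^4 - (D^2-Do^2)^2 / ln(D/Do)].
    ``dpdx`` is the streamwise pressure gradient (negative for flow in +x).
    Do = 0 dispatches to the circular-pipe (Hagen–Poiseuille) limit.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    return math.pi / (128.0 * mu) * (-dpdx) * annular_bracket(D, Do)


def friction_zeta(D: float, Do: float) -> float:
    """Annulus correction zeta = (D-Do)^2 (D^2-Do^2) / bracket.

    Makes f = 64 zeta / Re_Dh exact for the annulus.  zeta -> 1 as Do -> 0
    (circular pipe, f Re = 64) and -> 3/2 as Do -> D (plane channel,
    f Re = 96).  Do = D is a degenerate 0/0 and raises.
    """
    if Do == 0.0:
        return 1.0
    if not 0 < Do < D:
        raise ValueError("need 0 <= Do < D; the Do = D annulus is "
                         "degenerate (use the plane-channel limit 3/2)")
    return (D - Do) ** 2 * (D ** 2 - Do ** 2) / annular_bracket(D, Do)


def friction_factor(zeta: float, Re_Dh: float) -> float:
    """Laminar Darcy friction factor f = 64 zeta / Re_Dh."""
    if Re_Dh <= 0:
        raise ValueError("Re_Dh must be > 0")
    return 64.0 * zeta / Re_Dh


def pressure_loss(case: LumpedCase) -> Tuple[float, float, float]:
    """Total pressure loss P_L = P_viscosity + P_minor over the conduit.

    P_viscosity = f (L/Dh) rho U^2/2 with the annulus-exact f;
    P_minor = sum_j K_j rho U^2/2.  Returns (P_L, P_viscosity, P_minor), Pa.
    """
    U = case.mean_velocity
    Re = abs(U) * case.Dh * case.rho / case.mu
    dyn = case.rho * U * abs(U) / 2.0
    if Re == 0.0:
        p_visc = 0.0
    else:
        f = friction_factor(friction_zeta(case.D, case.Do), Re)
        p_visc = f * case.L / case.Dh * dyn
    p_minor = sum(case.K) * dyn
    return p_visc + p_minor, p_visc, p_minor


def loss_coefficients(Ds: float, D: float,
                      c: float = CONTRACTION_CONSTANT) -> Tuple[float, float]:
    """Sudden contraction/expansion coefficients at the stent lumen ends.

    Kc ≈ c (1 - Ds^2/D^2) at the inlet, Ke = (1 - Ds^2/D^2)^2 at the
    outlet.  Both vanish as Ds -> D.
    """
    if not 0 < Ds <= D:
        raise ValueError("need 0 < Ds <= D")
    beta = 1.0 - (Ds / D) ** 2
    return c * beta, beta ** 2


def pigtail_loss_scale(s: float, Ds: float) -> Tuple[float, str]:
    """Inlet-loss scaling K ~ s/Ds for a stent protruding/curling a length s.

    Returns the dimensionless scale and an interpretation flag:
    values >> 1 mean the inlet loss is protrusion-dominated, further
    impeding the luminal flow.
    """
    if s < 0 or Ds <= 0:
        raise ValueError("need s >= 0 and Ds > 0")
    scale = s / Ds
    flag = "protrusion-dominated inlet loss" if scale > 1.0 else "minor"
    return scale, flag


def stent_size_sweep(D: float, Do_grid: Sequence[float],
                     mode: str = "both") -> pd.DataFrame:
    """Relative flow rate and friction factor over a stent-size grid.

    Q(Do)/Q(ref) at constant pressure gradient and f(Do)/f(ref) at constant
    mean velocity, both relative to the first grid point.  ``mode`` selects
    'constant_dpdx' (Q only), 'constant_U' (f only) or 'both'.
    """
    Do_grid = list(Do_grid)
    if not Do_grid or not all(0 < d < D for d in Do_grid):
        raise ValueError("Do grid must lie in (0, D)")
    if mode not in ("both", "constant_dpdx", "constant_U"):
        raise ValueError(f"unknown mode {mode!r}")
    ref = Do_grid[0]
    br_ref = annular_bracket(D, ref)
    # at constant U-bar, f = 64 zeta nu / (U Dh) ~ zeta / Dh
    f_ref = friction_zeta(D, ref) / (D - ref)
    rows = []
    for Do in Do_grid:
        row = {"Do": Do}
        if mode in ("both", "constant_dpdx"):
            row["Q_ratio"] = annular_bracket(D, Do) / br_ref
        if mode in ("both", "constant_U"):
            row["f_ratio"] = friction_zeta(D, Do) / (D - Do) / f_ref
        rows.append(row)
    return pd.DataFrame(rows)


def design_numbers(Uc: float, D: float, nu: float, dp: float, rho_p: float,
                   mu: float, Q: Optional[float] = None) -> DesignNumbers:
    """Reynolds number, tracer response time and Stokes number (SI inputs).

    Re = Uc D / nu; tau_p = dp^2 rho_p / (18 mu); Stk = tau_p Uc / D.
    If ``Q`` is given, Uc is recomputed from pipe Poiseuille flow,
    Uc = 8 Q / (pi D^2) (twice the mean velocity).
    """
    if min(D, nu, dp, rho_p, mu) <= 0:
        raise ValueError("inputs must be positive")
    if Q is not None:
        Uc = 8.0 * Q / (math.pi * D ** 2)
    tau_p = dp ** 2 * rho_p / (18.0 * mu)
    return DesignNumbers(
        reynolds=Uc * D / nu,
        particle_response_time=tau_p,
        stokes=tau_p * Uc / D,
        flow_rate=Q if Q is not None else Uc / 2.0 * math.pi * D ** 2 / 4.0,
        centerline_velocity=Uc,
    )


def match_experiment_flow(Re_target: float, D: float, nu_exp: float) -> float:
    """Flow rate (ml/min) giving a pipe-Poiseuille centerline Reynolds number
    ``Re_target`` in a pipe of diameter D with working-fluid viscosity
    ``nu_exp`` (SI).  Uc = Re nu / D, Q = (Uc/2) pi D^2 / 4."""
    if min(Re_target, D, nu_exp) <= 0:
        raise ValueError("inputs must be positive")
    Uc = Re_target * nu_exp / D
    return ml_per_min(Uc / 2.0 * math.pi * D ** 2 / 4.0)
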