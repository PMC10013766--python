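"""Derived quantities from a flow field.

Implements the study's measurement chain: transverse-velocity extraction on
the stent outer surface, per-side-hole flux integrals and activation, the
luminal flux at the stent inlet, wall shear stress on the side-hole walls
by one-sided second-order finite differences, base-flow error metrics
against the Poiseuille reference, and nonparametric comparison of shear
distributions.

All functions accept any object with a ``velocity(x, r) -> (U, V)`` method
(a solved FlowField or an analytic ReferenceField), so every operation is
testable against closed-form fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import simpson
from scipy.stats import ranksums

from .geometry import SideHole, StentSpec

__all__ = [
    "UC_NORMALIZATION",
    "Q0_TOTAL_FLUX",
    "Profile",
    "SHFluxResult",
    "ShearStats",
    "ErrorMetrics",
    "sample_line",
    "sh_flux",
    "luminal_flux",
    "total_transverse_flux",
    "sh_wall_shear",
    "rank_sum_compare",
    "poiseuille_error",
    "aggregate_flux_shear",
]

#: Centerline velocity of the unstented channel flow (mm/s); default
#: normalization for velocities and fluxes.
UC_NORMALIZATION = 2.64

#: Total flux of the default case (inlet mean 0.235 mm/s x 30 mm), mm^2/s.
Q0_TOTAL_FLUX = 7.05

#: Side-hole activation threshold as a fraction of the total flux; fluxes
#: below the numerical-uncertainty level are treated as inactive.
ACTIVATION_FRACTION = 0.002


@dataclass
class Profile:
    """Sampled velocity profile along a line; coordinates in mm."""

    coords: np.ndarray
    u: np.ndarray
    v: np.ndarray
    Uc: float

    def __post_init__(self) -> None:
        d = np.diff(self.coords)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("profile coordinates must be strictly monotone")

    @property
    def u_tilde(self) -> np.ndarray:
        return self.u / self.Uc

    @property
    def v_tilde(self) -> np.ndarray:
        return self.v / self.Uc


@dataclass(frozen=True)
class SHFluxResult:
    """Signed flux through one side hole (positive = out of the lumen)."""

    sh_index: int
    flux_Q_SH: float      # mm^2/s
    q_tilde: float        # window integral of V/Uc over x (mm)
    active: bool


@dataclass
class ShearStats:
    """Wall-shear-stress distribution at one side hole (Pa)."""

    sh_index: int
    samples: np.ndarray
    median: float
    q1: float
    q3: float

    @classmethod
    def from_samples(cls, sh_index: int, samples: np.ndarray) -> "ShearStats":
        q1, med, q3 = np.percentile(samples, [25, 50, 75])
        return cls(sh_index=sh_index, samples=np.asarray(samples),
                   median=float(med), q1=float(q1), q3=float(q3))


@dataclass(frozen=True)
class ErrorMetrics:
    """Root-mean-square errors of normalized profiles (fractions)."""

    eps_u: float
    eps_v: float
    n_samples: int


def _domain_of(fld):
    mesh = getattr(fld, "mesh", None)
    return getattr(mesh, "domain", None)


def sample_line(fld, x_range: Tuple[float, float], r: float, n: int,
                Uc: float = UC_NORMALIZATION) -> Profile:
    """Sample U and V at ``n`` uniform points on the horizontal line ``r``.

    Raises if a sample point falls in the stent solid (the field's point
    evaluation names the offending point).
    """
    xs = np.linspace(x_range[0], x_range[1], n)
    u, v = fld.velocity(xs, np.full(n, r))
    return Profile(coords=xs, u=u, v=v, Uc=Uc)


def sh_flux(fld, sh: SideHole, Uc: float = UC_NORMALIZATION,
            window: float = 1.0, n: int = 401,
            r_line: Optional[float] = None, q0: Optional[float] = None,
            activation_fraction: float = ACTIVATION_FRACTION) -> SHFluxResult:
    """Signed side-hole flux from the transverse velocity on the stent
    outer surface.

    Integrates V over ``x_SH ± window`` (default ±1 mm) along the line
    ``r_line`` (default: the stent outer surface).  The sign convention is
    V > 0 upward, i.e. out of the lumen.  ``active`` is set when |Q_SH|
    exceeds ``activation_fraction`` of the total flux ``q0``.
    """
    if n < 200:
        raise ValueError("quadrature resolution must be >= 200 points")
    dom = _domain_of(fld)
    if r_line is None:
        r_line = dom.stent_top if dom is not None and dom.stent is not None else 0.0
    if dom is not None and dom.stent is not None:
        for other in dom.stent.side_holes:
            if other.index != sh.index and (
                abs(other.x_center - sh.x_center)
                < window + 0.5 * other.diameter_DSH
            ):
                raise ValueError(
                    f"±{window} mm window of SH{sh.index} overlaps "
                    f"SH{other.index}"
                )
    if q0 is None:
        bc = getattr(fld, "bc", None)
        if bc is not None and dom is not None:
            q0 = bc.inlet_mean_velocity * dom.ureter.cone_mouth_width
        else:
            q0 = Q0_TOTAL_FLUX
    xs = np.linspace(sh.x_center - window, sh.x_center + window, n)
    _, v = fld.velocity(xs, np.full(n, r_line))
    q_sh = float(simpson(v, x=xs))
    return SHFluxResult(
        sh_index=sh.index,
        flux_Q_SH=q_sh,
        q_tilde=q_sh / Uc,
        active=abs(q_sh) > activation_fraction * abs(q0),
    )


def luminal_flux(fld, stent: StentSpec, x: Optional[float] = None,
                 n: int = 401) -> float:
    """Streamwise flux through the lumen opening at the stent inlet tip.

    Integrates U over the lumen cross-section (mm^2/s, signed).  The
    integration line defaults to the tip x = -s; a line through the stent
    solid raises via the field's point evaluation.
    """
    dom = _domain_of(fld)
    if dom is not None and dom.stent is not None:
        r_lo, r_hi = dom.lumen_bottom, dom.lumen_top
        if x is None:
            x = dom.stent_x_min
    else:
        # stand-alone stent spec against an analytic field: assume the
        # default 4 mm ureter so the lumen is centred on r = -1 - (Ds-1)/2
        D = 4.0
        r_lo = -D / 2 + stent.wall_thickness
        r_hi = r_lo + stent.lumen_diameter_Ds
        if x is None:
            x = -stent.protrusion_s
    rs = np.linspace(r_lo, r_hi, n)
    u, _ = fld.velocity(np.full(n, x), rs)
    return float(simpson(u, x=rs))


def total_transverse_flux(results: Iterable[SHFluxResult]) -> float:
    """Q_t = sum of |Q_SH| over all side holes (magnitude sum, mm^2/s)."""
    return float(sum(abs(r.flux_Q_SH) for r in results))


def sh_wall_shear(fld, sh: SideHole, fluid, n_samples: int = 50,
                  delta: Optional[float] = None,
                  r_lo: Optional[float] = None,
                  r_hi: Optional[float] = None) -> ShearStats:
    """Wall shear stress on both side walls of a side-hole channel.

    tau = mu |dV/dx| evaluated at x = x_SH ± D_SH/2 by a one-sided
    second-order (3-point) finite difference into the fluid, at
    ``n_samples`` uniformly spaced r per wall (pooled).  The magnitude is
    used so that the two walls' opposite-signed gradients pool into one
    distribution.  ``delta`` defaults to D_SH/100; the stencil (2 delta)
    stays well inside the hole.
    """
    mu = getattr(fluid, "dynamic_viscosity_mu", fluid)
    if delta is None:
        delta = sh.diameter_DSH / 100.0
    if 2.0 * delta >= sh.diameter_DSH:
        raise ValueError("FD stencil wider than the side hole; shrink delta")
    dom = _domain_of(fld)
    if r_lo is None or r_hi is None:
        if dom is not None and dom.stent is not None:
            r_lo, r_hi = dom.lumen_top, dom.stent_top
        else:
            r_lo, r_hi = -0.5, 0.0
    rs = np.linspace(r_lo, r_hi, n_samples)
    taus = []
    for x_wall, sgn in ((sh.x_min, +1.0), (sh.x_max, -1.0)):
        xs = np.array([x_wall, x_wall + sgn * delta, x_wall + 2 * sgn * delta])
        for r in rs:
            _, v = fld.velocity(xs, np.full(3, r))
            dvdx = sgn * (-3.0 * v[0] + 4.0 * v[1] - v[2]) / (2.0 * delta)
            taus.append(abs(mu * dvdx))
    return ShearStats.from_samples(sh.index, np.asarray(taus))


def rank_sum_compare(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two shear-stress samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    return float(ranksums(a, b).pvalue)


def poiseuille_error(profile: Profile, reference: Profile) -> ErrorMetrics:
    """RMS base-flow error metrics on normalized profiles.

    eps_u is the RMS of (U~ - U~*) and eps_v the RMS of V~, both as
    fractions of the centerline velocity.  Profiles must share sample
    points and normalization; no silent interpolation.
    """
    if len(profile.coords) != len(reference.coords) or not np.allclose(
        profile.coords, reference.coords, rtol=0, atol=1e-12
    ):
        raise ValueError("profiles are sampled on different grids")
    if not np.isclose(profile.Uc, reference.Uc):
        raise ValueError("profiles use different normalization constants")
    du = profile.u_tilde - reference.u_tilde
    eps_u = float(np.sqrt(np.mean(du ** 2)))
    eps_v = float(np.sqrt(np.mean(profile.v_tilde ** 2)))
    return ErrorMetrics(eps_u=eps_u, eps_v=eps_v, n_samples=len(du))


def aggregate_flux_shear(
    cases: Sequence[Tuple[StentSpec, Sequence[SHFluxResult],
                          Sequence[ShearStats]]]
) -> pd.DataFrame:
    """Long-format flux/shear table, one row per (case, side hole).

    Columns: Ds, DSH, sh_index, Q_SH, tau_median, tau_q1, tau_q3, active.
    This is the source data of the flux-versus-shear scatter.
    """
    if len(cases) == 0:
        raise ValueError("need at least one case")
    rows = []
    for stent, fluxes, shears in cases:
        by_idx = {s.sh_index: s for s in shears}
        for fr in fluxes:
            st = by_idx.get(fr.sh_index)
            sh = next(h for h in stent.side_holes if h.index == fr.sh_index)
            rows.append({
                "Ds": stent.lumen_diameter_Ds,
                "DSH": sh.diameter_DSH,
                "sh_index": fr.sh_index,
                "Q_SH": fr.flux_Q_SH,
                "q_tilde": fr.q_tilde,
                "tau_median": st.median if st else np.nan,
                "tau_q1": st.q1 if st else np.nan,
                "tau_q3": st.q3 if st else np.nan,
                "active": fr.active,
            })
    return pd.DataFrame(rows)
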