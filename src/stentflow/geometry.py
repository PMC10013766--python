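"""Parametric 2D geometry of a stented ureter and its triangular mesh.

The model is the median (x–r) plane of a rigid, straight ureter with a
double-J-type stent resting on its lower wall.  Coordinates are in mm:
``x`` streamwise with 0 at the ureter inlet, ``r`` transverse with 0 on the
ureter axis (positive up).  The stent is a straight tube whose wall carries a
row of side holes (SHs) facing up, i.e. toward the extraluminal channel
between the stent and the upper ureter wall.  Conical chambers at both ends
emulate the renal-pelvis (UPJ) and bladder (UVJ) junctions; the stent tips
protrude into them.

The mesh generator is block-structured: the domain decomposes into
horizontal bands (cone expansions, stent wall, lumen, side-hole band,
extraluminal channel) that share one global, graded x-grid, so every
material interface coincides exactly with grid lines.  Cells are classified
fluid/solid by band and split into triangles; boundary facets are tagged by
geometric predicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "SideHole",
    "UreterSpec",
    "StentSpec",
    "Domain2D",
    "Mesh2D",
    "default_case",
    "build_domain",
    "generate_mesh",
]

_GEOM_TOL = 1e-9

# Default dimensions of the bench model (mm).
URETER_LENGTH = 270.6
URETER_DIAMETER = 4.0
STENT_OUTER_DIAMETER = 2.0
STENT_PROTRUSION = 14.7
SH_SPACING = 35.0
SH1_X = 12.8
N_SIDE_HOLES = 8
CONE_MOUTH_WIDTH = 30.0  # makes inlet flux Q0 = 0.235 mm/s * 30 mm = 7.05 mm^2/s
CONE_LENGTH = 20.0


@dataclass(frozen=True)
class SideHole:
    """One side hole: a slot through the upper stent wall.

    ``x_center`` is in ureter coordinates (mm); ``diameter_DSH`` is the slot
    width (the in-plane trace of the drilled hole diameter).
    """

    index: int
    x_center: float
    diameter_DSH: float

    def __post_init__(self) -> None:
        if self.diameter_DSH <= 0:
            raise ValueError(f"SH{self.index}: diameter_DSH must be > 0")

    @property
    def x_min(self) -> float:
        return self.x_center - 0.5 * self.diameter_DSH

    @property
    def x_max(self) -> float:
        return self.x_center + 0.5 * self.diameter_DSH


@dataclass(frozen=True)
class UreterSpec:
    """Rigid straight ureter with conical end chambers (all lengths mm)."""

    length_L: float = URETER_LENGTH
    diameter_D: float = URETER_DIAMETER
    cone_mouth_width: float = CONE_MOUTH_WIDTH
    cone_length: float = CONE_LENGTH

    def __post_init__(self) -> None:
        if self.length_L <= 0 or self.diameter_D <= 0 or self.cone_length <= 0:
            raise ValueError("ureter dimensions must be positive")
        if self.cone_mouth_width < self.diameter_D:
            raise ValueError("cone_mouth_width must be >= diameter_D")


@dataclass(frozen=True)
class StentSpec:
    """Straight stent with an ordered row of upward-facing side holes."""

    outer_diameter_Do: float = STENT_OUTER_DIAMETER
    lumen_diameter_Ds: float = 1.0
    protrusion_s: float = STENT_PROTRUSION
    side_holes: Tuple[SideHole, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0 < self.lumen_diameter_Ds < self.outer_diameter_Do:
            raise ValueError("need 0 < Ds < Do")
        if self.protrusion_s < 0:
            raise ValueError("protrusion_s must be >= 0")
        xs = [sh.x_center for sh in self.side_holes]
        if xs != sorted(xs):
            raise ValueError("side holes must be sorted by x_center")
        for a, b in zip(self.side_holes, self.side_holes[1:]):
            if a.x_max >= b.x_min:
                raise ValueError(
                    f"side holes SH{a.index} and SH{b.index} overlap"
                )

    @property
    def wall_thickness(self) -> float:
        """Stent wall thickness t = (Do - Ds) / 2 (mm)."""
        return 0.5 * (self.outer_diameter_Do - self.lumen_diameter_Ds)


def default_case(DSH: float, Ds: float) -> Tuple[UreterSpec, StentSpec]:
    """Specs of the bench geometry for a given side-hole and lumen diameter.

    Eight side holes spaced 35 mm apart, SH1 at x = 12.8 mm (hence SH8 at
    x = 257.8 mm), stent Do = 2 mm protruding 14.7 mm beyond the 270.6 mm
    ureter at each end.

    Parameters are in mm.  ``DSH`` may exceed ``Ds`` (the widest hole studied
    on the bench is 1.1 mm against a 1 mm lumen) but a slot as wide as the
    hole spacing is rejected.
    """
    if DSH <= 0:
        raise ValueError("DSH must be > 0")
    if DSH >= SH_SPACING:
        raise ValueError("side-hole channel wider than the 35 mm hole spacing")
    ureter = UreterSpec()
    if DSH >= STENT_OUTER_DIAMETER * 2:
        raise ValueError("DSH implausibly large for a 2 mm stent")
    holes = tuple(
        SideHole(index=i + 1, x_center=SH1_X + SH_SPACING * i, diameter_DSH=DSH)
        for i in range(N_SIDE_HOLES)
    )
    stent = StentSpec(lumen_diameter_Ds=Ds, side_holes=holes)
    # side holes must lie on the straight segment
    if holes[0].x_min <= 0 or holes[-1].x_max >= ureter.length_L:
        raise ValueError("side holes must lie within the straight ureter")
    return ureter, stent


@dataclass(frozen=True)
class Domain2D:
    """Fluid domain on the median plane, with derived band coordinates.

    The stent (when present) rests on the lower ureter wall: its solid
    occupies r in [-D/2, -D/2 + Do], the lumen is the band
    [-D/2 + t, -D/2 + t + Ds] and each side hole is a rectangular slot
    spanning the upper wall band [-t', 0] (t' = wall thickness) wherever
    Do = D/2; in general the slot ends on the stent outer surface r_so.
    """

    ureter: UreterSpec
    stent: Optional[StentSpec] = None

    # ---- derived coordinates -------------------------------------------------
    @property
    def x_min(self) -> float:
        return -self.ureter.cone_length

    @property
    def x_max(self) -> float:
        return self.ureter.length_L + self.ureter.cone_length

    @property
    def r_wall(self) -> float:
        return 0.5 * self.ureter.diameter_D

    @property
    def stent_bottom(self) -> float:
        return -self.r_wall

    @property
    def stent_top(self) -> float:
        assert self.stent is not None
        return -self.r_wall + self.stent.outer_diameter_Do

    @property
    def lumen_bottom(self) -> float:
        assert self.stent is not None
        return -self.r_wall + self.stent.wall_thickness

    @property
    def lumen_top(self) -> float:
        assert self.stent is not None
        return self.lumen_bottom + self.stent.lumen_diameter_Ds

    @property
    def stent_x_min(self) -> float:
        assert self.stent is not None
        return -self.stent.protrusion_s

    @property
    def stent_x_max(self) -> float:
        assert self.stent is not None
        return self.ureter.length_L + self.stent.protrusion_s

    # ---- walls ---------------------------------------------------------------
    def f_bot(self, x):
        """Lower wall r-coordinate (vectorized, mm)."""
        x = np.asarray(x, dtype=float)
        u = self.ureter
        expand = 0.5 * (u.cone_mouth_width - u.diameter_D)
        frac = np.maximum(0.0, np.maximum(-x, x - u.length_L)) / u.cone_length
        return -self.r_wall - expand * np.minimum(frac, 1.0)

    def f_top(self, x):
        """Upper wall r-coordinate (vectorized, mm)."""
        return -self.f_bot(x)

    def in_slot(self, x: float) -> bool:
        if self.stent is None:
            return False
        return any(sh.x_min < x < sh.x_max for sh in self.stent.side_holes)

    def in_fluid(self, x, r) -> np.ndarray:
        """Pointwise fluid-region indicator (open region, vectorized)."""
        x = np.asarray(x, dtype=float)
        r = np.asarray(r, dtype=float)
        inside = (
            (x > self.x_min) & (x < self.x_max)
            & (r > self.f_bot(x)) & (r < self.f_top(x))
        )
        if self.stent is None:
            return inside
        in_span = (x > self.stent_x_min) & (x < self.stent_x_max)
        in_outer = (r > self.stent_bottom - _GEOM_TOL) & (r < self.stent_top)
        in_lumen = (r > self.lumen_bottom) & (r < self.lumen_top)
        in_sh = np.zeros_like(inside)
        for sh in self.stent.side_holes:
            in_sh |= (
                (x > sh.x_min) & (x < sh.x_max)
                & (r > self.lumen_top) & (r < self.stent_top)
            )
        solid = in_span & in_outer & ~in_lumen & ~in_sh
        return inside & ~solid

    def area(self, nx: int = 2000, nr: int = 400) -> float:
        """Fluid area by midpoint quadrature on a fine grid (mm^2)."""
        xs = np.linspace(self.x_min, self.x_max, nx + 1)
        rb = self.f_bot(np.array([self.x_min]))[0]
        rs = np.linspace(rb, -rb, nr + 1)
        xm = 0.5 * (xs[:-1] + xs[1:])
        rm = 0.5 * (rs[:-1] + rs[1:])
        X, R = np.meshgrid(xm, rm, indexing="ij")
        mask = self.in_fluid(X.ravel(), R.ravel()).reshape(X.shape)
        return float(mask.sum() * (xs[1] - xs[0]) * (rs[1] - rs[0]))


def build_domain(ureter: UreterSpec, stent: Optional[StentSpec] = None) -> Domain2D:
    """Assemble and validate the median-plane fluid domain.

    Raises ``ValueError`` naming the offending feature on geometric
    inconsistency (tips longer than the cones, holes off the straight
    segment, slot overlapping a stent tip, stent taller than the ureter).
    """
    if stent is not None:
        if stent.outer_diameter_Do > ureter.diameter_D:
            raise ValueError("stent outer diameter exceeds ureter diameter")
        if stent.protrusion_s >= ureter.cone_length:
            raise ValueError("stent protrusion reaches beyond the cone chamber")
        for sh in stent.side_holes:
            if sh.x_min <= 0 or sh.x_max >= ureter.length_L:
                raise ValueError(
                    f"SH{sh.index} slot leaves the straight ureter segment"
                )
    return Domain2D(ureter=ureter, stent=stent)


# =============================================================================
# Meshing
# =============================================================================

@dataclass
class Mesh2D:
    """Triangular mesh with tagged boundary facets.

    ``points`` (n, 2) in mm; ``triangles`` (m, 3) CCW vertex indices;
    ``facets`` maps tag -> (k, 2) arrays of boundary vertex pairs.  Tags:
    ``inlet``, ``outlet``, ``ureter_wall``, ``stent_outer_wall``,
    ``stent_lumen_wall`` and ``sh_wall_<i>`` per side hole.
    """

    points: np.ndarray
    triangles: np.ndarray
    facets: Dict[str, np.ndarray]
    h_global: float
    h_sh: float
    domain: Domain2D

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    def facet_length(self, tag: str) -> float:
        f = self.facets[tag]
        if len(f) == 0:
            return 0.0
        d = self.points[f[:, 0]] - self.points[f[:, 1]]
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def boundary_length(self) -> float:
        return sum(self.facet_length(t) for t in self.facets)

    def wall_tags(self) -> Tuple[str, ...]:
        return tuple(t for t in self.facets if t not in ("inlet", "outlet"))


def _graded_axis(breaks: Sequence[float], zones: Sequence[Tuple[float, float, float]],
                 h_default: float) -> np.ndarray:
    """1D grid through all breakpoints, spacing h_default except in zones."""
    lo, hi = min(breaks), max(breaks)
    all_breaks = list(breaks) + [
        min(max(z, lo), hi) for za, zb, _ in zones for z in (za, zb)
    ]
    pts = np.array(sorted(set(round(b, 12) for b in all_breaks)))
    out = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        h = h_default
        for za, zb, zh in zones:
            if za < b - 1e-12 and zb > a + 1e-12:
                h = min(h, zh)
        n = max(1, int(math.ceil((b - a) / h - 1e-9)))
        out.extend(np.linspace(a, b, n + 1)[1:])
    return np.asarray(out)


def generate_mesh(domain: Domain2D, h_global: float = 1.0,
                  h_sh: float = 0.1) -> Mesh2D:
    """Graded block-structured triangle mesh of the fluid domain.

    ``h_global`` is the streamwise element size far from features;
    ``h_sh`` the size inside and within 2 D_SH of every side hole.  Stent
    tips and cone/ureter junctions get an intermediate size.  All material
    interfaces fall on grid lines, so fluid/solid classification by cell
    centroid is exact.
    """
    if not 0 < h_sh <= h_global:
        raise ValueError("need 0 < h_sh <= h_global")
    u, st = domain.ureter, domain.stent
    L = u.length_L

    # ---- x-grid --------------------------------------------------------------
    breaks = [domain.x_min, 0.0, L, domain.x_max]
    zones = []
    h_tip = min(h_global, max(2.0 * h_sh, 0.15))
    if st is not None:
        breaks += [domain.stent_x_min, domain.stent_x_max]
        for sh in st.side_holes:
            breaks += [sh.x_min, sh.x_max]
            zones.append((sh.x_center - 2 * sh.diameter_DSH,
                          sh.x_center + 2 * sh.diameter_DSH, h_sh))
        zones.append((domain.stent_x_min - 2.0, 2.0, h_tip))
        zones.append((L - 2.0, domain.stent_x_max + 2.0, h_tip))
    else:
        zones.append((-2.0, 2.0, h_tip))
        zones.append((L - 2.0, L + 2.0, h_tip))
    xs = _graded_axis(breaks, zones, h_global)
    ncol = len(xs)

    # ---- r-bands (bottom to top); each contributes rows of the global grid ---
    h_cross = min(0.25, max(h_global / 4.0, 2.0 * h_sh))
    D2 = domain.r_wall

    def nrows(thickness: float, target: float, nmin: int, nmax: int = 64) -> int:
        return int(min(nmax, max(nmin, math.ceil(thickness / target))))

    bands = []  # (kind, r_lo, r_hi, nrows); kind in {const, cone_bot, cone_top,
    #             lower_wall, lumen, slot, extra}
    n_cone = 6
    bands.append(("cone_bot", None, -D2, n_cone))
    if st is None:
        bands.append(("const", -D2, D2, nrows(2 * D2, h_cross, 10)))
    else:
        t = st.wall_thickness
        bands.append(("lower_wall", -D2, domain.lumen_bottom, nrows(t, h_cross, 3, 12)))
        bands.append(("lumen", domain.lumen_bottom, domain.lumen_top,
                      nrows(st.lumen_diameter_Ds, h_cross, 6, 24)))
        slot_h = domain.stent_top - domain.lumen_top
        bands.append(("slot", domain.lumen_top, domain.stent_top,
                      nrows(slot_h, max(h_sh, slot_h / 16.0), 4, 16)))
        bands.append(("extra", domain.stent_top, D2,
                      nrows(D2 - domain.stent_top, h_cross, 8, 32)))
    bands.append(("cone_top", D2, None, n_cone))

    # Row coordinates per column: R[col, row]
    fb = domain.f_bot(xs)
    ft = domain.f_top(xs)
    rows = []
    for kind, r_lo, r_hi, n in bands:
        if kind == "cone_bot":
            block = fb[:, None] + (-D2 - fb[:, None]) * (np.arange(n + 1) / n)
        elif kind == "cone_top":
            block = D2 + (ft[:, None] - D2) * (np.arange(n + 1) / n)
        else:
            rr = np.linspace(r_lo, r_hi, n + 1)
            block = np.broadcast_to(rr, (ncol, n + 1)).copy()
        if rows:
            block = block[:, 1:]  # shared row with previous band
        rows.append(block)
    band_of_row_interval = []
    for kind, _, _, n in bands:
        band_of_row_interval.extend([kind] * n)
    R = np.concatenate(rows, axis=1)
    nrow = R.shape[1]
    assert len(band_of_row_interval) == nrow - 1

    X = np.broadcast_to(xs[:, None], R.shape)

    # ---- classify cells and triangulate --------------------------------------
    sh_slots = [] if st is None else [(sh.x_min, sh.x_max) for sh in st.side_holes]

    def node_id(i, j):
        return i * nrow + j

    tris = []
    for j in range(nrow - 1):
        kind = band_of_row_interval[j]
        for i in range(ncol - 1):
            xm = 0.5 * (xs[i] + xs[i + 1])
            if kind in ("lower_wall", "slot"):
                in_span = domain.stent_x_min < xm < domain.stent_x_max
                if kind == "lower_wall":
                    if in_span:
                        continue
                else:  # slot band: solid unless outside span or inside a hole
                    if in_span and not any(a < xm < b for a, b in sh_slots):
                        continue
            a = node_id(i, j)
            b = node_id(i + 1, j)
            c = node_id(i + 1, j + 1)
            d = node_id(i, j + 1)
            if (i + j) % 2 == 0:
                tris.append((a, b, c))
                tris.append((a, c, d))
            else:
                tris.append((a, b, d))
                tris.append((b, c, d))

    pts = np.column_stack([X.ravel(), R.ravel()])
    tris = np.asarray(tris, dtype=np.int64)

    # merge geometrically coincident nodes (cone pinch columns)
    key = np.round(pts / _GEOM_TOL).astype(np.int64)
    _, uniq_idx, inverse = np.unique(key, axis=0, return_index=True,
                                     return_inverse=True)
    pts = pts[uniq_idx]
    tris = inverse[tris]

    # drop degenerate triangles, enforce CCW
    v0 = pts[tris[:, 1]] - pts[tris[:, 0]]
    v1 = pts[tris[:, 2]] - pts[tris[:, 0]]
    area2 = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
    keep = np.abs(area2) > 1e-12
    tris = tris[keep]
    area2 = area2[keep]
    flip = area2 < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]

    # compact node numbering
    used = np.unique(tris)
    remap = -np.ones(len(pts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    pts = pts[used]
    tris = remap[tris]

    facets = _tag_boundary(pts, tris, domain)
    return Mesh2D(points=pts, triangles=tris, facets=facets,
                  h_global=h_global, h_sh=h_sh, domain=domain)


def _tag_boundary(pts: np.ndarray, tris: np.ndarray,
                  domain: Domain2D) -> Dict[str, np.ndarray]:
    """Find boundary edges (on exactly one triangle) and tag them."""
    edges = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    edges_sorted = np.sort(edges, axis=1)
    uniq, counts = np.unique(edges_sorted, axis=0, return_counts=True)
    bedges = uniq[counts == 1]

    mid = 0.5 * (pts[bedges[:, 0]] + pts[bedges[:, 1]])
    xm, rm = mid[:, 0], mid[:, 1]
    tol = 1e-7
    st = domain.stent

    tags = np.full(len(bedges), "ureter_wall", dtype=object)
    tags[np.abs(xm - domain.x_min) < tol] = "inlet"
    tags[np.abs(xm - domain.x_max) < tol] = "outlet"

    if st is not None:
        span = (xm > domain.stent_x_min - tol) & (xm < domain.stent_x_max + tol)
        on_top = np.abs(rm - domain.stent_top) < tol
        on_bot = np.abs(rm - domain.stent_bottom) < tol
        in_cone = (xm < 0.0) | (xm > domain.ureter.length_L)
        on_tip = (np.abs(xm - domain.stent_x_min) < tol) | \
                 (np.abs(xm - domain.stent_x_max) < tol)
        tip_band = (rm > domain.stent_bottom - tol) & (rm < domain.stent_top + tol)
        outer = span & (on_top | (on_bot & in_cone)) | (on_tip & tip_band)
        tags[outer] = "stent_outer_wall"
        lumen = span & ~on_tip & (
            (np.abs(rm - domain.lumen_bottom) < tol)
            | (np.abs(rm - domain.lumen_top) < tol)
        )
        tags[lumen] = "stent_lumen_wall"
        slot_band = (rm > domain.lumen_top - tol) & (rm < domain.stent_top + tol)
        for sh in st.side_holes:
            on_wall = slot_band & (
                (np.abs(xm - sh.x_min) < tol) | (np.abs(xm - sh.x_max) < tol)
            )
            tags[on_wall] = f"sh_wall_{sh.index}"

    facets: Dict[str, np.ndarray] = {}
    names = ["inlet", "outlet", "ureter_wall"]
    if st is not None:
        names += ["stent_outer_wall", "stent_lumen_wall"]
        names += [f"sh_wall_{sh.index}" for sh in st.side_holes]
    for name in names:
        facets[name] = bedges[tags == name]
    return facets
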