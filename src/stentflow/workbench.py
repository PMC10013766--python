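"""Case orchestration: single runs, the DSH/Ds design sweeps and reports.

A :class:`CaseConfig` captures everything a run needs (geometry, fluid,
boundary conditions, mesh sizes, post-processing options) and round-trips
losslessly through YAML, so every result can name the exact configuration
hash that produced it.  Runs are deterministic: identical configs give
byte-identical result rows and artifacts (no timestamps in data files).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from . import postprocess as post
from .geometry import build_domain, default_case, generate_mesh
from .solver import BoundaryConditions, FluidProps, solve_steady_flow

__all__ = ["CaseConfig", "CaseResult", "run_case", "design_case_grid",
           "run_design_sweeps", "report"]

#: The bench design sweeps: seven side-hole diameters at 1 mm lumen and
#: four at 0.8 mm lumen (mm).
DSH_GRID_DS1 = (0.4, 0.5, 0.7, 0.8, 0.9, 1.0, 1.1)
DSH_GRID_DS08 = (0.4, 0.5, 0.7, 1.0)

#: Desk-scale mesh defaults (mm): coarse streamwise size away from
#: features, fine size in/near the side holes.
H_GLOBAL_DESK = 1.0
H_SH_DESK = 0.05


@dataclass(frozen=True)
class CaseConfig:
    """Full configuration of one stented (or unstented) case."""

    DSH: Optional[float] = 1.0       # side-hole diameter, mm; None = unstented
    Ds: float = 1.0                  # stent lumen diameter, mm
    density_rho: float = 1000.0      # kg/m^3
    kinematic_viscosity_nu: float = 1.005e-6   # m^2/s
    inlet_mean_velocity: float = 0.235         # mm/s
    h_global: float = H_GLOBAL_DESK  # mm
    h_sh: float = H_SH_DESK          # mm
    rel_tol: float = 1e-8
    flux_window: float = 1.0         # mm, side-hole flux half-window
    shear_samples: int = 50          # per wall
    Uc: float = post.UC_NORMALIZATION
    outdir: Optional[str] = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CaseConfig":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "CaseConfig":
        return cls.from_dict(yaml.safe_load(text))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def fluid(self) -> FluidProps:
        return FluidProps(density_rho=self.density_rho,
                          kinematic_viscosity_nu=self.kinematic_viscosity_nu)

    def bc(self) -> BoundaryConditions:
        return BoundaryConditions(inlet_mean_velocity=self.inlet_mean_velocity)


@dataclass
class CaseResult:
    config: CaseConfig
    rows: pd.DataFrame
    summary: Dict[str, float]
    flow: object = None
    artifacts: Dict[str, str] = field(default_factory=dict)


def run_case(config: CaseConfig, keep_field: bool = True) -> CaseResult:
    """Mesh, solve and post-process one case.

    For a stented case the result has one row per side hole with the
    signed flux, activation flag and wall-shear quartiles, plus a summary
    with the luminal flux Q_i, the magnitude sum Q_t, the total flux Q0
    and the mass imbalance.  For an unstented case the summary carries the
    base-flow validation metrics (eps_u, eps_v against the Poiseuille
    profile).  Any stage failure raises with the stage named.
    """
    from .synthetic import pipe_poiseuille_profile

    try:
        ureter, stent = _specs(config)
        domain = build_domain(ureter, stent)
        mesh = generate_mesh(domain, h_global=config.h_global, h_sh=config.h_sh)
    except Exception as e:
        raise RuntimeError(f"[mesh] {e}") from e
    fluid, bc = config.fluid(), config.bc()
    try:
        fld = solve_steady_flow(mesh, fluid, bc, rel_tol=config.rel_tol)
    except Exception as e:
        raise RuntimeError(f"[solve] {e}") from e

    q0 = bc.inlet_mean_velocity * ureter.cone_mouth_width
    summary: Dict[str, float] = {
        "Q0": q0,
        "mass_imbalance": fld.mass_imbalance(),
        "n_elements": mesh.n_elements,
        "config_hash": config.config_hash,
    }
    rows: List[dict] = []
    try:
        if stent is None:
            xs_mid = 0.5 * ureter.length_L
            rr = np.linspace(-ureter.diameter_D / 2 + 1e-9,
                             ureter.diameter_D / 2 - 1e-9, 201)
            u, v = fld.velocity(np.full(rr.shape, xs_mid), rr)
            prof = post.Profile(coords=rr, u=u, v=v, Uc=config.Uc)
            # reference amplitude: exact centerline of the straight channel,
            # 1.5 x mean velocity with the mean set by mass conservation
            uc_exact = 1.5 * q0 / ureter.diameter_D
            ref = pipe_poiseuille_profile(uc_exact, ureter.diameter_D, rr)
            ref.Uc = config.Uc
            err = post.poiseuille_error(prof, ref)
            summary.update(eps_u=err.eps_u, eps_v=err.eps_v)
        else:
            fluxes, shears = [], []
            for sh in stent.side_holes:
                fr = post.sh_flux(fld, sh, Uc=config.Uc,
                                  window=config.flux_window)
                st = post.sh_wall_shear(fld, sh, fluid,
                                        n_samples=config.shear_samples)
                fluxes.append(fr)
                shears.append(st)
                rows.append({
                    "Ds": stent.lumen_diameter_Ds, "DSH": sh.diameter_DSH,
                    "sh_index": sh.index, "Q_SH": fr.flux_Q_SH,
                    "q_tilde": fr.q_tilde, "active": fr.active,
                    "tau_median": st.median, "tau_q1": st.q1, "tau_q3": st.q3,
                    "Q0": q0,
                })
            q_i = post.luminal_flux(fld, stent)
            summary.update(
                Q_i=q_i, Q_i_fraction=q_i / q0,
                Q_t=post.total_transverse_flux(fluxes),
            )
    except Exception as e:
        raise RuntimeError(f"[post] {e}") from e

    df = pd.DataFrame(rows)
    artifacts: Dict[str, str] = {}
    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        stem = f"case_{config.config_hash}"
        sio.field_to_vtu(out / f"{stem}.vtu", fld)
        (out / f"{stem}.yaml").write_text(config.to_yaml())
        df.to_csv(out / f"{stem}_rows.csv", index=False)
        (out / f"{stem}_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=float))
        artifacts = {k: str(out / f"{stem}{s}") for k, s in
                     [("field", ".vtu"), ("config", ".yaml"),
                      ("rows", "_rows.csv"), ("summary", "_summary.json")]}
    return CaseResult(config=config, rows=df, summary=summary,
                      flow=fld if keep_field else None, artifacts=artifacts)


def _specs(config: CaseConfig):
    from .geometry import UreterSpec

    if config.DSH is None:
        return UreterSpec(), None
    return default_case(config.DSH, config.Ds)


def design_case_grid(**overrides) -> List[CaseConfig]:
    """The 11 bench cases: DSH grid at Ds = 1 mm plus the Ds = 0.8 mm set."""
    cases = [CaseConfig(DSH=d, Ds=1.0, **overrides) for d in DSH_GRID_DS1]
    cases += [CaseConfig(DSH=d, Ds=0.8, **overrides) for d in DSH_GRID_DS08]
    return cases


def run_design_sweeps(cases: Optional[Sequence[CaseConfig]] = None,
                     **overrides) -> pd.DataFrame:
    """Run the design sweep and return the long-format result table.

    One row per (case, side hole) with fluxes, activation, shear quartiles
    and the case-level Q_i, Q_t, Q0.  Per-case failures are collected in an
    ``error`` column and the sweep continues.
    """
    if cases is None:
        cases = design_case_grid(**overrides)
    frames = []
    for cfg in cases:
        try:
            res = run_case(cfg, keep_field=False)
        except RuntimeError as e:
            frames.append(pd.DataFrame([{"Ds": cfg.Ds, "DSH": cfg.DSH,
                                         "error": str(e)}]))
            continue
        df = res.rows.copy()
        df["Q_i"] = res.summary.get("Q_i", np.nan)
        df["Q_t"] = res.summary.get("Q_t", np.nan)
        df["error"] = ""
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def report(sweep: pd.DataFrame, lumped: Optional[pd.DataFrame] = None,
           outdir: str = "report") -> Dict[str, str]:
    """Write the sweep's figure-source tables and plots plus a checklist.

    Produces the per-hole flux table, the flux-versus-median-shear scatter
    data and (when a lumped sweep table is given) the relative Q/f curves,
    as CSV plus PNG; returns the artifact paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, str] = {}

    ok = sweep[sweep.get("error", "") == ""] if "error" in sweep else sweep
    ok.to_csv(out / "sweep_rows.csv", index=False)
    artifacts["sweep_rows"] = str(out / "sweep_rows.csv")

    if len(ok):
        fig, ax = plt.subplots(figsize=(5, 4))
        ends = ok[ok.sh_index.isin([1, 8])]
        mids = ok[~ok.sh_index.isin([1, 8])]
        ax.scatter(mids.Q_SH, mids.tau_median, c="0.6", s=18, label="SH2-7")
        ax.scatter(ends.Q_SH, ends.tau_median, c="tab:blue", s=24,
                   label="SH1/SH8")
        ax.set_xlabel("$Q_{SH}$ (mm$^2$/s)")
        ax.set_ylabel(r"median $\tau_{wall}$ (Pa)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "flux_vs_shear.png", dpi=150)
        plt.close(fig)
        artifacts["flux_vs_shear"] = str(out / "flux_vs_shear.png")

    if lumped is not None and len(lumped):
        lumped.to_csv(out / "lumped_sweep.csv", index=False)
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(lumped.Do, lumped.Q_ratio, "k-", label="$Q/Q_{ref}$")
        ax.plot(lumped.Do, lumped.f_ratio, "b--", label="$f/f_{ref}$")
        ax.set_xlabel("$D_o$ (mm)")
        ax.set_yscale("log")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "stent_size_sweep.png", dpi=150)
        plt.close(fig)
        artifacts["lumped"] = str(out / "lumped_sweep.csv")
    else:
        print("report: no lumped table given; skipping the stent-size section")

    checklist = _checklist(ok)
    (out / "checklist.txt").write_text(checklist)
    print(checklist)
    artifacts["checklist"] = str(out / "checklist.txt")
    return artifacts


def _checklist(rows: pd.DataFrame) -> str:
    """Qualitative expectations of the physical picture, evaluated on a sweep."""
    lines = []

    def check(name, ok):
        lines.append(f"[{'PASS' if ok else 'FAIL'}] {name}")

    if len(rows) == 0:
        return "no successful cases\n"
    sh1 = rows[rows.sh_index == 1]
    sh8 = rows[rows.sh_index == 8]
    mid = rows[rows.sh_index.isin([4, 5])]
    check("SH1 flux into the lumen (negative)", bool((sh1.Q_SH < 0).all()))
    check("SH8 flux out of the lumen (positive)", bool((sh8.Q_SH > 0).all()))
    if len(mid):
        check("middle side holes inactive", bool((~mid.active).all()))
    for ds, grp in rows[rows.sh_index == 1].groupby("Ds"):
        if len(grp) > 1:
            g = grp.sort_values("DSH")
            check(f"|Q_SH1| increasing with DSH (Ds={ds})",
                  bool(np.all(np.diff(np.abs(g.Q_SH)) >= -1e-12)))
            check(f"median shear at SH1 decreasing with DSH (Ds={ds})",
                  bool(np.all(np.diff(g.tau_median) <= 1e-12)))
    return "\n".join(lines) + "\n"
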