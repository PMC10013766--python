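"""Mesh, field and spec serialization.

Writers for ASCII VTU (XML unstructured grid) and Gmsh .msh 4.1, a reader
for the .msh files this package writes, and YAML/JSON round-tripping of the
geometry specs.  The formats are standard interchange formats; the writers
here cover the subset this package produces (2D triangle meshes with
tagged boundary lines, nodal scalar fields).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import yaml

from .geometry import Domain2D, Mesh2D, SideHole, StentSpec, UreterSpec

__all__ = [
    "write_vtu",
    "field_to_vtu",
    "write_msh",
    "read_msh",
    "domain_to_dict",
    "domain_from_dict",
    "save_domain",
    "load_domain",
]

PathLike = Union[str, Path]


def write_vtu(path: PathLike, mesh: Mesh2D,
              point_data: Optional[Dict[str, np.ndarray]] = None) -> None:
    """Write the triangulation (and optional nodal scalars) as ASCII VTU."""
    pts = mesh.points
    tris = mesh.triangles
    n, m = len(pts), len(tris)
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        '  <UnstructuredGrid>',
        f'    <Piece NumberOfPoints="{n}" NumberOfCells="{m}">',
        '      <Points>',
        '        <DataArray type="Float64" NumberOfComponents="3" format="ascii">',
    ]
    lines += [f"          {x:.12g} {r:.12g} 0" for x, r in pts]
    lines += [
        '        </DataArray>',
        '      </Points>',
        '      <Cells>',
        '        <DataArray type="Int64" Name="connectivity" format="ascii">',
    ]
    lines += [f"          {a} {b} {c}" for a, b, c in tris]
    lines += [
        '        </DataArray>',
        '        <DataArray type="Int64" Name="offsets" format="ascii">',
        "          " + " ".join(str(3 * (i + 1)) for i in range(m)),
        '        </DataArray>',
        '        <DataArray type="UInt8" Name="types" format="ascii">',
        "          " + " ".join("5" for _ in range(m)),
        '        </DataArray>',
        '      </Cells>',
    ]
    if point_data:
        lines.append('      <PointData>')
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            lines.append(
                f'        <DataArray type="Float64" Name="{name}" format="ascii">'
            )
            lines.append("          " + " ".join(f"{v:.12g}" for v in arr))
            lines.append('        </DataArray>')
        lines.append('      </PointData>')
    lines += ['    </Piece>', '  </UnstructuredGrid>', '</VTKFile>', '']
    Path(path).write_text("\n".join(lines))


def field_to_vtu(path: PathLike, field) -> None:
    """Write a solved flow field's vertex values (U, V in mm/s; p in Pa)."""
    mesh = field.mesh
    nv = len(mesh.points)
    p_pa = field.fluid.density_rho * field.p_kin * 1e-6
    write_vtu(path, mesh, {
        "U": field.ux[:nv], "V": field.uy[:nv], "p": p_pa,
    })


def write_msh(path: PathLike, mesh: Mesh2D) -> None:
    """Write the mesh as Gmsh 4.1 ASCII with one physical group per tag.

    Boundary facets become 2-node line elements grouped by tag; the fluid
    triangles carry the physical surface 'fluid'.
    """
    tags = list(mesh.facets)
    phys = {name: i + 1 for i, name in enumerate(tags)}
    surf_phys = len(tags) + 1
    pts = mesh.points
    out = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat", "$PhysicalNames",
           str(len(tags) + 1)]
    for name, num in phys.items():
        out.append(f'1 {num} "{name}"')
    out.append(f'2 {surf_phys} "fluid"')
    out.append("$EndPhysicalNames")

    # one curve entity per tag + one surface entity
    out += ["$Entities", f"0 {len(tags)} 1 0"]
    for name in tags:
        num = phys[name]
        out.append(f"{num} 0 0 0 0 0 0 1 {num} 0")
    out.append(f"{surf_phys} 0 0 0 0 0 0 1 {surf_phys} 0")
    out.append("$EndEntities")

    # all nodes on the surface entity
    n = len(pts)
    out += ["$Nodes", f"1 {n} 1 {n}", f"2 {surf_phys} 0 {n}"]
    out += [str(i + 1) for i in range(n)]
    out += [f"{x:.12g} {r:.12g} 0" for x, r in pts]
    out.append("$EndNodes")

    blocks = [(1, phys[name], 1, mesh.facets[name]) for name in tags
              if len(mesh.facets[name])]
    blocks.append((2, surf_phys, 2, mesh.triangles))
    total = sum(len(b[3]) for b in blocks)
    out += ["$Elements", f"{len(blocks)} {total} 1 {total}"]
    eid = 1
    for dim, ent, etype, conn in blocks:
        out.append(f"{dim} {ent} {etype} {len(conn)}")
        for row in conn:
            out.append(f"{eid} " + " ".join(str(v + 1) for v in row))
            eid += 1
    out.append("$EndElements")
    out.append("")
    Path(path).write_text("\n".join(out))


def read_msh(path: PathLike):
    """Read nodes, triangles and tagged line facets from a 4.1 ASCII file.

    Returns ``(points, triangles, facets)`` mirroring the writer's content.
    """
    text = Path(path).read_text().splitlines()
    it = iter(text)

    def until(tag):
        for line in it:
            if line.strip() == tag:
                return
        raise ValueError(f"section {tag} not found")

    until("$PhysicalNames")
    n_names = int(next(it))
    names = {}
    for _ in range(n_names):
        dim, num, name = next(it).split(maxsplit=2)
        names[int(num)] = name.strip('"')
    until("$Nodes")
    header = next(it).split()
    n_nodes = int(header[1])
    next(it)  # single block header
    for _ in range(n_nodes):
        next(it)  # node ids are 1..n
    pts = np.array([[float(v) for v in next(it).split()[:2]]
                    for _ in range(n_nodes)])
    until("$Elements")
    n_blocks = int(next(it).split()[0])
    tris = []
    facets: Dict[str, list] = {}
    for _ in range(n_blocks):
        dim, ent, etype, count = (int(v) for v in next(it).split())
        rows = [[int(v) - 1 for v in next(it).split()[1:]]
                for _ in range(count)]
        if etype == 2:
            tris.extend(rows)
        else:
            facets.setdefault(names[ent], []).extend(rows)
    return (pts, np.asarray(tris, dtype=np.int64),
            {k: np.asarray(v, dtype=np.int64) for k, v in facets.items()})


# ---- spec serialization ------------------------------------------------------

def domain_to_dict(domain: Domain2D) -> dict:
    u = domain.ureter
    d = {"ureter": {"length_L": u.length_L, "diameter_D": u.diameter_D,
                    "cone_mouth_width": u.cone_mouth_width,
                    "cone_length": u.cone_length}}
    if domain.stent is not None:
        s = domain.stent
        d["stent"] = {
            "outer_diameter_Do": s.outer_diameter_Do,
            "lumen_diameter_Ds": s.lumen_diameter_Ds,
            "protrusion_s": s.protrusion_s,
            "side_holes": [
                {"index": h.index, "x_center": h.x_center,
                 "diameter_DSH": h.diameter_DSH} for h in s.side_holes
            ],
        }
    return d


def domain_from_dict(d: dict) -> Domain2D:
    ureter = UreterSpec(**d["ureter"])
    stent = None
    if "stent" in d:
        s = dict(d["stent"])
        holes = tuple(SideHole(**h) for h in s.pop("side_holes", []))
        stent = StentSpec(side_holes=holes, **s)
    return Domain2D(ureter=ureter, stent=stent)


def save_domain(path: PathLike, domain: Domain2D) -> None:
    p = Path(path)
    d = domain_to_dict(domain)
    if p.suffix in (".yaml", ".yml"):
        p.write_text(yaml.safe_dump(d, sort_keys=True))
    else:
        p.write_text(json.dumps(d, indent=2, sort_keys=True))


def load_domain(path: PathLike) -> Domain2D:
    p = Path(path)
    text = p.read_text()
    d = yaml.safe_load(text) if p.suffix in (".yaml", ".yml") else json.loads(text)
    return domain_from_dict(d)
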