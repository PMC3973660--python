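"""Plain-text mesh and result I/O: ASCII Gmsh MSH v2.2 and ASCII VTU.

Only the small subset of each format the pipeline needs is supported:
tetrahedra (4- and 10-node), boundary triangles with physical surface tags,
and per-cell/per-point data arrays in the VTU writer.
"""

from __future__ import annotations

import xml.sax.saxutils as _sax
from pathlib import Path

import numpy as np

from .mesh import LVMesh

# Gmsh element type codes
_MSH_TRI3, _MSH_TET4, _MSH_TRI6, _MSH_TET10 = 2, 4, 9, 11
# Gmsh tet10 ordering differs from VTK in one midside pair (8 <-> 9)
_GMSH_FROM_VTK_TET10 = [0, 1, 2, 3, 4, 5, 6, 7, 9, 8]

_SURFACE_IDS = {"endocardium": 1, "epicardium": 2, "base": 3}


def write_msh(mesh: LVMesh, path) -> None:
    """Write the mesh as ASCII Gmsh MSH v2.2 with tagged surfaces."""
    path = Path(path)
    tags = {t: _SURFACE_IDS.get(t, 10 + i)
            for i, t in enumerate(sorted(mesh.surfaces))}
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    if tags:
        lines += ["$PhysicalNames", str(len(tags) + 1)]
        for t, i in sorted(tags.items(), key=lambda kv: kv[1]):
            lines.append(f'2 {i} "{t}"')
        lines.append('3 100 "tissue"')
        lines.append("$EndPhysicalNames")
    lines += ["$Nodes", str(mesh.n_nodes)]
    for i, p in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {p[0]:.16g} {p[1]:.16g} {p[2]:.16g}")
    lines.append("$EndNodes")
    n_elem = mesh.n_elements + sum(len(f) for f in mesh.surfaces.values())
    lines += ["$Elements", str(n_elem)]
    eid = 1
    for t, faces in sorted(mesh.surfaces.items()):
        for f in faces:
            conn = " ".join(str(v + 1) for v in f)
            lines.append(f"{eid} {_MSH_TRI3} 2 {tags[t]} {tags[t]} {conn}")
            eid += 1
    etype = _MSH_TET4 if mesh.order == 1 else _MSH_TET10
    for tet in mesh.tets:
        conn = tet if mesh.order == 1 else tet[_GMSH_FROM_VTK_TET10]
        lines.append(f"{eid} {etype} 2 100 100 "
                     + " ".join(str(v + 1) for v in conn))
        eid += 1
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")


def read_msh(path) -> LVMesh:
    """Read an ASCII Gmsh MSH v2.2 file written by :func:`write_msh`."""
    text = Path(path).read_text().splitlines()
    it = iter(text)

    def until(tag):
        out = []
        for line in it:
            if line.strip() == tag:
                return out
            out.append(line)
        raise ValueError(f"truncated MSH file: missing {tag}")

    names = {}
    nodes = None
    tets, order = [], 1
    surfaces = {}
    for line in it:
        s = line.strip()
        if s == "$MeshFormat":
            fmt = until("$EndMeshFormat")[0].split()
            if not fmt[0].startswith("2.2"):
                raise ValueError(f"unsupported MSH version {fmt[0]}; "
                                 "only ASCII v2.2 is supported")
        elif s == "$PhysicalNames":
            body = until("$EndPhysicalNames")
            for rec in body[1:]:
                parts = rec.split(maxsplit=2)
                if len(parts) == 3 and parts[0] == "2":
                    names[int(parts[1])] = parts[2].strip().strip('"')
        elif s == "$Nodes":
            body = until("$EndNodes")
            n = int(body[0])
            nodes = np.array([[float(x) for x in r.split()[1:4]]
                              for r in body[1:n + 1]])
        elif s == "$Elements":
            body = until("$EndElements")
            for rec in body[1:]:
                parts = [int(x) for x in rec.split()]
                etype, ntags = parts[1], parts[2]
                conn = [v - 1 for v in parts[3 + ntags:]]
                phys = parts[3] if ntags else 0
                if etype == _MSH_TRI3:
                    surfaces.setdefault(names.get(phys, f"surface{phys}"),
                                        []).append(conn)
                elif etype == _MSH_TET4:
                    tets.append(conn)
                elif etype == _MSH_TET10:
                    # the VTK<->gmsh midside swap is an involution
                    tets.append([conn[i] for i in _GMSH_FROM_VTK_TET10])
                    order = 2
    if nodes is None or not tets:
        raise ValueError("MSH file contains no nodes or tetrahedra")
    return LVMesh(nodes=nodes, tets=np.asarray(tets, dtype=np.int64),
                  order=order,
                  surfaces={t: np.asarray(f, dtype=np.int64)
                            for t, f in surfaces.items()})


def write_vtu(mesh: LVMesh, path, point_data=None, cell_data=None) -> None:
    """Write an ASCII VTU (XML UnstructuredGrid) file.

    ``point_data`` / ``cell_data`` map names to (n,) or (n, 3) float arrays.
    """
    path = Path(path)
    vtk_type = 10 if mesh.order == 1 else 24
    npts, ncell = mesh.n_nodes, mesh.n_elements
    nper = mesh.tets.shape[1]

    def arr_txt(a):
        a = np.asarray(a)
        return " ".join(f"{x:.10g}" for x in a.ravel())

    def data_arrays(data):
        out = []
        for name, a in (data or {}).items():
            a = np.asarray(a, dtype=float)
            ncomp = 1 if a.ndim == 1 else a.shape[1]
            out.append(
                f'<DataArray type="Float64" Name="{_sax.escape(name)}" '
                f'NumberOfComponents="{ncomp}" format="ascii">'
                f"{arr_txt(a)}</DataArray>")
        return "\n".join(out)

    xml = f"""<?xml version="1.0"?>
<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">
<UnstructuredGrid>
<Piece NumberOfPoints="{npts}" NumberOfCells="{ncell}">
<Points>
<DataArray type="Float64" NumberOfComponents="3" format="ascii">{arr_txt(mesh.nodes)}</DataArray>
</Points>
<Cells>
<DataArray type="Int64" Name="connectivity" format="ascii">{arr_txt(mesh.tets).replace('.0', '')}</DataArray>
<DataArray type="Int64" Name="offsets" format="ascii">{" ".join(str(nper * (i + 1)) for i in range(ncell))}</DataArray>
<DataArray type="UInt8" Name="types" format="ascii">{" ".join([str(vtk_type)] * ncell)}</DataArray>
</Cells>
<PointData>
{data_arrays(point_data)}
</PointData>
<CellData>
{data_arrays(cell_data)}
</CellData>
</Piece>
</UnstructuredGrid>
</VTKFile>
"""
    path.write_text(xml)


def write_structure_table(path, theta, beta, regions=None) -> None:
    """Plain-text per-element table: element id, helix angle, sheet angle,
    region label."""
    import pandas as pd
    df = pd.DataFrame({
        "element": np.arange(len(theta)),
        "helix_angle_deg": theta,
        "sheet_angle_deg": beta,
    })
    if regions is not None:
        df["region"] = regions
    df.to_csv(path, index=False)


def write_observations_csv(path, obs) -> None:
    import pandas as pd
    v = obs.vectors
    pd.DataFrame({"element": np.arange(len(v)), "vx": v[:, 0],
                  "vy": v[:, 1], "vz": v[:, 2]}).to_csv(path, index=False)


def read_observations_csv(path):
    import pandas as pd
    from .microstructure import FibreObservationSet
    df = pd.read_csv(path)
    v = df[["vx", "vy", "vz"]].to_numpy(dtype=float)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return FibreObservationSet(vectors=v)
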