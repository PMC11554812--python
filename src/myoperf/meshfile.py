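"""Plain-text mesh and field I/O: ASCII VTU (+PVD time series) and Gmsh MSH 4.1.

Only the unstructured-grid subset the simulator needs is supported:
tetrahedral volume cells plus triangular boundary facets carrying the
``endocardium`` / ``epicardium`` / ``base`` tags, with optional nodal and
cell fields.  Facet tags travel in a ``surface_tag`` cell array in VTU
(0 = volume, 1 = endocardium, 2 = epicardium, 3 = base) and as physical
surface names in MSH.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET

import numpy as np

from .geometry import BASE, ENDO, EPI, SURFACE_TAGS, WallMesh

_TAG_IDS = {ENDO: 1, EPI: 2, BASE: 3}
_ID_TAGS = {v: k for k, v in _TAG_IDS.items()}

VTK_TET, VTK_TRI = 10, 5


def _fmt(arr, per_line=6):
    flat = np.asarray(arr).ravel()
    if np.issubdtype(flat.dtype, np.floating):
        conv = "{:.17g}".format
    else:
        conv = str
    return "\n".join(
        " ".join(conv(v) for v in flat[i:i + per_line])
        for i in range(0, len(flat), per_line)
    )


def write_vtu(mesh: WallMesh, path, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Write a WallMesh (tets + tagged boundary triangles) as ASCII VTU.

    ``point_data`` maps names to (N,) nodal arrays; ``cell_data`` maps names
    to per-tet arrays (boundary triangles are padded with zeros).  The
    transmural coordinate is written automatically when available.
    """
    point_data = dict(point_data or {})
    if mesh.transmural is not None and "transmural" not in point_data:
        point_data["transmural"] = mesh.transmural

    tris, tri_tags = [], []
    for name in SURFACE_TAGS:
        f = np.asarray(mesh.surface_tags.get(name, np.empty((0, 3), int)), int)
        if len(f):
            tris.append(f)
            tri_tags.append(np.full(len(f), _TAG_IDS[name]))
    tris = np.vstack(tris) if tris else np.empty((0, 3), int)
    tri_tags = np.concatenate(tri_tags) if tri_tags else np.empty(0, int)

    n_cells = len(mesh.tets) + len(tris)
    conn = np.concatenate([mesh.tets.ravel(), tris.ravel()])
    offsets = np.concatenate([np.arange(1, len(mesh.tets) + 1) * 4,
                              len(mesh.tets) * 4 + np.arange(1, len(tris) + 1) * 3])
    types = np.concatenate([np.full(len(mesh.tets), VTK_TET),
                            np.full(len(tris), VTK_TRI)])
    surface_tag = np.concatenate([np.zeros(len(mesh.tets), int), tri_tags])

    lines = ['<?xml version="1.0"?>',
             '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
             ' <UnstructuredGrid>',
             f'  <Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{n_cells}">',
             '   <Points>',
             '    <DataArray type="Float64" NumberOfComponents="3" format="ascii">',
             _fmt(mesh.nodes.astype(float)), '    </DataArray>', '   </Points>',
             '   <Cells>',
             '    <DataArray type="Int64" Name="connectivity" format="ascii">',
             _fmt(conn), '    </DataArray>',
             '    <DataArray type="Int64" Name="offsets" format="ascii">',
             _fmt(offsets), '    </DataArray>',
             '    <DataArray type="UInt8" Name="types" format="ascii">',
             _fmt(types), '    </DataArray>', '   </Cells>']

    lines.append('   <PointData>')
    for name, arr in point_data.items():
        lines += [f'    <DataArray type="Float64" Name="{name}" format="ascii">',
                  _fmt(np.asarray(arr, float)), '    </DataArray>']
    lines.append('   </PointData>')

    lines.append('   <CellData>')
    lines += ['    <DataArray type="Int64" Name="surface_tag" format="ascii">',
              _fmt(surface_tag), '    </DataArray>']
    for name, arr in (cell_data or {}).items():
        padded = np.concatenate([np.asarray(arr, float), np.zeros(len(tris))])
        lines += [f'    <DataArray type="Float64" Name="{name}" format="ascii">',
                  _fmt(padded), '    </DataArray>']
    lines.append('   </CellData>')

    lines += ['  </Piece>', ' </UnstructuredGrid>', '</VTKFile>', '']
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_vtu(path) -> tuple[WallMesh, dict]:
    """Read an ASCII VTU written by :func:`write_vtu` (or equivalent).

    Returns ``(mesh, point_data)``.  Raises on non-tet/tri cells or missing
    surface tags.
    """
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    if piece is None:
        raise ValueError(f"{path}: no <Piece> element found")

    def parse_array(da, dtype):
        return np.array((da.text or "").split(), dtype=dtype)

    pts = parse_array(piece.find("Points/DataArray"), float).reshape(-1, 3)
    cells = {da.get("Name"): da for da in piece.findall("Cells/DataArray")}
    conn = parse_array(cells["connectivity"], np.int64)
    offsets = parse_array(cells["offsets"], np.int64)
    types = parse_array(cells["types"], np.int64)

    bad = set(types) - {VTK_TET, VTK_TRI}
    if bad:
        raise ValueError(f"{path}: unsupported cell types {sorted(bad)}; "
                         "only tetrahedra (10) and triangles (5) are handled")

    starts = np.concatenate([[0], offsets[:-1]])
    tets = np.array([conn[s:e] for s, e, t in zip(starts, offsets, types)
                     if t == VTK_TET], dtype=np.int64).reshape(-1, 4)
    tris = np.array([conn[s:e] for s, e, t in zip(starts, offsets, types)
                     if t == VTK_TRI], dtype=np.int64).reshape(-1, 3)
    if len(tets) == 0:
        raise ValueError(f"{path}: no tetrahedral cells found")

    cell_data = {da.get("Name"): parse_array(da, float)
                 for da in piece.findall("CellData/DataArray")}
    if "surface_tag" not in cell_data:
        raise ValueError(f"{path}: missing 'surface_tag' cell array "
                         f"(found: {sorted(cell_data)})")
    tag_vals = cell_data["surface_tag"].astype(int)[types == VTK_TRI]
    surface_tags = {name: tris[tag_vals == tid]
                    for name, tid in _TAG_IDS.items()}
    missing = [n for n in SURFACE_TAGS if len(surface_tags[n]) == 0]
    if missing:
        found = [n for n in SURFACE_TAGS if len(surface_tags[n])]
        raise ValueError(f"{path}: missing surface tags {missing} (found: {found})")

    point_data = {da.get("Name"): parse_array(da, float)
                  for da in piece.findall("PointData/DataArray")}
    mesh = WallMesh(pts, tets, surface_tags,
                    transmural=point_data.get("transmural"))
    return mesh, point_data


def write_pvd(path, steps) -> None:
    """Write a ParaView PVD collection; ``steps`` is [(time, vtu_path), ...]."""
    lines = ['<?xml version="1.0"?>',
             '<VTKFile type="Collection" version="0.1">', ' <Collection>']
    for t, f in steps:
        lines.append(f'  <DataSet timestep="{t!r}" part="0" file="{os.path.basename(f)}"/>')
    lines += [' </Collection>', '</VTKFile>', '']
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


# ---------------------------------------------------------------------------
# Gmsh MSH 4.1 (ASCII)

def write_msh(mesh: WallMesh, path) -> None:
    """Write the mesh in Gmsh MSH 4.1 ASCII with named physical surfaces."""
    tris = {name: np.asarray(mesh.surface_tags[name], int) for name in SURFACE_TAGS}
    lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat", "$PhysicalNames", "4"]
    for name, tid in _TAG_IDS.items():
        lines.append(f'2 {tid} "{name}"')
    lines.append('3 4 "myocardium"')
    lines.append("$EndPhysicalNames")
    # minimal entities: three surfaces + one volume, entity tag = physical tag
    lines += ["$Entities", "0 0 3 1"]
    for tid in _TAG_IDS.values():
        lines.append(f"{tid} 0 0 0 0 0 0 1 {tid} 0")
    lines.append("4 0 0 0 0 0 0 1 4 0")
    lines.append("$EndEntities")

    n = mesh.n_nodes
    lines += ["$Nodes", f"1 {n} 1 {n}", f"3 4 0 {n}"]
    lines += [str(i + 1) for i in range(n)]
    lines += [f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in mesh.nodes]
    lines.append("$EndNodes")

    blocks = []
    for name, tid in _TAG_IDS.items():
        if len(tris[name]):
            blocks.append((2, tid, 2, tris[name]))
    blocks.append((3, 4, 4, mesh.tets))
    lines += ["$Elements"]
    n_elem = sum(len(b[3]) for b in blocks)
    lines.append(f"{len(blocks)} {n_elem} 1 {n_elem}")
    eid = 1
    for dim, tag, etype, elems in blocks:
        lines.append(f"{dim} {tag} {etype} {len(elems)}")
        for el in elems:
            lines.append(str(eid) + " " + " ".join(str(v + 1) for v in el))
            eid += 1
    lines += ["$EndElements", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_msh(path) -> WallMesh:
    """Read a Gmsh MSH 4.1 ASCII mesh with tagged physical surfaces.

    Surface names must contain ``endo``, ``epi`` or ``base``; volume elements
    must be 4-node tetrahedra.
    """
    with open(path) as fh:
        text = fh.read()

    def section(name):
        try:
            body = text.split(f"${name}\n", 1)[1].split(f"$End{name}", 1)[0]
        except IndexError:
            raise ValueError(f"{path}: missing ${name} section") from None
        return body.strip().splitlines()

    fmt = section("MeshFormat")[0].split()
    if not fmt[0].startswith("4"):
        raise ValueError(f"{path}: only MSH 4.x ASCII is supported, got {fmt[0]}")

    phys_names = {}
    if "$PhysicalNames" in text:
        rows = section("PhysicalNames")
        for row in rows[1:]:
            parts = row.split(None, 2)
            phys_names[(int(parts[0]), int(parts[1]))] = parts[2].strip().strip('"')

    # (dim, entity tag) -> physical tag (first listed)
    ent_phys = {}
    if "$Entities" in text:
        rows = section("Entities")
        counts = [int(v) for v in rows[0].split()]
        k = 1
        for dim, cnt in enumerate(counts):
            for _ in range(cnt):
                parts = rows[k].split()
                k += 1
                tag = int(parts[0])
                npz = 4 if dim == 0 else 7
                nphys = int(parts[npz]) if len(parts) > npz else 0
                if nphys > 0:
                    ent_phys[(dim, tag)] = int(parts[npz + 1])

    rows = section("Nodes")
    n_blocks, n_nodes = int(rows[0].split()[0]), int(rows[0].split()[1])
    node_ids, coords = [], []
    k = 1
    for _ in range(n_blocks):
        blk_n = int(rows[k].split()[3])
        k += 1
        ids = [int(rows[k + i]) for i in range(blk_n)]
        k += blk_n
        for i in range(blk_n):
            coords.append([float(v) for v in rows[k + i].split()])
        k += blk_n
        node_ids.extend(ids)
    order = np.argsort(node_ids)
    remap = {node_ids[i]: rank for rank, i in enumerate(order)}
    nodes = np.asarray(coords)[order]

    rows = section("Elements")
    n_blocks = int(rows[0].split()[0])
    tets, surf = [], {ENDO: [], EPI: [], BASE: []}
    k = 1
    for _ in range(n_blocks):
        dim, ent, etype, blk_n = (int(v) for v in rows[k].split())
        k += 1
        elems = [[remap[int(v)] for v in rows[k + i].split()[1:]]
                 for i in range(blk_n)]
        k += blk_n
        if etype == 4:
            tets.extend(elems)
        elif etype == 2:
            phys = ent_phys.get((dim, ent), ent)
            name = phys_names.get((dim, phys), _ID_TAGS.get(phys, ""))
            key = next((t for t in SURFACE_TAGS if t[:4] in name.lower()), None)
            if key is None:
                raise ValueError(f"{path}: surface entity {ent} has no "
                                 "endo/epi/base physical name")
            surf[key].extend(elems)
        elif etype in (1, 15):
            continue  # lines / points: ignore
        else:
            raise ValueError(f"{path}: unsupported element type {etype}; "
                             "only tetrahedra and triangles are handled")
    if not tets:
        raise ValueError(f"{path}: no tetrahedral elements found")
    missing = [n for n in SURFACE_TAGS if not surf[n]]
    if missing:
        found = [n for n in SURFACE_TAGS if surf[n]]
        raise ValueError(f"{path}: missing surface tags {missing} (found: {found})")
    return WallMesh(nodes, np.asarray(tets, np.int64),
                    {n: np.asarray(v, np.int64) for n, v in surf.items()})


def read_mesh(path, fmt: str | None = None) -> WallMesh:
    """Read a wall mesh from ``path`` (format from extension unless given)."""
    fmt = fmt or os.path.splitext(str(path))[1].lstrip(".").lower()
    if fmt == "vtu":
        return read_vtu(path)[0]
    if fmt == "msh":
        return read_msh(path)
    raise ValueError(f"unsupported mesh format {fmt!r}; use 'msh' or 'vtu'")
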