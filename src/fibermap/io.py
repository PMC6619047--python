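"""Readers and writers for meshes, fiber fields, landmarks, images and config.

Mesh formats: Gmsh MSH 2.2 (ASCII), VTK legacy ASCII and VTU (inline ASCII
XML).  Surface node sets travel as one ``tag:<name>`` 0/1 point-data array
per tag in the VTK dialects and as point-element physical groups in MSH, so
tag names survive a round trip in every format.  Images use MetaImage
(SimpleITK) or NIfTI (nibabel); landmarks are CSV ``name,x,y,z`` or JSON.
"""

from __future__ import annotations

import json
import os
import xml.etree.ElementTree as ET

import numpy as np
import yaml

from .core import (
    AffineTransform,
    BinaryImage3D,
    ContentError,
    DisplacementField,
    FiberField,
    FormatError,
    LandmarkSet,
    TetMesh,
)

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_fibers",
    "write_fibers",
    "read_landmarks",
    "write_landmarks",
    "read_image",
    "write_image",
    "read_displacement",
    "write_displacement",
    "read_affine",
    "write_affine",
    "load_config",
    "save_config",
]

_TAG_PREFIX = "tag:"


def _infer_format(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".msh",):
        return "msh"
    if ext in (".vtu",):
        return "vtu"
    if ext in (".vtk",):
        return "vtk"
    raise FormatError(f"cannot infer mesh format from {path!r}")


# ----------------------------------------------------------------------
# Gmsh MSH 2.2
# ----------------------------------------------------------------------

def _read_msh(path):
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    try:
        sections = {}
        i = 0
        while i < len(lines):
            if lines[i].startswith("$") and not lines[i].startswith("$End"):
                name = lines[i][1:]
                j = lines.index(f"$End{name}", i)
                sections[name] = lines[i + 1 : j]
                i = j + 1
            else:
                i += 1
        phys_names = {}
        for ln in sections.get("PhysicalNames", [])[1:]:
            parts = ln.split(None, 2)
            phys_names[(int(parts[0]), int(parts[1]))] = parts[2].strip('"')
        node_lines = sections["Nodes"]
        n = int(node_lines[0])
        ids = np.empty(n, dtype=np.int64)
        pts = np.empty((n, 3))
        for k, ln in enumerate(node_lines[1 : n + 1]):
            parts = ln.split()
            ids[k] = int(parts[0])
            pts[k] = [float(v) for v in parts[1:4]]
        id2row = {int(i): k for k, i in enumerate(ids)}
        elem_lines = sections["Elements"]
        m = int(elem_lines[0])
        tets, tags = [], {}
        tri_nodes_by_phys = {}
        for ln in elem_lines[1 : m + 1]:
            parts = [int(v) for v in ln.split()]
            etype, ntags = parts[1], parts[2]
            phys = parts[3] if ntags >= 1 else 0
            conn = parts[3 + ntags :]
            if etype == 4:  # tetrahedron
                tets.append([id2row[c] for c in conn])
            elif etype == 15:  # point
                name = phys_names.get((0, phys), f"group{phys}")
                tags.setdefault(name, []).append(id2row[conn[0]])
            elif etype == 2:  # triangle: collect nodes under its group
                name = phys_names.get((2, phys), f"group{phys}")
                tri_nodes_by_phys.setdefault(name, set()).update(id2row[c] for c in conn)
    except (KeyError, ValueError, IndexError) as exc:
        raise FormatError(f"not a valid MSH 2.2 file: {path}") from exc
    if not tets:
        raise ContentError(f"mesh in {path} contains no tetrahedra")
    for name, nodes in tri_nodes_by_phys.items():
        tags.setdefault(name, []).extend(sorted(nodes))
    surface_tags = {k: np.array(sorted(set(v)), dtype=np.int64) for k, v in tags.items()}
    return TetMesh(pts, np.array(tets, dtype=np.int64), surface_tags)


def _write_msh(mesh: TetMesh, path):
    tag_names = sorted(mesh.surface_tags)
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        if tag_names:
            fh.write("$PhysicalNames\n%d\n" % len(tag_names))
            for i, name in enumerate(tag_names, start=1):
                fh.write('0 %d "%s"\n' % (i, name))
            fh.write("$EndPhysicalNames\n")
        fh.write("$Nodes\n%d\n" % len(mesh.nodes))
        for i, p in enumerate(mesh.nodes, start=1):
            fh.write("%d %.17g %.17g %.17g\n" % (i, p[0], p[1], p[2]))
        fh.write("$EndNodes\n")
        n_pts = sum(len(v) for v in mesh.surface_tags.values())
        fh.write("$Elements\n%d\n" % (n_pts + len(mesh.tets)))
        eid = 1
        for gi, name in enumerate(tag_names, start=1):
            for node in mesh.surface_tags[name]:
                fh.write("%d 15 2 %d %d %d\n" % (eid, gi, gi, node + 1))
                eid += 1
        for tet in mesh.tets:
            fh.write("%d 4 2 0 0 %d %d %d %d\n" % (eid, *(tet + 1)))
            eid += 1
        fh.write("$EndElements\n")


# ----------------------------------------------------------------------
# VTK legacy ASCII
# ----------------------------------------------------------------------

def _read_vtk(path):
    with open(path) as fh:
        tokens = fh.read().split()
    try:
        tl = [t.upper() for t in tokens]
        i = tl.index("POINTS")
        n = int(tokens[i + 1])
        pts = np.array(tokens[i + 3 : i + 3 + 3 * n], dtype=float).reshape(n, 3)
        i = tl.index("CELLS")
        ncell = int(tokens[i + 1])
        total = int(tokens[i + 2])
        raw = np.array(tokens[i + 3 : i + 3 + total], dtype=np.int64)
        i = tl.index("CELL_TYPES")
        ctypes = np.array(tokens[i + 2 : i + 2 + ncell], dtype=np.int64)
        cells, pos = [], 0
        for _ in range(ncell):
            cnt = raw[pos]
            cells.append(raw[pos + 1 : pos + 1 + cnt])
            pos += cnt + 1
        tets = [c for c, t in zip(cells, ctypes) if t == 10]
    except (ValueError, IndexError) as exc:
        raise FormatError(f"not a valid legacy VTK file: {path}") from exc
    if not tets:
        raise ContentError(f"mesh in {path} contains no tetrahedra")
    arrays = _read_vtk_point_data(tokens, tl, n)
    mesh = TetMesh(pts, np.array(tets), _tags_from_arrays(arrays, n))
    return mesh, arrays


def _read_vtk_point_data(tokens, tl, n):
    arrays = {}
    if "POINT_DATA" not in tl:
        return arrays
    i = tl.index("POINT_DATA") + 2
    while i < len(tokens):
        kw = tl[i]
        if kw == "SCALARS":
            name = tokens[i + 1]
            i += 3  # past SCALARS name type
            if tl[i] != "LOOKUP_TABLE":
                i += 1  # optional numComponents
            i += 2  # LOOKUP_TABLE <name>
            arrays[name] = np.array(tokens[i : i + n], dtype=float)
            i += n
        elif kw == "VECTORS":
            name = tokens[i + 1]
            i += 3
            arrays[name] = np.array(tokens[i : i + 3 * n], dtype=float).reshape(n, 3)
            i += 3 * n
        else:
            break
    return arrays


def _write_vtk(mesh: TetMesh, path, point_data=None):
    pd = dict(point_data or {})
    pd.update(_arrays_from_tags(mesh))
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfibermap mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write("POINTS %d double\n" % len(mesh.nodes))
        np.savetxt(fh, mesh.nodes, fmt="%.17g")
        m = len(mesh.tets)
        fh.write("CELLS %d %d\n" % (m, 5 * m))
        np.savetxt(fh, np.hstack([np.full((m, 1), 4, dtype=np.int64), mesh.tets]), fmt="%d")
        fh.write("CELL_TYPES %d\n" % m)
        fh.write("\n".join(["10"] * m) + "\n")
        if pd:
            fh.write("POINT_DATA %d\n" % len(mesh.nodes))
            for name, arr in pd.items():
                arr = np.asarray(arr, dtype=float)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr, fmt="%.17g")
                else:
                    fh.write(f"VECTORS {name} double\n")
                    np.savetxt(fh, arr, fmt="%.17g")


# ----------------------------------------------------------------------
# VTU (XML, inline ASCII)
# ----------------------------------------------------------------------

def _write_vtu(mesh: TetMesh, path, point_data=None):
    pd = dict(point_data or {})
    pd.update(_arrays_from_tags(mesh))
    n, m = len(mesh.nodes), len(mesh.tets)
    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1", byte_order="LittleEndian")
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(grid, "Piece", NumberOfPoints=str(n), NumberOfCells=str(m))
    pts = ET.SubElement(piece, "Points")
    _vtu_array(pts, "Points", mesh.nodes, 3)
    if pd:
        pde = ET.SubElement(piece, "PointData")
        for name, arr in pd.items():
            arr = np.asarray(arr, dtype=float)
            _vtu_array(pde, name, arr, 3 if arr.ndim > 1 else 1)
    cells = ET.SubElement(piece, "Cells")
    _vtu_array(cells, "connectivity", mesh.tets, 1, dtype="Int64")
    _vtu_array(cells, "offsets", 4 * (np.arange(m) + 1), 1, dtype="Int64")
    _vtu_array(cells, "types", np.full(m, 10), 1, dtype="UInt8")
    ET.ElementTree(root).write(path)


def _vtu_array(parent, name, data, ncomp, dtype="Float64"):
    el = ET.SubElement(
        parent,
        "DataArray",
        type=dtype,
        Name=name,
        NumberOfComponents=str(ncomp),
        format="ascii",
    )
    flat = np.asarray(data).ravel()
    fmt = "%d" if dtype in ("Int64", "UInt8") else "%.17g"
    el.text = " ".join(fmt % v for v in flat)


def _read_vtu(path):
    try:
        root = ET.parse(path).getroot()
        piece = root.find("UnstructuredGrid/Piece")
        arrays = {}
        for da in piece.find("Points").iter("DataArray"):
            pts = np.array(da.text.split(), dtype=float).reshape(-1, 3)
        cells = {da.get("Name"): np.array(da.text.split(), dtype=np.int64)
                 for da in piece.find("Cells").iter("DataArray")}
        pde = piece.find("PointData")
        if pde is not None:
            for da in pde.iter("DataArray"):
                ncomp = int(da.get("NumberOfComponents", "1"))
                a = np.array(da.text.split(), dtype=float)
                arrays[da.get("Name")] = a.reshape(-1, ncomp) if ncomp > 1 else a
        conn, offs, ctypes = cells["connectivity"], cells["offsets"], cells["types"]
    except (ET.ParseError, AttributeError, KeyError, ValueError) as exc:
        raise FormatError(f"not a valid VTU file: {path}") from exc
    starts = np.concatenate([[0], offs[:-1]])
    tets = [conn[s:e] for s, e, t in zip(starts, offs, ctypes) if t == 10]
    if not tets:
        raise ContentError(f"mesh in {path} contains no tetrahedra")
    mesh = TetMesh(pts, np.array(tets), _tags_from_arrays(arrays, len(pts)))
    return mesh, arrays


def _arrays_from_tags(mesh: TetMesh):
    out = {}
    for name, idx in mesh.surface_tags.items():
        a = np.zeros(len(mesh.nodes))
        a[idx] = 1.0
        out[_TAG_PREFIX + name] = a
    return out


def _tags_from_arrays(arrays, n):
    tags = {}
    for name in list(arrays):
        if name.startswith(_TAG_PREFIX):
            tags[name[len(_TAG_PREFIX):]] = np.nonzero(arrays.pop(name) > 0.5)[0]
    return tags


# ----------------------------------------------------------------------
# public mesh / fiber API
# ----------------------------------------------------------------------

def read_mesh(path, format: str | None = None) -> TetMesh:
    """Read a tetrahedral mesh (MSH 2.2, VTK legacy, or VTU)."""
    fmt = format or _infer_format(path)
    if fmt == "msh":
        mesh = _read_msh(path)
    elif fmt == "vtk":
        mesh, _ = _read_vtk(path)
    elif fmt == "vtu":
        mesh, _ = _read_vtu(path)
    else:
        raise FormatError(f"unknown mesh format {fmt!r}")
    return mesh.validate()


def write_mesh(mesh: TetMesh, path, format: str | None = None, point_data=None) -> None:
    fmt = format or _infer_format(path)
    if fmt == "msh":
        if point_data:
            raise FormatError("point data not supported in MSH output")
        _write_msh(mesh, path)
    elif fmt == "vtk":
        _write_vtk(mesh, path, point_data)
    elif fmt == "vtu":
        _write_vtu(mesh, path, point_data)
    else:
        raise FormatError(f"unknown mesh format {fmt!r}")


def write_fibers(mesh: TetMesh, fibers: FiberField, path, extra_point_data=None) -> None:
    """Write mesh + per-node ``fiber`` vectors (and validity mask) to VTU/VTK."""
    if len(fibers) != len(mesh.nodes):
        raise ContentError("fiber field length does not match mesh")
    if not fibers.defined_mask.all():
        raise ContentError("fibers undefined on some nodes; fill before writing")
    pd = {"fiber": fibers.vectors, "fiber_defined": fibers.defined_mask.astype(float)}
    pd.update(extra_point_data or {})
    write_mesh(mesh, path, point_data=pd)


def read_fibers(path) -> tuple[TetMesh, FiberField]:
    fmt = _infer_format(path)
    if fmt == "vtu":
        mesh, arrays = _read_vtu(path)
    elif fmt == "vtk":
        mesh, arrays = _read_vtk(path)
    else:
        raise FormatError("fiber fields are stored in VTU or VTK files")
    if "fiber" not in arrays:
        raise ContentError(f"no 'fiber' point-data array in {path}")
    mask = arrays.get("fiber_defined")
    mask = mask > 0.5 if mask is not None else None
    return mesh.validate(), FiberField(arrays["fiber"], mask)


# ----------------------------------------------------------------------
# landmarks
# ----------------------------------------------------------------------

def read_landmarks(path) -> LandmarkSet:
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            data = json.load(fh)
        if isinstance(data, dict):
            items = list(data.items())
        else:
            items = [(d["name"], d["point"]) for d in data]
        names = [k for k, _ in items]
        pts = [v for _, v in items]
    else:
        names, pts = [], []
        with open(path) as fh:
            for ln in fh:
                ln = ln.strip()
                if not ln or ln.startswith("#"):
                    continue
                parts = [p.strip() for p in ln.split(",")]
                if parts[0].lower() == "name":
                    continue  # header
                if len(parts) != 4:
                    raise FormatError(f"landmark CSV row needs name,x,y,z: {ln!r}")
                names.append(parts[0])
                pts.append([float(v) for v in parts[1:]])
    return LandmarkSet(names, np.asarray(pts, dtype=float).reshape(-1, 3))


def write_landmarks(lm: LandmarkSet, path) -> None:
    path = str(path)
    if path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump([{"name": n, "point": list(map(float, p))}
                       for n, p in zip(lm.names, lm.points)], fh, indent=1)
    else:
        with open(path, "w") as fh:
            fh.write("name,x,y,z\n")
            for n, p in zip(lm.names, lm.points):
                fh.write("%s,%.17g,%.17g,%.17g\n" % (n, p[0], p[1], p[2]))


# ----------------------------------------------------------------------
# images and displacement fields
# ----------------------------------------------------------------------

def write_image(image: BinaryImage3D, path) -> None:
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        aff = np.eye(4)
        aff[:3, :3] = np.diag(image.spacing)
        aff[:3, 3] = image.origin
        nib.save(nib.Nifti1Image(image.values.astype(np.float32), aff), path)
    else:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(image.values.transpose(2, 1, 0)))
        img.SetOrigin(tuple(image.origin))
        img.SetSpacing(tuple(image.spacing))
        sitk.WriteImage(img, path)


def read_image(path) -> BinaryImage3D:
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        aff = img.affine
        vals = np.asarray(img.dataobj, dtype=float)
        return BinaryImage3D(aff[:3, 3], np.diag(aff[:3, :3]).copy(), vals)
    import SimpleITK as sitk

    img = sitk.ReadImage(path)
    vals = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(float)
    return BinaryImage3D(np.array(img.GetOrigin()), np.array(img.GetSpacing()), vals)


def write_displacement(field: DisplacementField, path) -> None:
    import SimpleITK as sitk

    arr = np.ascontiguousarray(field.u.transpose(2, 1, 0, 3))
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetOrigin(tuple(field.origin))
    img.SetSpacing(tuple(field.spacing))
    sitk.WriteImage(img, str(path))


def read_displacement(path) -> DisplacementField:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise FormatError(f"{path} is not a 3-component displacement image")
    return DisplacementField(
        np.array(img.GetOrigin()), np.array(img.GetSpacing()), arr.transpose(2, 1, 0, 3)
    )


# ----------------------------------------------------------------------
# transforms and config
# ----------------------------------------------------------------------

def write_affine(tf: AffineTransform, path) -> None:
    with open(path, "w") as fh:
        json.dump({"matrix": tf.as_flat()}, fh, indent=1)


def read_affine(path) -> AffineTransform:
    with open(path) as fh:
        data = json.load(fh)
    return AffineTransform.from_flat(data["matrix"])


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
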