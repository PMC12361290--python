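"""Surface I/O: PLY (ASCII and binary, with per-vertex scalar fields),
legacy-VTK PolyData point-data arrays, OBJ geometry, and colour export.

PLY per-vertex float properties beyond x/y/z become SurfaceFields on
load; NaN values are read back as missing.  A companion property named
``<field>_missing`` (uchar) is written when a field has a non-trivial
missing mask, so masks round-trip exactly.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .mesh import MeshValidationError, SurfaceField, TriangleMesh

__all__ = ["load_mesh", "save_mesh", "save_colored_ply"]

_FORMATS = ("ply", "vtk", "obj")


class MeshFormatError(ValueError):
    """The file could not be parsed as the named format."""


def _infer_format(path, fmt: str | None) -> str:
    if fmt is None:
        fmt = Path(path).suffix.lstrip(".").lower()
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}; expected {_FORMATS}")
    return fmt


def load_mesh(path, format: str | None = None, patch_label: str | None = None,
              validate: bool = True):
    """Read a surface mesh and any per-vertex scalar fields.

    Returns ``(TriangleMesh, dict of name -> SurfaceField)``.  The mesh
    is validated against the structural invariants unless
    ``validate=False``.
    """
    fmt = _infer_format(path, format)
    if fmt == "ply":
        verts, faces, fields = _read_ply(path)
    elif fmt == "vtk":
        verts, faces, fields = _read_vtk(path)
    else:
        verts, faces, fields = _read_obj(path)
    mesh = TriangleMesh(verts, faces, patch_label=patch_label)
    if validate:
        mesh.validate()
    out = {}
    skip = {n for n in fields if n.endswith("_missing")}
    for name, vals in fields.items():
        if name in skip:
            continue
        mask_vals = fields.get(name + "_missing")
        mask = mask_vals.astype(bool) if mask_vals is not None else np.isnan(vals)
        units = "mm" if name.endswith("_mm") or name == "thickness" else "dimensionless"
        out[name] = SurfaceField(vals, units=units, missing_mask=mask, name=name)
        if validate:
            out[name].check_against(mesh)
    return mesh, out


def save_mesh(mesh: TriangleMesh, fields=None, path=None, format: str | None = None,
              binary: bool = False) -> None:
    """Write a mesh with named per-vertex fields.

    ``fields`` may be a dict name -> SurfaceField or a list of
    SurfaceFields (their ``name`` attributes are used).  OBJ stores
    geometry only and refuses fields.
    """
    fmt = _infer_format(path, format)
    fdict = _as_field_dict(fields)
    for f in fdict.values():
        if len(f.values) != mesh.n_vertices:
            raise MeshValidationError(
                f"field {f.name!r} length {len(f.values)} != {mesh.n_vertices} vertices"
            )
    if fmt == "ply":
        _write_ply(mesh, fdict, path, binary=binary)
    elif fmt == "vtk":
        _write_vtk(mesh, fdict, path)
    else:
        if fdict:
            raise MeshValidationError("OBJ stores geometry only; drop the fields")
        _write_obj(mesh, path)


def _as_field_dict(fields) -> dict:
    if fields is None:
        return {}
    if isinstance(fields, dict):
        return dict(fields)
    return {f.name: f for f in fields}


# ---------------------------------------------------------------------------
# PLY
# ---------------------------------------------------------------------------

_PLY_DTYPES = {
    "float": "<f4", "float32": "<f4", "double": "<f8", "float64": "<f8",
    "int": "<i4", "int32": "<i4", "uint": "<u4", "uint32": "<u4",
    "short": "<i2", "int16": "<i2", "ushort": "<u2", "uint16": "<u2",
    "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
}


def _read_ply(path):
    with open(path, "rb") as fh:
        first = fh.readline().strip()
        if first != b"ply":
            raise MeshFormatError(f"{path}: not a PLY file (missing 'ply' magic)")
        fmt_line = None
        elements = []  # (name, count, [(prop_name, dtype, is_list, count_t, item_t)])
        while True:
            raw = fh.readline()
            if not raw:
                raise MeshFormatError(f"{path}: unexpected EOF in PLY header")
            line = raw.decode("ascii", "replace").strip()
            if not line or line.startswith("comment"):
                continue
            if line.startswith("format"):
                fmt_line = line.split()[1]
            elif line.startswith("element"):
                _, name, cnt = line.split()
                elements.append((name, int(cnt), []))
            elif line.startswith("property"):
                parts = line.split()
                if parts[1] == "list":
                    elements[-1][2].append((parts[4], None, True, parts[2], parts[3]))
                else:
                    elements[-1][2].append((parts[2], parts[1], False, None, None))
            elif line == "end_header":
                break
            else:
                raise MeshFormatError(f"{path}: unrecognised PLY header line {line!r}")
        if fmt_line is None:
            raise MeshFormatError(f"{path}: PLY header has no format line")
        if fmt_line == "ascii":
            data = _read_ply_ascii_body(fh, elements, path)
        elif fmt_line == "binary_little_endian":
            data = _read_ply_binary_body(fh, elements, path)
        else:
            raise MeshFormatError(f"{path}: unsupported PLY format {fmt_line!r}")
    return _assemble_ply(data, path)


def _read_ply_ascii_body(fh, elements, path):
    tokens = fh.read().decode("ascii", "replace").split()
    pos = 0
    data = {}
    for name, count, props in elements:
        rows = []
        for i in range(count):
            row = {}
            for pname, dtype, is_list, _, _ in props:
                if is_list:
                    if pos >= len(tokens):
                        raise MeshFormatError(f"{path}: truncated at {name} record {i}")
                    n = int(tokens[pos]); pos += 1
                    row[pname] = [float(t) for t in tokens[pos:pos + n]]
                    if len(row[pname]) != n:
                        raise MeshFormatError(f"{path}: truncated list at {name} record {i}")
                    pos += n
                else:
                    if pos >= len(tokens):
                        raise MeshFormatError(f"{path}: truncated at {name} record {i}")
                    row[pname] = float(tokens[pos]); pos += 1
            rows.append(row)
        data[name] = (props, rows)
    return data


def _read_ply_binary_body(fh, elements, path):
    data = {}
    for name, count, props in elements:
        if not any(p[2] for p in props):            # fixed-width element
            dtype = np.dtype([(p[0], _PLY_DTYPES[p[1]]) for p in props])
            arr = np.frombuffer(fh.read(dtype.itemsize * count), dtype=dtype)
            if len(arr) != count:
                raise MeshFormatError(f"{path}: truncated binary element {name}")
            rows = [{p[0]: float(rec[p[0]]) for p in props} for rec in arr]
        else:
            rows = []
            for i in range(count):
                row = {}
                for pname, dtype, is_list, count_t, item_t in props:
                    if is_list:
                        ct = np.dtype(_PLY_DTYPES[count_t])
                        n = int(np.frombuffer(fh.read(ct.itemsize), dtype=ct)[0])
                        it = np.dtype(_PLY_DTYPES[item_t])
                        row[pname] = np.frombuffer(
                            fh.read(it.itemsize * n), dtype=it).tolist()
                    else:
                        dt = np.dtype(_PLY_DTYPES[dtype])
                        row[pname] = float(np.frombuffer(fh.read(dt.itemsize), dt)[0])
                rows.append(row)
        data[name] = (props, rows)
    return data


def _assemble_ply(data, path):
    if "vertex" not in data or "face" not in data:
        raise MeshFormatError(f"{path}: PLY lacks vertex/face elements")
    vprops, vrows = data["vertex"]
    for axis in ("x", "y", "z"):
        if not any(p[0] == axis for p in vprops):
            raise MeshFormatError(f"{path}: vertex element lacks property {axis!r}")
    verts = np.array([[r["x"], r["y"], r["z"]] for r in vrows], dtype=np.float64)
    verts = verts.reshape(-1, 3)
    fields = {}
    for pname, _, is_list, _, _ in vprops:
        if pname in ("x", "y", "z") or is_list:
            continue
        fields[pname] = np.array([r[pname] for r in vrows], dtype=np.float64)
    _, frows = data["face"]
    key = "vertex_indices" if (frows and "vertex_indices" in frows[0]) else "vertex_index"
    faces = []
    for i, r in enumerate(frows):
        idx = r.get(key)
        if idx is None:
            raise MeshFormatError(f"{path}: face record {i} lacks vertex indices")
        if len(idx) != 3:
            raise MeshFormatError(f"{path}: face record {i} is not a triangle")
        faces.append(idx)
    faces = np.array(faces, dtype=np.int64).reshape(-1, 3)
    return verts, faces, fields


def _ply_header(mesh, prop_lines, binary):
    fmt = "binary_little_endian" if binary else "ascii"
    lines = ["ply", f"format {fmt} 1.0", f"element vertex {mesh.n_vertices}",
             "property double x", "property double y", "property double z"]
    lines += prop_lines
    lines += [f"element face {mesh.n_faces}",
              "property list uchar int vertex_indices", "end_header"]
    return "\n".join(lines) + "\n"


def _write_ply(mesh, fdict, path, binary=False):
    prop_lines, columns = [], [mesh.vertices[:, 0], mesh.vertices[:, 1],
                               mesh.vertices[:, 2]]
    col_dtypes = ["<f8"] * 3
    for name, f in fdict.items():
        _check_ply_name(name)
        prop_lines.append(f"property double {name}")
        vals = np.where(f.missing_mask, np.nan, f.values)
        columns.append(vals)
        col_dtypes.append("<f8")
        if f.missing_mask.any():
            prop_lines.append(f"property uchar {name}_missing")
            columns.append(f.missing_mask.astype(np.uint8))
            col_dtypes.append("u1")
    header = _ply_header(mesh, prop_lines, binary)
    if binary:
        vdt = np.dtype([(f"c{i}", d) for i, d in enumerate(col_dtypes)])
        varr = np.empty(mesh.n_vertices, dtype=vdt)
        for i, c in enumerate(columns):
            varr[f"c{i}"] = c
        fdt = np.dtype([("n", "u1"), ("i", "<i4", (3,))])
        farr = np.empty(mesh.n_faces, dtype=fdt)
        farr["n"] = 3
        farr["i"] = mesh.faces
        with open(path, "wb") as fh:
            fh.write(header.encode("ascii"))
            fh.write(varr.tobytes())
            fh.write(farr.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write(header)
            for row in zip(*columns):
                fh.write(" ".join(_fmt_ascii(v) for v in row) + "\n")
            for face in mesh.faces:
                fh.write(f"3 {face[0]} {face[1]} {face[2]}\n")


def _fmt_ascii(v):
    if float(v).is_integer() and abs(v) < 1e15:
        return str(int(v))
    return repr(float(v))


def _check_ply_name(name):
    if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", name):
        raise MeshValidationError(f"field name {name!r} not storable as PLY property")


# ---------------------------------------------------------------------------
# legacy VTK PolyData (ASCII)
# ---------------------------------------------------------------------------

def _read_vtk(path):
    with open(path) as fh:
        tokens_lines = fh.read().splitlines()
    if len(tokens_lines) < 4 or not tokens_lines[0].startswith("# vtk DataFile"):
        raise MeshFormatError(f"{path}: not a legacy VTK file")
    if tokens_lines[2].strip().upper() != "ASCII":
        raise MeshFormatError(f"{path}: only ASCII legacy VTK is supported")
    if "POLYDATA" not in tokens_lines[3].upper():
        raise MeshFormatError(f"{path}: DATASET is not POLYDATA")
    tokens = " ".join(tokens_lines[4:]).split()
    pos = 0

    def expect(word):
        nonlocal pos
        if pos >= len(tokens) or tokens[pos].upper() != word:
            got = tokens[pos] if pos < len(tokens) else "<eof>"
            raise MeshFormatError(f"{path}: expected {word}, got {got!r}")
        pos += 1

    expect("POINTS")
    n_pts = int(tokens[pos]); pos += 2          # skip dtype token
    verts = np.array(tokens[pos:pos + 3 * n_pts], dtype=np.float64).reshape(-1, 3)
    pos += 3 * n_pts
    expect("POLYGONS")
    n_poly = int(tokens[pos]); pos += 1
    total = int(tokens[pos]); pos += 1
    conn = tokens[pos:pos + total]
    pos += total
    faces, i = [], 0
    for _ in range(n_poly):
        k = int(conn[i])
        if k != 3:
            raise MeshFormatError(f"{path}: non-triangle polygon of size {k}")
        faces.append([int(c) for c in conn[i + 1:i + 4]])
        i += k + 1
    faces = np.array(faces, dtype=np.int64).reshape(-1, 3)
    fields = {}
    if pos < len(tokens) and tokens[pos].upper() == "POINT_DATA":
        pos += 2
        while pos < len(tokens):
            kind = tokens[pos].upper()
            if kind == "SCALARS":
                name = tokens[pos + 1]
                pos += 3                          # SCALARS name dtype [ncomp]
                if pos < len(tokens) and tokens[pos].isdigit():
                    pos += 1
                if tokens[pos].upper() != "LOOKUP_TABLE":
                    raise MeshFormatError(f"{path}: SCALARS without LOOKUP_TABLE")
                pos += 2
                fields[name] = np.array(tokens[pos:pos + n_pts], dtype=np.float64)
                pos += n_pts
            elif kind == "FIELD":
                n_arr = int(tokens[pos + 2]); pos += 3
                for _ in range(n_arr):
                    name = tokens[pos]
                    ncomp = int(tokens[pos + 1]); ntup = int(tokens[pos + 2])
                    pos += 4
                    vals = np.array(tokens[pos:pos + ncomp * ntup], dtype=np.float64)
                    pos += ncomp * ntup
                    if ncomp == 1 and ntup == n_pts:
                        fields[name] = vals
            else:
                break
    return verts, faces, fields


def _write_vtk(mesh, fdict, path):
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncasm surface\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for p in mesh.vertices:
            fh.write(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        if fdict:
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            for name, f in fdict.items():
                _check_ply_name(name)
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                vals = np.where(f.missing_mask, np.nan, f.values)
                fh.write("\n".join(repr(float(v)) for v in vals) + "\n")
                if f.missing_mask.any():
                    fh.write(f"SCALARS {name}_missing double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(str(int(v)) for v in f.missing_mask) + "\n")


# ---------------------------------------------------------------------------
# OBJ (geometry only), via trimesh
# ---------------------------------------------------------------------------

def _read_obj(path):
    import trimesh

    try:
        m = trimesh.load(str(path), file_type="obj", process=False)
    except Exception as exc:                     # noqa: BLE001 - reraise typed
        raise MeshFormatError(f"{path}: OBJ parse failure: {exc}") from exc
    if not hasattr(m, "faces"):
        raise MeshFormatError(f"{path}: OBJ contains no faces")
    return np.asarray(m.vertices, float), np.asarray(m.faces, np.int64), {}


def _write_obj(mesh, path):
    with open(path, "w") as fh:
        for p in mesh.vertices:
            fh.write(f"v {float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


# ---------------------------------------------------------------------------
# colour export for result maps
# ---------------------------------------------------------------------------

def save_colored_ply(mesh: TriangleMesh, field: SurfaceField, path,
                     significance_mask=None, cmap: str = "RdBu_r",
                     symmetric: bool | None = None,
                     desaturation: float = 0.8) -> None:
    """Export a field as per-vertex uchar RGB for external viewers.

    The field is mapped through a diverging colormap; where
    ``significance_mask`` is False the colour is blended towards white
    ("washed out"), the usual rendering of non-significant regions in
    surface-statistics maps.  Fields in signed units (t-statistics,
    effects) get a symmetric range so zero maps to the neutral colour.
    """
    import matplotlib

    field.check_against(mesh)
    if symmetric is None:
        symmetric = field.units in ("t", "mm_per_unit") or (field.values < 0).any()
    vals = np.where(field.missing_mask, np.nan, field.values)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        lo, hi = -1.0, 1.0
    elif symmetric:
        m = max(np.abs(finite).max(), 1e-12)
        lo, hi = -m, m
    else:
        lo, hi = float(finite.min()), float(finite.max())
        if hi <= lo:
            hi = lo + 1e-12
    norm = (np.nan_to_num(vals, nan=0.5 * (lo + hi)) - lo) / (hi - lo)
    rgba = matplotlib.colormaps[cmap](np.clip(norm, 0, 1))
    rgb = rgba[:, :3]
    if significance_mask is not None:
        mask = np.asarray(significance_mask, dtype=bool)
        rgb[~mask] = (1 - desaturation) * rgb[~mask] + desaturation * 1.0
    rgb[field.missing_mask] = 0.5
    rgb8 = np.clip(np.round(rgb * 255), 0, 255).astype(np.uint8)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for p, c in zip(mesh.vertices, rgb8):
            fh.write(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r} {c[0]} {c[1]} {c[2]}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
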