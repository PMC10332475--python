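"""Point-cloud file I/O: PLY (ascii / binary_little_endian) and PCD v0.7.

Coordinates are written as float32 (the native precision of the depth
sensor); intensity is written as float64 so a write/read round trip
preserves it exactly.  RGB colours are collapsed to grayscale with the
ITU-R BT.601 luminance weights 0.299 R + 0.587 G + 0.114 B.
"""

from __future__ import annotations

import os

import numpy as np

from .errors import CloudIOError

LUMA = np.array([0.299, 0.587, 0.114])

_PLY_DTYPES = {
    "float": "<f4", "float32": "<f4", "double": "<f8", "float64": "<f8",
    "uchar": "u1", "uint8": "u1", "char": "i1", "int8": "i1",
    "short": "<i2", "ushort": "<u2", "int16": "<i2", "uint16": "<u2",
    "int": "<i4", "int32": "<i4", "uint": "<u4", "uint32": "<u4",
}


def rgb_to_intensity(rgb: np.ndarray) -> np.ndarray:
    """Luminance of (n, 3) RGB values in [0, 255]."""
    return np.asarray(rgb, dtype=np.float64) @ LUMA


def read_cloud(path):
    """Read a PLY or PCD file into a PointCloud (extension-dispatched)."""
    from .core import PointCloud

    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".ply":
        pts, inten = _read_ply(path)
    elif ext == ".pcd":
        pts, inten = _read_pcd(path)
    else:
        raise CloudIOError(f"unknown point-cloud extension {ext!r} (want .ply or .pcd)")
    return PointCloud(np.clip(pts, -1e9, 1e9), inten, frame="camera")


def write_cloud(cloud, path, *, binary: bool = False) -> None:
    """Write a PointCloud as PLY or PCD (extension-dispatched)."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".ply":
        _write_ply(cloud, path, binary=binary)
    elif ext == ".pcd":
        _write_pcd(cloud, path, binary=binary)
    else:
        raise CloudIOError(f"unknown point-cloud extension {ext!r} (want .ply or .pcd)")


# --------------------------------------------------------------------- PLY

def _read_ply(path):
    with open(path, "rb") as fh:
        data = fh.read()
    end = data.find(b"end_header")
    if not data.startswith(b"ply") or end < 0:
        raise CloudIOError("malformed PLY header")
    end = data.index(b"\n", end) + 1
    header = data[:end].decode("ascii", errors="replace").splitlines()
    body = data[end:]

    fmt = None
    n_vertex = None
    props: list[tuple[str, str]] = []
    in_vertex = False
    for line in header[1:]:
        tok = line.strip().split()
        if not tok:
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            in_vertex = tok[1] == "vertex"
            if in_vertex:
                n_vertex = int(tok[2])
        elif tok[0] == "property" and in_vertex:
            if tok[1] == "list":
                raise CloudIOError("list properties on vertices are not supported")
            props.append((tok[2], tok[1]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise CloudIOError(f"unsupported PLY format {fmt!r}")
    if n_vertex is None:
        raise CloudIOError("PLY header has no vertex element")
    names = [p[0] for p in props]
    for axis in ("x", "y", "z"):
        if axis not in names:
            raise CloudIOError(f"PLY vertex element lacks property {axis!r}")

    dtype = np.dtype([(name, _PLY_DTYPES[typ]) for name, typ in props])
    if fmt == "ascii":
        text = body.decode("ascii", errors="replace").split()
        expected = n_vertex * len(props)
        if len(text) < expected:
            raise CloudIOError("PLY body has fewer values than the header declares")
        arr = np.array(text[:expected], dtype=np.float64).reshape(n_vertex, len(props))
        rec = {name: arr[:, i] for i, (name, _) in enumerate(props)}
    else:
        need = dtype.itemsize * n_vertex
        if len(body) < need:
            raise CloudIOError("PLY binary body is shorter than the header declares")
        raw = np.frombuffer(body[:need], dtype=dtype)
        rec = {name: raw[name].astype(np.float64) for name, _ in props}

    pts = np.column_stack([rec["x"], rec["y"], rec["z"]])
    if "intensity" in rec:
        inten = rec["intensity"]
    elif all(c in rec for c in ("red", "green", "blue")):
        inten = rgb_to_intensity(np.column_stack([rec["red"], rec["green"], rec["blue"]]))
    else:
        inten = None
    return pts, inten


def _write_ply(cloud, path, *, binary: bool) -> None:
    n = len(cloud)
    has_i = cloud.intensity is not None
    fmt = "binary_little_endian 1.0" if binary else "ascii 1.0"
    header = ["ply", f"format {fmt}", f"element vertex {n}",
              "property float x", "property float y", "property float z"]
    if has_i:
        header.append("property double intensity")
    header.append("end_header")
    fields = [("x", "<f4"), ("y", "<f4"), ("z", "<f4")]
    if has_i:
        fields.append(("intensity", "<f8"))
    rec = np.zeros(n, dtype=np.dtype(fields))
    xyz = cloud.points.astype(np.float32)
    rec["x"], rec["y"], rec["z"] = xyz[:, 0], xyz[:, 1], xyz[:, 2]
    if has_i:
        rec["intensity"] = cloud.intensity
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(rec.tobytes())
        else:
            cols = [rec["x"], rec["y"], rec["z"]] + ([rec["intensity"]] if has_i else [])
            lines = []
            for row in zip(*cols):
                lines.append(" ".join(repr(float(v)) for v in row))
            fh.write(("\n".join(lines) + ("\n" if lines else "")).encode("ascii"))


# --------------------------------------------------------------------- PCD

def _read_pcd(path):
    with open(path, "rb") as fh:
        raw = fh.read()
    # header is ascii text up to and including the DATA line
    lines = []
    pos = 0
    data_kind = None
    while pos < len(raw):
        nl = raw.index(b"\n", pos)
        line = raw[pos:nl].decode("ascii", errors="replace").strip()
        pos = nl + 1
        if line.startswith("#") or not line:
            continue
        lines.append(line)
        if line.split()[0] == "DATA":
            data_kind = line.split()[1]
            break
    hdr = {l.split()[0]: l.split()[1:] for l in lines}
    if data_kind is None or "FIELDS" not in hdr or "POINTS" not in hdr:
        raise CloudIOError("malformed PCD header")
    fields = hdr["FIELDS"]
    sizes = [int(s) for s in hdr.get("SIZE", ["4"] * len(fields))]
    types = hdr.get("TYPE", ["F"] * len(fields))
    n = int(hdr["POINTS"][0])
    for axis in ("x", "y", "z"):
        if axis not in fields:
            raise CloudIOError(f"PCD lacks field {axis!r}")

    np_types = {("F", 4): "<f4", ("F", 8): "<f8", ("U", 1): "u1", ("U", 2): "<u2",
                ("U", 4): "<u4", ("I", 1): "i1", ("I", 2): "<i2", ("I", 4): "<i4"}
    dtype = np.dtype([(f, np_types[(t, s)]) for f, t, s in zip(fields, types, sizes)])

    if data_kind == "ascii":
        text = raw[pos:].decode("ascii", errors="replace").split()
        expected = n * len(fields)
        if len(text) < expected:
            raise CloudIOError("PCD body has fewer values than POINTS declares")
        arr = np.array(text[:expected], dtype=np.float64).reshape(n, len(fields))
        rec = {f: arr[:, i] for i, f in enumerate(fields)}
        if "rgb" in fields:
            # ascii rgb is the float re-interpretation of a packed 0x00RRGGBB
            packed = arr[:, fields.index("rgb")].astype(np.float32).view(np.uint32)
            rec["rgb"] = packed.astype(np.float64)
    elif data_kind == "binary":
        need = dtype.itemsize * n
        if len(raw) - pos < need:
            raise CloudIOError("PCD binary body is shorter than POINTS declares")
        rows = np.frombuffer(raw[pos:pos + need], dtype=dtype)
        rec = {f: rows[f].astype(np.float64) for f in fields}
        if "rgb" in fields:
            rec["rgb"] = rows["rgb"].view(np.uint32).astype(np.float64)
    else:
        raise CloudIOError(f"unsupported PCD data kind {data_kind!r}")

    pts = np.column_stack([rec["x"], rec["y"], rec["z"]])
    if "intensity" in rec:
        inten = rec["intensity"]
    elif "rgb" in rec:
        packed = rec["rgb"].astype(np.uint32)
        rgb = np.column_stack([(packed >> 16) & 0xFF, (packed >> 8) & 0xFF, packed & 0xFF])
        inten = rgb_to_intensity(rgb)
    else:
        inten = None
    return pts, inten


def _write_pcd(cloud, path, *, binary: bool) -> None:
    n = len(cloud)
    has_i = cloud.intensity is not None
    fields = ["x", "y", "z"] + (["intensity"] if has_i else [])
    sizes = ["4", "4", "4"] + (["8"] if has_i else [])
    header = [
        "# .PCD v0.7 - Point Cloud Data file format",
        "VERSION 0.7",
        "FIELDS " + " ".join(fields),
        "SIZE " + " ".join(sizes),
        "TYPE " + " ".join(["F"] * len(fields)),
        "COUNT " + " ".join(["1"] * len(fields)),
        f"WIDTH {n}",
        "HEIGHT 1",
        "VIEWPOINT 0 0 0 1 0 0 0",
        f"POINTS {n}",
        "DATA " + ("binary" if binary else "ascii"),
    ]
    dt = [("x", "<f4"), ("y", "<f4"), ("z", "<f4")] + ([("intensity", "<f8")] if has_i else [])
    rec = np.zeros(n, dtype=np.dtype(dt))
    xyz = cloud.points.astype(np.float32)
    rec["x"], rec["y"], rec["z"] = xyz[:, 0], xyz[:, 1], xyz[:, 2]
    if has_i:
        rec["intensity"] = cloud.intensity
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(rec.tobytes())
        else:
            cols = [rec[f] for f in fields]
            lines = [" ".join(repr(float(v)) for v in row) for row in zip(*cols)]
            fh.write(("\n".join(lines) + ("\n" if lines else "")).encode("ascii"))
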