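"""Minimal PLY vertex-cloud codec.

Reads ascii and binary_little_endian PLY files into a numpy structured
array of vertex properties; writes binary_little_endian. Only the vertex
element is handled (list properties and faces are skipped on read), which
is all a point-cloud pipeline needs.
"""
from __future__ import annotations

import numpy as np

_PLY_TO_NUMPY = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


class PLYFormatError(ValueError):
    """Raised when a file is not a parseable PLY vertex cloud."""


def _parse_header(fh):
    magic = fh.readline().strip()
    if magic != b"ply":
        raise PLYFormatError("not a PLY file (missing 'ply' magic)")
    fmt = None
    elements = []  # list of (name, count, [(prop_name, dtype_str)])
    current = None
    while True:
        line = fh.readline()
        if not line:
            raise PLYFormatError("unexpected end of header")
        tokens = line.decode("ascii", "replace").strip().split()
        if not tokens or tokens[0] == "comment":
            continue
        if tokens[0] == "format":
            fmt = tokens[1]
        elif tokens[0] == "element":
            current = (tokens[1], int(tokens[2]), [])
            elements.append(current)
        elif tokens[0] == "property":
            if current is None:
                raise PLYFormatError("property before element")
            if tokens[1] == "list":
                current[2].append((tokens[-1], ("list", tokens[2], tokens[3])))
            else:
                if tokens[1] not in _PLY_TO_NUMPY:
                    raise PLYFormatError(f"unsupported property type {tokens[1]}")
                current[2].append((tokens[-1], _PLY_TO_NUMPY[tokens[1]]))
        elif tokens[0] == "end_header":
            break
    if fmt not in ("ascii", "binary_little_endian"):
        raise PLYFormatError(f"unsupported PLY format {fmt!r}")
    return fmt, elements


def read_ply_vertices(path) -> np.ndarray:
    """Read the vertex element of a PLY file as a structured array."""
    with open(path, "rb") as fh:
        fmt, elements = _parse_header(fh)
        out = None
        for name, count, props in elements:
            if any(isinstance(d, tuple) for _, d in props):
                if name == "vertex":
                    raise PLYFormatError("list properties on vertices unsupported")
                break  # stop before list-typed elements (faces)
            dtype = np.dtype([(p, "<" + d) for p, d in props])
            if fmt == "ascii":
                rows = []
                for _ in range(count):
                    rows.append(tuple(fh.readline().split()))
                arr = np.array(rows, dtype=dtype) if count else np.empty(0, dtype)
            else:
                arr = np.frombuffer(fh.read(count * dtype.itemsize), dtype=dtype, count=count)
            if name == "vertex":
                out = arr
                break
        if out is None:
            raise PLYFormatError("no vertex element found")
        return out


def write_ply_vertices(path, arr: np.ndarray) -> None:
    """Write a structured array as a binary_little_endian PLY vertex element."""
    inverse = {v: k for k, v in _PLY_TO_NUMPY.items()
               if k in ("char", "uchar", "short", "ushort", "int", "uint",
                        "float", "double")}
    lines = ["ply", "format binary_little_endian 1.0",
             f"element vertex {arr.shape[0]}"]
    fields = []
    for name in arr.dtype.names:
        sub = arr.dtype[name]
        kind = sub.kind + str(sub.itemsize)
        if kind not in inverse:
            raise PLYFormatError(f"cannot encode dtype {sub} for property {name}")
        lines.append(f"property {inverse[kind]} {name}")
        fields.append((name, "<" + kind))
    lines.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(lines) + "\n").encode("ascii"))
        fh.write(np.ascontiguousarray(arr.astype(np.dtype(fields))).tobytes())
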