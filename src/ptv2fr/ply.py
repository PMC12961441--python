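"""PLY reader/writer for labeled clouds.

Supports the two dialects the pipeline produces and consumes: ``ascii 1.0``
and ``binary_little_endian 1.0`` vertex-only files with float ``x,y,z``,
optional uchar ``red,green,blue`` and optional int ``label``.  Files are
written binary-little-endian by default (compactness); ASCII on request.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .cloud import LabeledCloud

_PLY_TYPES = {
    "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


class PlyFormatError(ValueError):
    pass


def read_ply(path: str | Path) -> LabeledCloud:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise PlyFormatError(f"{path}: not a PLY file")
        fmt = None
        n_vertex = None
        props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise PlyFormatError(f"{path}: truncated header")
            tok = line.decode("ascii", "replace").split()
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
                    raise PlyFormatError(f"{path}: list properties not supported on vertices")
                props.append((tok[2], _PLY_TYPES[tok[1]]))
            elif tok[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise PlyFormatError(f"{path}: unsupported format {fmt!r}")
        names = [p[0] for p in props]
        if not {"x", "y", "z"} <= set(names):
            raise PlyFormatError(f"{path}: vertex element lacks x,y,z properties")
        dtype = np.dtype([(n, "<" + t) for n, t in props])
        if fmt == "binary_little_endian":
            data = np.frombuffer(fh.read(dtype.itemsize * n_vertex), dtype=dtype,
                                 count=n_vertex)
        else:
            rows = []
            while len(rows) < n_vertex:
                line = fh.readline()
                if not line:
                    raise PlyFormatError(f"{path}: truncated vertex data")
                if line.strip():
                    rows.append(tuple(line.split()))
            data = np.array(rows, dtype=dtype)
    points = np.stack([data["x"], data["y"], data["z"]], axis=1).astype(np.float64)
    if {"red", "green", "blue"} <= set(names):
        colors = np.stack([data["red"], data["green"], data["blue"]], axis=1).astype(np.uint8)
    else:
        colors = None
    labels = data["label"].astype(np.int64) if "label" in names else None
    pot_id = path.stem
    return LabeledCloud(points=points, colors=colors, labels=labels, pot_id=pot_id)


def write_ply(cloud: LabeledCloud, path: str | Path, binary: bool = True,
              write_labels: bool = True) -> None:
    path = Path(path)
    n = len(cloud)
    fmt = "binary_little_endian" if binary else "ascii"
    header = [
        "ply",
        f"format {fmt} 1.0",
        f"element vertex {n}",
        "property float x",
        "property float y",
        "property float z",
        "property uchar red",
        "property uchar green",
        "property uchar blue",
    ]
    if write_labels:
        header.append("property int label")
    header.append("end_header")
    xyz = cloud.points.astype(np.float32)
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fields = [("x", "<f4"), ("y", "<f4"), ("z", "<f4"),
                      ("red", "u1"), ("green", "u1"), ("blue", "u1")]
            if write_labels:
                fields.append(("label", "<i4"))
            rec = np.empty(n, dtype=np.dtype(fields))
            rec["x"], rec["y"], rec["z"] = xyz[:, 0], xyz[:, 1], xyz[:, 2]
            rec["red"], rec["green"], rec["blue"] = cloud.colors.T
            if write_labels:
                rec["label"] = cloud.labels.astype(np.int32)
            fh.write(rec.tobytes())
        else:
            for i in range(n):
                row = [repr(float(v)) for v in xyz[i]] + [str(int(v)) for v in cloud.colors[i]]
                if write_labels:
                    row.append(str(int(cloud.labels[i])))
                fh.write((" ".join(row) + "\n").encode("ascii"))
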