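"""Readers/writers for the pipeline's on-disk formats.

Meshes are written as OFF; per-vertex labels as two-column TSV
(vertex_id, label); signal/connectivity matrices as TSV; reports and
manifests as JSON; configs as YAML.  Floating-point values are written
with 12 significant digits so stage checksums are reproducible.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import yaml

from .mesh import SurfaceMesh

FLOAT_FMT = "%.12g"


def write_mesh_off(mesh: SurfaceMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {len(mesh.triangles)} 0\n")
        for xyz in mesh.coords:
            fh.write(" ".join(FLOAT_FMT % v for v in xyz) + "\n")
        for tri in mesh.triangles:
            fh.write("3 " + " ".join(str(int(v)) for v in tri) + "\n")


def read_mesh_off(path) -> SurfaceMesh:
    with open(path) as fh:
        tokens = fh.read().split()
    if tokens[0] != "OFF":
        raise ValueError("not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    body = tokens[4:]
    coords = np.array(body[: nv * 3], dtype=float).reshape(nv, 3)
    rest = body[nv * 3:]
    tris = []
    k = 0
    for _ in range(nf):
        cnt = int(rest[k])
        if cnt != 3:
            raise ValueError("only triangular faces supported")
        tris.append([int(rest[k + 1]), int(rest[k + 2]), int(rest[k + 3])])
        k += 4
    return SurfaceMesh(coords, np.asarray(tris, dtype=np.int64))


def write_labels_tsv(labels: np.ndarray, path, header: str = "label") -> None:
    with open(path, "w") as fh:
        fh.write(f"vertex_id\t{header}\n")
        for v, lab in enumerate(np.asarray(labels)):
            fh.write(f"{v}\t{int(lab)}\n")


def read_labels_tsv(path) -> np.ndarray:
    rows = np.loadtxt(path, dtype=np.int64, skiprows=1)
    order = np.argsort(rows[:, 0])
    return rows[order, 1]


def write_matrix_tsv(matrix: np.ndarray, path, row_labels=None) -> None:
    matrix = np.asarray(matrix)
    with open(path, "w") as fh:
        for i, row in enumerate(matrix):
            prefix = f"{row_labels[i]}\t" if row_labels is not None else ""
            fh.write(prefix + "\t".join(FLOAT_FMT % v for v in row) + "\n")


def read_matrix_tsv(path, has_row_labels: bool = False) -> np.ndarray:
    data = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if has_row_labels:
                parts = parts[1:]
            data.append([float(x) for x in parts])
    return np.asarray(data)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    version = cfg.get("schema_version", 1)
    if version != 1:
        raise ValueError(f"unsupported config schema_version: {version}")
    return cfg


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
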