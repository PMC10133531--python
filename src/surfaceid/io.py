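"""Readers/writers for every on-disk artifact.

Featurized surfaces travel as binary little-endian PLY with the five
feature channels as extra per-vertex float properties (plus normals);
geometry-only meshes can also be written as OFF.  A sidecar JSON
records provenance (source, parameters, standardization statistics).
Descriptor sets are stored one file per mesh together with the hash of
the model that produced them, so a search can refuse descriptors from
a different model.  Score matrices go to TSV, groups and transforms to
JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import trimesh

from .align import RigidTransform
from .mesh import FEATURE_CHANNELS, SurfaceMesh
from .search import Hit, HitGroup

__all__ = [
    "save_mesh_ply", "load_mesh_ply", "save_mesh_off",
    "save_descriptors", "load_descriptors",
    "save_groups", "load_groups", "save_transform", "load_transform",
    "save_score_matrix", "write_manifest",
]

_PLY_DTYPE = np.float32   # on-disk precision: binary little-endian float


def save_mesh_ply(path, mesh: SurfaceMesh, sidecar: bool = True) -> None:
    """Write a binary PLY with per-vertex features and a provenance sidecar.

    All per-vertex data is stored as 32-bit floats (the conventional PLY
    precision); a write -> read -> write cycle is bitwise stable.
    """
    path = Path(path)
    tm = trimesh.Trimesh(mesh.vertices.astype(_PLY_DTYPE),
                         mesh.faces, process=False)
    tm.vertex_attributes["nx"] = mesh.normals[:, 0].astype(_PLY_DTYPE)
    tm.vertex_attributes["ny"] = mesh.normals[:, 1].astype(_PLY_DTYPE)
    tm.vertex_attributes["nz"] = mesh.normals[:, 2].astype(_PLY_DTYPE)
    for i, name in enumerate(FEATURE_CHANNELS):
        tm.vertex_attributes[name] = mesh.features[:, i].astype(_PLY_DTYPE)
    tm.export(path, encoding="binary")
    if sidecar:
        side = {"mesh_id": mesh.mesh_id, "n_vertices": mesh.n_vertices,
                "n_faces": len(mesh.faces), "channels": list(FEATURE_CHANNELS),
                **{k: v for k, v in mesh.meta.items()
                   if isinstance(v, (str, int, float, bool, dict, list))}}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(side, indent=1))


def load_mesh_ply(path, mesh_id: str | None = None,
                  require_features: bool = True) -> SurfaceMesh:
    """Read a PLY written by :func:`save_mesh_ply`.

    Raises ``ValueError`` naming any missing feature property when
    ``require_features`` is set.
    """
    path = Path(path)
    tm = trimesh.load(path, process=False)
    raw = tm.metadata.get("_ply_raw", {}).get("vertex", {}).get("data")
    names = raw.dtype.names if raw is not None else ()
    features = np.full((len(tm.vertices), len(FEATURE_CHANNELS)), np.nan)
    missing = [c for c in FEATURE_CHANNELS if c not in names]
    if missing and require_features:
        raise ValueError(
            f"PLY {path.name} lacks feature properties: {', '.join(missing)}")
    for i, name in enumerate(FEATURE_CHANNELS):
        if name in names:
            features[:, i] = np.asarray(raw[name], dtype=float)
    if all(n in names for n in ("nx", "ny", "nz")):
        normals = np.column_stack([np.asarray(raw[n], dtype=float)
                                   for n in ("nx", "ny", "nz")])
    else:
        normals = np.asarray(tm.vertex_normals).copy()
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return SurfaceMesh(
        vertices=np.asarray(tm.vertices, dtype=float),
        faces=np.asarray(tm.faces), normals=normals, features=features,
        mesh_id=mesh_id or meta.get("mesh_id", path.stem), meta=meta)


def save_mesh_off(path, mesh: SurfaceMesh) -> None:
    """Geometry-only OFF export."""
    trimesh.Trimesh(mesh.vertices, mesh.faces, process=False).export(
        Path(path), file_type="off")


def save_descriptors(path, center_vertices: np.ndarray,
                     descriptors: np.ndarray, model_hash: str) -> None:
    np.savez_compressed(Path(path), center_vertices=center_vertices,
                        descriptors=descriptors,
                        model_hash=np.frombuffer(
                            model_hash.encode(), dtype=np.uint8))


def load_descriptors(path, expect_model_hash: str | None = None):
    with np.load(Path(path)) as z:
        centers = z["center_vertices"]
        desc = z["descriptors"]
        mh = bytes(z["model_hash"]).decode()
    if expect_model_hash is not None and mh != expect_model_hash:
        raise ValueError(
            f"descriptor store was produced by model {mh}, "
            f"expected {expect_model_hash}")
    return centers, desc, mh


def _group_to_dict(g: HitGroup) -> dict:
    return {
        "query_vertices": np.asarray(g.query_vertices).tolist(),
        "candidate_vertices": np.asarray(g.candidate_vertices).tolist(),
        "correspondences": [[h.query_vertex, h.candidate_vertex,
                             h.descriptor_distance]
                            for h in g.correspondences],
        "ss": g.ss, "extended": bool(g.extended),
        "query_vertices_extended": np.asarray(g.query_vertices_extended).tolist(),
        "candidate_vertices_extended":
            np.asarray(g.candidate_vertices_extended).tolist(),
        "meta": g.meta,
    }


def save_groups(path, groups: list[HitGroup]) -> None:
    Path(path).write_text(json.dumps([_group_to_dict(g) for g in groups]))


def load_groups(path) -> list[HitGroup]:
    out = []
    for d in json.loads(Path(path).read_text()):
        out.append(HitGroup(
            query_vertices=np.asarray(d["query_vertices"]),
            candidate_vertices=np.asarray(d["candidate_vertices"]),
            correspondences=[Hit(int(q), int(c), float(dd))
                             for q, c, dd in d["correspondences"]],
            ss=d["ss"], extended=d["extended"],
            query_vertices_extended=np.asarray(d["query_vertices_extended"]),
            candidate_vertices_extended=
                np.asarray(d["candidate_vertices_extended"]),
            meta=d.get("meta", {})))
    return out


def save_transform(path, transform: RigidTransform, extra: dict | None = None):
    payload = {"matrix": transform.as_matrix().tolist(), **(extra or {})}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_transform(path) -> RigidTransform:
    payload = json.loads(Path(path).read_text())
    return RigidTransform.from_matrix(np.asarray(payload["matrix"]))


def save_score_matrix(path, matrix: np.ndarray, names: list[str],
                      labels=None) -> None:
    """Symmetric score matrix as TSV (optionally with cluster labels)."""
    with open(path, "w") as fh:
        header = ["name"] + list(names)
        if labels is not None:
            header.append("cluster")
        fh.write("\t".join(header) + "\n")
        for i, name in enumerate(names):
            row = [name] + [f"{v:.6g}" for v in matrix[i]]
            if labels is not None:
                row.append(str(int(labels[i])))
            fh.write("\t".join(row) + "\n")


def write_manifest(out_dir, files: list, config: dict | None = None) -> Path:
    """Write a manifest of produced files with sha256 content hashes."""
    out_dir = Path(out_dir)
    entries = []
    for f in files:
        f = Path(f)
        digest = hashlib.sha256(f.read_bytes()).hexdigest()
        entries.append({"file": f.name, "sha256": digest,
                        "bytes": f.stat().st_size})
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps(
        {"files": entries, "config": config or {}}, indent=1))
    return manifest
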