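"""Readers and writers: PLY/OBJ scans, HDF5 model and gallery containers.

PLY is the canonical scan format (ascii and binary little-endian, via
trimesh); OBJ is accepted read-only.  Coordinates pass through unchanged —
the package assumes millimetres everywhere.  Models and galleries are
stored as HDF5 containers of named arrays with a content hash that is
verified on load.
"""

from __future__ import annotations

import csv
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import h5py
import numpy as np
import trimesh

from .errors import IntegrityError, InvalidInputError, ParseError
from .geometry import PointCloud
from .model import MorphableModel, ShapeParameters
from .recognition import Gallery
from .registration import TemplateMesh

__all__ = [
    "read_scan",
    "write_scan",
    "read_mesh",
    "save_model",
    "load_model",
    "save_gallery",
    "load_gallery",
    "write_scan_set",
    "read_scan_dir",
]

_SCHEMA_VERSION = 1


def _declared_ply_vertex_count(path: Path) -> int | None:
    """Vertex count declared in a PLY header, or None for non-PLY files."""
    try:
        with open(path, "rb") as fh:
            head = fh.read(16384)
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    if not head.startswith(b"ply"):
        return None
    count = None
    for offset, line in enumerate(head.split(b"\n")):
        token = line.strip().split()
        if len(token) == 3 and token[0] == b"element" and token[1] == b"vertex":
            try:
                count = int(token[2])
            except ValueError as exc:
                raise ParseError(f"{path}: malformed vertex count near header line {offset}") from exc
        if line.strip() == b"end_header":
            return count
    raise ParseError(f"{path}: PLY header has no end_header within the first 16 kB")


def read_scan(path, label: str | None = None, scan_id: str | None = None) -> PointCloud:
    """Load a PLY or OBJ file as a point cloud (faces ignored, not required).

    Raises :class:`ParseError` on malformed or truncated files — a PLY file
    whose header declares more vertices than the body provides is rejected
    rather than silently partially loaded.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    declared = _declared_ply_vertex_count(path) if path.suffix.lower() == ".ply" else None
    try:
        obj = trimesh.load(str(path), process=False)
    except Exception as exc:  # trimesh raises a zoo of types on bad input
        raise ParseError(f"{path}: {exc}") from exc
    verts = np.asarray(getattr(obj, "vertices", np.empty((0, 3))), dtype=float)
    if verts.size == 0:
        raise ParseError(f"{path}: no vertices found")
    if declared is not None and verts.shape[0] != declared:
        raise ParseError(
            f"{path}: truncated PLY — header declares {declared} vertices, "
            f"file holds {verts.shape[0]}"
        )
    return PointCloud(verts, label=label, scan_id=scan_id or path.stem)


def write_scan(cloud: PointCloud, path, faces: np.ndarray | None = None, binary: bool = False) -> Path:
    """Write a point cloud (optionally with faces) as a PLY file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if faces is not None:
        mesh = trimesh.Trimesh(vertices=cloud.points, faces=faces, process=False)
        encoding = "binary" if binary else "ascii"
        mesh.export(str(path), file_type="ply", encoding=encoding)
    else:
        pc = trimesh.PointCloud(cloud.points)
        data = pc.export(file_type="ply")
        if not binary:
            data = _ascii_point_ply(cloud.points)
        path.write_bytes(data if isinstance(data, bytes) else data.encode())
    return path


def _ascii_point_ply(points: np.ndarray) -> bytes:
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {points.shape[0]}",
        "property float x",
        "property float y",
        "property float z",
        "end_header",
    ]
    body = "\n".join(" ".join(f"{c:.8g}" for c in p) for p in points)
    return ("\n".join(lines) + "\n" + body + "\n").encode()


def read_mesh(path) -> TemplateMesh:
    """Load a PLY/OBJ file that carries faces as a template mesh."""
    path = Path(path)
    try:
        obj = trimesh.load(str(path), process=False)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    faces = np.asarray(getattr(obj, "faces", np.empty((0, 3))), dtype=np.int64)
    if faces.size == 0:
        raise ParseError(f"{path}: no faces — not usable as a template mesh")
    return TemplateMesh(np.asarray(obj.vertices, dtype=float), faces)


def _content_hash(arrays: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for name in sorted(arrays):
        h.update(name.encode())
        h.update(np.ascontiguousarray(arrays[name]).tobytes())
    return h.hexdigest()


def save_model(model: MorphableModel, path, provenance: dict | None = None) -> Path:
    """Serialize a morphable model to an HDF5 container with a content hash."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {
        "mean": model.mean,
        "components": model.components,
        "eigenvalues": model.eigenvalues,
    }
    if model.faces is not None:
        arrays["faces"] = model.faces
    with h5py.File(path, "w") as fh:
        for name, arr in arrays.items():
            fh.create_dataset(name, data=arr)
        fh.attrs["schema_version"] = _SCHEMA_VERSION
        fh.attrs["kind"] = "morphable-model"
        fh.attrs["topology_id"] = model.topology_id
        fh.attrs["content_hash"] = _content_hash(arrays)
        fh.attrs["created"] = datetime.now(timezone.utc).isoformat()
        fh.attrs["provenance"] = json.dumps(provenance or {})
    return path


def load_model(path) -> MorphableModel:
    """Load a model container, verifying the content hash and orthonormality."""
    path = Path(path)
    try:
        with h5py.File(path, "r") as fh:
            if fh.attrs.get("kind") != "morphable-model":
                raise IntegrityError(f"{path}: not a morphable-model container")
            if int(fh.attrs.get("schema_version", -1)) > _SCHEMA_VERSION:
                raise IntegrityError(f"{path}: container schema is newer than this package")
            arrays = {name: np.asarray(fh[name]) for name in fh.keys()}
            stored = str(fh.attrs["content_hash"])
            tid = str(fh.attrs["topology_id"])
    except OSError as exc:
        raise IntegrityError(f"{path}: unreadable container ({exc})") from exc
    if _content_hash(arrays) != stored:
        raise IntegrityError(f"{path}: content hash mismatch — container corrupted or tampered")
    try:
        return MorphableModel(
            mean=arrays["mean"],
            components=arrays["components"],
            eigenvalues=arrays["eigenvalues"],
            topology_id=tid,
            faces=arrays.get("faces"),
        )
    except InvalidInputError as exc:
        raise IntegrityError(f"{path}: invalid model content ({exc})") from exc


def save_gallery(gallery: Gallery, path, provenance: dict | None = None) -> Path:
    """Serialize a gallery (labeled α vectors + model hash) to HDF5."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels = gallery.labels
    alphas = gallery.alpha_matrix() if labels else np.empty((0, 0))
    arrays = {"alphas": alphas}
    with h5py.File(path, "w") as fh:
        fh.create_dataset("alphas", data=alphas)
        fh.create_dataset("labels", data=np.array(labels, dtype=h5py.string_dtype()))
        fh.attrs["schema_version"] = _SCHEMA_VERSION
        fh.attrs["kind"] = "gallery"
        fh.attrs["model_hash"] = gallery.model_hash
        fh.attrs["created"] = gallery.created
        fh.attrs["content_hash"] = _content_hash(arrays)
        fh.attrs["provenance"] = json.dumps(provenance or {})
        fh.attrs["diagnostics"] = json.dumps(gallery.diagnostics)
    return path


def load_gallery(path, expected_model_hash: str | None = None) -> Gallery:
    """Load a gallery container; refuses galleries from a different model."""
    path = Path(path)
    try:
        with h5py.File(path, "r") as fh:
            if fh.attrs.get("kind") != "gallery":
                raise IntegrityError(f"{path}: not a gallery container")
            alphas = np.asarray(fh["alphas"])
            labels = [l.decode() if isinstance(l, bytes) else str(l) for l in fh["labels"][()]]
            model_hash = str(fh.attrs["model_hash"])
            created = str(fh.attrs["created"])
            stored = str(fh.attrs["content_hash"])
            diagnostics = json.loads(fh.attrs.get("diagnostics", "{}"))
    except OSError as exc:
        raise IntegrityError(f"{path}: unreadable container ({exc})") from exc
    if _content_hash({"alphas": alphas}) != stored:
        raise IntegrityError(f"{path}: content hash mismatch — container corrupted or tampered")
    if expected_model_hash is not None and model_hash != expected_model_hash:
        raise IntegrityError(
            f"{path}: gallery was built from model {model_hash}, expected {expected_model_hash}"
        )
    entries = {
        label: ShapeParameters(alphas[i], model_hash, label=label) for i, label in enumerate(labels)
    }
    return Gallery(entries=entries, model_hash=model_hash, created=created, diagnostics=diagnostics)


def write_scan_set(scan_set, directory) -> Path:
    """Write a synthetic scan set as PLY files plus manifest and truth CSVs.

    Layout: ``gallery/<scan_id>.ply``, ``probes/<scan_id>.ply``,
    ``manifest.csv`` (path, label, split) and ``truth.csv`` (label, one
    column per latent coefficient).
    """
    directory = Path(directory)
    (directory / "gallery").mkdir(parents=True, exist_ok=True)
    (directory / "probes").mkdir(parents=True, exist_ok=True)
    rows = []
    for split, scans in (("gallery", scan_set.gallery_scans), ("probes", scan_set.probe_scans)):
        for scan in scans:
            rel = f"{split}/{scan.scan_id}.ply"
            write_scan(scan, directory / rel)
            rows.append((rel, scan.label, split))
    with open(directory / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["path", "label", "split"])
        w.writerows(rows)
    latent_dim = len(next(iter(scan_set.truth.values())))
    with open(directory / "truth.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label"] + [f"alpha_{k}" for k in range(latent_dim)])
        for label in sorted(scan_set.truth):
            w.writerow([label] + [f"{v:.10g}" for v in scan_set.truth[label]])
    return directory


def read_scan_dir(directory, split: str | None = None) -> list[PointCloud]:
    """Read scans from a directory, honoring ``manifest.csv`` when present.

    Without a manifest, every ``*.ply``/``*.obj`` file is read and the label
    is the filename stem up to the first underscore.
    """
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    scans: list[PointCloud] = []
    if manifest.exists():
        with open(manifest, newline="") as fh:
            for row in csv.DictReader(fh):
                if split is not None and row["split"] != split:
                    continue
                p = directory / row["path"]
                scans.append(read_scan(p, label=row["label"], scan_id=Path(row["path"]).stem))
    else:
        for p in sorted(directory.rglob("*")):
            if p.suffix.lower() in (".ply", ".obj"):
                scans.append(read_scan(p, label=p.stem.split("_")[0], scan_id=p.stem))
    if not scans:
        raise InvalidInputError(f"no scans found under {directory}")
    return scans
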