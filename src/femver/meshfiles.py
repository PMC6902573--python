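"""Reading and writing surface models (ASCII PLY / STL / OBJ) and landmark JSON.

The landmark file is a JSON object mapping canonical landmark names to
``[x, y, z]`` in the mesh coordinate system, with two reserved keys:
``side`` ("left" | "right") and ``STEM_NECK`` (a list of face indices
labelling the implant-neck region on postoperative models).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import STEM_NECK, SurfaceModel

_FORMATS = (".ply", ".stl", ".obj")


# -- landmarks --------------------------------------------------------------


def write_landmarks(model: SurfaceModel, path) -> None:
    payload: dict = {k: [float(x) for x in v] for k, v in model.landmarks.items()}
    payload["side"] = model.side
    for label, idx in model.face_labels.items():
        payload[label] = [int(i) for i in idx]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_landmarks(path) -> tuple[dict, str, dict]:
    """Returns (landmarks, side, face_labels)."""
    raw = json.loads(Path(path).read_text())
    side = raw.pop("side", "right")
    face_labels = {}
    if STEM_NECK in raw:
        face_labels[STEM_NECK] = np.asarray(raw.pop(STEM_NECK), dtype=np.int64)
    landmarks = {k: np.asarray(v, dtype=float) for k, v in raw.items()}
    return landmarks, side, face_labels


# -- meshes -----------------------------------------------------------------


def write_mesh(model: SurfaceModel, path) -> None:
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".ply":
        _write_ply(model, path)
    elif ext == ".stl":
        _write_stl(model, path)
    elif ext == ".obj":
        _write_obj(model, path)
    else:
        raise ValueError(f"unsupported mesh format {ext!r} (use {_FORMATS})")


def read_mesh(path, landmarks_path=None) -> SurfaceModel:
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".ply":
        v, f = _read_ply(path)
    elif ext == ".stl":
        v, f = _read_stl(path)
    elif ext == ".obj":
        v, f = _read_obj(path)
    else:
        raise ValueError(f"unsupported mesh format {ext!r} (use {_FORMATS})")
    landmarks, side, labels = ({}, "right", {})
    if landmarks_path is not None:
        landmarks, side, labels = read_landmarks(landmarks_path)
    return SurfaceModel(v, f, landmarks, side, labels)


def _write_ply(model: SurfaceModel, path: Path) -> None:
    v, f = model.vertices, model.faces
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(v)}",
        "property float x",
        "property float y",
        "property float z",
        f"element face {len(f)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    body_v = "\n".join(f"{a:.8g} {b:.8g} {c:.8g}" for a, b, c in v)
    body_f = "\n".join(f"3 {a} {b} {c}" for a, b, c in f)
    path.write_text("\n".join(lines) + "\n" + body_v + "\n" + body_f + "\n")


def _read_ply(path: Path) -> tuple[np.ndarray, np.ndarray]:
    text = path.read_text().splitlines()
    if not text or text[0].strip() != "ply":
        raise ValueError(f"{path} is not a PLY file")
    n_v = n_f = 0
    i = 0
    for i, line in enumerate(text):
        t = line.split()
        if t[:2] == ["element", "vertex"]:
            n_v = int(t[2])
        elif t[:2] == ["element", "face"]:
            n_f = int(t[2])
        elif t and t[0] == "format" and t[1] != "ascii":
            raise ValueError("only ASCII PLY is supported")
        elif t and t[0] == "end_header":
            break
    body = text[i + 1 :]
    v = np.array([[float(x) for x in ln.split()[:3]] for ln in body[:n_v]])
    f = np.array(
        [[int(x) for x in ln.split()[1:4]] for ln in body[n_v : n_v + n_f]],
        dtype=np.int64,
    )
    return v, f


def _write_obj(model: SurfaceModel, path: Path) -> None:
    out = ["# femver surface model"]
    out += [f"v {a:.8g} {b:.8g} {c:.8g}" for a, b, c in model.vertices]
    out += [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in model.faces]
    path.write_text("\n".join(out) + "\n")


def _read_obj(path: Path) -> tuple[np.ndarray, np.ndarray]:
    verts, faces = [], []
    for line in path.read_text().splitlines():
        t = line.split()
        if not t:
            continue
        if t[0] == "v":
            verts.append([float(x) for x in t[1:4]])
        elif t[0] == "f":
            faces.append([int(x.split("/")[0]) - 1 for x in t[1:4]])
    return np.asarray(verts, dtype=float), np.asarray(faces, dtype=np.int64)


def _write_stl(model: SurfaceModel, path: Path) -> None:
    v, f = model.vertices, model.faces
    tri = v[f]  # (m, 3, 3)
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    n = np.divide(n, norm, out=np.zeros_like(n), where=norm > 0)
    out = ["solid femver"]
    for normal, pts in zip(n, tri):
        out.append(f" facet normal {normal[0]:.8g} {normal[1]:.8g} {normal[2]:.8g}")
        out.append("  outer loop")
        for p in pts:
            out.append(f"   vertex {p[0]:.8g} {p[1]:.8g} {p[2]:.8g}")
        out.append("  endloop")
        out.append(" endfacet")
    out.append("endsolid femver")
    path.write_text("\n".join(out) + "\n")


def _read_stl(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """ASCII STL; duplicated triangle-soup vertices are merged exactly."""
    pts = []
    for line in path.read_text().splitlines():
        t = line.split()
        if t and t[0] == "vertex":
            pts.append([float(x) for x in t[1:4]])
    soup = np.asarray(pts, dtype=float)
    if len(soup) % 3:
        raise ValueError("malformed STL: vertex count not a multiple of 3")
    uniq, inverse = np.unique(soup.round(8), axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3).astype(np.int64)
    return uniq, faces
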