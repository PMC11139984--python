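"""STL input/output and shared-vertex welding for dental surface scans.

Intraoral scanners export STL, which stores an unindexed triangle soup:
every triangle carries its three corner coordinates verbatim, so a vertex
shared by k triangles appears k times in the file.  The grid-cutting
pipeline is vertex-based, so on read the soup is *welded* into a
shared-vertex mesh: corner points whose coordinates agree to within
``WELD_TOLERANCE`` on every axis are merged into a single vertex.
Coordinates are taken as millimetres, unchanged.

File normals are ignored; orientation is established geometrically by the
occlusal-side-up step downstream.  Non-manifold and disconnected meshes are
accepted — intraoral scans routinely contain unconnected cheek or lip flaps
and the algorithm never walks the surface.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

log = logging.getLogger(__name__)

#: Two triangle corners are considered the same scanner vertex when every
#: coordinate agrees to within this distance (mm).  Scanner exports repeat
#: shared corners bit-identically; a larger tolerance risks fusing fine
#: occlusal detail.
WELD_TOLERANCE = 1e-6


class MeshError(ValueError):
    """Base class for mesh I/O and validation errors."""


class MeshFormatError(MeshError):
    """The file is not parseable as ASCII or binary STL."""


class EmptyMeshError(MeshError):
    """The STL solid contains no triangles."""


@dataclass(frozen=True)
class SurfaceMesh:
    """A shared-vertex triangle mesh in millimetres.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm.
    faces : (m, 3) int array
        Triangles as triples of vertex indices.  Edges are implicit as
        face boundaries.

    An empty mesh (zero vertices, zero faces) is a valid value — a crop can
    legitimately remove everything — but operations that fit planes or
    build grids require at least three vertices.
    """

    vertices: np.ndarray
    faces: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=np.int64))

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        f = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(v)):
            raise MeshError("mesh has non-finite vertex coordinates")
        if f.size:
            if f.min() < 0 or f.max() >= len(v):
                raise MeshError(
                    f"face index out of range (vertex count {len(v)}, "
                    f"max index {f.max() if f.size else 'n/a'})"
                )
            degenerate_idx = (
                (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
            )
            if degenerate_idx.any():
                raise MeshError(
                    f"{int(degenerate_idx.sum())} face(s) repeat a vertex index"
                )
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) corner of the axis-aligned bounding box."""
        if self.n_vertices == 0:
            raise EmptyMeshError("empty mesh has no bounding box")
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def translated(self, offset) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices + np.asarray(offset, dtype=np.float64), self.faces)


def weld(corners: np.ndarray, tolerance: float = WELD_TOLERANCE) -> tuple[np.ndarray, np.ndarray]:
    """Merge coincident points; return (unique vertices, index map).

    Points are binned by quantising each coordinate to ``tolerance``; all
    points in one bin collapse onto the coordinates of the first occurrence,
    so no coordinate moves by more than ``tolerance`` per axis.  First-seen
    order of the surviving vertices is preserved, which keeps welding
    deterministic across dialects.
    """
    corners = np.asarray(corners, dtype=np.float64).reshape(-1, 3)
    keys = np.round(corners / tolerance).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    # np.unique sorts lexicographically; remap to first-seen order.
    order = np.argsort(first, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return corners[first[order]], rank[inverse]


def _classify_stl(data: bytes, path: Path) -> str:
    """Return 'ascii' or 'binary', or raise MeshFormatError with a location."""
    stripped = data.lstrip()
    if stripped[:5].lower() == b"solid" and b"facet" in data[:4096]:
        return "ascii"
    if len(data) >= 84:
        n = int(np.frombuffer(data[80:84], dtype="<u4")[0])
        if len(data) >= 84 + 50 * n:
            return "binary"
        raise MeshFormatError(
            f"{path}: binary STL header at byte 80 declares {n} triangles "
            f"({84 + 50 * n} bytes) but the file has only {len(data)} bytes"
        )
    if stripped[:5].lower() == b"solid":
        return "ascii"  # empty or header-only ASCII solid; parser decides
    raise MeshFormatError(
        f"{path}: not an STL file — no 'solid' keyword at byte 0 and "
        f"too short ({len(data)} bytes) for a binary header"
    )


def read_stl(path) -> SurfaceMesh:
    """Read an ASCII or binary STL file into a welded shared-vertex mesh.

    Raises
    ------
    MeshFormatError
        If the file is not parseable STL (the message names the offending
        byte offset or line).
    EmptyMeshError
        If the solid contains no triangles.
    """
    path = Path(path)
    data = path.read_bytes()
    dialect = _classify_stl(data, path)
    try:
        raw = trimesh.load(
            io.BytesIO(data), file_type="stl", process=False, force="mesh"
        )
    except Exception as exc:  # trimesh raises plain ValueError on bad ASCII
        raise MeshFormatError(f"{path}: unparseable {dialect} STL ({exc})") from exc
    if not isinstance(raw, trimesh.Trimesh) or len(raw.faces) == 0:
        if dialect == "ascii" and b"facet" in data:
            line = data[: data.find(b"facet")].count(b"\n") + 1
            raise MeshFormatError(
                f"{path}: ASCII STL declares facets but none could be parsed "
                f"(first facet near line {line})"
            )
        raise EmptyMeshError(f"{path}: STL solid contains no triangles")
    corners = np.asarray(raw.vertices, dtype=np.float64)[np.asarray(raw.faces).ravel()]
    vertices, index_map = weld(corners)
    faces = index_map.reshape(-1, 3)
    degenerate = (
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 0] == faces[:, 2])
    )
    if degenerate.any():
        # Zero-area slivers are common in scanner output; they carry no
        # vertex information beyond their corners, which welding kept.
        log.info("%s: dropped %d degenerate triangle(s)", path, int(degenerate.sum()))
        faces = faces[~degenerate]
        if len(faces) == 0:
            raise EmptyMeshError(f"{path}: all triangles are degenerate")
    return SurfaceMesh(vertices, faces)


def write_stl(mesh: SurfaceMesh, path, dialect: str = "binary") -> None:
    """Write a mesh as STL.  ``dialect`` is ``'binary'`` or ``'ascii'``.

    STL stores triangles only, so vertices not referenced by any face are
    not representable and are dropped by the format itself.
    """
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"dialect must be 'binary' or 'ascii', got {dialect!r}")
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    payload = tm.export(file_type="stl" if dialect == "binary" else "stl_ascii")
    if isinstance(payload, str):
        payload = payload.encode("ascii")
    try:
        path.write_bytes(payload)
    except OSError as exc:
        raise MeshError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Label sidecar (synthetic fixtures): one label per vertex line, in welded
# vertex order, values {tooth, soft}.

LABEL_VALUES = ("tooth", "soft")


def write_labels(labels, path) -> None:
    labels = list(labels)
    bad = sorted({str(l) for l in labels} - set(LABEL_VALUES))
    if bad:
        raise ValueError(f"unknown label value(s): {bad}")
    Path(path).write_text("\n".join(str(l) for l in labels) + "\n")


def read_labels(path) -> np.ndarray:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    for i, ln in enumerate(lines, start=1):
        if ln not in LABEL_VALUES:
            raise ValueError(f"{path}: line {i}: unknown label {ln!r}")
    return np.array(lines)
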