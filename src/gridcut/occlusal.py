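"""Scan orientation and occlusal-plane approximation.

The occlusal plane is the imaginary plane touching the biting surfaces of
the posterior teeth and the incisal edges of the front teeth.  It is
approximated in five steps over an occlusal-side-up mesh:

1. fit a least-squares plane through *all* vertices (the "fitting plane");
2. discard every vertex strictly below that plane — what survives is the
   upper relief: cusps, incisal edges, and whatever soft tissue rises that
   high;
3. partition the survivors' xy-bounding box into six sections (thirds in x,
   halves in y);
4. in each section pick the vertex farthest above the fitting plane (the
   *section representative* — an approximate occlusal point);
5. of the representatives, keep the four with the largest z and fit a
   least-squares plane through them: the approximated occlusal plane.

"Least squares" here is ordinary least squares of z on (x, y): the scan is
oriented z-up and every comparison in the pipeline ("below the plane",
"largest z") is z-based, so the z-residual fit is the consistent choice
over total least squares.  The same routine fits both planes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .mesh_io import EmptyMeshError, MeshError, SurfaceMesh

Jaw = Literal["maxilla", "mandible"]

JAWS = ("maxilla", "mandible")

#: Section grid: thirds along x, halves along y → 3 × 2 = 6 sections.
N_SECTIONS_X = 3
N_SECTIONS_Y = 2
N_REPRESENTATIVES = 4


class DegenerateFitError(MeshError):
    """The points are collinear in xy-projection; no unique plane fits."""


class OcclusalApproximationError(MeshError):
    """Too few non-empty sections to pick four occlusal representatives."""


@dataclass(frozen=True)
class PlaneFit:
    """The plane z = a·x + b·y + c, with an upward unit normal.

    ``a`` and ``b`` are slopes (mm/mm), ``c`` the height at the origin (mm).
    The unit normal is proportional to (−a, −b, 1), so its z-component is
    always positive.
    """

    a: float
    b: float
    c: float

    @property
    def normal(self) -> np.ndarray:
        n = np.array([-self.a, -self.b, 1.0])
        return n / np.linalg.norm(n)

    def height(self, x, y):
        """z of the plane above (x, y)."""
        return self.a * np.asarray(x) + self.b * np.asarray(y) + self.c

    def signed_distance(self, points) -> np.ndarray:
        """Perpendicular distance, positive above the plane, negative below."""
        p = np.atleast_2d(np.asarray(points, dtype=np.float64))
        res = p[..., 2] - self.height(p[..., 0], p[..., 1])
        return res * self.normal[2]

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "c": self.c, "normal": self.normal.tolist()}


@dataclass(frozen=True)
class SectionRecord:
    """One of the six occlusal sections and its representative vertex."""

    index: tuple[int, int]          # (x-third, y-half)
    x_bounds: tuple[float, float]
    y_bounds: tuple[float, float]
    n_vertices: int
    rep_id: int | None              # vertex id in the input mesh; None if empty
    rep_xyz: tuple[float, float, float] | None
    rep_distance: float | None      # perpendicular distance above fitting plane
    chosen: bool

    def to_dict(self) -> dict:
        return {
            "index": list(self.index),
            "x_bounds": list(self.x_bounds),
            "y_bounds": list(self.y_bounds),
            "n_vertices": self.n_vertices,
            "rep_id": self.rep_id,
            "rep_xyz": list(self.rep_xyz) if self.rep_xyz is not None else None,
            "rep_distance": self.rep_distance,
            "chosen": self.chosen,
        }


@dataclass(frozen=True)
class SectionReport:
    """Full account of the occlusal approximation, for the run report."""

    fitting_plane: PlaneFit
    sections: tuple[SectionRecord, ...]
    chosen_ids: tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "fitting_plane": self.fitting_plane.to_dict(),
            "sections": [s.to_dict() for s in self.sections],
            "chosen_ids": list(self.chosen_ids),
        }


def orient(mesh: SurfaceMesh, jaw: str) -> SurfaceMesh:
    """Turn the scan occlusal-side-up.

    Mandibular scans already face up and are returned unchanged.  Maxillary
    scans are rotated 180° about the x-axis through the mesh centroid — a
    rigid flip that preserves chirality (a mirror would swap left and right
    anatomy).  Connectivity is untouched.
    """
    if jaw not in JAWS:
        raise ValueError(f"jaw must be one of {JAWS}, got {jaw!r}")
    if jaw == "mandible":
        return mesh
    if mesh.n_vertices == 0:
        raise EmptyMeshError("cannot orient an empty mesh")
    centroid = mesh.vertices.mean(axis=0)
    v = mesh.vertices.copy()
    v[:, 1] = 2.0 * centroid[1] - v[:, 1]
    v[:, 2] = 2.0 * centroid[2] - v[:, 2]
    return SurfaceMesh(v, mesh.faces)


def fit_plane_mse(points) -> PlaneFit:
    """Least-squares plane z = a·x + b·y + c minimising mean squared z-residual.

    Raises :class:`DegenerateFitError` when the xy-projection of the points
    is rank-deficient (fewer than three points, or all collinear).
    """
    p = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(p) < 3:
        raise DegenerateFitError(f"plane fit needs ≥3 points, got {len(p)}")
    design = np.column_stack([p[:, 0], p[:, 1], np.ones(len(p))])
    coeffs, _, rank, _ = np.linalg.lstsq(design, p[:, 2], rcond=None)
    if rank < 3:
        raise DegenerateFitError(
            "points are collinear in the xy-projection; plane fit is degenerate"
        )
    return PlaneFit(a=float(coeffs[0]), b=float(coeffs[1]), c=float(coeffs[2]))


def _section_index(xy: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Map xy points into the 3×2 section grid over [lo, hi] (half-open bins,
    last bin closed)."""
    extent = hi - lo
    nx, ny = N_SECTIONS_X, N_SECTIONS_Y
    with np.errstate(divide="ignore", invalid="ignore"):
        fx = np.where(extent[0] > 0, (xy[:, 0] - lo[0]) / extent[0], 0.0)
        fy = np.where(extent[1] > 0, (xy[:, 1] - lo[1]) / extent[1], 0.0)
    ix = np.minimum((fx * nx).astype(np.int64), nx - 1)
    iy = np.minimum((fy * ny).astype(np.int64), ny - 1)
    return ix, iy


def approximate_occlusal_plane(mesh: SurfaceMesh) -> tuple[PlaneFit, SectionReport]:
    """Approximate the occlusal plane of an occlusal-side-up scan.

    The input mesh is not modified; the below-plane cut applies only within
    this computation.  Vertices exactly on the fitting plane survive the
    cut.  Ties (equal distance within a section, equal z among
    representatives) are broken toward the lowest vertex id so the result
    is order-stable and deterministic.

    Returns the occlusal :class:`PlaneFit` and a :class:`SectionReport`
    recording the six sections, their representatives, and which four were
    used.

    Raises :class:`OcclusalApproximationError` when fewer than four
    sections contain vertices above the fitting plane.
    """
    if mesh.n_vertices < 3:
        raise EmptyMeshError(
            f"occlusal approximation needs ≥3 vertices, got {mesh.n_vertices}"
        )
    fitting = fit_plane_mse(mesh.vertices)
    dist = fitting.signed_distance(mesh.vertices)
    above = dist >= 0.0  # non-strict: on-plane vertices survive
    ids_above = np.flatnonzero(above)
    if len(ids_above) == 0:
        raise OcclusalApproximationError("no vertices on or above the fitting plane")
    xy = mesh.vertices[ids_above, :2]
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    ix, iy = _section_index(xy, lo, hi)

    x_edges = np.linspace(lo[0], hi[0], N_SECTIONS_X + 1)
    y_edges = np.linspace(lo[1], hi[1], N_SECTIONS_Y + 1)

    reps: list[tuple[int, float, float]] = []  # (vertex id, distance, z)
    records: list[dict] = []
    empty_sections: list[tuple[int, int]] = []
    for i in range(N_SECTIONS_X):
        for j in range(N_SECTIONS_Y):
            in_section = (ix == i) & (iy == j)
            n_in = int(in_section.sum())
            rec = {
                "index": (i, j),
                "x_bounds": (float(x_edges[i]), float(x_edges[i + 1])),
                "y_bounds": (float(y_edges[j]), float(y_edges[j + 1])),
                "n_vertices": n_in,
            }
            if n_in == 0:
                empty_sections.append((i, j))
                rec.update(rep_id=None, rep_xyz=None, rep_distance=None)
            else:
                member_ids = ids_above[in_section]  # ascending → argmax = lowest id
                member_dist = dist[member_ids]
                rep = member_ids[int(np.argmax(member_dist))]
                rec.update(
                    rep_id=int(rep),
                    rep_xyz=tuple(float(v) for v in mesh.vertices[rep]),
                    rep_distance=float(dist[rep]),
                )
                reps.append((int(rep), float(dist[rep]), float(mesh.vertices[rep, 2])))
            records.append(rec)

    if len(reps) < N_REPRESENTATIVES:
        raise OcclusalApproximationError(
            f"only {len(reps)} of {N_SECTIONS_X * N_SECTIONS_Y} sections are "
            f"non-empty above the fitting plane (need ≥{N_REPRESENTATIVES}); "
            f"empty sections: {empty_sections}"
        )

    # Four representatives with the largest z; lowest id on z-ties.
    reps_sorted = sorted(reps, key=lambda r: (-r[2], r[0]))
    chosen_ids = tuple(r[0] for r in reps_sorted[:N_REPRESENTATIVES])
    occlusal = fit_plane_mse(mesh.vertices[list(chosen_ids)])

    sections = tuple(
        SectionRecord(chosen=rec["rep_id"] in chosen_ids, **rec) for rec in records
    )
    return occlusal, SectionReport(
        fitting_plane=fitting, sections=sections, chosen_ids=chosen_ids
    )
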