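"""Grid splitting, per-square analysis, and the unified grid-cutting crop.

The method rests on three user variables:

``G`` (grid size, mm)
    Edge length of the xy-grid squares; the granularity of the crop.
``I`` (inclusion criterion, mm)
    Within each square, how far below the square's highest vertex —
    measured along the occlusal-plane normal — the surface is retained.
``R`` (ratio of inclusion, fraction)
    Whole-square exclusion: if the square's highest vertex lies further
    below the occlusal plane than ``R`` times the scan's total z-range, the
    square contains no tooth and is removed wholesale.

Each square is analysed independently.  The square's highest-z vertex is
its *evaluation point* E_p (a fast stand-in for the vertex closest to the
occlusal plane).  For squares that survive the R-check, an inclusion
threshold point is placed I mm from E_p along the occlusal normal N_o, on
the side away from the occlusal plane (E_p is the square's top, so the
retained band extends downward from it): T = E_p − I·N_o, with N_o
normalised to point up.  Every vertex with z at or above z(T) is kept.

The crop is purely per-vertex: no vertex is ever moved or created, and a
face is dropped as soon as any of its corners is removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .mesh_io import EmptyMeshError, SurfaceMesh
from .occlusal import (
    JAWS,
    PlaneFit,
    SectionReport,
    approximate_occlusal_plane,
    orient,
)

#: Defaults: grid size 1 mm, inclusion criterion 7 mm, ratio of inclusion
#: 33% of the scan's z-range (empirically determined).
DEFAULT_GRID_SIZE = 1.0
DEFAULT_INCLUSION = 7.0
DEFAULT_RATIO = 0.33

Verdict = Literal["excluded_empty", "excluded_far", "cropped"]


@dataclass(frozen=True)
class CropParams:
    """User parameters of one grid-cutting run."""

    jaw: str
    grid_size: float = DEFAULT_GRID_SIZE
    inclusion: float = DEFAULT_INCLUSION
    ratio: float = DEFAULT_RATIO

    def __post_init__(self) -> None:
        if self.jaw not in JAWS:
            raise ValueError(f"jaw must be one of {JAWS}, got {self.jaw!r}")
        if not self.grid_size > 0:
            raise ValueError(f"grid size G must be > 0 mm, got {self.grid_size}")
        if not self.inclusion >= 0:
            raise ValueError(f"inclusion criterion I must be ≥ 0 mm, got {self.inclusion}")
        if not 0 < self.ratio <= 1:
            raise ValueError(f"ratio of inclusion R must be in (0, 1], got {self.ratio}")

    def to_dict(self) -> dict:
        return {
            "jaw": self.jaw,
            "grid_size": self.grid_size,
            "inclusion": self.inclusion,
            "ratio": self.ratio,
        }


@dataclass(frozen=True)
class ScanFrame:
    """The grid laid over the oriented scan, plus scan-level quantities.

    The grid is anchored at the xy-bounding-box minimum.  Square (c, r)
    covers [x_min + c·G, x_min + (c+1)·G) × [y_min + r·G, y_min + (r+1)·G),
    half-open so a vertex on an interior grid line belongs to the
    higher-indexed square; the last column/row is closed above so every
    vertex belongs to exactly one square.  ``z_range`` is computed once over
    the whole oriented scan, before any removal.
    """

    origin: tuple[float, float]
    grid_size: float
    nx: int
    ny: int
    z_min: float
    z_max: float
    occlusal: PlaneFit

    @property
    def z_range(self) -> float:
        return self.z_max - self.z_min

    def square_of(self, points) -> tuple[np.ndarray, np.ndarray]:
        """Column/row index of each point's grid square."""
        p = np.atleast_2d(np.asarray(points, dtype=np.float64))
        col = np.floor((p[:, 0] - self.origin[0]) / self.grid_size).astype(np.int64)
        row = np.floor((p[:, 1] - self.origin[1]) / self.grid_size).astype(np.int64)
        return np.clip(col, 0, self.nx - 1), np.clip(row, 0, self.ny - 1)

    def to_dict(self) -> dict:
        return {
            "origin": list(self.origin),
            "grid_size": self.grid_size,
            "nx": self.nx,
            "ny": self.ny,
            "z_min": self.z_min,
            "z_max": self.z_max,
            "z_range": self.z_range,
            "occlusal_plane": self.occlusal.to_dict(),
        }


@dataclass(frozen=True)
class SquareDecision:
    """Outcome of analysing one grid square."""

    square: tuple[int, int]                 # (col, row)
    member_ids: np.ndarray                  # vertex ids in the oriented mesh
    ep_id: int | None                       # evaluation point (max z, lowest id on ties)
    ep_xyz: tuple[float, float, float] | None
    ep_distance: float | None               # ⊥ distance of E_p below occlusal plane
    verdict: str
    threshold_z: float | None               # z of the inclusion threshold point
    kept_ids: np.ndarray

    def to_dict(self, *, with_members: bool = False) -> dict:
        d = {
            "square": list(self.square),
            "n_members": int(len(self.member_ids)),
            "ep_id": self.ep_id,
            "ep_xyz": list(self.ep_xyz) if self.ep_xyz is not None else None,
            "ep_distance": self.ep_distance,
            "verdict": self.verdict,
            "threshold_z": self.threshold_z,
            "n_kept": int(len(self.kept_ids)),
        }
        if with_members:
            d["member_ids"] = self.member_ids.tolist()
            d["kept_ids"] = self.kept_ids.tolist()
        return d


@dataclass(frozen=True)
class CropResult:
    """A cropped scan with its full decision log.

    ``mesh`` is in the oriented (occlusal-side-up) frame; ``kept_ids``
    indexes the oriented input mesh, in ascending order, and row k of
    ``mesh.vertices`` is oriented vertex ``kept_ids[k]``.
    """

    mesh: SurfaceMesh
    oriented_input: SurfaceMesh
    frame: ScanFrame
    decisions: tuple[SquareDecision, ...]
    kept_ids: np.ndarray
    removed_vertex_count: int
    params: CropParams
    section_report: SectionReport
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def verdict_counts(self) -> dict:
        counts = {"excluded_empty": 0, "excluded_far": 0, "cropped": 0}
        for d in self.decisions:
            counts[d.verdict] += 1
        return counts


_EMPTY_IDS = np.empty(0, dtype=np.int64)


def build_frame(mesh: SurfaceMesh, occlusal: PlaneFit, grid_size: float) -> ScanFrame:
    """Lay the xy-grid over an oriented mesh."""
    if not grid_size > 0:
        raise ValueError(f"grid size must be > 0, got {grid_size}")
    if mesh.n_vertices == 0:
        raise EmptyMeshError("cannot grid an empty mesh")
    lo, hi = mesh.bounds()
    nx = max(1, math.ceil((hi[0] - lo[0]) / grid_size))
    ny = max(1, math.ceil((hi[1] - lo[1]) / grid_size))
    return ScanFrame(
        origin=(float(lo[0]), float(lo[1])),
        grid_size=float(grid_size),
        nx=nx,
        ny=ny,
        z_min=float(lo[2]),
        z_max=float(hi[2]),
        occlusal=occlusal,
    )


def analyse_square(
    member_ids,
    vertices: np.ndarray,
    frame: ScanFrame,
    params: CropParams,
    square: tuple[int, int] = (0, 0),
) -> SquareDecision:
    """Decide one square: exclude it wholesale, or crop it at its threshold.

    ``member_ids`` are the ids of the vertices whose xy falls in the square;
    ``vertices`` is the full oriented vertex array they index.  The
    operation is total: an empty square yields verdict ``excluded_empty``.
    """
    member_ids = np.asarray(member_ids, dtype=np.int64)
    member_ids = np.sort(member_ids)
    if len(member_ids) == 0:
        return SquareDecision(
            square=square, member_ids=_EMPTY_IDS, ep_id=None, ep_xyz=None,
            ep_distance=None, verdict="excluded_empty", threshold_z=None,
            kept_ids=_EMPTY_IDS,
        )
    member_z = vertices[member_ids, 2]
    ep_local = int(np.argmax(member_z))  # first max → lowest id (ids sorted)
    ep_id = int(member_ids[ep_local])
    ep = vertices[ep_id]
    # Signed ⊥ distance of E_p *below* the occlusal plane: positive when the
    # square's top is below the plane, ≤ 0 on or above (then the square
    # always passes the R-check, since R·z_range ≥ 0).
    d = -float(frame.occlusal.signed_distance(ep[None, :])[0])
    if d > params.ratio * frame.z_range:
        return SquareDecision(
            square=square, member_ids=member_ids, ep_id=ep_id,
            ep_xyz=tuple(float(v) for v in ep), ep_distance=d,
            verdict="excluded_far", threshold_z=None, kept_ids=_EMPTY_IDS,
        )
    threshold_z = float(ep[2] - params.inclusion * frame.occlusal.normal[2])
    kept = member_ids[member_z >= threshold_z]  # non-strict: E_p survives even at I=0
    return SquareDecision(
        square=square, member_ids=member_ids, ep_id=ep_id,
        ep_xyz=tuple(float(v) for v in ep), ep_distance=d,
        verdict="cropped", threshold_z=threshold_z, kept_ids=kept,
    )


def grid_cut(mesh: SurfaceMesh, params: CropParams) -> CropResult:
    """Run the full grid-cutting pipeline on a raw scan.

    orient → approximate occlusal plane → build grid → analyse every square
    → delete non-kept vertices → drop every face touching a deleted vertex
    → reindex.  Deterministic: identical input and parameters give an
    identical result.  The cropped mesh may legitimately be empty (every
    square excluded); that is reported via ``warnings``, not an error.
    """
    oriented = orient(mesh, params.jaw)
    occlusal_plane, report = approximate_occlusal_plane(oriented)
    frame = build_frame(oriented, occlusal_plane, params.grid_size)

    col, row = frame.square_of(oriented.vertices)
    flat = col * frame.ny + row
    order = np.argsort(flat, kind="stable")
    flat_sorted = flat[order]
    boundaries = np.flatnonzero(np.diff(flat_sorted)) + 1
    groups = np.split(order, boundaries)
    occupied = {int(flat[g[0]]): g for g in groups if len(g)}

    decisions: list[SquareDecision] = []
    kept_chunks: list[np.ndarray] = []
    for c in range(frame.nx):
        for r in range(frame.ny):
            members = occupied.get(c * frame.ny + r, _EMPTY_IDS)
            dec = analyse_square(members, oriented.vertices, frame, params, square=(c, r))
            decisions.append(dec)
            if len(dec.kept_ids):
                kept_chunks.append(dec.kept_ids)

    kept_ids = (
        np.sort(np.concatenate(kept_chunks)) if kept_chunks else _EMPTY_IDS
    )
    keep_mask = np.zeros(oriented.n_vertices, dtype=bool)
    keep_mask[kept_ids] = True
    new_index = np.full(oriented.n_vertices, -1, dtype=np.int64)
    new_index[kept_ids] = np.arange(len(kept_ids))
    face_ok = keep_mask[oriented.faces].all(axis=1) if oriented.n_faces else np.empty(0, bool)
    cropped = SurfaceMesh(
        oriented.vertices[kept_ids], new_index[oriented.faces[face_ok]]
    )
    warnings: tuple[str, ...] = ()
    if len(kept_ids) == 0:
        warnings = ("empty_result: every grid square was excluded",)
    return CropResult(
        mesh=cropped,
        oriented_input=oriented,
        frame=frame,
        decisions=tuple(decisions),
        kept_ids=kept_ids,
        removed_vertex_count=oriented.n_vertices - len(kept_ids),
        params=params,
        section_report=report,
        warnings=warnings,
    )
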