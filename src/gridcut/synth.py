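"""Labeled synthetic dental arches for testing the grid-cutting method.

Real intraoral scans cannot be redistributed, so every claim about tooth
preservation is exercised on synthetic arches instead.  The generator
builds a parabolic band of gingiva-like tissue carrying smooth crown-like
elevations (truncated Gaussians) at the tooth positions, with a gingival
skirt falling away on both sides of the dental ridge.  Optional features
emulate the conditions that matter to the method in practice:

* **missing teeth** — gaps in the arch;
* a **partly erupted / ectopic third molar** — a low bump at one distal
  end, far below the occlusal plane, which height-based cropping is known
  to remove as if it were soft tissue;
* a **retromolar flap** — a tall soft-tissue ridge behind the last molar
  that can distort the approximated occlusal plane.

Anatomical realism is deliberately out of scope: the algorithm consumes
heights only, so smooth analytic bumps test everything a sculpted crown
would.  Each vertex is labeled ``tooth`` or ``soft``; the tooth label is
conservative (crown-only: the upper half of each bump), because the
success criterion is tooth preservation, not gingival-margin accuracy.

Every arch is deterministic given its seed; the only randomness is a small
z-jitter emulating scanner noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .gridcore import CropResult
from .mesh_io import MeshError, SurfaceMesh

#: Half-width of the tissue band either side of the dental ridge (mm).
BAND_HALFWIDTH = 5.0
#: Fraction of the arch's arc length reserved at each distal end for
#: retromolar features (no regular tooth is placed there).
DISTAL_MARGIN = 0.08
#: Scanner-noise emulation: σ of the seeded z-jitter (mm).
JITTER_SD = 0.02
#: Tooth bump width: σ of the Gaussian as a fraction of the tooth spacing.
SIGMA_PER_SPACING = 1.0 / 3.6

SIDES = ("left", "right")


class ArchSpecError(MeshError):
    """The arch specification is invalid or unrealisable at this resolution."""


@dataclass(frozen=True)
class EctopicMolar:
    """A partly erupted/ectopic third molar at one distal end.

    ``eruption_fraction`` scales the crown height: 1.0 is a fully erupted
    tooth, 0.3 a crown barely breaking the gingiva.  ``tilt`` (degrees)
    displaces the crown laterally off the dental ridge, emulating an
    ectopic position.
    """

    side: str = "left"
    eruption_fraction: float = 0.3
    tilt: float = 0.0

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ArchSpecError(f"side must be one of {SIDES}, got {self.side!r}")
        if not 0 < self.eruption_fraction <= 1:
            raise ArchSpecError(
                f"eruption_fraction must be in (0, 1], got {self.eruption_fraction}"
            )


@dataclass(frozen=True)
class RetromolarFlap:
    """A soft-tissue ridge behind the last molar on one side."""

    side: str = "left"
    height: float = 9.0

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ArchSpecError(f"side must be one of {SIDES}, got {self.side!r}")
        if not self.height > 0:
            raise ArchSpecError(f"flap height must be > 0 mm, got {self.height}")


@dataclass(frozen=True)
class ArchSpec:
    """Parameters of one synthetic dental arch (lengths in mm)."""

    n_teeth: int = 14
    missing: frozenset = frozenset()
    tooth_height: float = 8.0
    arch_width: float = 50.0
    arch_depth: float = 40.0
    gingiva_drop: float = 5.0
    ectopic_molar: Optional[EctopicMolar] = None
    retromolar_flap: Optional[RetromolarFlap] = None
    mesh_resolution: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_teeth <= 16:
            raise ArchSpecError(f"n_teeth must be in [1, 16], got {self.n_teeth}")
        for name in ("tooth_height", "arch_width", "arch_depth",
                     "gingiva_drop", "mesh_resolution"):
            if not getattr(self, name) > 0:
                raise ArchSpecError(f"{name} must be > 0, got {getattr(self, name)}")
        missing = frozenset(int(m) for m in self.missing)
        if not missing <= set(range(self.n_teeth)):
            raise ArchSpecError(
                f"missing positions {sorted(missing)} not all in 0..{self.n_teeth - 1}"
            )
        object.__setattr__(self, "missing", missing)

    @property
    def present_positions(self) -> tuple[int, ...]:
        return tuple(p for p in range(self.n_teeth) if p not in self.missing)

    # -- JSON config ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "n_teeth": self.n_teeth,
            "missing": sorted(self.missing),
            "tooth_height": self.tooth_height,
            "arch_width": self.arch_width,
            "arch_depth": self.arch_depth,
            "gingiva_drop": self.gingiva_drop,
            "mesh_resolution": self.mesh_resolution,
            "seed": self.seed,
        }
        if self.ectopic_molar is not None:
            d["ectopic_molar"] = {
                "side": self.ectopic_molar.side,
                "eruption_fraction": self.ectopic_molar.eruption_fraction,
                "tilt": self.ectopic_molar.tilt,
            }
        if self.retromolar_flap is not None:
            d["retromolar_flap"] = {
                "side": self.retromolar_flap.side,
                "height": self.retromolar_flap.height,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchSpec":
        d = dict(d)
        if "missing" in d:
            d["missing"] = frozenset(d["missing"])
        if d.get("ectopic_molar") is not None:
            d["ectopic_molar"] = EctopicMolar(**d["ectopic_molar"])
        if d.get("retromolar_flap") is not None:
            d["retromolar_flap"] = RetromolarFlap(**d["retromolar_flap"])
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ArchSpecError(f"unknown arch-spec field(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "ArchSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class LabeledArch:
    """A synthetic arch mesh with ground-truth labels.

    ``labels`` is 'tooth'/'soft' per vertex; ``tooth_of`` maps each vertex
    to an index into ``tooth_keys`` (−1 for soft tissue); ``apexes`` maps
    each tooth key to the coordinates of its highest labeled vertex.  Tooth
    keys are the position numbers (as strings) plus ``'ectopic_<side>'``
    for an ectopic molar.
    """

    mesh: SurfaceMesh
    labels: np.ndarray
    tooth_of: np.ndarray
    tooth_keys: tuple[str, ...]
    apexes: dict
    spec: ArchSpec


# ---------------------------------------------------------------------------
# Geometry

def _centerline(spec: ArchSpec, n_dense: int = 2001):
    """Arc-length parameterisation of the arch midline (a parabola).

    Returns an interpolator t ∈ [0, 1] → (point, unit normal) and the total
    arc length.  t = 0 is the left distal end (x < 0), t = 1 the right.
    """
    u = np.linspace(-1.0, 1.0, n_dense)
    x = 0.5 * spec.arch_width * u
    y = spec.arch_depth * (1.0 - u ** 2)
    seg = np.hypot(np.diff(x), np.diff(y))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    length = float(s[-1])
    t_dense = s / length

    def at(t):
        t = np.atleast_1d(np.asarray(t, dtype=np.float64))
        px = np.interp(t, t_dense, x)
        py = np.interp(t, t_dense, y)
        # tangent via the parabola's derivative in u
        uu = np.interp(t, t_dense, u)
        tx = np.full_like(uu, 0.5 * spec.arch_width)
        ty = -2.0 * spec.arch_depth * uu
        norm = np.hypot(tx, ty)
        nx, ny = -ty / norm, tx / norm  # tangent rotated +90°
        return np.column_stack([px, py]), np.column_stack([nx, ny])

    return at, length


def _tooth_centers_t(spec: ArchSpec) -> np.ndarray:
    """Arc-fraction of every tooth position (present or not)."""
    k = np.arange(spec.n_teeth)
    return DISTAL_MARGIN + (1.0 - 2.0 * DISTAL_MARGIN) * (k + 0.5) / spec.n_teeth


def make_arch(spec: ArchSpec) -> LabeledArch:
    """Generate a labeled synthetic dental arch.

    The surface is a height field over a band following the arch midline:
    parameter t runs along the arch, s ∈ [−1, 1] across the band.  The base
    is the gingival skirt z = −gingiva_drop·s²; present teeth add Gaussian
    crowns of height ``tooth_height`` on the ridge; the optional ectopic
    molar and retromolar flap add their bumps at the distal ends.  A small
    seeded z-jitter emulates scanner noise.

    Raises :class:`ArchSpecError` when ``mesh_resolution`` is too coarse to
    realise a tooth with at least 8 labeled vertices.
    """
    at, length = _centerline(spec)
    res = spec.mesh_resolution
    nt = max(int(np.ceil(length / res)) + 1, 8)
    ns = max(int(np.ceil(2.0 * BAND_HALFWIDTH / res)) + 1, 5)
    t = np.linspace(0.0, 1.0, nt)
    s = np.linspace(-1.0, 1.0, ns)

    centers, normals = at(t)
    # vertex grid: index = it * ns + is
    tt = np.repeat(np.arange(nt), ns)
    ss = np.tile(s, nt)
    xy = centers[tt] + (ss * BAND_HALFWIDTH)[:, None] * normals[tt]
    z = -spec.gingiva_drop * ss ** 2

    spacing = (1.0 - 2.0 * DISTAL_MARGIN) * length / spec.n_teeth
    sigma = SIGMA_PER_SPACING * spacing

    # Tooth bumps (present positions), plus optional distal features.
    bump_centers: list[np.ndarray] = []
    bump_heights: list[float] = []
    bump_sigmas: list[float] = []
    tooth_keys: list[str] = []

    t_positions = _tooth_centers_t(spec)
    for pos in spec.present_positions:
        c, _ = at(t_positions[pos])
        bump_centers.append(c[0])
        bump_heights.append(spec.tooth_height)
        bump_sigmas.append(sigma)
        tooth_keys.append(str(pos))

    if spec.ectopic_molar is not None:
        m = spec.ectopic_molar
        t_m = 0.04 if m.side == "left" else 0.96
        c, n = at(t_m)
        lateral = 2.5 * np.sin(np.radians(m.tilt))
        bump_centers.append(c[0] + lateral * n[0])
        bump_heights.append(m.eruption_fraction * spec.tooth_height)
        bump_sigmas.append(sigma)
        tooth_keys.append(f"ectopic_{m.side}")

    n_teeth_bumps = len(bump_centers)

    if spec.retromolar_flap is not None:
        f = spec.retromolar_flap
        t_f = 0.03 if f.side == "left" else 0.97
        c, _ = at(t_f)
        bump_centers.append(c[0])
        bump_heights.append(f.height)
        bump_sigmas.append(1.5 * sigma)  # pads are broader than crowns

    bump_values = np.zeros((len(xy), len(bump_centers)))
    for k, (c, h, sg) in enumerate(zip(bump_centers, bump_heights, bump_sigmas)):
        r2 = np.sum((xy - c) ** 2, axis=1)
        bump_values[:, k] = h * np.exp(-r2 / (2.0 * sg ** 2))
    z = z + bump_values.sum(axis=1)

    rng = np.random.default_rng(spec.seed)
    z = z + rng.normal(0.0, JITTER_SD, size=len(z))

    vertices = np.column_stack([xy, z])
    faces = _band_faces(nt, ns)
    mesh = SurfaceMesh(vertices, faces)

    # Labels: crown-only.  A vertex belongs to tooth k when that bump
    # contributes at least half the tooth's height AND the vertex sits in
    # the upper half of the crown (z within tooth_height/2 of the apex) —
    # flank vertices below the crown equator stay 'soft'.
    tooth_of = np.full(len(vertices), -1, dtype=np.int64)
    apexes: dict = {}
    if n_teeth_bumps:
        tooth_bumps = bump_values[:, :n_teeth_bumps]
        best = np.argmax(tooth_bumps, axis=1)
        best_val = tooth_bumps[np.arange(len(vertices)), best]
        heights = np.asarray(bump_heights[:n_teeth_bumps])
        apex_z = heights  # ridge base is z = 0 at s = 0
        is_tooth = (best_val >= 0.5 * heights[best]) & (
            z >= apex_z[best] - 0.5 * heights[best]
        )
        tooth_of[is_tooth] = best[is_tooth]
        for k, key in enumerate(tooth_keys):
            members = np.flatnonzero(tooth_of == k)
            if len(members) < 8:
                raise ArchSpecError(
                    f"mesh_resolution {res} mm too coarse: tooth {key} has "
                    f"{len(members)} labeled vertices (< 8)"
                )
            apex = members[int(np.argmax(z[members]))]
            apexes[key] = vertices[apex].copy()

    labels = np.where(tooth_of >= 0, "tooth", "soft")
    return LabeledArch(
        mesh=mesh,
        labels=labels,
        tooth_of=tooth_of,
        tooth_keys=tuple(tooth_keys),
        apexes=apexes,
        spec=spec,
    )


def _band_faces(nt: int, ns: int) -> np.ndarray:
    """Triangulate the (t, s) grid: two triangles per quad."""
    it, js = np.meshgrid(np.arange(nt - 1), np.arange(ns - 1), indexing="ij")
    v00 = (it * ns + js).ravel()
    v01 = v00 + 1
    v10 = v00 + ns
    v11 = v10 + 1
    upper = np.column_stack([v00, v10, v11])
    lower = np.column_stack([v00, v11, v01])
    return np.concatenate([upper, lower])


# ---------------------------------------------------------------------------
# Crop evaluation against ground truth

@dataclass(frozen=True)
class CropMetrics:
    """Ground-truth evaluation of one crop of a synthetic arch."""

    tooth_vertices_removed: int
    teeth_damaged: int
    soft_retained_fraction: float
    per_tooth: dict

    def to_dict(self) -> dict:
        return {
            "tooth_vertices_removed": self.tooth_vertices_removed,
            "teeth_damaged": self.teeth_damaged,
            "soft_retained_fraction": self.soft_retained_fraction,
            "per_tooth": self.per_tooth,
        }


def evaluate_crop(arch: LabeledArch, result: CropResult) -> CropMetrics:
    """Score a crop of ``arch.mesh`` against the vertex labels.

    Reports the number of removed tooth-labeled vertices, the number of
    teeth that lost at least one whole grid square (every tooth vertex in
    some occupied square removed — the study's notion of a damaged tooth),
    the fraction of soft-tissue vertices retained, and a per-tooth
    breakdown.  Orientation does not reindex vertices, so labels align
    with the oriented mesh by index.
    """
    n = arch.mesh.n_vertices
    if result.oriented_input.n_vertices != n:
        raise MeshError(
            f"crop result has {result.oriented_input.n_vertices} oriented "
            f"vertices but the arch has {n}"
        )
    kept = np.zeros(n, dtype=bool)
    kept[result.kept_ids] = True
    is_tooth = arch.tooth_of >= 0
    tooth_removed = int(np.sum(is_tooth & ~kept))
    n_soft = int(np.sum(~is_tooth))
    soft_kept = int(np.sum(~is_tooth & kept))
    soft_retained = soft_kept / n_soft if n_soft else 1.0

    per_tooth: dict = {
        key: {"vertices": 0, "removed": 0, "squares": 0, "squares_lost": 0}
        for key in arch.tooth_keys
    }
    for k, key in enumerate(arch.tooth_keys):
        members = arch.tooth_of == k
        per_tooth[key]["vertices"] = int(members.sum())
        per_tooth[key]["removed"] = int(np.sum(members & ~kept))
    for dec in result.decisions:
        if len(dec.member_ids) == 0:
            continue
        t_ids = arch.tooth_of[dec.member_ids]
        kept_mask = kept[dec.member_ids]
        for k in np.unique(t_ids[t_ids >= 0]):
            key = arch.tooth_keys[k]
            per_tooth[key]["squares"] += 1
            if not np.any(kept_mask & (t_ids == k)):
                per_tooth[key]["squares_lost"] += 1
    teeth_damaged = sum(1 for v in per_tooth.values() if v["squares_lost"] > 0)
    return CropMetrics(
        tooth_vertices_removed=tooth_removed,
        teeth_damaged=teeth_damaged,
        soft_retained_fraction=float(soft_retained),
        per_tooth=per_tooth,
    )


def standard_arch(seed: int, **overrides) -> LabeledArch:
    """Convenience: a plain arch (no ectopic molar, no flap) for a seed."""
    return make_arch(replace(ArchSpec(seed=seed), **overrides))
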