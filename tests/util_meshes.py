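"""Procedurally generated test meshes (no fixture files on disk)."""

import numpy as np

from gridcut import SurfaceMesh


def grid_faces(nx: int, ny: int) -> np.ndarray:
    """Triangulate an nx x ny vertex grid (row-major, index = i*ny + j)."""
    ii, jj = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), indexing="ij")
    v00 = (ii * ny + jj).ravel()
    v01 = v00 + 1
    v10 = v00 + ny
    v11 = v10 + 1
    return np.concatenate(
        [np.column_stack([v00, v10, v11]), np.column_stack([v00, v11, v01])]
    )


def random_relief_mesh(seed: int, n_side: int = 18) -> SurfaceMesh:
    """A random bumpy height field — relief everywhere, like a dentition.

    A rectangular grid of up to n_side^2 vertices carrying 6-10 Gaussian
    bumps of random height, plus a random base tilt, jitter, and a random
    rigid translation so grids are never axis-anchored at the origin.
    """
    rng = np.random.default_rng(seed)
    ext_x = rng.uniform(18.0, 30.0)
    ext_y = rng.uniform(14.0, 24.0)
    xs = np.linspace(0.0, ext_x, n_side)
    ys = np.linspace(0.0, ext_y, n_side)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    Z = rng.uniform(-0.05, 0.05) * X + rng.uniform(-0.05, 0.05) * Y
    n_bumps = rng.integers(6, 11)
    for _ in range(n_bumps):
        cx = rng.uniform(0.1 * ext_x, 0.9 * ext_x)
        cy = rng.uniform(0.1 * ext_y, 0.9 * ext_y)
        h = rng.uniform(4.0, 9.0)
        sg = rng.uniform(1.2, 2.5)
        Z = Z + h * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * sg**2))
    Z = Z + rng.normal(0.0, 0.05, Z.shape)
    offset = rng.uniform(-40.0, 40.0, size=3)
    vertices = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()]) + offset
    return SurfaceMesh(vertices, grid_faces(n_side, n_side))


#: xy centres of the six cusps, one per 3x2 occlusal section.
CUSP_CENTERS = tuple((x, y) for x in (5.0, 15.0, 25.0) for y in (5.0, 15.0))


def cusp_plate_mesh(apex_heights=(8.0,) * 6, plane=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """A plate carrying six narrow cusps, one per occlusal section.

    The plate lies on the plane z = a*x + b*y + c; cusp k rises
    ``apex_heights[k]`` above it, apex exactly on a grid vertex at
    ``CUSP_CENTERS[k]``.  Grid spacing 1 mm over [0,30] x [0,20].
    """
    a, b, c = plane
    xs = np.arange(0.0, 30.5, 1.0)
    ys = np.arange(0.0, 20.5, 1.0)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    Z = a * X + b * Y + c
    for (cx, cy), h in zip(CUSP_CENTERS, apex_heights):
        Z = Z + h * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * 0.8**2))
    vertices = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    return SurfaceMesh(vertices, grid_faces(len(xs), len(ys)))
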