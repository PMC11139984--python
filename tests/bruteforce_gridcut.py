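"""Independent brute-force reimplementation of the grid-cutting pipeline.

Used only as an oracle in tests: every step is an explicit Python loop over
plain lists, and plane fits solve the 3x3 normal equations by Cramer's
rule.  No code is shared with the gridcut package.
"""

import math


def _det3(m):
    return (
        m[0][0] * (m[1][1] * m[2][2] - m[1][2] * m[2][1])
        - m[0][1] * (m[1][0] * m[2][2] - m[1][2] * m[2][0])
        + m[0][2] * (m[1][0] * m[2][1] - m[1][1] * m[2][0])
    )


def fit_plane(points):
    """Least-squares z = a*x + b*y + c via normal equations + Cramer."""
    sxx = sxy = sx = syy = sy = s1 = 0.0
    sxz = syz = sz = 0.0
    for x, y, z in points:
        sxx += x * x
        sxy += x * y
        sx += x
        syy += y * y
        sy += y
        s1 += 1.0
        sxz += x * z
        syz += y * z
        sz += z
    A = [[sxx, sxy, sx], [sxy, syy, sy], [sx, sy, s1]]
    rhs = [sxz, syz, sz]
    d = _det3(A)
    if d == 0.0:
        raise ValueError("degenerate plane fit")
    cols = []
    for j in range(3):
        m = [list(row) for row in A]
        for i in range(3):
            m[i][j] = rhs[i]
        cols.append(_det3(m) / d)
    return cols[0], cols[1], cols[2]


def _dist_above(p, plane):
    a, b, c = plane
    return (p[2] - (a * p[0] + b * p[1] + c)) / math.sqrt(a * a + b * b + 1.0)


def orient(vertices, jaw):
    if jaw == "mandible":
        return [tuple(v) for v in vertices]
    n = len(vertices)
    cy = sum(v[1] for v in vertices) / n
    cz = sum(v[2] for v in vertices) / n
    return [(v[0], 2.0 * cy - v[1], 2.0 * cz - v[2]) for v in vertices]


def occlusal_plane(vertices):
    fitting = fit_plane(vertices)
    survivors = [i for i, v in enumerate(vertices) if _dist_above(v, fitting) >= 0.0]
    if not survivors:
        raise ValueError("no survivors above fitting plane")
    xmin = min(vertices[i][0] for i in survivors)
    xmax = max(vertices[i][0] for i in survivors)
    ymin = min(vertices[i][1] for i in survivors)
    ymax = max(vertices[i][1] for i in survivors)
    xe, ye = xmax - xmin, ymax - ymin
    reps = {}
    for i in survivors:
        fx = (vertices[i][0] - xmin) / xe if xe > 0 else 0.0
        fy = (vertices[i][1] - ymin) / ye if ye > 0 else 0.0
        sec = (min(int(fx * 3), 2), min(int(fy * 2), 1))
        d = _dist_above(vertices[i], fitting)
        if sec not in reps or d > reps[sec][0]:
            reps[sec] = (d, i)
    if len(reps) < 4:
        raise ValueError("fewer than 4 non-empty sections")
    ranked = sorted(
        (rep_i for _, rep_i in reps.values()),
        key=lambda i: (-vertices[i][2], i),
    )
    chosen = ranked[:4]
    return fit_plane([vertices[i] for i in chosen])


def grid_cut(vertices, faces, jaw, G, I, R):
    """Full pipeline; returns (kept ids, oriented kept vertices, reindexed faces)."""
    vs = orient(vertices, jaw)
    occ = occlusal_plane(vs)
    a, b, c = occ
    nz = 1.0 / math.sqrt(a * a + b * b + 1.0)
    xmin = min(v[0] for v in vs)
    ymin = min(v[1] for v in vs)
    xmax = max(v[0] for v in vs)
    ymax = max(v[1] for v in vs)
    zmin = min(v[2] for v in vs)
    zmax = max(v[2] for v in vs)
    zrange = zmax - zmin
    nx = max(1, math.ceil((xmax - xmin) / G))
    ny = max(1, math.ceil((ymax - ymin) / G))
    squares = {}
    for i, v in enumerate(vs):
        col = min(max(int(math.floor((v[0] - xmin) / G)), 0), nx - 1)
        row = min(max(int(math.floor((v[1] - ymin) / G)), 0), ny - 1)
        squares.setdefault((col, row), []).append(i)
    kept = []
    for members in squares.values():
        ep = members[0]
        for i in members[1:]:
            if vs[i][2] > vs[ep][2]:
                ep = i
        d = -_dist_above(vs[ep], occ)
        if d > R * zrange:
            continue
        thr = vs[ep][2] - I * nz
        for i in members:
            if vs[i][2] >= thr:
                kept.append(i)
    kept.sort()
    newid = {old: new for new, old in enumerate(kept)}
    out_faces = [
        tuple(newid[i] for i in f)
        for f in faces
        if all(i in newid for i in f)
    ]
    return kept, [vs[i] for i in kept], out_faces
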