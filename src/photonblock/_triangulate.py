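"""Constrained triangulation of planar polygons with holes.

Ear clipping over a simple polygon, with holes eliminated first by the
classic bridge construction: each hole is joined to the outer boundary
through a mutually visible vertex pair (both endpoints duplicated), turning
the region into one weakly simple polygon.  Visibility is established by
brute-force segment tests against every boundary edge — loops here are a
few hundred vertices at most, and robustness matters far more than
asymptotics, because the caps these triangulations produce must close
watertight solids.  No Steiner points are added, so every output triangle
vertex is an input vertex and cap boundaries coincide exactly with the
loops the wall meshes are lofted from.

Orientation convention: outer loops counter-clockwise, holes clockwise
(both normalized internally); output triangles are CCW in the plane.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-9


class TriangulationError(ValueError):
    """The polygon (or its holes) could not be triangulated."""


def _signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def _points_in_triangle(p: np.ndarray, a, b, c, eps: float) -> np.ndarray:
    """Strict containment mask for an array of points in CCW triangle abc."""
    d1 = (b[0] - a[0]) * (p[:, 1] - a[1]) - (b[1] - a[1]) * (p[:, 0] - a[0])
    d2 = (c[0] - b[0]) * (p[:, 1] - b[1]) - (c[1] - b[1]) * (p[:, 0] - b[0])
    d3 = (a[0] - c[0]) * (p[:, 1] - c[1]) - (a[1] - c[1]) * (p[:, 0] - c[0])
    return (d1 > eps) & (d2 > eps) & (d3 > eps)


def _segments_block(p, q, edges: np.ndarray, eps: float) -> bool:
    """True if open segment p-q is obstructed by any edge in ``edges``.

    An edge blocks if it properly crosses p-q, or if one of its endpoints
    lies in the open interior of p-q (grazing contact at p or q itself is
    allowed — that is how the bridge attaches).
    """
    def cross2(u, v):
        return u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]

    p = np.asarray(p, float)
    q = np.asarray(q, float)
    a, b = edges[:, 0, :], edges[:, 1, :]
    d1 = cross2(q - p, a - p)
    d2 = cross2(q - p, b - p)
    d3 = cross2(b - a, p - a)
    d4 = cross2(b - a, q - a)
    proper = (
        (np.sign(d1) * np.sign(d2) < 0)
        & (np.sign(d3) * np.sign(d4) < 0)
        & (np.abs(d1) > eps) & (np.abs(d2) > eps)
        & (np.abs(d3) > eps) & (np.abs(d4) > eps)
    )
    if proper.any():
        return True
    # endpoint of an edge lying strictly inside p-q
    for pts in (a, b):
        t = (pts - p) @ (q - p)
        L2 = float((q - p) @ (q - p))
        on_line = np.abs(cross2(q - p, pts - p)) <= eps * np.sqrt(L2)
        interior = (t > eps * L2) & (t < (1 - 1e-12) * L2 - eps * L2)
        if (on_line & interior).any():
            return True
    return False


def _point_in_loop(pt: np.ndarray, loop: np.ndarray) -> bool:
    """Ray-parity point-in-polygon (even-odd rule, +x ray)."""
    x, y = pt
    a = loop
    b = np.roll(loop, -1, axis=0)
    crosses = (a[:, 1] > y) != (b[:, 1] > y)
    with np.errstate(divide="ignore", invalid="ignore"):
        xi = a[:, 0] + (y - a[:, 1]) / (b[:, 1] - a[:, 1]) * (b[:, 0] - a[:, 0])
    return bool(np.count_nonzero(crosses & (xi > x)) % 2)


def _loop_edges(loop: list[np.ndarray]) -> np.ndarray:
    arr = np.asarray(loop)
    return np.stack([arr, np.roll(arr, -1, axis=0)], axis=1)


def _bridge_hole(
    loop: list[np.ndarray],
    loop_ids: list[int],
    hole: list[np.ndarray],
    hole_ids: list[int],
    pending_holes: list[list[np.ndarray]],
) -> tuple[list[np.ndarray], list[int]]:
    """Splice one hole (CW) into the loop (CCW) via a visible vertex pair.

    ``loop_ids``/``hole_ids`` track each point's index into the original
    input vertex set, so bridge duplicates stay identified with their
    source vertex exactly (no coordinate re-merging later)."""
    obstacle_edges = [_loop_edges(loop), _loop_edges(hole)]
    obstacle_edges += [_loop_edges(h) for h in pending_holes]
    edges = np.concatenate(obstacle_edges, axis=0)
    scale = float(np.abs(np.asarray(loop)).max())
    eps = _EPS * max(scale, 1.0)

    loop_arr = np.asarray(loop)
    # avoid stacking two bridges on the same outer vertex: duplicated
    # coordinates mark previous bridge attachment points
    _, counts_idx, counts = np.unique(
        np.round(loop_arr, 9), axis=0, return_inverse=True, return_counts=True
    )
    multiplicity = counts[counts_idx]

    hole_arr = np.asarray(hole)
    hole_order = np.argsort(-hole_arr[:, 0])  # rightmost hole vertices first
    for mi in hole_order:
        m = hole[mi]
        dists = np.hypot(loop_arr[:, 0] - m[0], loop_arr[:, 1] - m[1])
        for vi in np.argsort(dists):
            if multiplicity[vi] > 1:
                continue
            v = loop[vi]
            # drop edges incident to m or v before the obstruction test
            inc = (
                (np.all(np.isclose(edges[:, 0], m, atol=1e-12), axis=1))
                | (np.all(np.isclose(edges[:, 1], m, atol=1e-12), axis=1))
                | (np.all(np.isclose(edges[:, 0], v, atol=1e-12), axis=1))
                | (np.all(np.isclose(edges[:, 1], v, atol=1e-12), axis=1))
            )
            if _segments_block(m, v, edges[~inc], eps):
                continue
            rotated = hole[mi:] + hole[:mi]  # starts at m, CW order
            rotated_ids = hole_ids[mi:] + hole_ids[:mi]
            new_loop = (
                loop[: vi + 1]
                + rotated
                + [m.copy(), v.copy()]
                + loop[vi + 1:]
            )
            new_ids = (
                loop_ids[: vi + 1]
                + rotated_ids
                + [hole_ids[mi], loop_ids[vi]]
                + loop_ids[vi + 1:]
            )
            return new_loop, new_ids
    raise TriangulationError("no visible bridge found for hole")


def _ear_clip(loop: list[np.ndarray], scale: float) -> list[tuple[int, int, int]]:
    """Triangulate a weakly simple CCW polygon; returns index triples."""
    n = len(loop)
    idx = list(range(n))
    pts = np.asarray(loop)
    eps = _EPS * max(scale, 1.0) ** 2
    tris: list[tuple[int, int, int]] = []
    while len(idx) > 3:
        m = len(idx)
        for k in range(m):
            i0, i1, i2 = idx[(k - 1) % m], idx[k], idx[(k + 1) % m]
            a, b, c = pts[i0], pts[i1], pts[i2]
            cr = _cross(a, b, c)
            if cr < -eps:
                continue  # reflex corner
            others = np.array([j for j in idx if j not in (i0, i1, i2)])
            if len(others) and _points_in_triangle(pts[others], a, b, c, eps).any():
                continue
            if cr > eps:
                tris.append((i0, i1, i2))
            # a zero-area ear is clipped but emits no triangle
            del idx[k]
            break
        else:
            raise TriangulationError(
                f"ear clipping stalled with {len(idx)} vertices remaining"
            )
    a, b, c = idx
    if _cross(pts[a], pts[b], pts[c]) > eps:
        tris.append((a, b, c))
    return tris


def triangulate_polygon(
    outer: np.ndarray, holes: list[np.ndarray] | tuple = ()
) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate a polygon with optional holes.

    Parameters
    ----------
    outer
        ``(n, 2)`` boundary loop (any winding; normalized to CCW).
    holes
        Iterable of ``(m, 2)`` hole loops strictly inside ``outer``,
        mutually disjoint.

    Returns
    -------
    vertices, faces
        ``(k, 2)`` float vertices — exactly the input points of the
        (winding-normalized) outer loop followed by the holes, bit-for-bit
        — and ``(t, 3)`` CCW index triples whose areas sum to
        ``area(outer) - sum(area(holes))``.
    """
    outer = np.asarray(outer, dtype=float)
    if _signed_area(outer) < 0:
        outer = outer[::-1]
    hole_arrays = []
    for h in holes:
        h = np.asarray(h, dtype=float)
        if _signed_area(h) > 0:
            h = h[::-1]
        if not _point_in_loop(h[0], outer):
            raise TriangulationError("hole lies outside the outer boundary")
        hole_arrays.append(h)
    # bridge right-to-left so earlier bridges cannot cross later holes
    hole_arrays.sort(key=lambda h: -h[:, 0].max())

    vertices = (np.concatenate([outer] + hole_arrays, axis=0)
                if hole_arrays else outer.copy())
    loop = [v.copy() for v in outer]
    ids = list(range(len(outer)))
    offset = len(outer)
    for i, h in enumerate(hole_arrays):
        pending = [list(g) for g in hole_arrays[i + 1:]]
        loop, ids = _bridge_hole(
            loop, ids, [v.copy() for v in h],
            list(range(offset, offset + len(h))), pending,
        )
        offset += len(h)

    pts = np.asarray(loop)
    scale = float(np.abs(pts).max())
    tris = _ear_clip(loop, scale)
    id_arr = np.asarray(ids, dtype=int)
    faces = id_arr[np.asarray(tris, dtype=int)]
    return vertices, faces


def triangulation_area(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Total area of a triangle set — the oracle counterpart to the shoelace."""
    a = vertices[faces[:, 0]]
    b = vertices[faces[:, 1]]
    c = vertices[faces[:, 2]]
    return float(
        0.5
        * np.abs(
            (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
            - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
        ).sum()
    )
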