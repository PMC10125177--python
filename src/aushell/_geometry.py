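"""Polyhedral direction sets and small rotation helpers.

The idealized cluster geometry is assembled from icosahedrally symmetric
direction sets sharing one canonical frame: the regular icosahedron with
vertices at cyclic permutations of (0, +-1, +-phi), its 30 edge-midpoint
directions (an icosidodecahedron), and the 60-vertex rhombicosidodecahedron
in the same frame.
"""

from __future__ import annotations

import numpy as np

PHI = (1.0 + np.sqrt(5.0)) / 2.0


def _cyclic(coords: tuple[float, float, float]) -> list[tuple[float, float, float]]:
    x, y, z = coords
    return [(x, y, z), (z, x, y), (y, z, x)]


def icosahedron_vertices() -> np.ndarray:
    """12 unit vectors to the vertices of a regular icosahedron."""
    pts = []
    for sy in (1.0, -1.0):
        for sz in (1.0, -1.0):
            pts.extend(_cyclic((0.0, sy, sz * PHI)))
    arr = np.array(pts)
    return arr / np.linalg.norm(arr, axis=1, keepdims=True)


def icosahedron_edges(vertices: np.ndarray | None = None) -> list[tuple[int, int]]:
    """The 30 vertex-index pairs forming icosahedron edges (i < j)."""
    v = icosahedron_vertices() if vertices is None else vertices
    # adjacent unit vertices satisfy v_i . v_j = 1/sqrt(5)
    target = 1.0 / np.sqrt(5.0)
    edges = []
    for i in range(len(v)):
        for j in range(i + 1, len(v)):
            if abs(float(v[i] @ v[j]) - target) < 1e-6:
                edges.append((i, j))
    assert len(edges) == 30
    return edges


def edge_midpoint_directions() -> np.ndarray:
    """30 unit vectors through icosahedron edge midpoints (icosidodecahedron)."""
    v = icosahedron_vertices()
    dirs = np.array([v[i] + v[j] for i, j in icosahedron_edges(v)])
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def edge_tangents() -> np.ndarray:
    """Unit vectors along each icosahedron edge (v_i - v_j), matching
    :func:`edge_midpoint_directions` ordering."""
    v = icosahedron_vertices()
    t = np.array([v[i] - v[j] for i, j in icosahedron_edges(v)])
    return t / np.linalg.norm(t, axis=1, keepdims=True)


def icosahedron_faces(vertices: np.ndarray | None = None) -> list[tuple[int, int, int]]:
    """The 20 vertex-index triples forming icosahedron faces."""
    v = icosahedron_vertices() if vertices is None else vertices
    target = 1.0 / np.sqrt(5.0)
    adj = np.abs(v @ v.T - target) < 1e-6
    faces = []
    for i in range(12):
        for j in range(i + 1, 12):
            if not adj[i, j]:
                continue
            for k in range(j + 1, 12):
                if adj[i, k] and adj[j, k]:
                    faces.append((i, j, k))
    assert len(faces) == 20
    return faces


def rhombicosidodecahedron_vertices() -> np.ndarray:
    """60 unit vectors in a rhombicosidodecahedral arrangement, aligned
    with :func:`icosahedron_vertices`.

    One vertex per (icosahedron vertex, incident face) flag:
    ``normalize(v + t * f)`` with the face-center unit vector ``f`` and the
    mixing ``t`` solved so that the two edge types (same-vertex and
    same-face) have equal length, which is the canonical solid.
    """
    v = icosahedron_vertices()
    faces = icosahedron_faces(v)
    fc = np.array([v[i] + v[j] + v[k] for i, j, k in faces])
    fc /= np.linalg.norm(fc, axis=1, keepdims=True)

    # reference flags for the edge-length equalization
    i0, j0, k0 = faces[0]
    # second face sharing edge (i0, j0)
    other = next(f for f in faces[1:] if i0 in f and j0 in f)
    f0 = fc[faces.index((i0, j0, k0))]
    f1 = fc[faces.index(other)]

    def edge_gap(t: float) -> float:
        a = v[i0] + t * f0
        a /= np.linalg.norm(a)
        b = v[i0] + t * f1
        b /= np.linalg.norm(b)   # same vertex, two faces (square edge)
        c = v[j0] + t * f0
        c /= np.linalg.norm(c)   # same face, adjacent vertices (triangle edge... pentagon)
        return float(np.linalg.norm(a - b) - np.linalg.norm(a - c))

    lo, hi = 0.05, 5.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if edge_gap(lo) * edge_gap(mid) <= 0:
            hi = mid
        else:
            lo = mid
    t = 0.5 * (lo + hi)

    pts = []
    for vi in range(12):
        for fi, face in enumerate(faces):
            if vi in face:
                p = v[vi] + t * fc[fi]
                pts.append(p / np.linalg.norm(p))
    arr = np.array(pts)
    assert len(arr) == 60
    return arr


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis, Rodrigues form."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    theta = np.deg2rad(angle_deg)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(theta) * k + (1.0 - np.cos(theta)) * (k @ k)


def frame_from_axis(axis: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Right-handed orthonormal frame whose third column is ``axis``.

    ``reference`` (if given) fixes the roll: the first column is the
    component of ``reference`` perpendicular to ``axis``. Falls back to a
    deterministic world axis when the reference is (nearly) parallel.
    """
    z = np.asarray(axis, dtype=float)
    z = z / np.linalg.norm(z)
    candidates = [] if reference is None else [np.asarray(reference, dtype=float)]
    candidates += [np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0])]
    for ref in candidates:
        x = ref - (ref @ z) * z
        n = np.linalg.norm(x)
        if n > 1e-8:
            x = x / n
            break
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral lattice), deterministic."""
    i = np.arange(n, dtype=float) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
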