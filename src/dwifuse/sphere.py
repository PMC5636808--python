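"""Sphere tessellations for discrete extrema search."""

from __future__ import annotations

import functools

import numpy as np
from scipy.spatial import ConvexHull

__all__ = ["icosphere", "vertex_adjacency"]

_PHI = (1.0 + np.sqrt(5.0)) / 2.0

_ICO_VERTS = np.array(
    [
        [-1, _PHI, 0], [1, _PHI, 0], [-1, -_PHI, 0], [1, -_PHI, 0],
        [0, -1, _PHI], [0, 1, _PHI], [0, -1, -_PHI], [0, 1, -_PHI],
        [_PHI, 0, -1], [_PHI, 0, 1], [-_PHI, 0, -1], [-_PHI, 0, 1],
    ],
    dtype=float,
)

_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ]
)


@functools.lru_cache(maxsize=8)
def icosphere(subdivisions: int = 3) -> np.ndarray:
    """Unit vertices of a subdivided icosahedron (642 vertices at level 3)."""
    verts = _ICO_VERTS / np.linalg.norm(_ICO_VERTS, axis=1, keepdims=True)
    faces = _ICO_FACES.copy()
    for _ in range(subdivisions):
        verts, faces = _subdivide(verts, faces)
    verts.setflags(write=False)
    return verts


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    verts = list(verts)
    midpoint_cache: dict[tuple[int, int], int] = {}

    def midpoint(a: int, b: int) -> int:
        key = (min(a, b), max(a, b))
        if key not in midpoint_cache:
            m = verts[a] + verts[b]
            m /= np.linalg.norm(m)
            midpoint_cache[key] = len(verts)
            verts.append(m)
        return midpoint_cache[key]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces.extend([[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]])
    return np.array(verts), np.array(new_faces)


@functools.lru_cache(maxsize=8)
def vertex_adjacency(subdivisions: int = 3) -> tuple[tuple[int, ...], ...]:
    """Neighbor lists of the icosphere mesh, from the convex hull triangulation."""
    verts = icosphere(subdivisions)
    hull = ConvexHull(verts)
    nbrs: list[set[int]] = [set() for _ in range(len(verts))]
    for a, b, c in hull.simplices:
        nbrs[a].update((b, c))
        nbrs[b].update((a, c))
        nbrs[c].update((a, b))
    return tuple(tuple(sorted(s)) for s in nbrs)
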