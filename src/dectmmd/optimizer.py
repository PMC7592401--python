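"""Hausdorff-distance triangle matching.

When a pixel falls outside its initial barycentric triangle, a replacement
containing triangle is chosen to be as similar as possible to the initial
one.  Similarity between the two vertex sets is scored by the Hausdorff
distance, computed with the early-break scan: points are visited in a
randomized order and the inner loop aborts as soon as a neighbor closer
than the running maximum is found.  The randomization only affects how much
work is done — the returned value is always the exact max-min distance.

Two symmetrized conventions are exposed: ``"standard-max"``
(max of the two directed distances — the classical Hausdorff metric, and
the operational definition used by the early-break scan) and ``"paper-min"``
(min of the two directed distances).
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np

__all__ = ["directed_hausdorff", "bidirectional_hausdorff", "select_triangle"]


def _as_points(s) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(s, dtype=float))
    if pts.size == 0:
        raise ValueError("point set must be non-empty")
    return pts


def directed_hausdorff(A, B, seed: int = 0) -> float:
    """Directed Hausdorff distance h(A, B) = max_{a in A} min_{b in B} |a-b|.

    Implemented with the randomized early-break scan: points of A already in
    B are excluded (their nearest-neighbor distance is zero), both sets are
    scanned in a seeded random order, and the inner minimization breaks as
    soon as it finds a distance below the running maximum (such a point
    cannot raise it).  Returns 0 when A is a subset of B.
    """
    a, b = _as_points(A), _as_points(B)
    # E <- A \ (A intersect B)
    in_b = (a[:, None, :] == b[None, :, :]).all(axis=2).any(axis=1)
    e = a[~in_b]
    if len(e) == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    e = e[rng.permutation(len(e))]
    b = b[rng.permutation(len(b))]
    d_max = 0.0
    for x in e:
        d_min = np.inf
        early = False
        for y in b:
            d = float(np.linalg.norm(x - y))
            if d < d_max:
                early = True  # min over B is < d_max: x cannot raise d_max
                break
            if d < d_min:
                d_min = d
        if not early and d_min > d_max:
            d_max = d_min
    return d_max


def bidirectional_hausdorff(A, B, convention: str = "standard-max", seed: int = 0) -> float:
    """Symmetrized Hausdorff distance between two point sets.

    ``"standard-max"`` returns max(h(A,B), h(B,A)) — the classical Hausdorff
    metric; ``"paper-min"`` returns min of the two directed values.  Both are
    symmetric in A and B.
    """
    hab = directed_hausdorff(A, B, seed=seed)
    hba = directed_hausdorff(B, A, seed=seed)
    if convention == "standard-max":
        return max(hab, hba)
    if convention == "paper-min":
        return min(hab, hba)
    raise ValueError(f"unknown convention {convention!r}")


def select_triangle(
    point,
    initial,
    library,
    clusters: Sequence | None = None,
    *,
    convention: str = "standard-max",
    search_scope: str = "group",
    inside_tol: float = 1e-9,
):
    """Choose a containing triangle most similar to the initial one.

    If ``point`` already lies inside ``initial``, the initial triangle is
    returned unchanged.  Otherwise every candidate triangle — all
    3-combinations of library materials within the point's group, plus
    cluster-agent triplets — whose barycentric solve contains the point is
    scored by the bi-directional Hausdorff distance between its vertex set
    and the initial triangle's, and the closest wins (ties broken
    lexicographically on sorted vertex names).

    Raises ``OutsideHullError`` when no candidate contains the point.
    """
    from .decompose import (DegenerateTriangleError, Triangle, _point_coord,
                            solve_barycentric)

    p = _point_coord(point)
    if solve_barycentric(p, initial, tol=inside_tol).inside:
        return initial

    # candidate vertex pool
    if search_scope == "group" and clusters is not None:
        agents = np.array([c.agent for c in clusters])
        nearest = int(np.argmin(np.linalg.norm(agents - p, axis=1)))
        group = clusters[nearest].group
        pool = [m for m in library.materials if library.groups[m.name] == group]
        if len(pool) < 3:
            pool = list(library.materials)
    else:
        pool = list(library.materials)

    candidates = [tuple(tri) for tri in combinations(pool, 3)]
    if clusters is not None:
        from .decompose import _agent_material

        agent_mats = [
            c.members[0] if len(c.members) == 1 else _agent_material(c, ci)
            for ci, c in enumerate(clusters)
        ]
        for tri in combinations(agent_mats, 3):
            if tri not in candidates:
                candidates.append(tri)

    best = None
    ref = initial.coords
    for tri in candidates:
        try:
            t = Triangle(tri)
        except DegenerateTriangleError:
            continue
        if not solve_barycentric(p, t, tol=inside_tol).inside:
            continue
        d = bidirectional_hausdorff(t.coords, ref, convention=convention)
        key = (d, tuple(sorted(t.names)))
        if best is None or key < best[0]:
            best = (key, t)
    if best is None:
        raise OutsideHullError(
            "no candidate triangle contains the point: outside the material hull"
        )
    return best[1]


class OutsideHullError(ValueError):
    """The query point lies outside the convex hull of every candidate."""
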