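"""Per-pixel three-material volume-fraction decomposition.

Each pixel of a dual-energy scan is a point ``(mu_low, mu_high)`` in
attenuation space.  Writing its attenuation as a volume-fraction weighted
sum of three candidate materials, with the volume-conservation constraint
``sum(alpha) = 1``, gives the 3x3 linear system

    [ mu_low(L1)   mu_low(L2)   mu_low(L3)  ] [a1]   [ mu_low(pixel)  ]
    [ mu_high(L1)  mu_high(L2)  mu_high(L3) ] [a2] = [ mu_high(pixel) ]
    [ 1            1            1           ] [a3]   [ 1              ]

whose solution is the pixel's barycentric coordinates with respect to the
triangle the three materials span.  A pixel is *inside* the triangle when
all fractions are non-negative; otherwise a new, most-similar containing
triangle is sought (see :mod:`dectmmd.optimizer`), and points outside the
material convex hull are projected onto its boundary and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np

from .images import DectImagePair, hu_to_mu
from .materials import Cluster, Material, MaterialLibrary, cluster_materials

__all__ = [
    "AttenuationPoint",
    "Triangle",
    "DegenerateTriangleError",
    "VolumeFractionResult",
    "VolumeFractionMap",
    "solve_barycentric",
    "decompose_pixel",
    "decompose_image",
    "volume_to_mass_fraction",
]

INSIDE_TOL = 1e-9
DEGENERACY_TOL = 1e-12


class AttenuationPoint(NamedTuple):
    """A pixel's coordinate in 2-D attenuation space (cm^-1)."""

    mu_low: float
    mu_high: float

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.mu_low, self.mu_high])


class DegenerateTriangleError(ValueError):
    pass


@dataclass(frozen=True)
class Triangle:
    """An ordered triplet of materials serving as barycentric vertices."""

    vertices: tuple[Material, Material, Material]

    def __post_init__(self) -> None:
        if len(self.vertices) != 3:
            raise ValueError("a triangle needs exactly three vertices")
        scale = max(1.0, float(np.abs(self.coords).max())) ** 2
        if abs(np.linalg.det(self.matrix)) < DEGENERACY_TOL * scale:
            names = ", ".join(v.name for v in self.vertices)
            raise DegenerateTriangleError(
                f"collinear vertices ({names}): triangle is degenerate"
            )

    @property
    def coords(self) -> np.ndarray:
        """(3, 2) vertex coordinates in (mu_low, mu_high)."""
        return np.array([v.coord for v in self.vertices])

    @property
    def matrix(self) -> np.ndarray:
        """The 3x3 system matrix: attenuation rows plus the sum-to-one row."""
        c = self.coords
        return np.array([c[:, 0], c[:, 1], np.ones(3)])

    @property
    def names(self) -> tuple[str, str, str]:
        return tuple(v.name for v in self.vertices)

    def contains(self, point, tol: float = INSIDE_TOL) -> bool:
        return solve_barycentric(point, self, tol=tol).inside


@dataclass
class VolumeFractionResult:
    """Solution of one barycentric solve."""

    fractions: np.ndarray  # (3,)
    inside: bool
    residual: float
    triangle: Triangle


def _point_coord(point) -> np.ndarray:
    if isinstance(point, AttenuationPoint):
        return point.coord
    return np.asarray(point, dtype=float)[:2]


def solve_barycentric(point, triangle: Triangle, tol: float = INSIDE_TOL) -> VolumeFractionResult:
    """Solve the 3x3 volume-fraction system for one point and one triangle.

    Fractions always sum to one (the constraint is a row of the system);
    ``inside`` is true when no fraction is below ``-tol``.
    """
    p = _point_coord(point)
    b = np.array([p[0], p[1], 1.0])
    a = np.linalg.solve(triangle.matrix, b)
    residual = float(np.linalg.norm(triangle.matrix @ a - b))
    return VolumeFractionResult(a, bool(a.min() >= -tol), residual, triangle)


def volume_to_mass_fraction(fractions: np.ndarray, library: MaterialLibrary) -> np.ndarray:
    """Convert per-material volume fractions to mass fractions,
    m_i = a_i rho_i / sum_j a_j rho_j, along the last axis."""
    a = np.asarray(fractions, dtype=float)
    w = a * library.densities
    total = w.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("all-zero density weighting: cannot form mass fractions")
    return w / total


@dataclass
class VolumeFractionMap:
    """Per-pixel volume fractions over a material library.

    ``fractions`` has shape (H, W, n_materials) with at most three non-zero
    entries per pixel, all in [0, 1] and summing to one.  ``triangle_ids``
    indexes into ``triangles`` (vertex-name triples); ``outside_hull`` marks
    pixels that were projected onto the material convex hull.
    """

    fractions: np.ndarray
    materials: list[str]
    triangle_ids: np.ndarray
    triangles: list[tuple[str, str, str]]
    outside_hull: np.ndarray
    library: MaterialLibrary | None = None

    def fraction_image(self, material: str) -> np.ndarray:
        return self.fractions[..., self.materials.index(material)]

    def argmax_labels(self) -> np.ndarray:
        """Index of the dominant material per pixel."""
        return np.argmax(self.fractions, axis=-1)

    def mass_fractions(self, library: MaterialLibrary | None = None) -> np.ndarray:
        lib = library or self.library
        if lib is None:
            raise ValueError("a material library is required for mass fractions")
        return volume_to_mass_fraction(self.fractions, lib)


# ---------------------------------------------------------------------------
# vectorized decomposition engine


def _agent_material(cluster: Cluster, idx: int) -> Material:
    if len(cluster.members) == 1:
        return cluster.members[0]
    name = f"agent{idx}(" + "+".join(m.name for m in cluster.members) + ")"
    rho = float(np.mean([m.density for m in cluster.members])) if cluster.members else 1.0
    return Material(name, rho, float(cluster.agent[0]), float(cluster.agent[1]))


class _Vertex(NamedTuple):
    material: Material
    lib_index: int      # -1 when the vertex is a multi-member cluster agent
    cluster_index: int  # -1 when the vertex is a plain library material


class Decomposer:
    """Precomputed machinery for decomposing many pixels against one
    library/cluster configuration.  Pixels are independent, so any pixel
    ordering or chunking yields identical results."""

    def __init__(
        self,
        library: MaterialLibrary,
        clusters: Sequence[Cluster] | None = None,
        *,
        search_scope: str = "group",
        hausdorff_convention: str = "standard-max",
        inside_tol: float = INSIDE_TOL,
    ) -> None:
        from . import optimizer  # local import: optimizer depends on this module

        self.library = library
        self.clusters = list(clusters) if clusters is not None else cluster_materials(library)
        self.inside_tol = inside_tol
        self._hausdorff = lambda a, b: optimizer.bidirectional_hausdorff(
            a, b, convention=hausdorff_convention
        )

        # vertex table: library materials first, then multi-member agents
        self.vertices: list[_Vertex] = [
            _Vertex(m, i, -1) for i, m in enumerate(library.materials)
        ]
        self._agent_vertex_idx: list[int] = []
        for ci, c in enumerate(self.clusters):
            if len(c.members) == 1:
                self._agent_vertex_idx.append(library.index(c.members[0].name))
            else:
                self.vertices.append(_Vertex(_agent_material(c, ci), -1, ci))
                self._agent_vertex_idx.append(len(self.vertices) - 1)
        self.vertex_coords = np.array([v.material.coord for v in self.vertices])
        # which cluster each library material sits in (for member refinement)
        self._material_cluster = {}
        for ci, c in enumerate(self.clusters):
            for m in c.members:
                self._material_cluster[library.index(m.name)] = ci

        # candidate triangles: 3-combinations of library materials within
        # each group (or the whole library), plus cluster-agent triplets
        cand: list[tuple[int, int, int]] = []
        if search_scope == "group":
            groups = sorted(set(library.groups.values()))
            for g in groups:
                idx = [i for i, m in enumerate(library.materials)
                       if library.groups[m.name] == g]
                cand.extend(combinations(idx, 3))
        else:
            cand.extend(combinations(range(len(library)), 3))
        if len(self._agent_vertex_idx) >= 3:
            for tri in combinations(sorted(set(self._agent_vertex_idx)), 3):
                if tri not in cand:
                    cand.append(tri)
        self.candidates: list[tuple[int, int, int]] = []
        self._cand_inv: list[np.ndarray] = []
        for tri in cand:
            c = self.vertex_coords[list(tri)]
            mat = np.vstack([c[:, 0], c[:, 1], np.ones(3)])
            scale = max(1.0, float(np.abs(c).max())) ** 2
            if abs(np.linalg.det(mat)) < DEGENERACY_TOL * scale:
                continue  # collinear triple: not a usable triangle
            self.candidates.append(tri)
            self._cand_inv.append(np.linalg.inv(mat))
        if not self.candidates:
            raise ValueError("library spans no non-degenerate triangle")
        self._order_cache: dict[tuple[int, int, int], list[int]] = {}
        self._hull = self._build_hull()

    # -- helpers ------------------------------------------------------------
    def _build_hull(self) -> np.ndarray:
        """Edge list (n_edges, 2, 2) of the convex hull of all vertices."""
        from scipy.spatial import ConvexHull

        pts = self.vertex_coords
        hull = ConvexHull(pts)
        return np.array([[pts[s[0]], pts[s[1]]] for s in hull.simplices])

    def project_to_hull(self, points: np.ndarray) -> np.ndarray:
        """Project points onto the nearest point of the material convex
        hull boundary (used for out-of-hull pixels, e.g. metal artifacts)."""
        p = np.atleast_2d(points)  # (n, 2)
        a = self._hull[:, 0]       # (e, 2)
        ab = self._hull[:, 1] - a  # (e, 2)
        denom = (ab ** 2).sum(axis=1)
        t = ((p[:, None, :] - a) * ab).sum(axis=2) / denom  # (n, e)
        t = np.clip(t, 0.0, 1.0)
        proj = a + t[..., None] * ab                        # (n, e, 2)
        d2 = ((p[:, None, :] - proj) ** 2).sum(axis=2)
        best = np.argmin(d2, axis=1)
        return proj[np.arange(len(p)), best]

    def _candidate_order(self, initial: tuple[int, int, int]) -> list[int]:
        """Candidate indices sorted by triangle similarity (bi-directional
        Hausdorff distance) to the initial triangle, ties broken by the
        lexicographic order of vertex names."""
        if initial in self._order_cache:
            return self._order_cache[initial]
        ref = self.vertex_coords[list(initial)]
        keyed = []
        for k, tri in enumerate(self.candidates):
            d = self._hausdorff(self.vertex_coords[list(tri)], ref)
            names = tuple(sorted(self.vertices[i].material.name for i in tri))
            keyed.append((d, names, k))
        order = [k for _, _, k in sorted(keyed)]
        self._order_cache[initial] = order
        return order

    def initial_triples(self, points: np.ndarray) -> np.ndarray:
        """For each point, the (sorted) vertex-index triple of the three
        nearest cluster agents (falling back to the three nearest library
        materials when fewer than three clusters exist)."""
        p = np.atleast_2d(points)
        if len(set(self._agent_vertex_idx)) >= 3:
            pool = sorted(set(self._agent_vertex_idx))
        else:
            pool = list(range(len(self.library)))
        coords = self.vertex_coords[pool]
        d = np.linalg.norm(p[:, None, :] - coords[None, :, :], axis=2)
        nearest = np.argsort(d, axis=1, kind="stable")[:, :3]
        triples = np.sort(np.asarray(pool, dtype=int)[nearest], axis=1)
        return triples

    def _solve_candidate(self, cand_idx: int, points: np.ndarray) -> np.ndarray:
        # alpha = Minv @ [mu_low, mu_high, 1]; expanded elementwise so the
        # result is bit-identical regardless of batch size (chunking /
        # concurrency contract)
        inv = self._cand_inv[cand_idx]
        return (points[:, 0, None] * inv[:, 0]
                + points[:, 1, None] * inv[:, 1]
                + inv[:, 2])

    def _attribute(
        self,
        tri: tuple[int, int, int],
        alphas: np.ndarray,
        points: np.ndarray,
        out: np.ndarray,
    ) -> None:
        """Scatter triangle fractions onto library materials.  A fraction on
        a multi-member cluster-agent vertex goes to the cluster member
        nearest each pixel's attenuation point."""
        for v_pos, v_idx in enumerate(tri):
            v = self.vertices[v_idx]
            if v.lib_index >= 0:
                out[:, v.lib_index] += alphas[:, v_pos]
            else:
                members = self.clusters[v.cluster_index].members
                mcoords = np.array([m.coord for m in members])
                midx = np.array([self.library.index(m.name) for m in members])
                nearest = np.argmin(
                    np.linalg.norm(points[:, None, :] - mcoords[None], axis=2), axis=1
                )
                np.add.at(out, (np.arange(len(points)), midx[nearest]), alphas[:, v_pos])

    # -- main entry ---------------------------------------------------------
    def decompose_points(self, points: np.ndarray):
        """Decompose an (n, 2) array of attenuation points.

        Returns ``(fractions (n, n_materials), triangle_ids (n,),
        outside_hull (n,), triangle_table)``.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(points)
        nmat = len(self.library)
        fractions = np.zeros((n, nmat))
        tri_ids = np.full(n, -1, dtype=int)
        outside = np.zeros(n, dtype=bool)

        tri_table: list[tuple[int, int, int]] = []
        tri_lookup: dict[tuple[int, int, int], int] = {}

        def tri_id(tri: tuple[int, int, int]) -> int:
            if tri not in tri_lookup:
                tri_lookup[tri] = len(tri_table)
                tri_table.append(tri)
            return tri_lookup[tri]

        initial = self.initial_triples(points)
        # group pixels by their initial triple
        uniq, inverse = np.unique(initial, axis=0, return_inverse=True)
        for u in range(len(uniq)):
            tri = tuple(int(i) for i in uniq[u])
            sel = np.where(inverse == u)[0]
            pts = points[sel]
            # the initial triple may be collinear; skip straight to reselection
            cand_k = self._tri_candidate_index(tri)
            unresolved = np.ones(len(sel), dtype=bool)
            if cand_k is not None:
                a = self._solve_candidate(cand_k, pts)
                ok = a.min(axis=1) >= -self.inside_tol
                if ok.any():
                    self._assign(fractions, tri_ids, tri_id, sel[ok], tri, a[ok], pts[ok])
                    unresolved[ok] = False
            if unresolved.any():
                self._reselect(
                    tri, sel[unresolved], points, fractions, tri_ids, outside, tri_id
                )

        # tidy: clip float dust and renormalize
        fractions[np.abs(fractions) < 10 * self.inside_tol] = 0.0
        fractions = np.clip(fractions, 0.0, 1.0)
        fractions /= fractions.sum(axis=1, keepdims=True)
        names_table = [
            tuple(self.vertices[i].material.name for i in tri) for tri in tri_table
        ]
        return fractions, tri_ids, outside, names_table

    def _write(self, fractions, rows, tri, alphas, pts):
        block = np.zeros((len(rows), fractions.shape[1]))
        self._attribute(tri, alphas, pts, block)
        fractions[rows] = block

    def _vertex_cluster(self, i: int) -> int | None:
        v = self.vertices[i]
        if v.cluster_index >= 0:
            return v.cluster_index
        return self._material_cluster.get(v.lib_index)

    def _needs_refinement(self, tri: tuple[int, int, int]) -> bool:
        for i in tri:
            ci = self._vertex_cluster(i)
            if self.vertices[i].lib_index < 0:
                return True
            if ci is not None and len(self.clusters[ci].members) > 1:
                return True
        return False

    def _member_triangles(self, tri: tuple[int, int, int]):
        """Member-level triangles local to a triangle with clustered
        vertices: all 3-combinations of the union of the members of the
        clusters the three vertices belong to."""
        pool: list[int] = []
        for i in tri:
            ci = self._vertex_cluster(i)
            if ci is None:
                j = self.vertices[i].lib_index
                if j >= 0 and j not in pool:
                    pool.append(j)
                continue
            for m in self.clusters[ci].members:
                j = self.library.index(m.name)
                if j not in pool:
                    pool.append(j)
        out = []
        for combo in combinations(sorted(pool), 3):
            k = self._tri_candidate_index(combo)
            if k is not None:
                out.append((combo, k))
        return out

    def _assign(self, fractions, tri_ids, tri_id, rows, tri, alphas, pts):
        """Record an accepted triangle solve.

        When the triangle has vertices in multi-member clusters, look for a
        *sparse* member-level representation: a triangle of actual cluster
        members that explains the point with at most two materials (the
        point sits on its edge or at a vertex, as noiseless mixture data
        does).  Such a representation is exact and is preferred — among
        several, the one with the nearest vertices wins.  Points with no
        sparse member representation (generic noisy pixels) keep the
        well-conditioned agent-level solve, with each agent vertex's
        fraction attributed to the cluster member nearest the point —
        member triangles of near-collinear materials would amplify noise.
        """
        if not self._needs_refinement(tri):
            self._write(fractions, rows, tri, alphas, pts)
            tri_ids[rows] = tri_id(tri)
            return
        cands = self._member_triangles(tri)
        n = len(rows)
        best_supp = np.full(n, 4, dtype=int)
        best_key = np.full(n, np.inf)
        best_c = np.full(n, -1, dtype=int)
        sols = []
        for c, (combo, k) in enumerate(cands):
            a = self._solve_candidate(k, pts)
            sols.append(a)
            contains = a.min(axis=1) >= -self.inside_tol
            supp = (a > self.inside_tol).sum(axis=1)
            key = np.linalg.norm(
                pts[:, None, :] - self.vertex_coords[list(combo)][None], axis=2
            ).sum(axis=1)
            better = contains & (
                (supp < best_supp)
                | ((supp == best_supp) & (key < best_key - 1e-15))
            )
            best_supp[better] = supp[better]
            best_key[better] = key[better]
            best_c[better] = c
        refine = (best_c >= 0) & (best_supp <= 2)
        for c, (combo, k) in enumerate(cands):
            sel = refine & (best_c == c)
            if sel.any():
                self._write(fractions, rows[sel], combo, sols[c][sel], pts[sel])
                tri_ids[rows[sel]] = tri_id(combo)
        keep = ~refine
        if keep.any():
            self._write(fractions, rows[keep], tri, alphas[keep], pts[keep])
            tri_ids[rows[keep]] = tri_id(tri)

    def _tri_candidate_index(self, tri: tuple[int, int, int]) -> int | None:
        try:
            return self.candidates.index(tri)
        except ValueError:
            c = self.vertex_coords[list(tri)]
            mat = np.vstack([c[:, 0], c[:, 1], np.ones(3)])
            scale = max(1.0, float(np.abs(c).max())) ** 2
            if abs(np.linalg.det(mat)) < DEGENERACY_TOL * scale:
                return None
            self.candidates.append(tri)
            self._cand_inv.append(np.linalg.inv(mat))
            return len(self.candidates) - 1

    def _reselect(self, initial_tri, rows, points, fractions, tri_ids, outside, tri_id):
        """Hausdorff-guided triangle reselection for pixels outside their
        initial triangle; leftover pixels are projected onto the hull."""
        order = self._candidate_order(initial_tri)
        pending = rows.copy()
        pts = points[pending]
        for k in order:
            if len(pending) == 0:
                return
            a = self._solve_candidate(k, pts)
            ok = a.min(axis=1) >= -self.inside_tol
            if ok.any():
                tri = self.candidates[k]
                self._assign(fractions, tri_ids, tri_id, pending[ok], tri, a[ok], pts[ok])
                pending = pending[~ok]
                pts = pts[~ok]
        if len(pending) == 0:
            return
        # outside the material convex hull: project and flag
        proj = self.project_to_hull(pts)
        outside[pending] = True
        remaining = np.ones(len(pending), dtype=bool)
        for k in order:
            if not remaining.any():
                break
            a = self._solve_candidate(k, proj[remaining])
            ok = a.min(axis=1) >= -1e-7  # hull projection sits on an edge
            if ok.any():
                tri = self.candidates[k]
                rws = pending[remaining][ok]
                self._assign(fractions, tri_ids, tri_id, rws,
                             tri, np.clip(a[ok], 0.0, None), proj[remaining][ok])
                keep = remaining.copy()
                keep[np.where(remaining)[0][ok]] = False
                remaining = keep
        if remaining.any():  # numerically pathological: fall back to nearest vertex
            rws = pending[remaining]
            d = np.linalg.norm(
                points[rws][:, None, :] - self.library.coords[None], axis=2
            )
            nearest = np.argmin(d, axis=1)
            fractions[rws] = 0.0
            fractions[rws, nearest] = 1.0


def decompose_pixel(point, clusters, library: MaterialLibrary, **kwargs):
    """Decompose a single attenuation point against the library.

    Returns ``(fractions over the library, Triangle used)``.  The initial
    triangle is spanned by the three cluster agents nearest the point; if it
    does not contain the point, a most-similar containing triangle is chosen
    by bi-directional Hausdorff distance.
    """
    dec = Decomposer(library, clusters, **kwargs)
    p = _point_coord(point)
    fr, tri_ids, outside, table = dec.decompose_points(p[None, :])
    by_name = {v.material.name: v.material for v in dec.vertices}
    names = table[tri_ids[0]] if tri_ids[0] >= 0 else tuple(
        dec.vertices[i].material.name for i in dec.candidates[0]
    )
    tri = Triangle(tuple(by_name[n] for n in names))
    return fr[0], tri


def decompose_image(
    image_pair: DectImagePair,
    library: MaterialLibrary,
    clusters=None,
    *,
    n_chunks: int = 1,
    **kwargs,
) -> VolumeFractionMap:
    """Decompose every pixel of a co-registered dual-energy pair.

    Pixels are independent, so the result is identical for any ``n_chunks``
    (serial or concurrent execution).
    """
    pair = image_pair.to_mu()
    h, w = pair.shape
    pts = np.column_stack([pair.image_low.ravel(), pair.image_high.ravel()])
    dec = Decomposer(library, clusters, **kwargs)
    fractions = np.empty((h * w, len(library)))
    tri_ids = np.empty(h * w, dtype=int)
    outside = np.empty(h * w, dtype=bool)
    table: list[tuple[str, str, str]] = []
    for chunk in np.array_split(np.arange(h * w), max(1, n_chunks)):
        fr, ti, oh, names = dec.decompose_points(pts[chunk])
        remap = np.array([_merge_name(table, nm) for nm in names], dtype=int) \
            if names else np.empty(0, dtype=int)
        fractions[chunk] = fr
        tri_ids[chunk] = np.where(ti >= 0, remap[ti], -1) if len(names) else ti
        outside[chunk] = oh
    return VolumeFractionMap(
        fractions.reshape(h, w, -1),
        library.names,
        tri_ids.reshape(h, w),
        table,
        outside.reshape(h, w),
        library=library,
    )


def _merge_name(table: list, names: tuple[str, str, str]) -> int:
    if names not in table:
        table.append(names)
    return table.index(names)
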