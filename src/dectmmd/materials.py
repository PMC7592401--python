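"""Material attenuation library and local clustering in attenuation space.

A *material* is a point in the 2-D space of linear attenuation coefficients
``(mu_low, mu_high)`` measured at the effective energies of the two tube
voltages of a dual-energy scan.  Decomposition restricts its search for
barycentric triangles to *clusters* of materials with similar X-ray
response; clusters are built by a deterministic greedy agglomeration under
a Euclidean radius constraint, and each cluster is represented by an
*agent* — the centroid of its members' coordinates.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Material",
    "MaterialLibrary",
    "Cluster",
    "Histogram2D",
    "build_histogram2d",
    "cluster_materials",
    "assign_cluster",
    "update_subgroups",
    "mix_materials",
    "iodine_solution",
    "koh_solution",
    "default_library",
]


@dataclass(frozen=True)
class Material:
    """One library entry: a named material with density and its linear
    attenuation coefficients (cm^-1) at the low- and high-energy settings."""

    name: str
    density: float
    mu_low: float
    mu_high: float

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"material {self.name!r}: density must be > 0")
        if self.mu_low < 0 or self.mu_high < 0:
            raise ValueError(f"material {self.name!r}: attenuation must be >= 0")

    @property
    def coord(self) -> np.ndarray:
        """Coordinate in (mu_low, mu_high) attenuation space."""
        return np.array([self.mu_low, self.mu_high])


class MaterialLibrary:
    """Ordered collection of materials partitioned into named groups.

    Parameters
    ----------
    materials
        Materials in library order (order defines tie-breaks downstream).
    groups
        Mapping material name -> group label.  Materials not listed fall in
        the ``"default"`` group.
    energy_pair
        The two tube voltages (kVp) the attenuation values correspond to.
    """

    def __init__(
        self,
        materials: Sequence[Material],
        groups: dict[str, str] | None = None,
        energy_pair: tuple[float, float] = (80.0, 140.0),
    ) -> None:
        materials = list(materials)
        names = [m.name for m in materials]
        if len(set(names)) != len(names):
            raise ValueError("material names must be unique within a library")
        coords = np.array([[m.mu_low, m.mu_high] for m in materials])
        if len(materials) > 1:
            d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() == 0.0:
                i, j = np.unravel_index(np.argmin(d), d.shape)
                raise ValueError(
                    "degenerate library: materials "
                    f"{names[i]!r} and {names[j]!r} share identical "
                    "(mu_low, mu_high) coordinates"
                )
        self.materials = materials
        self.groups = {m.name: (groups or {}).get(m.name, "default") for m in materials}
        self.energy_pair = tuple(energy_pair)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.materials)

    def __iter__(self):
        return iter(self.materials)

    def __getitem__(self, key: int | str) -> Material:
        if isinstance(key, str):
            for m in self.materials:
                if m.name == key:
                    return m
            raise KeyError(key)
        return self.materials[key]

    def __contains__(self, name: str) -> bool:
        return any(m.name == name for m in self.materials)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.materials]

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of material coordinates in attenuation space."""
        return np.array([[m.mu_low, m.mu_high] for m in self.materials])

    @property
    def densities(self) -> np.ndarray:
        return np.array([m.density for m in self.materials])

    def index(self, name: str) -> int:
        return self.names.index(name)

    def group_members(self, group: str) -> list[Material]:
        return [m for m in self.materials if self.groups[m.name] == group]

    def subset(self, names: Iterable[str]) -> "MaterialLibrary":
        mats = [self[n] for n in names]
        return MaterialLibrary(mats, {m.name: self.groups[m.name] for m in mats},
                               self.energy_pair)

    def diagonal(self) -> float:
        """Length of the bounding-box diagonal in attenuation space."""
        c = self.coords
        return float(np.linalg.norm(c.max(axis=0) - c.min(axis=0)))

    # -- serialization ------------------------------------------------------
    @classmethod
    def from_csv(cls, path, energy_pair=(80.0, 140.0)) -> "MaterialLibrary":
        """Read a library from a delimited table with columns
        name, density_g_cm3, mu_low_cm1, mu_high_cm1[, group]."""
        df = pd.read_csv(path)
        required = {"name", "density_g_cm3", "mu_low_cm1", "mu_high_cm1"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"library table missing columns: {sorted(missing)}")
        mats = [
            Material(r["name"], float(r["density_g_cm3"]),
                     float(r["mu_low_cm1"]), float(r["mu_high_cm1"]))
            for _, r in df.iterrows()
        ]
        groups = None
        if "group" in df.columns:
            groups = dict(zip(df["name"], df["group"].astype(str)))
        return cls(mats, groups, energy_pair)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "name": self.names,
                "density_g_cm3": self.densities,
                "mu_low_cm1": [m.mu_low for m in self.materials],
                "mu_high_cm1": [m.mu_high for m in self.materials],
                "group": [self.groups[n] for n in self.names],
            }
        ).to_csv(path, index=False)


def default_library(include_solutes: bool = False) -> MaterialLibrary:
    """The packaged 80/140 kVp library (air, water, blood, fat, bone,
    Lexan, Acrylic, Teflon; optionally the pure-solute mixing bases)."""
    ref = importlib.resources.files("dectmmd.data") / "attenuation_80_140.csv"
    with importlib.resources.as_file(ref) as path:
        lib = MaterialLibrary.from_csv(path)
    if not include_solutes:
        lib = lib.subset([n for n in lib.names if lib.groups[n] != "solute"])
    return lib


# -- ideal-solution mixing helpers ------------------------------------------

def mix_materials(name: str, components: Sequence[tuple[Material, float]]) -> Material:
    """Volume-additive ideal mixture: mu and density are volume-fraction
    weighted sums of the components'. Fractions must be non-negative and
    sum to 1."""
    fracs = np.array([f for _, f in components], dtype=float)
    if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("mixture volume fractions must be >= 0 and sum to 1")
    mu_low = sum(f * m.mu_low for m, f in components)
    mu_high = sum(f * m.mu_high for m, f in components)
    rho = sum(f * m.density for m, f in components)
    return Material(name, rho, mu_low, mu_high)


def _solutes() -> MaterialLibrary:
    return default_library(include_solutes=True)


def iodine_solution(mg_per_ml: float, name: str | None = None) -> Material:
    """Aqueous iodine contrast at the given iodine concentration (mg/ml),
    modelled as a volume-additive mixture of water and elemental iodine.
    Omnipaque 350 corresponds to 350 mg/ml."""
    if mg_per_ml < 0:
        raise ValueError("concentration must be >= 0")
    lib = _solutes()
    iodine, water = lib["iodine"], lib["water"]
    f = mg_per_ml / 1000.0 / iodine.density  # solute volume fraction
    if f > 1:
        raise ValueError("concentration exceeds pure iodine")
    return mix_materials(name or f"iodine_{mg_per_ml:g}mgml",
                         [(water, 1.0 - f), (iodine, f)])


def koh_solution(percent_ww: float, name: str | None = None) -> Material:
    """Aqueous KOH at the given mass concentration (% w/w), modelled as a
    volume-additive mixture of water and solid KOH.  Used as the
    calcium-plaque surrogate in the angiography phantom."""
    if not 0 <= percent_ww < 100:
        raise ValueError("percent w/w must be in [0, 100)")
    lib = _solutes()
    koh, water = lib["koh_solid"], lib["water"]
    w = percent_ww / 100.0
    # solve mass fraction -> volume fraction under volume-additive mixing
    f = w * water.density / (koh.density * (1.0 - w) + w * water.density)
    return mix_materials(name or f"koh_{percent_ww:g}pct",
                         [(water, 1.0 - f), (koh, f)])


# -- 2-D attenuation histogram ----------------------------------------------

@dataclass
class Histogram2D:
    """Joint histogram of pixel coordinates in (mu_low, mu_high) space."""

    edges_low: np.ndarray
    edges_high: np.ndarray
    counts: np.ndarray

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())


def build_histogram2d(image_pair, n_bins: int) -> Histogram2D:
    """Histogram a dual-energy image pair in the linear attenuation domain.

    ``image_pair`` must already be in attenuation units (cm^-1); see
    :meth:`dectmmd.images.DectImagePair.to_mu`.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be a positive integer")
    if getattr(image_pair, "units", "mu") == "hu":
        image_pair = image_pair.to_mu()
    low, high = np.asarray(image_pair.image_low), np.asarray(image_pair.image_high)
    if low.shape != high.shape:
        raise ValueError(f"image shapes differ: {low.shape} vs {high.shape}")
    if low.size == 0:
        raise ValueError("cannot histogram an empty image")
    counts, edges_low, edges_high = np.histogram2d(
        low.ravel(), high.ravel(), bins=n_bins
    )
    return Histogram2D(edges_low, edges_high, counts.astype(np.int64))


# -- local clustering ---------------------------------------------------------

@dataclass
class Cluster:
    """A cluster of materials (or bare attenuation points) represented by
    its agent: the centroid of member coordinates.  ``members`` may be empty
    for clusters created from unassigned image points; ``point_coords`` then
    holds the coordinates the agent summarizes."""

    agent: np.ndarray
    members: list[Material] = field(default_factory=list)
    radius: float = 0.0
    point_coords: np.ndarray | None = None
    group: str = "default"

    def member_coords(self) -> np.ndarray:
        if self.members:
            return np.array([m.coord for m in self.members])
        if self.point_coords is not None:
            return np.asarray(self.point_coords, dtype=float)
        return self.agent[None, :]


def _agglomerate(coords: np.ndarray, radius: float) -> list[list[int]]:
    """Greedy agglomerative grouping: repeatedly merge the closest pair of
    clusters (centroid distance, lowest-index tie-break) whose merged members
    all stay within ``radius`` of the merged centroid.  Deterministic."""
    parts: list[list[int]] = [[i] for i in range(len(coords))]
    while len(parts) > 1:
        cents = np.array([coords[p].mean(axis=0) for p in parts])
        d = np.linalg.norm(cents[:, None] - cents[None, :], axis=-1)
        # candidate merges ordered by distance then (i, j) index
        order = sorted(
            ((d[i, j], i, j) for i in range(len(parts)) for j in range(i + 1, len(parts))),
        )
        merged = False
        for _, i, j in order:
            idx = parts[i] + parts[j]
            cent = coords[idx].mean(axis=0)
            if np.all(np.linalg.norm(coords[idx] - cent, axis=1) <= radius):
                parts[i] = idx
                del parts[j]
                merged = True
                break
        if not merged:
            break
    # stable order: by smallest member index
    parts.sort(key=min)
    return parts


def cluster_materials(library: MaterialLibrary, radius: float | None = None) -> list[Cluster]:
    """Cluster the library's materials within each group.

    Materials whose attenuation coordinates lie within ``radius`` of a
    common centroid are merged greedily; every member ends within ``radius``
    of its cluster agent.  Default radius is 5% of the library's
    attenuation-space bounding-box diagonal.
    """
    if radius is None:
        radius = 0.05 * library.diagonal()
    if radius <= 0:
        raise ValueError("radius must be > 0")
    clusters: list[Cluster] = []
    seen_groups: list[str] = []
    for name in library.names:  # preserve library order of first appearance
        g = library.groups[name]
        if g not in seen_groups:
            seen_groups.append(g)
    for g in seen_groups:
        members = library.group_members(g)
        coords = np.array([m.coord for m in members])
        for part in _agglomerate(coords, radius):
            mats = [members[i] for i in part]
            agent = coords[part].mean(axis=0)
            clusters.append(Cluster(agent=agent, members=mats, radius=radius, group=g))
    return clusters


def assign_cluster(point, clusters: Sequence[Cluster]) -> Cluster | None:
    """Assign an attenuation point to the cluster with the nearest agent.

    Returns ``None`` ("no-cluster") when the nearest agent is farther than
    that cluster's radius.  Equidistant agents break ties by cluster index.
    """
    if len(clusters) == 0:
        raise ValueError("need at least one cluster")
    p = np.asarray(point, dtype=float)[:2]
    dists = np.array([np.linalg.norm(p - c.agent) for c in clusters])
    best = int(np.argmin(dists))  # argmin returns first minimum: low-index tie-break
    if dists[best] <= clusters[best].radius:
        return clusters[best]
    return None


def update_subgroups(
    library: MaterialLibrary,
    clusters: Sequence[Cluster],
    unassigned: Sequence,
) -> list[Cluster]:
    """Augment the cluster set so every previously unassigned point becomes
    assignable.  Unassigned points are agglomerated under the same radius
    rule and appended as new (member-less) clusters; existing clusters are
    returned unchanged."""
    clusters = list(clusters)
    if len(unassigned) == 0:
        return clusters
    radius = max(c.radius for c in clusters) if clusters else 0.05 * library.diagonal()
    pts = np.array([np.asarray(p, dtype=float)[:2] for p in unassigned])
    for part in _agglomerate(pts, radius):
        agent = pts[part].mean(axis=0)
        clusters.append(
            Cluster(agent=agent, members=[], radius=radius, point_coords=pts[part])
        )
    return clusters
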