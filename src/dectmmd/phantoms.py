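"""Synthetic dual-energy CT phantoms with pixel-level ground truth.

Three evaluation objects are modelled after the physical phantoms typically
used for this task:

* an *angiography* phantom — a water-filled Plexiglas cylinder carrying
  twelve 12 mm vials on a ring, filled with dilutions of iodinated contrast
  (Omnipaque 350) and of KOH (a calcium-plaque surrogate);
* a *QA* phantom — a body section with Water/Lexan/Acrylic/Teflon inserts
  and a head section with small air pinholes (1–3 mm) probing resolution;
* a synthetic *abdominal* slice with air, blood-equivalent soft tissue,
  subcutaneous fat and bone regions.

Each phantom is a :class:`PhantomSpec` (geometry + per-shape composition as
volume fractions over named materials).  :func:`render_dect` renders the
spec at two effective energies — per pixel, attenuation is the
volume-fraction weighted sum of the constituent materials' attenuations,
with partial volume handled by 4x4 supersampling — converts to Hounsfield
units and adds seeded Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .images import WATER_MU, DectImagePair, mu_to_hu
from .materials import (Material, MaterialLibrary, default_library,
                        iodine_solution, koh_solution)

__all__ = [
    "PhantomShape",
    "PhantomSpec",
    "make_angio_phantom",
    "make_qa_body",
    "make_qa_head",
    "make_abdomen",
    "render_dect",
    "angio_library",
    "angio_render_library",
    "abdomen_library",
    "qa_library",
]

SUPERSAMPLE = 4  # per axis -> 16 sub-pixels per pixel


@dataclass
class PhantomShape:
    """One geometric region: circle/annulus/rectangle/ellipse, centered at
    ``center`` (mm from grid center, x right / y down), with a composition
    given as volume fractions over material names."""

    geometry: str  # "circle" | "annulus" | "rectangle" | "ellipse"
    center: tuple[float, float]
    size: tuple[float, ...]  # circle: (diameter,); annulus: (outer_d, inner_d);
    # rectangle: (width, height); ellipse: (semi_x, semi_y)
    composition: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9 or any(v < 0 for v in self.composition.values()):
            raise ValueError(
                f"shape composition must be non-negative and sum to 1 (got {total})"
            )

    def mask(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        cx, cy = self.center
        dx, dy = x - cx, y - cy
        if self.geometry == "circle":
            r = self.size[0] / 2.0
            return dx ** 2 + dy ** 2 <= r ** 2
        if self.geometry == "annulus":
            ro, ri = self.size[0] / 2.0, self.size[1] / 2.0
            rr = dx ** 2 + dy ** 2
            return (rr <= ro ** 2) & (rr > ri ** 2)
        if self.geometry == "rectangle":
            w, h = self.size
            return (np.abs(dx) <= w / 2.0) & (np.abs(dy) <= h / 2.0)
        if self.geometry == "ellipse":
            a, b = self.size
            return (dx / a) ** 2 + (dy / b) ** 2 <= 1.0
        raise ValueError(f"unknown geometry {self.geometry!r}")

    def extent(self) -> tuple[float, float]:
        """Half-extent of the shape's bounding box along x and y (mm)."""
        if self.geometry in ("circle", "annulus"):
            r = self.size[0] / 2.0
            return (r, r)
        if self.geometry == "rectangle":
            return (self.size[0] / 2.0, self.size[1] / 2.0)
        return (self.size[0], self.size[1])


@dataclass
class PhantomSpec:
    """Geometry + composition description of a 2-D phantom slice."""

    name: str
    grid_shape: tuple[int, int]  # (rows, cols)
    spacing_mm: float
    background: str  # material name
    shapes: list[PhantomShape]
    rois: dict[str, list[tuple[float, float, float]]] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ny, nx = self.grid_shape
        half_x, half_y = nx * self.spacing_mm / 2.0, ny * self.spacing_mm / 2.0
        for s in self.shapes:
            ex, ey = s.extent()
            if (abs(s.center[0]) + ex > half_x) or (abs(s.center[1]) + ey > half_y):
                raise ValueError(f"shape at {s.center} does not fit inside the grid")

    def material_names(self) -> list[str]:
        names = {self.background}
        for s in self.shapes:
            names.update(s.composition)
        return sorted(names)

    def pixel_coords(self, supersample: int = 1):
        """Sub-pixel center coordinates (mm, grid-centered), shape
        (rows*ss, cols*ss)."""
        ny, nx = self.grid_shape
        step = self.spacing_mm / supersample
        xs = (np.arange(nx * supersample) + 0.5) * step - nx * self.spacing_mm / 2.0
        ys = (np.arange(ny * supersample) + 0.5) * step - ny * self.spacing_mm / 2.0
        return np.meshgrid(xs, ys)

    def roi_mask(self, cx: float, cy: float, r: float) -> np.ndarray:
        x, y = self.pixel_coords()
        return (x - cx) ** 2 + (y - cy) ** 2 < r ** 2


def render_composition(spec: PhantomSpec, library: MaterialLibrary) -> np.ndarray:
    """Ground-truth per-pixel volume fractions (rows, cols, n_materials),
    with boundary pixels mixed by sub-pixel area weighting."""
    for name in spec.material_names():
        if name not in library:
            raise KeyError(f"material {name!r} not in library")
    ny, nx = spec.grid_shape
    x, y = spec.pixel_coords(SUPERSAMPLE)
    label = np.zeros(x.shape, dtype=np.int32)  # 0 = background
    for i, s in enumerate(spec.shapes, start=1):
        label[s.mask(x, y)] = i  # painter's order: later shapes on top
    comp_table = np.zeros((len(spec.shapes) + 1, len(library)))
    comp_table[0, library.index(spec.background)] = 1.0
    for i, s in enumerate(spec.shapes, start=1):
        for mat, frac in s.composition.items():
            comp_table[i, library.index(mat)] = frac
    sub = comp_table[label]  # (ny*ss, nx*ss, M)
    return sub.reshape(ny, SUPERSAMPLE, nx, SUPERSAMPLE, -1).mean(axis=(1, 3))


def render_dect(
    spec: PhantomSpec,
    library: MaterialLibrary,
    kvp_pair: tuple[float, float] = (80.0, 140.0),
    noise_sigma_hu: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
) -> DectImagePair:
    """Forward-render a phantom at two energies.

    Per pixel and energy, mu = sum_i alpha_i mu_i(E) over the ground-truth
    composition; images are returned in HU with additive Gaussian noise of
    the requested per-energy standard deviation (same generator, seeded)."""
    truth = render_composition(spec, library)
    mu_low = truth @ np.array([m.mu_low for m in library.materials])
    mu_high = truth @ np.array([m.mu_high for m in library.materials])
    wl, wh = WATER_MU[float(kvp_pair[0])], WATER_MU[float(kvp_pair[1])]
    img_low = mu_to_hu(mu_low, wl)
    img_high = mu_to_hu(mu_high, wh)
    rng = np.random.default_rng(seed)
    if noise_sigma_hu[0] > 0:
        img_low = img_low + rng.normal(0.0, noise_sigma_hu[0], img_low.shape)
    if noise_sigma_hu[1] > 0:
        img_high = img_high + rng.normal(0.0, noise_sigma_hu[1], img_high.shape)
    return DectImagePair(
        img_low,
        img_high,
        kvp_pair=kvp_pair,
        spacing_mm=spec.spacing_mm,
        units="hu",
        truth_fractions=truth,
        truth_materials=library.names,
        meta={"phantom": spec.name, "noise_sigma_hu": tuple(noise_sigma_hu),
              "seed": seed},
    )


# ---------------------------------------------------------------------------
# libraries for the three study objects


def angio_library() -> MaterialLibrary:
    """Task-specific basis for the angiography study: water and the two
    reference dilutions the vial series is expressed against — iodine at
    10 mg/ml and KOH at 50% w/w.  At two energies the decomposition basis
    must be limited to the materials of interest; the Plexiglas shell is
    not part of the basis (shell pixels are flagged outside-hull)."""
    base = default_library()
    mats = [base["water"],
            iodine_solution(10.0, name="iodine10"),
            koh_solution(50.0, name="koh50")]
    return MaterialLibrary(mats, energy_pair=base.energy_pair)


def angio_render_library() -> MaterialLibrary:
    """Materials needed to *render* the angiography phantom: the task basis
    plus the Plexiglas (acrylic) shell."""
    base = default_library()
    lib = angio_library()
    return MaterialLibrary(list(lib.materials) + [base["acrylic"]],
                           energy_pair=lib.energy_pair)


def abdomen_library() -> MaterialLibrary:
    base = default_library()
    return base.subset(["air", "blood", "fat", "bone"])


def qa_library() -> MaterialLibrary:
    base = default_library()
    return base.subset(["air", "water", "lexan", "acrylic", "teflon"])


# ---------------------------------------------------------------------------
# phantom builders


DEFAULT_IODINE_MG_ML = [1.0, 2.0, 3.0, 5.0, 7.5, 10.0]
DEFAULT_KOH_PCT = [5.0, 10.0, 20.0, 30.0, 40.0, 50.0]


def make_angio_phantom(
    concentrations_iodine: list[float] | None = None,
    concentrations_koh: list[float] | None = None,
    grid: int = 256,
    spacing_mm: float = 0.5,
) -> PhantomSpec:
    """The angiography phantom: a Plexiglas cylinder filled with water,
    carrying twelve 12 mm vials on a ring — an iodine dilution series
    (mg iodine per ml) and a KOH series (% w/w)."""
    iod = DEFAULT_IODINE_MG_ML if concentrations_iodine is None else list(concentrations_iodine)
    koh = DEFAULT_KOH_PCT if concentrations_koh is None else list(concentrations_koh)
    if len(iod) + len(koh) > 12:
        raise ValueError("the phantom holds at most 12 vials")

    shapes = [
        PhantomShape("circle", (0.0, 0.0), (110.0,), {"acrylic": 1.0}),
        PhantomShape("circle", (0.0, 0.0), (100.0,), {"water": 1.0}),
    ]
    vials = []
    ring_r, vial_d = 30.0, 12.0
    n = len(iod) + len(koh)
    series = [("iodine", c) for c in iod] + [("koh", c) for c in koh]
    for k, (kind, conc) in enumerate(series):
        ang = 2 * np.pi * k / max(n, 1)
        cx, cy = ring_r * np.cos(ang), ring_r * np.sin(ang)
        if kind == "iodine":
            alpha = conc / 10.0  # volume fraction of the 10 mg/ml reference
            ref = "iodine10"
        else:
            # under ideal volume-additive mixing, density is linear in the
            # solute volume fraction, so the fraction of the 50% reference is
            alpha = (koh_solution(conc).density - 1.0) / (koh_solution(50.0).density - 1.0)
            ref = "koh50"
        comp = {"water": 1.0 - alpha, ref: alpha} if alpha > 0 else {"water": 1.0}
        shapes.append(PhantomShape("circle", (cx, cy), (vial_d,), comp))
        vials.append(
            {"kind": kind, "concentration": conc, "center": (cx, cy),
             "diameter": vial_d, "ref_material": ref, "ref_volume_fraction": alpha}
        )
    rois = {
        "vials": [(v["center"][0], v["center"][1], vial_d / 2.0 - 1.5) for v in vials]
    }
    return PhantomSpec(
        "angiography",
        (grid, grid),
        spacing_mm,
        "water",
        shapes,
        rois=rois,
        extras={"vials": vials},
    )


def make_qa_body(grid: int = 192, spacing_mm: float = 1.0) -> PhantomSpec:
    """QA phantom body section: a water-filled cylinder with pure Lexan,
    Acrylic, Teflon and water inserts."""
    shapes = [PhantomShape("circle", (0.0, 0.0), (150.0,), {"water": 1.0})]
    inserts = ["lexan", "acrylic", "teflon", "water"]
    for k, mat in enumerate(inserts):
        ang = 2 * np.pi * k / len(inserts) + np.pi / 4
        cx, cy = 45.0 * np.cos(ang), 45.0 * np.sin(ang)
        shapes.append(PhantomShape("circle", (cx, cy), (25.0,), {mat: 1.0}))
    rois = {mat: [(s.center[0], s.center[1], 8.0)]
            for mat, s in zip(inserts, shapes[1:])}
    return PhantomSpec("qa_body", (grid, grid), spacing_mm, "air", shapes, rois=rois)


def make_qa_head(
    pin_diameters_mm: list[float] | None = None,
    grid: int = 128,
    spacing_mm: float = 0.5,
) -> PhantomSpec:
    """QA phantom head section: a uniform Acrylic cylinder with air
    pinholes of the requested diameters (resolution probe)."""
    pins = [1.0, 2.0, 3.0] if pin_diameters_mm is None else list(pin_diameters_mm)
    for d in pins:
        if not 0.5 <= d <= 5.0:
            raise ValueError(f"pin diameter {d} mm outside the supported [0.5, 5] mm")
    shapes = [PhantomShape("circle", (0.0, 0.0), (56.0,), {"acrylic": 1.0})]
    centers = []
    for k, d in enumerate(pins):
        ang = 2 * np.pi * k / max(len(pins), 1)
        cx, cy = 16.0 * np.cos(ang), 16.0 * np.sin(ang)
        # snap pin centers to a pixel center so detection probes geometry,
        # not sub-pixel placement luck
        cx = (np.floor(cx / spacing_mm) + 0.5) * spacing_mm
        cy = (np.floor(cy / spacing_mm) + 0.5) * spacing_mm
        shapes.append(PhantomShape("circle", (cx, cy), (d,), {"air": 1.0}))
        centers.append((cx, cy))
    return PhantomSpec(
        "qa_head",
        (grid, grid),
        spacing_mm,
        "air",
        shapes,
        extras={"pins": [{"diameter": d, "center": c} for d, c in zip(pins, centers)]},
    )


def make_abdomen(grid: int = 256, spacing_mm: float = 1.25) -> PhantomSpec:
    """Synthetic abdominal slice: subcutaneous fat ring, blood-equivalent
    soft tissue, a bone (spine) region and bowel-gas pockets, in air.

    Eight blood and eight fat evaluation ROIs are placed programmatically
    and verified to sit in pure-material regions."""
    shapes = [
        PhantomShape("ellipse", (0.0, 0.0), (150.0, 110.0), {"fat": 1.0}),
        PhantomShape("ellipse", (0.0, 0.0), (133.0, 93.0), {"blood": 1.0}),
        # spine (posterior, +y is "down" toward the table)
        PhantomShape("circle", (0.0, 72.0), (26.0,), {"bone": 1.0}),
        # bowel gas pockets
        PhantomShape("circle", (-62.0, -20.0), (18.0,), {"air": 1.0}),
        PhantomShape("circle", (-42.0, -50.0), (16.0,), {"air": 1.0}),
        # a second bone fragment (iliac hint)
        PhantomShape("circle", (58.0, 52.0), (16.0,), {"bone": 1.0}),
    ]
    spec = PhantomSpec("abdomen", (grid, grid), spacing_mm, "air", shapes)

    lib = abdomen_library()
    truth = render_composition(spec, lib)

    def pure_disk(material: str, cx: float, cy: float, r: float) -> bool:
        m = spec.roi_mask(cx, cy, r)
        return bool(m.any()) and bool(
            (truth[..., lib.index(material)][m] > 0.999).all()
        )

    blood_rois = []
    for ang in np.linspace(0, 2 * np.pi, 16, endpoint=False):
        cx, cy = 38.0 * np.cos(ang), 30.0 * np.sin(ang)
        if len(blood_rois) < 8 and pure_disk("blood", cx, cy, 8.0):
            blood_rois.append((cx, cy, 8.0))
    fat_rois = []
    for ang in np.linspace(0, 2 * np.pi, 32, endpoint=False):
        cx, cy = 141.5 * np.cos(ang), 101.5 * np.sin(ang)
        if len(fat_rois) < 8 and pure_disk("fat", cx, cy, 3.0):
            fat_rois.append((cx, cy, 3.0))
    if len(blood_rois) < 8 or len(fat_rois) < 8:
        raise RuntimeError("could not place 8 pure blood/fat ROIs")
    spec.rois = {"blood": blood_rois, "fat": fat_rois}
    return spec
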