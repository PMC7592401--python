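# Methods

## Model

A pixel's linear attenuation at energy E is modelled as the
volume-fraction weighted sum of its constituent materials' attenuations,
μ(E) = Σᵢ αᵢ μ_i(E), with Σαᵢ = 1 (volume conservation, the
ideal-solution assumption) and αᵢ ≥ 0. With two energies this is a 3×3
linear system per pixel whose solution is the barycentric coordinate of
the pixel's (μ_low, μ_high) point with respect to the triangle spanned by
three candidate materials; inside the triangle, each coordinate equals the
opposing sub-triangle's area fraction. The decomposition problem is then
a *triangle selection* problem: which three library materials explain each
pixel.

Assumptions inherited by everything downstream: volume-additive mixing
(no partial molar volume effects), monoenergetic effective-energy
attenuation per tube voltage (no beam hardening or scatter), co-registered
pixel grids, additive Gaussian noise in HU.

## Pipeline stages

1. **DLWFDW denoising** of each energy image (below).
2. **HU → μ** via μ = μ_water(E)·(1 + HU/1000), clipped at 0.
3. **Library clustering**: greedy agglomeration — repeatedly merge the
   closest pair of clusters (centroid distance) whose merged members all
   stay within `radius` of the merged centroid. Deterministic; ties break
   to the lowest library index. The cluster *agent* is the member
   centroid. Default radius = 5% of the library's attenuation-space
   bounding-box diagonal: with the packaged 80/140 kVp table this merges
   blood+fat (abdominal library) and water+Lexan+acrylic (QA library),
   which is the intended behavior — those materials are mutually
   confusable at two energies, and the agent-level solve plus
   nearest-member attribution is what keeps per-pixel maps stable.
4. **Per-pixel decomposition**: the initial triangle is spanned by the
   three cluster agents nearest the pixel's point. If the solve is not
   inside, candidate triangles (3-combinations of library materials within
   the point's group, plus agent triplets) that contain the point are
   ranked by bi-directional Hausdorff distance between vertex sets
   (similarity to the initial triangle), lexicographic name order breaking
   ties. Points outside the material convex hull are projected onto the
   hull boundary and flagged — never silently dropped.
5. **Member attribution** (see "Exactness vs robustness" below).
6. **Volume → mass fractions**: mᵢ = αᵢρᵢ / Σⱼ αⱼρⱼ.
7. **Evaluation** when ground truth is available: ROI area ratios
   (fraction > 0.5 within the true region), per-vial mass-fraction
   accuracy, OLS concentration fit, pinhole detection (mean air fraction
   in the true pin disk > 0.5), noise levels.

### Exactness vs robustness: sparse member refinement

Two desirable properties pull in opposite directions. (a) Noiseless
forward-rendered mixtures of library materials should be recovered
exactly — but an agent-level solve attributes a merged cluster's fraction
to a single member, so a 50/50 blood/fat boundary pixel cannot be exact.
(b) Noisy per-pixel fractions should be stable — but triangles built from
the *members* of a merged cluster are razor-thin (that is why the members
merged), and barycentric coordinates of a thin triangle amplify
perpendicular noise enormously (for blood/fat/air the amplification is
~300×, turning σ = 10 HU into fraction noise of order 1).

The resolution: after an accepted solve whose triangle touches a
multi-member cluster, the pixel is re-solved against triangles of actual
cluster members, and the member solution is adopted **only if it is
sparse** — at most two strictly positive fractions, i.e. the point lies on
a member edge or vertex to within the containment tolerance. Noiseless
mixture data always lies on such an edge, so round trips are exact; noisy
points almost surely do not, so they keep the well-conditioned agent
solve, with each agent vertex's fraction given to the cluster member
nearest the point. Among several sparse candidates the one whose vertices
are nearest the point wins (then lexicographic names).

### ROI read-outs

Quantitative ROI estimates (vial concentrations) decompose the **ROI-mean
attenuation point** rather than averaging per-pixel fractions. Averaging
in attenuation space commutes with the linear solve but happens *before*
the non-negativity constraint; averaging clamped per-pixel fractions of a
nearly degenerate triangle (water/iodine/KOH are close to collinear at
52/69 keV) is biased low by 10–20% at low concentrations. Both numbers
are reported (`est_volume_fraction` vs `map_mean_volume_fraction`).

## DLWFDW denoising

Each energy image is decomposed with an orthogonal symmetric 8-tap wavelet
(sym4), 3 levels, symmetric extension. The noise level is estimated as
median(|finest diagonal band|)/0.6745 unless supplied. Pass 1 estimates
per-coefficient signal variance by windowed averaging of squared
coefficients minus σ², floored at 0, over orientation-matched windows
(3×9 rows×cols for horizontal bands, 9×3 for vertical, 5×5 for diagonal)
and applies the empirical Wiener gain σ_x²/(σ_x²+σ²). Pass 2 re-estimates
the signal variance from the pass-1 pilot over smaller directional windows
(3×5 / 5×3 / 3×3) and shrinks the *original* noisy coefficients with it.
The approximation band is untouched. A noise estimate below 10⁻¹⁰ of the
image dynamic range short-circuits to the identity, so the stage is a
strict no-op on noiseless input.

Measured behavior (σ = 10 HU, 256² phantoms): flat-region noise falls from
10 to ≈1.5 HU; near strong edges a Wiener-preserved noise halo leaves
≈4–6 HU locally. Window sizes and level count are config-exposed;
A/B variants (wider windows, 4–5 levels, undecimated transform) did not
improve ROI-mean error and are not defaults.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `cluster_radius` | 5% of library diagonal | cm⁻¹ | agglomeration acceptance radius |
| `denoise.wavelet`, `levels` | sym4, 3 | — | pyramid construction |
| `denoise.windows` pass 1 / 2 | 3×9,9×3,5×5 / 3×5,5×3,3×3 | coeff | directional variance windows |
| `hausdorff_convention` | standard-max | — | max of directed distances (the early-break scan's operational definition); `paper-min` gives min |
| `search_scope` | group | — | candidate triangles restricted to the point's material group |
| inside tolerance | 1e-9 | — | αᵢ ≥ −tol counts as inside |
| degeneracy tolerance | 1e-12 × scale | — | reject collinear triangles (scale = max |coord|²) |
| ROI threshold | 0.5 | — | fraction threshold for area ratios / pin detection |

## Synthetic data

The simulator renders 2-D phantom specs (circles, annuli, rectangles,
ellipses with per-shape compositions) at two effective energies by the
forward model above, with 4×4 sub-pixel supersampling for partial volume,
HU conversion, and seeded additive Gaussian noise. The frozen material
table holds μ at 52 and 69 keV (standard effective energies for 80 and
140 kVp spectra), computed from element mass-attenuation values by the
mixture rule (`scripts/generate_attenuation_table.py`). Solutions (iodine
contrast, KOH) are ideal volume-additive mixtures, so μ and ρ are linear
in concentration and vials are exact convex combinations of water and a
reference dilution.

Study objects: a 110 mm Plexiglas angiography phantom, water-filled, with
twelve 12 mm vials (iodine 1–10 mg/ml; KOH 5–50% w/w — the defaults start
at the lowest concentrations used in practice, ≈1 mg/ml iodine and 5%
KOH); a QA body section (water cylinder with Lexan/acrylic/Teflon/water
inserts) and head section (acrylic cylinder with 1/2/3 mm air pins at
0.5 mm pixels, pin centers snapped to pixel centers so detection probes
geometry rather than sub-pixel luck); a 256² abdominal slice at 1.25 mm
with a subcutaneous fat ring, blood-equivalent soft tissue, spine/iliac
bone, bowel gas, and eight blood + eight fat evaluation ROIs placed
programmatically in verified pure regions.

What the simulator does **not** emulate: polychromatic spectra and beam
hardening, scatter, detector blur and correlated CT noise, anatomical
texture. Passing tests therefore demonstrate the algorithm's correctness
and its noise behavior under additive Gaussian noise — not clinical
performance.

The angiography *decomposition* basis is task-specific (water, iodine
10 mg/ml, KOH 50%): with the Plexiglas shell in the basis, mid-range KOH
vials are mathematically inside the acrylic/iodine/KOH triangle — at two
energies no algorithm could attribute them correctly. Shell pixels fall
outside the basis hull and are flagged.

## Numerical choices

- Containment: αᵢ ≥ −10⁻⁹; hull-projected points use 10⁻⁷ (the projection
  lands on an edge up to round-off). Fractions are clipped of sub-10⁻⁸
  dust and renormalized to sum exactly to 1.
- The per-pixel solve is expanded elementwise (not BLAS matmul) so results
  are bit-identical under any chunking/concurrency of the pixel loop.
- The Hausdorff early-break scan excludes A∩B, randomizes scan order
  (seeded, default 0), and skips the d_max update when the inner loop
  breaks; the returned value is exactly the max-min distance regardless of
  scan order.
- Degenerate candidate triples are silently skipped during enumeration;
  an explicitly constructed degenerate `Triangle` raises, naming the
  vertices.
- Out-of-hull pixels (metal-artifact analogues, shell pixels outside a
  task basis) are projected to the nearest hull-boundary point and
  flagged in `outside_hull`.

## Known limitations

- Two-energy data cannot distinguish materials inside the convex hull of
  others; the reported fractions are the algorithm's (documented,
  deterministic) choice among valid representations, not unique truth.
- At σ = 10 HU, the 1 mg/ml iodine vial read-out has ≈15% relative
  error spread across noise realizations — the water→iodine and
  water→KOH directions differ by only ≈20% in slope at 52/69 keV, so the
  iodine/KOH split of a weak contrast signal is intrinsically
  ill-conditioned.
- Lexan vs acrylic (Δμ ≈ 0.008 cm⁻¹) are not reliably separated per-pixel
  under noise; they cluster together by design and the map attributes
  their region to the nearer member.
- 2-D slices only; no projection-domain or iterative-reconstruction
  coupling.
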