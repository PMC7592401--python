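# dectmmd — image-domain multi-material decomposition for dual-energy CT

Dual-energy CT (DECT) scans an object at two tube voltages, giving each
pixel a coordinate (μ_low, μ_high) in the plane of linear attenuation
coefficients. Two measurements determine at most two basis materials; to
separate **three** materials per pixel — the situation in contrast-agent
imaging, where iodine, calcified plaque and soft tissue must be told apart
— a volume-conservation constraint is added, and the decomposition becomes
a barycentric-coordinate problem:

```
[ μ₁(E₁)  μ₂(E₁)  μ₃(E₁) ] [α₁]   [ μ(E₁) ]
[ μ₁(E₂)  μ₂(E₂)  μ₃(E₂) ] [α₂] = [ μ(E₂) ]      αᵢ ≥ 0,  Σαᵢ = 1
[ 1       1       1      ] [α₃]   [ 1     ]
```

The volume fractions αᵢ are the barycentric coordinates of the pixel with
respect to the triangle spanned by three candidate materials; a pixel is
accepted only if it lies inside the triangle (all αᵢ ≥ 0). `dectmmd`
implements a full pipeline around this solve:

* **Local clustering** of the material library in attenuation space
  (greedy agglomeration under a Euclidean radius): clusters of materials
  with similar X-ray response are represented by *agents*, which shrink the
  triangle search space and make the per-pixel solves robust for
  near-collinear tissues.
* **Hausdorff-guided triangle re-selection**: when a pixel falls outside
  its initial triangle (the three nearest cluster agents), the replacement
  is the containing candidate most similar to it — similarity scored by the
  bi-directional Hausdorff distance between vertex sets, computed with a
  randomized early-break scan.
* **DLWFDW denoising**: a doubly local Wiener filter with directional
  windows in the wavelet domain, applied to each energy image first —
  essential, because soft tissues are nearly collinear in (μ_low, μ_high)
  and per-pixel fractions amplify noise.
* **Synthetic phantoms** with pixel-level ground truth (an angiography
  phantom with 12 contrast/KOH vials, a QA body/head phantom with plastic
  inserts and 1–3 mm air pinholes, and an abdominal slice), so the whole
  pipeline is testable without scanner data.

## Worked example

```python
from dectmmd import MaterialDecomposition, phantoms

spec = phantoms.make_angio_phantom()                  # 12-vial contrast phantom
pair = phantoms.render_dect(spec, phantoms.angio_render_library(),
                            noise_sigma_hu=(10, 10), seed=0)
model = MaterialDecomposition(pair, phantoms.angio_library())
res = model.fit()
print(res.summary())
iodine = res.fraction_image("iodine10")               # per-pixel fraction map
```

or from the shell:

```sh
dectmmd evaluate angio --noise 10,10 --seed 0
```

which prints (excerpt):

```
iodine_fit_r2                                 0.9984
iodine_fit_slope                              0.0981
koh_fit_r2                                    0.9999
noise_sigma_low_est                          10.3215
[vials]
  kind  concentration  true_mass_fraction  est_mass_fraction  accuracy_pct
iodine         1.0000              0.1007             0.1001       99.3687
iodine         5.0000              0.5020             0.4875       97.1229
   koh         5.0000              0.1000             0.1007       99.3419
   koh        50.0000              1.0000             1.0000      100.0000
```

Each vial's mass fraction of the reference dilution (iodine at 10 mg/ml,
KOH at 50% w/w) is read out by decomposing the vial-ROI mean attenuation;
`accuracy_pct = 100·(1 − |m̂ − m|/m)`. The concentration-series fit slope
0.0981 ≈ 1/(10 mg/ml) and R² > 0.99 show the estimated mass fraction is
linear in true concentration. The estimated noise level (≈10 HU) matches
the simulated noise.

CLI verbs: `simulate` (phantom → HU grids), `decompose` (two images →
fraction maps; DICOM/NIfTI/CSV/npy in, CSV/PNG/NIfTI out), `evaluate`
(phantom → metrics report), `demo` (all three experiments).

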