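# liverlsm

Semi-automatic segmentation of the liver and of liver tumors in 2D CT
slices, built around a *unified* level-set flow that combines edge
information (a geodesic edge indicator) with region information (a
signed-pressure balloon force derived from Chan–Vese region statistics).
The package is aimed at medical-image-analysis researchers who want a
tested, scriptable reference implementation of this family of
double-information active-contour methods, together with synthetic CT
phantoms that exercise their classical failure modes.

## The model

The contour is the zero level set of a field φ (object = {φ > 0}) evolved
by an explicit gradient flow with three terms:

```
∂φ/∂t = μ div(d_p(|∇φ|) ∇φ)  +  λ δ_ε(φ) div(g ∇φ/|∇φ|)  +  B δ_ε(φ)
```

* the first term is distance regularization with the double-well
  potential, which keeps |∇φ| ≈ 1 near the contour and lets a binary step
  function serve as the initial field;
* the second is the geodesic length term weighted by the edge indicator
  g = 1/(1 + |∇(G_σ ∗ I)|²) ∈ (0, 1], small at strong edges;
* B is the balloon force: **B = α·g·SPF** for the unified model, where
  SPF = (I − (c₁+c₂)/2)/max|·| ∈ [−1, 1] is the signed pressure force
  built from the mean intensities c₁, c₂ inside/outside the contour.
  The edge-only model uses B = α·g and the region-only model B = α·SPF.

**Liver pipeline** — a hybrid preprocessing chain (Perona–Malik
diffusion → scale-specific gradient magnitude → sigmoid contrast
conversion → binarization at (max+min)/θ) turns the slice into a binary
image on which seeded region growing (gray-level homogeneity |v − mean| <
W) trivially extracts the rough liver; the unified flow then refines it
and interior holes are filled.

**Tumor pipeline** — inside a user rectangle (ROI): a two-phase
local-intensity-clustering level set jointly estimates a multiplicative
bias field b (model I = b·J + n) and the phase partition; HMRF-EM
(Gaussian class likelihoods, Potts prior, ICM labeling, EM parameter
updates) refines the binary classification; an enhanced edge indicator
g_enhanced = max(g_binary, g) is built from it; and the unified flow,
initialized by a small rectangle inside the lesion, produces the final
mask.

**Evaluation** — volumetric overlap error (VOE, %), relative volume
difference (RVD, %, signed), and average / RMS / maximum symmetric
surface distance (ASD, RMSD, MSD, mm), plus challenge-style scoring:
100 points for a perfect measure, 75 points at the interobserver
references VOE 6.4%, RVD 4.7%, ASD 1.0 mm, RMSD 1.8 mm, MSD 19 mm,
linearly interpolated and clamped at 0.

## Worked example

```python
import liverlsm as L

# liver: phantom -> preprocess -> region growing -> unified refinement
img, truth = L.make_liver_phantom(L.PhantomSpec(noise_sigma=0.0))
mask = L.segment_liver(img, seeds=[(128, 116)])
report = L.evaluate_masks(mask, truth)
print(report.to_dict())
print(L.sliver_score(report).total)

# tumor: low-contrast lesion under a 30% bias field
roi_img, roi_truth, _ = L.make_tumor_phantom(L.TumorPhantomSpec(seed=5))
tumor = L.segment_tumor(roi_img, L.RoiRect(0, 0, 80, 80), L.RoiRect(26, 28, 54, 52))
print(L.dice_coefficient(tumor, roi_truth))
```

Output:

```
{'voe': 0.799, 'rvd': -0.799, 'asd': 0.375, 'rmsd': 0.612, 'msd': 1.0}
94.7
0.998
```

The liver mask overlaps the ground-truth envelope to within 0.8% VOE
(the negative RVD indicates a slight under-segmentation at the boundary
band); all five challenge scores are well above the 75-point
interobserver mark. The tumor branch recovers the lesion at Dice 0.998
despite the 0.1 contrast and the 30% multiplicative inhomogeneity.

The same pipelines are available from the shell:

```sh
liverlsm make-phantom --seed 7 --out-prefix phantom
liverlsm segment-liver phantom.png liver.png --seed-point 128,116
liverlsm evaluate --pred liver.png --ref phantom_truth.png --score
```

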