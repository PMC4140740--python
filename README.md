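# earmorph

Patient-specific ear reconstruction — whether by tissue-engineered scaffold
or carved framework — needs an image of the cartilage sheet inside the
auricle, not just the skin surface.  Clinical MRI plus manual contouring can
provide it, but only if the measurement chain is *precise* (different raters
obtain the same shape) and *accurate* (the MRI-resolution numbers agree with
a high-resolution reference).  `earmorph` implements that entire quantitative
chain for researchers evaluating such protocols: 3D morphometry of binary
cartilage masks, a contrast-enhanced micro-CT reference segmentation, the
precision and accuracy statistics, and a synthetic-phantom framework that
validates every step against known ground truth.

## What it computes

For a binary mask with voxel spacing `(sx, sy, sz)` in mm:

* **Cg.V** (mm³) — cartilage volume: foreground count × voxel volume.
* **Cg.S** (mm²) — surface area of the triangulated 0.5-isosurface
  (marching cubes after a one-voxel Gaussian pre-smooth).
* **Cg.Th** (mm) — model-independent mean thickness: per voxel, the
  diameter of the largest sphere containing it that fits inside the
  foreground (distance-transform based, on an isotropic grid).

Precision of repeated segmentations (n subjects × m raters) is summarized
by Glüer precision errors and the intraclass correlation ICC(A,1):

    PE_SD  = sqrt( (1/n) Σ_j SD_j² )          PE_%CV = 100·sqrt( (1/n) Σ_j CV_j² )
    ICC    = (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))

plus voxelwise pairwise Pearson correlation and overlap maps of rater pairs.
Accuracy across two measurement chains (MRI-resolution rater masks vs a
micro-CT chain: Gaussian filter σ = 1.2, support 1, attenuation threshold
0.9–2.2 cm⁻¹) is summarized by per-metric Pearson r with slope/intercept and
a 1-voxel (0.45 mm) thickness error band.

See `docs/methods.md` for the algorithms, defaults and their rationale.

## Worked example

Measure a phantom whose truth is known in closed form — a spherical shell of
inner radius 8 mm and wall 1.0 mm, rasterized at 0.1 mm (truth: V = 908.97 mm³,
S = 1822.12 mm², Th = 1.0 mm):

```python
from earmorph import PhantomSpec, make_phantom, morphometry_all

spec = PhantomSpec(shape="spherical_shell", thickness=1.0, inner_radius=8.0)
grid, truth = make_phantom(spec, spacing=(0.1, 0.1, 0.1))
res = morphometry_all(grid, "shell")
print(f"Cg.V = {res.cg_v:.2f} mm^3   Cg.S = {res.cg_s:.2f} mm^2   Cg.Th = {res.cg_th:.4f} mm")
```

```
Cg.V = 909.41 mm^3   Cg.S = 1826.80 mm^2   Cg.Th = 0.9731 mm
```

i.e. +0.05% on volume, +0.26% on surface, −2.7% on thickness relative to the
closed forms.  A full synthetic precision study (14 subjects × 3 simulated
raters at the clinical 0.45 × 0.45 × 0.40 mm grid) runs from the command
line:

```bash
earmorph precision --out-dir results/precision --seed 0
```

and writes `precision_report.json` with, per metric, the mean, PE_SD,
PE_%CV, degrees of freedom and ICC — reproducing the characteristic regime
of manual contouring: single-digit PE_%CV for all three metrics, high ICC
for volume and surface, collapsed ICC for mean thickness (because subjects
barely differ in mean thickness, not because the masks are poor — the
pairwise mask correlations stay high).  `earmorph accuracy` runs the
6-specimen two-modality comparison; `phantom`, `cohort`, `morpho` and
`segment-ct` expose the individual stages.

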