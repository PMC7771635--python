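# atriaquant

Automatic quantification of left-atrial (LA) fibrosis from paired magnetic
resonance volumes: a bright-blood angiographic channel that delineates the
endocardium, and a late-enhancement channel in which fibrotic wall retains
gadolinium and appears bright.

Atrial fibrosis burden — the fraction of the atrial wall showing
enhancement — predicts ablation outcome in atrial fibrillation, but manual
analysis takes an expert ~15 minutes per scan and differences of only 2-3
percentage points can move a patient between clinical strata.  `atriaquant`
implements a fully automatic pipeline: multilabel segmentation of the
chamber (blood pool, pulmonary veins + appendage, mitral valve), rigid
alignment of the two channels, and surface-based scoring of the enhancement
image, together with the evaluation statistics used to validate such
pipelines and a synthetic phantom generator that provides exact ground
truth for every stage.

## Method

For a mesh vertex $v$ on the endocardial surface (marching cubes on the
blood-pool segmentation), the wall intensity is the maximum-intensity
projection along the outward unit normal $\hat n_v$,

$$ I_v \;=\; \max_{t \in [-1\,\mathrm{mm},\; +3\,\mathrm{mm}]} \; L\!\left(x_v + t\,\hat n_v\right), $$

where $L$ is the (registered) enhancement image.  With $\mu, \sigma$ the
mean and SD of $L$ over the 3-voxel-eroded blood pool, the global burden is
the percentage of surface vertices above threshold under three published
rules:

* $I_v/\mu > 0.97$  (image intensity ratio, any fibrosis),
* $I_v/\mu > 1.61$  (dense scar),
* $I_v > \mu + 3.3\,\sigma$.

Vertices bounding the veins, appendage or valve are excluded from the
denominator.  Registration maximizes normalized mutual information
$\mathrm{NMI} = (H(A)+H(B))/H(A,B)$ over rotations and translations;
segmentation is a multilabel 2D U-Net (implemented in numpy) trained with a
balanced two-phase curriculum, or a geometric route (region growing,
medial-axis vein clipping at the ostia, three-point valve sphere) that also
generates training labels.  Agreement statistics include per-label overlap
(Dice, accuracy, sensitivity, specificity, precision), shape-measure errors,
Pearson/RMSE/Bland-Altman, and the one-way random-effects intraclass
correlation ICC(1,1) with F-distribution confidence bounds.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Score a synthetic phantom with 30% painted fibrosis, letting the pipeline
register the two channels and using the known labels:

```python
from atriaquant import PhantomSpec, generate_phantom
from atriaquant.pipeline import PipelineConfig, run_pipeline

spec = PhantomSpec(
    body_semiaxes=(18, 15, 12), wall_thickness=2.5, vein_radius=3.5,
    vein_length=14, mv_orifice_radius=8, grid_shape=(96, 96, 96),
    fibrosis_fraction=0.30, seed=21,
)
mra, lge, truth = generate_phantom(spec)
res = run_pipeline(PipelineConfig(labels_mode="provided"),
                   mra=mra, lge=lge, labels=truth.labels)
print(f"true burden     {100 * truth.true_burden:.1f}%")
print(f"burden (+3.3SD) {res.result.burden_sd33:.1f}%")
print(f"burden (IIR>0.97) {res.result.burden_iir097:.1f}%")
print(f"burden (IIR>1.61) {res.result.burden_iir161:.1f}%")
print("recovered offset", res.transform.translation.round(2),
      res.transform.rotation_deg.round(2))
```

Output:

```
true burden     30.0%
burden (+3.3SD) 28.5%
burden (IIR>0.97) 78.1%
burden (IIR>1.61) 28.4%
recovered offset [ 1.99 -2.96  1.51] [ 2.01 -0.87  1.61]
```

The +3.3 SD and dense-scar (IIR > 1.61) rules recover the painted 30%
within ~1.5 points; the IIR > 0.97 rule also counts every vertex whose
projected intensity reaches 97% of blood — on this phantom that includes
much of the healthy wall's partial-volume boundary with the blood pool,
illustrating why the three rules are reported separately.  The recovered
offset matches the phantom's built-in misalignment of (2, -3, 1.5) mm and
(2, -1, 1.5) degrees.

The same pipeline is available from a shell:

```bash
atriaquant phantom --seed 21 --fibrosis-fraction 0.3 --out work/
atriaquant run --mra work/mra.nii.gz --lge work/lge.nii.gz \
               --labels work/labels.nii.gz --out work/result/
```

which writes the surface mesh with per-vertex scalars (`surface.vtk`), the
transported labels, the transform, and a JSON report.

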