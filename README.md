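# glaucroi

ROI-based glaucoma detection from OCT texture enface images: dual
class-specific autoencoders, Markov-random-field segmentation of their
reconstruction-error maps, and a clustered, cross-validated diagnostic
evaluation — exercisable end to end on a built-in phantom generator.

## The problem

Diagnosing glaucoma in myopic eyes is hard: axial elongation tilts the
optic disc and thins the retinal nerve fibre layer (RNFL), so the standard
structural marker — global peripapillary RNFL thickness — loses
specificity.  An alternative is to read the *texture* of the tissue in a
70 µm slab under the inner limiting membrane (ILM), rendered frontally as
a texture enface map, and to look for localized glaucoma-like regions
rather than global averages, since early glaucomatous damage is focal
(arcuate bundle defects).

## The method

1. **Texture enface construction.** For each B-scan of an ONH raster
   volume, a difference-of-Gaussians band-pass isolates local granularity
   in the sub-ILM slab; the response is z-normalised over a 9×9 window and
   quantised into equal-frequency homogeneous bins (H-bins).  The enface
   value of an A-scan is the mean binned response over the slab depth.
2. **Dual autoencoders.** Two 5-layer dense autoencoders
   ([D, 256, 64, 256, D], tanh hidden layers, Glorot-uniform init, Adam,
   lr 10⁻³, batch 50, 150 epochs, MSE loss) are trained per
   cross-validation fold: one exclusively on healthy maps, one exclusively
   on glaucomatous maps.  Each map presented to both yields a per-pixel
   2-vector of squared reconstruction errors (e_H, e_G): the healthy model
   reconstructs healthy anatomy well and defects poorly, and vice versa.
3. **MRF segmentation.** The error-feature image is segmented into
   healthy-like / glaucoma-like regions by minimising a
   Gaussian-likelihood + Potts energy

   E(L) = Σ_p −log N(f_p | μ_{L_p}, Σ_{L_p}) + β Σ_{p∼q} 1[L_p ≠ L_q]

   with iterated conditional modes from the maximum-likelihood labelling.
   A degeneracy guard returns "no ROI" for eyes whose error image does not
   split into two separated components.
4. **ROI-Based Glaucoma Score.**

   GLS = 0.5 · ROI_size / Total_area + 0.5 · clamp(1 − Mean_ROI / Mean_Healthy, 0, 1)

   combining the extent of the glaucoma-like region with its intensity
   loss relative to the fold's healthy training reference.  Empty ROI ⇒ 0.
5. **Evaluation.** Patient-level stratified 5-fold cross-validation with
   horizontal-mirroring augmentation of the minority class; AUROC (rank
   formula), AUPRC (step integration), sensitivity at 80%/95% specificity;
   percentile CIs and Wald tests from a patient-cluster bootstrap; optional
   covariate-adjusted AUROC via placement values.  Baselines: negated
   annulus (2–6 mm) means of RNFL thickness and texture intensity.

Because no clinical scans are distributed, the package ships a phantom
generator (`glaucroi.synthetic`) producing manifests, texture enface maps,
RNFL thickness maps and layered OCT volumes with the statistical structure
the analysis assumes: arcuate-bundle anatomy, wedge-shaped angular defects
anchored at the disc margin, age-related intensity decline, intra-patient
correlation, and per-diagnosis axial-length distributions.

## Worked example

```python
from glaucroi.synthetic import PhantomConfig, generate_cohort
from glaucroi.evaluation import ExperimentConfig, run_experiment
from glaucroi.autoencoder import AEConfig
from glaucroi.mrf import MRFConfig

cohort = generate_cohort(PhantomConfig(
    n_patients_healthy=20, n_patients_glaucoma=20,
    map_height=32, map_width=32,
    defect_depth_range=(0.15, 0.35), seed=3,
))
config = ExperimentConfig(
    ae=AEConfig(input_size=(32, 32), epochs=60, seed=0),
    mrf=MRFConfig(), n_boot=200, seed=11,
)
report = run_experiment(cohort.records, cohort.enface, cohort.thickness, config)
print(report.metrics[["auroc", "auroc_ci_low", "auroc_ci_high", "auprc"]].round(3))
```

prints

```
                auroc  auroc_ci_low  auroc_ci_high  auprc
model
dual_ae         0.812         0.743          0.882  0.812
single_ae       0.812         0.743          0.882  0.812
rnfl_global     1.000         1.000          1.000  1.000
texture_global  0.740         0.583          0.882  0.787
```

Each row is one diagnostic model's pooled out-of-fold performance on the
64-eye phantom cohort: the two autoencoder-ROI models score eyes by GLS,
the two baselines by (negated) 2–6 mm annulus means.  With these shallow
defects (15–35% intensity loss) the ROI models detect most but not all
defect eyes; the RNFL baseline is perfect here because phantom thickness
maps are low-noise affine transforms of the same latent pattern.
`report.pairwise` carries the bootstrap Wald tests between models, e.g.
dual vs. RNFL delta AUROC −0.19, p < 10⁻³ on this small cohort.

The same experiment from a shell:

```bash
glaucroi simulate --config run.yaml --out cohort/
glaucroi evaluate --manifest cohort/manifest.csv --config run.yaml --out report/
```

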