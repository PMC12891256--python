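# gcfield

Structure–function analysis of widefield OCT ganglion cell–inner plexiform
layer (GCIPL) thickness maps against 24-2 visual fields, across the glaucoma
spectrum.

Clinicians judge glaucoma partly by *structure–function concordance*: does
retinal thinning on OCT co-localise with sensitivity loss on perimetry?
Widefield OCT protocols now image GCIPL thickness over essentially the whole
retinal area sampled by the 24-2 test grid, making that comparison possible
point by point. This package implements the full analysis chain for such
data, aimed at vision scientists and biostatisticians working with
structure–function datasets:

1. **Projection & sampling** — 24-2 test locations are projected onto the
   160×160 raster of 100 µm GCIPL squares (Goldmann III stimulus, 0.43°,
   plus a 0.5° microsaccade allowance; Bennett-style magnification
   `q = 0.01306·(AL − 1.82)` mm/deg; Henle-fibre displacement of the 16
   central locations).
2. **Ganglion-cell counts** — sampled GCIPL is converted to GCL thickness,
   `GCL = 0.5651·GCIPL − 0.9026` (µm), multiplied by co-localised volumetric
   GC density and stimulus area, and expressed in dB (10·log₁₀ cells).
3. **Segmented structure–function regression** — VF threshold *y* (dB) vs
   GC count *x* (dB): `y = β₀ + β₁x + β₂(x − ψ)₊` with breakpoint ψ
   (initial estimate 15.5 dB), stratified by diagnosis and by pointwise VF
   defect status (Hodapp–Parrish–Anderson rule: ≥3 contiguous points at
   p<5% with ≥1 at p<1% on the pattern-deviation probability map).
   Davies-style tests, nested F tests, MAE/RMSE.
4. **Normative deviation maps** — per-grid-square age/tilt-adjusted
   reference distributions; squares below the 5th residual percentile are
   flagged; a relative ("pattern-deviation"-style) map re-references each
   eye's deviation to its own 85th percentile.
5. **Hemi-cluster classification** — five GCIPL features per hemi-cluster
   (mean, SD, asymmetry, relative mean, relative asymmetry) condensed by
   PCA into logistic classifiers of hemi-cluster VF status, with backward
   elimination; the cascaded *PCA plus central* variant feeds each model the
   adjacent more-central prediction. The *percentile* method scores a
   hemi-cluster by its flagged proportion (VF defect criterion: ≥25% of the
   hemi-cluster's points defective).
6. **Evaluation** — ROC curves, AUC with DeLong variance, paired DeLong
   comparisons, Youden thresholds fixed on a ROC-construction ("ROCC")
   cohort and applied unchanged to the held-out test cohort,
   sensitivity/specificity with participant-clustered bootstrap CIs.

A first-class synthetic cohort generator (`gcfield.simulate`) produces
thickness maps, biometry and coupled visual fields with stored ground truth,
so the entire pipeline is testable and demonstrable without clinical data.

## Worked example

```python
from gcfield.pipeline import PipelineConfig, run_pipeline
from gcfield.simulate import GeneratorConfig

cfg = PipelineConfig(
    seed=1,
    generator=GeneratorConfig(n_healthy=60, n_suspect=20, n_glaucoma=60,
                              seed=1, n_reference_vf=40),
    n_reference_eyes=40, n_boot=100)
res = run_pipeline(cfg, out_dir="demo_run")
print(res.sf_table[["model", "n", "intercept", "slope1", "breakpoint",
                    "slope2", "mae_dB", "rmse_dB"]].round(2))
```

prints (seed 1):

```
                 model    n  intercept  slope1  breakpoint  slope2  mae_dB  rmse_dB
               healthy 2918      23.48    0.45       18.04    0.13    1.54     1.95
 suspect:non-defective  922      26.84    0.25       33.51   -2.21    1.71     2.46
     suspect:defective   68    4440.57 -283.31       15.61    0.54    5.09     6.56
glaucoma:non-defective 2390      27.20    0.24       33.13   -1.69    1.77     2.41
    glaucoma:defective  574     -11.37    1.90       15.25    0.47    5.72     6.96
                pooled 6872    -115.20    9.48       15.30    0.22    2.68     4.53
```

The healthy stratum recovers the generating forward model (intercept 24.26,
slope1 0.41, breakpoint 17.8 dB, slope2 0.14) from noisy observations, and
the defective strata show the characteristic error inflation (MAE ≈ 5–6 dB
vs ≈ 1.5–1.8 dB at non-defective locations) with essentially unidentified
breakpoints — their Davies p-values in `res.sf_table` are non-significant,
which is the intended reading of such fits. The classification report
(`res.report.auc_table`) gives per-hemi-cluster AUCs for the percentile, PCA
and cascaded methods; on this cohort the peripheral inferior ring shows the
signature pattern of plain PCA collapsing (AUC 0.50) while the cascade
restores discrimination (0.93). Youden operating points in
`res.report.operating_table` are derived on the ROCC cohort and carried
unchanged to the test cohort.

A CLI wraps the same stages:

```sh
gcfield simulate --seed 1 --out cohort_dir
gcfield run-all  --seed 1 --out run_dir [--stages vf,sf]
gcfield vf-classify cohort_dir/vf/H0000_0.csv
```

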