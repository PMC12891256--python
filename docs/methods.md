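# Methods

This note records the models, conventions and numerical choices behind
`gcfield`, and what the synthetic experiments do and do not establish.

## Coordinate conventions

Visual-field coordinates are right-eye-normalised: x positive temporal,
y positive superior *in field space*; left-eye records are mirrored in x on
read. The 24-2 grid has 54 locations on a 6° lattice (nasal extension at
−27°, blind spot at +15°, ±3°); 52 are analyzable. The retinal raster is
fovea-centred, 160×160 squares of 100 µm, row index increasing toward the
inferior retina; square centres sit at (i − 79.5)·0.1 mm. Because the
retinal image is inverted, field-to-retina projection flips both axes, so a
VF location's hemifield is opposite to the hemifield of its retinal
projection. Hemifield names on hemi-clusters follow the *visual-field*
convention.

## Projection and sampling

Angular distances convert to retinal millimetres with the linear
Bennett-style scale q = 0.01306·(AL − 1.82) mm/deg by default; a
tangential-plane model is available and any callable with the same
signature can be plugged in (the exact nonlinear correction used on real
instruments varies). Axial length is mandatory — no silent emmetropic
default.

Stimulus regions are ellipses of angular radius 0.43/2 + 0.5 = 0.715°,
i.e. the 0.5° microsaccade allowance is added to the stimulus *radius*;
this is one of two defensible readings (radius vs diameter) and is
configurable. Radii are converted at the local eccentricity by a symmetric
difference, which is exact for the linear model.

Henle-fibre displacement applies to the 16 central locations
(|x|, |y| ≤ 9°): the inner and outer radial margins are each displaced
outward by D(ecc) and the centre/radial radius recomputed. The shipped
displacement curve is a smooth unimodal stand-in (peak 0.37 mm at 0.8 mm,
smoothstep-tapered to zero at the 3.4 mm edge of the maximum displacement
zone), *not* a reproduction of any published fit; substitute a calibrated
curve for quantitative work near the fovea.

Sampling takes the mean of valid squares whose centres fall inside the
ellipse; coverage is the valid overlapped area over the region area.
Regions with zero valid overlap yield a missing value, never zero, and the
pipeline excludes observations with coverage < 0.5 (peripheral nasal
locations genuinely fall off the scanned raster in long eyes).

## Ganglion-cell counts

GCL = max(0, 0.5651·GCIPL − 0.9026) µm; the clamp handles the conversion's
negative intercept at near-zero thickness, since a negative layer thickness
is meaningless. Counts are GCL(mm) × ellipse area (mm²) × mean volumetric
density (cells/mm³), reported in dB re 1 cell. Counts below one cell are
floored at 0 dB and flagged; floored points are excluded from regressions by
default (configurable). The default density field is an analytic synthetic
stand-in (ridge peaking at 6×10⁵ cells/mm³ near 1 mm eccentricity, decaying
to ~1.2×10⁴ peripherally, magnitudes loosely informed by histology); real
analyses should supply a histology-derived raster.

## Segmented regression

The model is y = β₀ + β₁x + β₂(x − ψ)₊, continuous at ψ; "slope2" is always
reported as the total right-hand slope β₁ + β₂. ψ is estimated by Muggeo
iterative linearisation (start 15.5 dB plus deterministic quantile
restarts, tolerance 1e-10, 100 iterations) backed by an exact global
safeguard: between consecutive observed x values the profile SSR is a
rational function of ψ with a closed-form stationary point, so scanning all
admissible intervals (thinned to 800 for very large n) finds the global
optimum; the reported fit is the better of the two. ψ is constrained to
keep at least ~n/20 (clipped to 3–10) observations on each side — without
this, weak-signal strata produce degenerate edge fits with absurd
extrapolated intercepts. A 0.01 dB grid search remains available as
`grid_search_breakpoint`.

The Davies-style test computes the slope-change Wald statistic at K = 10
breakpoints evenly spaced between the 10th and 90th x-percentiles, maps each
through its exact t null to a normal score, and by default evaluates the
p-value of the maximum against the exact joint-Gaussian null (design-implied
correlation; deterministic Sobol quasi-Monte Carlo with 2¹³ points, with a
Bonferroni floor beyond QMC resolution). Davies' analytic upper bound is
available as `method="davies-bound"`; it is conservative (measured type-I
error ≈ 0.034 at α = 0.05 vs ≈ 0.046 for the default), which is why the
joint-normal reference is the default.

Stratified fits use the five cells healthy, suspect×{defect, no-defect},
glaucoma×{defect, no-defect}; nested comparisons use the
extra-sum-of-squares F with 4 parameters per segmented fit.

## Normative model and deviation maps

Per grid square, thickness ~ age + tilt is fitted by least squares across
reference eyes (a linear-adjustment reading of "matching for age and tilt";
an explicit matching scheme would need far larger references) and the
empirical residuals are stored. A square is flagged when its deviation
falls strictly below the type-7 (linearly interpolated) 5% residual
quantile. Squares with fewer than 20 references are masked from flags and
proportions. The relative map subtracts the 85th percentile of the eye's
own total deviation over *all* of its valid squares; by construction at
most 15% of valid squares are positive, up to one rank unit of
quantile-interpolation slack.

## Hemi-cluster features and classifiers

The shipped cluster template is a schematic synthetic default: each
hemifield's 26 analyzable locations are ranked by eccentricity and split
2/4/7/9/4 into groups named 6-8 (central) through 1 (peripheral); grid
squares take the hemi-cluster of the nearest projected location within the
matching retinal hemifield. True cluster boundaries from normative-database
work are not reproduced; every analysis accepts a user-supplied labelled
raster + JSON legend.

Backward elimination interprets "repeat until all parameters are
significant" as Wald tests (α = 0.05) on the standardised raw parameters in
a multiple logistic fit, applied before PCA — significance of a raw
parameter inside a PC regression is not well defined. PCA is an
eigendecomposition of the correlation matrix of the survivors;
eigenvalue > 1 components are retained (minimum one), with the
largest-loading-positive sign convention. Logistic fits fall back to
Firth's Jeffreys-prior penalised likelihood on separation or
non-convergence (common on strongly separable synthetic data); the model
records when that happened. The cascade trains central → peripheral per
hemifield, offering each model the adjacent more-central model's predicted
*probability* (information-preserving; a hard-class variant is available)
as one more candidate parameter under the same elimination.

The percentile method's score is the flagged proportion itself — no fitted
model — mirroring how such proportions are used clinically.

## Evaluation

AUC is tie-corrected Mann–Whitney concordance; its SE and paired
comparisons come from DeLong structural components. Youden thresholds
break ties toward higher specificity (screening context); "score ≥
threshold" predicts defective for proportions and probabilities alike.
Thresholds are derived on the ROCC cohort only and applied unchanged
elsewhere; the report records this structurally. Sensitivity/specificity
CIs default to a participant-level nonparametric bootstrap (2000 reps,
percentile) because hemi-clusters within an eye are correlated; Wilson
intervals are the independent-data fallback, and the method used is
recorded per row. α = 0.05 two-sided throughout, no multiplicity
adjustment across hemi-clusters.

## Synthetic cohort

Healthy GCIPL is a radial surface 45 + 55·u²·e^{2(1−u)} µm (u = ecc/1.2 mm:
~45 µm at the fovea and far periphery, ~100 µm ridge), plus a per-eye
offset (SD 6 µm), an age effect of −0.1 µm/yr about age 55, a tilt-scaled
vertical gradient (0.2 µm/deg at the map edge) and i.i.d. 2 µm measurement
noise, masked to an elliptical ~55°×45° scan area. Defects are arcuate
wedges, hemifield losses or paracentral discs in retinal coordinates with
smooth margins, clipped at a 30 µm non-neural floor, strictly respecting
the horizontal midline. Each eye's noiseless thickness is a continuous
function of position, so ground-truth counts exist even where the
projection leaves the raster.

Visual fields are generated by state-dependent segmented forward models of
the eye's own noiseless counts. Defaults take the pooled non-defective
(24.26, 0.41, 17.8, 0.14) and defective (10.85, 0.51, 17.31, 1.00)
parameter sets with noise SD 2 dB (non-defective) and 9 dB (defective),
reproducing the characteristic error contrast between states. A location
is in the defective state when ≥50% of its stimulus region lies inside the
defect mask. TD/PD values and their probability categories are referenced
to an internally simulated healthy ensemble (150 eyes by default),
mirroring how perimeters derive normative limits: PD subtracts the 85th
percentile of the eye's own TD; MD is the mean TD and PSD its RMS about MD
(simplified, unweighted). Cohort sizes default to 311/268/269
(healthy/suspect/glaucoma); the ROCC cohort is ~38% of healthy eyes plus
about half of the perimetric glaucoma eyes.

`high_coupling_config` defines the low-noise, high-coupling condition used
to probe the classification ceiling: small noise everywhere, deep defects
whose inner edge sits inside the central zone (so central features and
central VF status cannot be decoupled by geometry straddling the
Henle-displaced sampling annulus), no paracentral pattern, a defective
forward model well below the healthy one at every count, and an eccentric
depth taper — the structural signature fades peripherally while the defect
extent (hence VF status) persists, which is exactly the regime where the
cascaded classifier should outperform plain PCA on peripheral rings.

What the synthetic data do not emulate: OCT speckle and segmentation
failure patterns, blood-vessel artefacts, disease-related changes in GC
density or soma size, perimetric response variability beyond Gaussian
noise, temporal raphe asymmetries, and the true spatial covariance of
human GCIPL thickness. Passing tests therefore establish internal
consistency, calibration and recoverability of the pipeline — not clinical
performance on real cohorts.

## Problem sizes

Tests and the acceptance script run deliberately scaled-down experiments
chosen to make their Monte-Carlo tolerances meaningful: 1,000 random
probability maps for the defect-rule oracle; 50 datasets of n = 200 (σ = 2
dB) for the breakpoint-vs-grid comparison and one noiseless n = 300
recovery; 1,000 pure-linear simulations (n = 100) for Davies calibration;
200 reference + 300 held-out eyes for normative calibration (the flag-rate
tolerance is eye-clustered — 3 SE of the per-eye rates plus 0.005
finite-reference allowance — because within-eye flags share the eye's
thickness offset); a 10,000-rep bootstrap against the DeLong variance on
one 200-case instance; a 300-eye high-coupling cohort for the end-to-end
run; and a 300-eye noiseless cohort for forward-model recovery.

## Known limitations

The Henle displacement curve, density field and cluster template are
synthetic stand-ins (each labelled as such); the magnification model is
linear by default; MD/PSD are unweighted simplifications; the Ying-style
clustered confidence machinery is approximated by a participant bootstrap;
and the severity staging uses MD bands (−6, −12 dB) plus defect presence as
a stand-in for full clinical staging criteria.
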