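# Methods

## Stimulus model

The stimulator is modelled as four narrow-band primaries (red 660, green
558, cyan 516, blue 460 nm) with Gaussian emission spectra of 9 nm FWHM —
interference-filtered LEDs are well approximated this way, and measured
spectra can be substituted from two-column CSVs.  Photoreceptor
fundamentals are generated from the Govardovskii A1 visual-pigment template
(alpha and beta bands; pigment maxima L 559, M 530, S 419, rod 493 nm)
multiplied by the transmission of two prereceptoral filters: an ageing-lens
density template (exponential in wavelength, ~1.8 density at 400 nm) and a
macular-pigment template (Gaussian at 460 nm, peak density 0.35; not
applied to rods, which sit outside the macula).  The resulting corneal
peaks (565/540/438/507 nm) agree with conventional 10° fundamentals and the
scotopic luminosity function to a few nanometres, which is ample: none of
the package's quantitative claims depends on the fundamental tables beyond
their qualitative shape and overlap.  Both filter densities carry scalar
scales; individual deviation from the standard observer is modelled as a
change of these scales and quantified by `isolation_error`.

CIE 1931 colour-matching functions use the Wyman–Sloan–Shirley multi-lobe
piecewise-Gaussian fit (sub-1% of peak).  The background solver fixes a
target chromaticity (default x = 0.38, y = 0.28) and retinal illuminance
(289 photopic Td through a 3-mm artificial pupil) and resolves the fourth
degree of freedom by maximizing the smallest primary intensity — keeping
all channels lit gives the most balanced operating point.  Device ceilings
default to twice the background (operating point at half max), so each
primary has unit Michelson headroom.  With these defaults the
gamut-limited maximum contrasts are ≈0.34 (L), 0.29 (M), 0.32 (rod) and
0.87 (S): the S-cone asymmetry is structural (the blue primary drives S
almost exclusively) and is the quantity reported by
`scripts/acceptance.py`.

Numerical choices: wavelength grid 390–780 nm at 1 nm, linear interpolation
with zero extrapolation; trapezoid integration; "silent" means residual
untargeted receptor contrast below 1e-10 at solve time (physiological
residuals under observer deviation are reported separately by
`isolation_error`); the A-matrix is rejected above condition number 1e8.

## Normative model and defects

Defects are measured sensitivity minus an age-correlated norm.  The norm is
a per-receptor, per-frequency intercept at a reference age of 40 years plus
a linear ageing slope (−0.3 dB/decade L/M, −0.4 S, −0.5 rods) — a
configurable stand-in with plausible healthy tCS shapes (low-pass for L/M,
low absolute S-cone sensitivity, band-pass rod curve peaking near 8–10 Hz).
The cohort generator uses the same model, so simulated defects are exactly
defined; with real data the coefficients should be replaced via YAML.  The
validity window is 18–90 years.

MD features are plain band means of per-frequency defects: L/M low band
{1,2,4,6} Hz, L/M high band {8,10,12,20} Hz (the literal protocol set; 16 Hz
is measured but not band-averaged by default — membership is configurable),
S band {1,2,4,6} Hz, rod band {6,8,10,12} Hz.  RMD averages *defects*, like
every other feature (the alternative reading — averaging raw sensitivities —
would put RMD on a different scale than the other five features and break
the shared-unit premise of unscaled clustering).  Missing frequencies drop
out of the band mean; censored thresholds enter at the conservative
floor value and are counted per feature.  Aggregation is a two-stage mean:
sessions within an eye, then across eyes.  Patients with a fully missing
feature are dropped by default (cohort-mean imputation is available).

## Synthetic cohort

The generator emulates the study conditions: four diagnostic groups with
sizes 9 (normal), 16 (RP), 14 (STGD), 11 (OMD); ages truncated-normal per
group (means 35–52 years); band-level defects drawn from a multivariate
normal per group with a shared correlation structure (L/M defects within a
band nearly collinear, low/high bands within a cone class strongly
correlated, S and rod losses moderately coupled).  Band defects are
expanded to the nine frequencies as band constants plus mean-centred 0.3 dB
within-band jitter.  Optional two-component mixtures model the clinically
observed bimodal subgroups (an RP subset with deep red–green loss; an OMD
subset with dichromat-like LMD_low below −10 dB); they are exercised by the
`bimodal_templates()` preset and are off in the default templates, which
describe the baseline unimodal conditions.

Default template means (dB; LMD_low, LMD_high, MMD_low, MMD_high, SMD, RMD):

| group  | means | sds |
|--------|-------|-----|
| normal | +1.2, +0.8, +1.2, +0.8, +0.5, +1.2 | 0.5, 0.5, 0.5, 0.5, 0.6, 0.35 |
| RP     | −2.4, −1.9, −2.4, −1.9, −5.4, −4.1 | 0.8, 0.75, 0.8, 0.75, 1.25, 1.0 |
| STGD   | −4.1, −3.5, −4.1, −3.5, −2.3, −2.1 | 0.7, 0.7, 0.7, 0.7, 1.0, 0.75 |
| OMD    | −8.0, −4.5, −8.0, −4.5, −2.9, +1.2 | 1.2, 1.0, 1.2, 1.0, 1.0, 0.35 |

The design rationale: every patient group loses L/M-driven sensitivity;
rod loss is severe in RP, moderate in STGD and absent in OMD; S-cone loss
is deepest in RP; low-frequency L/M loss (red–green discrimination) is
deepest in OMD.  Normal means are small *positive* offsets rather than
exactly zero: study controls measured on one rig typically sit slightly
above an externally derived ageing norm, and the planted decision
boundaries (good vs poor rod function near RMD ≈ 0 dB, STGD vs RP near
SMD ≈ −3.9 dB, OMD vs normal on LMD_low) are only well-posed if the
control distribution lies above the rod cutoff.  Group separations were
calibrated jointly so that the planted structure is recoverable by both
analyses at study scale: the good/poor-rod contrast is the only clean
two-vs-two split (Gini favours peeling the largest single class, so the
S-cone RP contrast must stay partially overlapped with STGD at the cohort
level while remaining the dominant discriminator *within* the poor-rod
subset), and the four groups form blobs separated enough for a k = 4
complete-linkage cut.  These template values are configuration, not
constants.

The staircase simulator runs two randomly interleaved 1-up/1-down tracks on
log contrast (starts: device maximum and effectively zero), step sizes
halving from 4 dB to 1 dB at reversals, eight reversals or 80 trials per
track, against a logistic psychometric observer (default slope 8, lapse
0.02); the estimate is the geometric mean of the late reversals of both
tracks.  Estimates at the device maximum are censored and reported at the
maximum (the floor rule).  The estimator is approximately unbiased for
in-range thresholds (<5% at steep slope) — the exact adaptive procedure of
a real device need not match trial-for-trial, only these two properties
matter downstream.  A fast `method="ideal"` path replaces the staircase by
unbiased Gaussian dB noise (0.5 dB) plus the same floor rule, for large
simulation studies.

What the generator does **not** emulate: fixation instability, eccentric
fixation, media opacities, spatial topography of damage within the test
annulus, learning/fatigue across sessions, or any relationship between
visual acuity and tCS.  Passing recovery tests therefore shows the
analysis chain is correct and well-calibrated for data of this structure —
not that real cohorts will separate this cleanly; the real-data accuracies
(66% supervised, 50% unsupervised) are far below the synthetic ones
because real phenotypes overlap more than these templates.

## Supervised analysis (CART)

Gini-impurity recursive partitioning; a node splits only with ≥ `minsplit`
(default 5) observations and positive impurity; thresholds are midpoints of
adjacent sorted unique values; ties break to the lowest feature index, then
the smallest threshold, making fits deterministic and row-order invariant.
`feature < threshold` routes left.  Pruning is weakest-link
cost-complexity on resubstitution misclassification scaled by the root
risk; links with `g < cp` (default cp = 0.1) collapse iteratively, so
cp = 0 is the identity and large cp yields the majority-class stump.
No surrogate splits, case weights, or cross-validated cp selection: with
cp fixed a priori they are unnecessary.  Accuracy CIs are exact
Clopper–Pearson (Wilson available); the printed intervals for 33/50, 25/50
and 43/50 correct match the exact method after rounding.

## Unsupervised analysis

Complete-linkage agglomeration on raw Euclidean distances in the 6-D MD
space.  No feature scaling by default: the six features share units (dB)
and magnitude (a `scale` flag exists for sensitivity analysis).  Merge
heights are monotone under complete linkage; cutting at k undoes the last
k−1 merges, cutting at height h keeps merges with height ≤ h.  Cluster
stability: B = 100 bootstrap resamples (resample with replacement,
recluster, cut at k); each original cluster records its best Jaccard
overlap with any bootstrap cluster, computed on the original points present
in the resample; means above 0.6 count as stable.  Modal-diagnosis ties
break alphabetically.

## Problem sizes

Recovery studies use cohorts of n = 200 (group sizes scaled 36/64/56/44)
over 100 seeds with the fast measurement path, B = 100 bootstrap resamples
(50 in the study-scale test fixture), and 1000 null simulations for the
Kruskal–Wallis calibration check — sizes chosen so the whole suite runs in
a couple of minutes while keeping Monte-Carlo error well below the asserted
margins.

## Known limitations

* The normative coefficients and fundamental tables are plausible defaults,
  not fitted to any published normative data set; replace them for real use.
* The lens/macular density templates are single-parameter families; real
  prereceptoral variation is richer.
* The staircase model is a generic transformed up-down procedure, not a
  reimplementation of any specific device firmware.
* Height-based dendrogram cuts are scale-specific; on synthetic cohorts
  only k-based cuts are meaningful.
* Melanopsin/ipRGC control is out of scope (no fifth primary in the device
  model).
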