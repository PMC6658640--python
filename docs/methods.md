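# Methods

## Problem

The Deauville score (DS) grades lymphoma therapy response on a 5-point
ordinal scale by comparing the hottest lesion's FDG uptake to two
physiological references: the mediastinal blood pool (DS 2/3 boundary)
and the liver (DS 3/4 boundary), with DS 5 defined here as uptake above
2x the liver maximum. Because SUV quantification depends on the
reconstruction algorithm's effective resolution, the same examination
can receive different scores under different reconstruction settings.
petharmony implements the full analysis chain — uptake quantification,
scoring, and paired ordinal statistics — together with a digital-phantom
simulator so the chain can be exercised and validated without patient
data.

## Reconstruction-setting model

A setting (`ReconProfile`) is reduced to four effective properties:
isotropic PSF FWHM (mm), background noise coefficient of variation,
output matrix/pixel size, and slice thickness. Simulation is

1. Gaussian blur of the ground-truth uptake map with the profile's FWHM
   (on the fine truth grid, zero-padded borders);
2. linear resampling onto the profile's output grid;
3. additive zero-mean Gaussian noise with per-voxel standard deviation
   `noise_cv * signal`.

Sinogram-level physics (attenuation, scatter, Poisson counting,
iterative reconstruction) is not modeled. Consequences: noise here is
spatially uncorrelated and strictly signal-proportional, whereas real
reconstructed PET noise is correlated and count-limited; and a BSREM
reconstruction is represented only by an *effective* FWHM. Passing tests
therefore demonstrate that the analysis chain responds correctly to
resolution and noise differences, not that the simulator reproduces any
scanner's image statistics. Count-statistics effects (e.g. acquisition
time) are deliberately out of scope.

The three default settings: `earl_lower` (OSEM-like, 7 mm FWHM, 192
matrix at 3.64 mm), `earl_upper` (5 mm FWHM, same grid), `qclear`
(BSREM-like, 256 matrix at 2.73 mm). Slice thickness is 2.79 mm for
all. BSREM is nonlinear and has no literal post-filter FWHM; we assign
it an effective 4 mm because the harmonization question only requires
that it resolve small lesions better than the 5 mm EARL upper bound,
and 4 mm is a conservative choice for a modern SiPM system. It is
config-exposed. Default noise CV is 10% for all three settings.

## Phantoms

Ground truth is rasterized at 1 mm isotropic (>= 2.7x finer than every
output grid) from shape primitives (ellipsoid, cylinder, sphere) with
uniform uptake; a voxel takes the uptake of the innermost shape
containing its center. The anthropomorphic cohort phantom is a compact
150 x 110 x 100 mm torso section: a liver ellipsoid (70 x 60 x 56 mm), a
32 mm thoracic-aorta cylinder (caliber chosen so a 3-voxel box erosion
on the 2.73 mm grid leaves a non-empty core), and one focal lesion.
The NEMA IQ preset places the six standard spheres (10/13/17/22/28/37 mm)
on a 114.4 mm ring inside a torso-shaped compartment; its large field of
view makes a 2 mm truth grid the default (1 mm available when needed).

Cohort defaults emulate a 54-examination lymphoma cohort: liver true
uptake 2.2 +/- 0.3 SUV, blood pool 1.7 +/- 0.2 (both truncated at 0.5 and
chosen, in the absence of published reference-organ values, near typical
clinical liver/mediastinum SUVmax ranges so that lesion contrasts of
0.5-4x liver straddle every DS boundary); lesion diameter uniform in
10-40 mm, lesion uptake uniform in 1.1-8.8 SUV; body weight 79 +/- 16 kg
with 4 MBq/kg injected and ~62 min uptake time. Per-study randomness
uses `SeedSequence(seed, spawn_key=(study_index,))` so growing the
cohort never reshuffles earlier studies.

## Measurement procedure

All volumes are resampled (linear) onto the sharpest setting's grid —
mirroring the protocol of regridding the EARL reconstructions to the
sharp reconstruction's pixel size — masks follow by nearest-neighbor,
and liver/blood-pool masks are eroded by 3 voxels per axis (box
erosion; reach 3 x spacing = 8.2 x 8.2 x 8.4 mm on the 2.73/2.79 mm
grid) to avoid organ edges and vessel walls. Lesion masks are never
eroded: they are drawn to include the lesion maximum. "Eroded by 3
voxels in all directions" is read as a per-direction reach of 3 voxels
(a (2k+1)^3 box neighborhood test), the only reading consistent with
the 8.2 x 8.2 x 8.4 mm kernel.

SUV uses body-weight normalization with the injected activity decay-
corrected (F-18 half-life 109.77 min) from injection to a single
acquisition time point. SUVmax is the hottest masked voxel. SUVpeak is
the maximum 1 mL spherical mean (radius 6.2 mm over voxel centers) over
candidates centered in the mask; there is no universal SUVpeak
standard, so the sphere volume and the center constraint are
config-exposed. The sphere may extend beyond the mask but not beyond
the volume (candidates too close to the border are skipped; if none
remain the peak is flagged undefined), and the reported peak is capped
at the region SUVmax so the (peak, max) pair is always coherent even
when the sphere spills onto hotter neighbors. Like-for-like metrics are
compared throughout (lesion SUVmax vs organ SUVmax, and likewise for
SUVpeak, with identically eroded organ masks for both).

Recovery coefficients on the NEMA preset are `rc_max` (hottest
reconstructed voxel in the true sphere mask / true uptake) and
`rc_mean`; accreditation limit bands are user-supplied configuration,
not claimed values.

## Scoring rules

First-match with inclusive lower boundaries: lesion L, mediastinum M,
liver H; L <= M -> DS 2, L <= H -> DS 3, L <= mult*H -> DS 4 (mult = 2
by default, 3 supported), else DS 5. Equality resolves to the lower
score ("not above reference"). DS 1 requires an explicit
no-measurable-lesion input, since any measured lesion is compared
against M. When M > H (observed clinically and in noisy simulations) no
guideline exists; the first-match order still applies — a lesion with
H < L <= M scores DS 2 — and the result carries a
`mediastinum_exceeds_liver` warning. Responders are DS 1-3 by default
(boundary configurable).

## Statistics

- Cross-tabulations, discordance (off-diagonal count and fraction,
  percentages rounded to one decimal) and major discordance (pairs
  crossing the responder boundary).
- Wilcoxon signed-rank on paired scores: zeros dropped, midranks on
  |d|, W+ = sum of positive ranks,
  `z = (W+ - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24 - sum(t^3 - t)/48)`,
  two-sided normal p, **no continuity correction**. This convention is
  chosen because it reproduces published SPSS-style values for heavily
  tied ordinal differences (a continuity-corrected variant gives ~0.13
  instead of 0.102 on the embedded panel C); tests verify the null
  moments against exact sign-flip enumeration (n <= 12). The normal
  approximation is poor below n ~ 10 with heavy ties (exact two-sided p
  for panel C's pattern is 0.219 vs asymptotic 0.102); the package
  reports the asymptotic convention deliberately, for comparability.
- Friedman test across k = 3 settings with the tie-corrected chi-square
  approximation (df = 2), delegated to scipy and verified against a
  textbook-formula oracle and exact permutation enumeration at n = 10.
  Rows with any missing setting are excluded listwise.
- Bonferroni: alpha/m rounded to 4 decimals for reporting (0.05/3 ->
  0.0167).

The embedded fixture module ships the six published 4x4 cross-
tabulations. Everything derivable from them (discordance, major
discordance, pairwise Wilcoxon) is recomputed at run time; the
published three-setting Friedman p-values are **not recomputable** from
pairwise tables, because the per-study joint triples cannot be
recovered, and the validation report states this explicitly.

## Problem sizes and numerical choices

Test and acceptance runs use 54-study cohorts (up to ten seeds pooled)
at the default 1 mm truth grid; oracle comparisons use single-sphere
phantoms on odd-dimension 1 mm grids so a voxel center coincides with
the sphere center (the closed-form blurred-sphere center value
`B + (A-B)[erf(R/(sigma sqrt2)) - sqrt(2/pi)(R/sigma)e^(-R^2/2sigma^2)]`
then agrees within 1%). Regridding clamps to edge values so constants
stay constant; total activity is conserved by the blur exactly for
compactly supported sources and to <= 0.5% after resampling. Erosion
treats the volume border as outside the mask. Masks eroded to empty are
flagged, not errored, and the affected setting/role carries no value.

## Known limitations

No DICOM ingestion, no oblique orientation matrices, no lesion
auto-segmentation, no metabolic tumor volume metrics, no longitudinal
("new lesion") DS 5 rule, no survival analysis. The simulator's noise
and resolution model is an abstraction; see above for what that implies
about transferring synthetic results to scanner data.
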