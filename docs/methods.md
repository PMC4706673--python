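# Methods

This note documents the models, parameter choices and numerical
conventions behind `collagenkit`, and what the synthetic-data generators
do and do not emulate.

## Histology segmentation

Segmentation is purely per-pixel in hue/saturation/brightness space
(standard hexcone RGB→HSV conversion). Slide background is defined as
saturation < 0.08 **and** brightness > 0.9 (configurable): bare glass is
bright and colourless, and scanners in practice only capture tissue-bearing
regions, so the cut is deliberately conservative. Among tissue pixels the
rule is ordinal — epithelium occupies the lowest brightness and hue,
adipose the highest, stroma the middle — and the two brightness cuts are
found by three-class Otsu (variance-minimising) thresholding of the tissue
brightness histogram. The hue channel is cut the same way and arbitrates
via a 2:1 brightness:hue weighted vote, so a pixel whose two channels
disagree moves only when hue disagrees strongly. A near-constant channel is
treated as neutral (all pixels in its middle class). No morphological
cleanup is applied by default (`min_object_px` enables optional
small-object removal) because the rule is defined per pixel.

The PSR birefringence positivity threshold (default 0.15 of full scale on
the polarised-image intensity) and the Masson blue-green hue band
([0.33, 0.72] with saturation ≥ 0.2) are package conventions: the
literature treats both stains semiquantitatively and no standard numeric
cut exists. Both are exposed as arguments.

The peri-ductal band is the Euclidean-distance annulus (0, w] around a
supplied duct mask (default w = 20 µm), computed by distance transform;
duct interiors are excluded and multiple ducts union naturally. Duct masks
are inputs — automatic duct detection is out of scope.

## Structure-tensor orientation and coherency

Gradients are centred finite differences after Gaussian pre-smoothing at
`sigma_grad` (default 1 px); the tensor is windowed at `sigma_window`
(default 4 px); boundary handling is edge replication throughout. Reported
orientation θ ∈ (−90°, 90°] is that of *structures* (the eigenvector of
the smaller eigenvalue, i.e. ridge direction), measured from the image
x-axis with y up, matching the convention of the widely used orientation
plugins. Coherency is (λ₁−λ₂)/(λ₁+λ₂), clipped into [0, 1] against
rounding; where the tensor trace is zero (constant image) the orientation
is undefined and masked. `mean_coherency` excludes pixels at or below the
10 % energy quantile of the ROI so structureless background does not
dilute the estimate.

Published coherency values for this assay are printed with a "%" symbol
(0.38 % ± 0.11 vs 0.21 % ± 0.11); the magnitudes only make sense as
unitless coherencies in [0, 1], so the package treats the symbol as
typographic and never rescales.

## Synthetic fibre images and the coherency calibration

Fibre images are sums of anti-aliased Gaussian-profile ridges (default
1500 fibres of width 1.0 px on a 256² field, amplitude jitter, additive
Gaussian pixel noise of SD 0.02). Orientations follow an axial
wrapped-normal distribution; the mapping from the requested mean coherency
to the wrapped-normal spread is a lookup table built once by pilot
simulation (10 seeds per spread value at the generator defaults) and
frozen in the source. The calibration is defined at `sigma_grad = 1`,
`sigma_window = 8`, energy gate 0.1 (`FIBRE_CALIBRATION`): the mean
coherency of a dense crossing texture has a floor set by the ratio of the
analysis window to the texture correlation length, and at the 4 px default
window that floor (~0.26) sits above the low end of the physiological
range, whereas an 8 px window resolves the full 0.2–1.0 span. Targets of
1 give strictly parallel fibres; targets at or below the isotropic floor
give uniformly random orientations. Recovery accuracy is about ±0.05
(seed-to-seed SD ≤ 0.03 across the range).

## Synthetic height maps and D-band analysis

Fibrils are long Gaussian-profile ridges (width 150 nm, height 25 nm)
whose height is modulated sinusoidally along the fibril axis (banding
depth 0.3) at the requested period; overlapping fibrils composite by
maximum, as topography of stacked fibrils does, plus 1 nm Gaussian height
noise. The `tendon` preset uses aligned fibrils (1.5° jitter) banded at
66 nm; `gel` uses uniformly random orientations. Default scans are 512²
at 9.76 nm spacing (a 5 µm field). Generation rejects periods below four
pixel spacings (sampling margin).

Spectra are computed after least-squares plane detrending (raw AFM maps
carry scanner tilt) and 2-D Hann windowing; non-square maps are
zero-padded square. Radial power is binned at the fundamental 1/scan_size;
the D-band peak is the in-band argmax refined by parabolic interpolation
of log-power (bin quantisation alone is ~2 nm at 66 nm on a 5 µm scan,
worse on smaller fields). The 40–100 nm search band brackets the collagen
D-period while excluding the fibril-diameter peak (~150 nm). Peak
prominence (peak / median in-band power) below 2 flags a low-confidence
detection. The banding period is a property of the structure, so the same
peak appears in height or amplitude channels; the package operates on
height maps. Angular anisotropy is the resultant length of the
power-weighted doubled-angle distribution over the period annulus: 0 for
a diffuse ring, →1 for the discrete spot pair of parallel fibrils.

Recovered periods on the tendon preset run ~65.4–65.8 nm across seeds:
the ~0.5 nm downward bias relative to the planted 66 nm comes from
windowing and the asymmetric spectral background and is well inside the
±2 nm acceptance used throughout.

## Force curves and Hertz fitting

Units are nm for z and deflection, N/m for the spring constant (so force
k·d is in nN), µm for tip radius and kPa for moduli. The baseline is a
straight line fitted to the first 30 % of samples (the far-from-surface
end) and subtracted. Contact is found by exhaustive search over sample
indices of the two-part model (zero deflection before contact, through-
origin F ∝ δ^{3/2} after), scored by total squared residual, then refined
continuously between neighbouring samples — the refinement removes grid
quantisation so noiseless curves invert essentially exactly. A coarse
stride (`coarse_step`) with local re-scan accelerates long curves. If no
split beats the flat-only model the curve is flagged "no contact".

The modulus solver is the closed-form least-squares slope of F against
δ^{3/2} through the origin, using only post-contact samples with force at
most 70 % of the curve peak (`fit_fraction`, the instrument-software
convention for "maximum force fit"): restricting to shallower contact
keeps the fit inside the Hertzian half-space regime. Reduced modulus is
reported directly, without Poisson-ratio conversion (a helper exists).
Quality control is a single pass per map: mean and SD computed once, all
values outside ±2 SD discarded, no re-iteration — on a homogeneous
Gaussian map this removes the expected ~4.6 % tail, comfortably below the
~10 % operational bound for failed indents.

The force-grid generator plants the Hertz law exactly (bisection solve of
k·d = (4/3)E√R·(z−z_c−d)^{3/2}) beyond a per-point random contact
(SD 20 nm about 150 nm), adds a random linear baseline tilt
(SD 0.5 nm/µm) and Gaussian deflection noise (default SD 0.5 nm). The
default turnaround force of 20 nN (k = 3 N/m, R = 1 µm, E ~ 500 kPa
⇒ peak deflection ~6.7 nm, indentation ~96 nm) reflects a setpoint an
experimenter would choose for usable signal-to-noise on tissue this
stiff with such a stiff lever. Under these conditions the median
contact-point error is ≈4.6 nm and the median modulus error ≈3 % per
curve. Contact localisation is quoted in physical units because an error
expressed "in samples" depends on the arbitrary z-sampling density.

Group contrasts use the exact Mann–Whitney U (all rank assignments) for
combined n ≤ 20 without ties and the tie-corrected normal approximation
otherwise; ANOVA is the classical one-way F test. The 6-vs-6 power
property uses patient-level medians that are log-normal about group
centres in a 2.5 : 1 ratio with patient log-SD 0.4 (geometric SD ≈ 1.5)
and within-map log-SD 0.3 — spreads consistent with the within-group
variation reported for this assay once map-level averaging is accounted
for.

## Proteome screening

Group summaries are arithmetic means of normalised abundances (total-sum
by default; median-ratio and none available — which scale the published
workflow used is not stated, and total-sum is the least informative
assumption). Fold change is mean(high)/mean(low); proteins with an empty
group or zero low-group mean are flagged, never silently dropped, and no
imputation is performed. The differential screen uses strict inequalities
(fold > t up, fold < 1/t down, boundary unchanged) per the ">2-fold"
convention, and no per-protein significance testing is performed — with
three samples per group the screen is a magnitude filter. Note that
sub-threshold regulators (e.g. 1.3-fold) are deliberately *not* listed at
the 2-fold screen even though their folds are accurately measured; the
threshold is a parameter.

The generator draws per-protein baselines from a log-normal (σ = 1 about
10⁶ arbitrary units) and per-measurement noise as log-normal with the
requested CV (mean-corrected so the arithmetic mean matches the planted
value); planted folds multiply the high-group mean.

## Cohort simulation and study report

The simulated cohort mirrors the study design: 22 patients; Volpara
uniform on 3–25 % volume; VAS planted as a linear function of Volpara
with Gaussian noise calibrated to a population r² of 0.70; peri-ductal
PSR fraction likewise calibrated to r² = 0.8658; tissue fractions from
generated histology run through the real segmentation stage,
uncorrelated with density (as observed for this cohort). The 12 patients
most extreme in Volpara are split 6 low / 6 high; each receives a fibre
image (coherency target 0.21 or 0.38) analysed at the calibration window
and a force grid (group centres 247 / 611 kPa, patient log-SD 0.4)
analysed by the full fitting chain. Correlation is Pearson (the assay's
scatter plots are linear fits; the method is pinned as an assumption),
with r² and two-sided p from the t transform; group membership comes from
explicit per-patient flags, and no multiple-testing correction is applied
(raw p-values are reported along with the number of tests). Reports are
validated against a pydantic schema (`StudyReport`; the JSON Schema is
also written alongside the report), contain every stage seed, and exclude
timestamps so identical configurations produce byte-identical output.

Because Table-level per-patient source data are not public, the printed
cohort correlations (e.g. VAS–Volpara r² = 0.70) are design properties of
the simulation, not re-derivable facts; recovery tests therefore check
the *mean* simulated r² over seeds against the planted value.

## What the generators do not emulate

Histology images are coloured blob fields obeying the segmentation rule's
ordering, not photorealistic stains; exact compartment colours are a
fixture convention (`HISTOLOGY_COLOURS`). Fibre images have straight,
infinite fibres with no curvature, bundling or polarisation optics.
Height maps ignore tip convolution and scanner artefacts beyond plane
tilt. Force curves are purely elastic (no adhesion, viscoelasticity or
finite-thickness effects; the 10 %-of-thickness indentation rule is a
protocol matter, not modelled). Proteome tables have independent
log-normal noise with no missingness structure. Passing recovery tests
therefore demonstrates correctness of the estimators under their stated
models, not robustness to every artefact of real acquisitions.

## Problem sizes

Default test/acceptance problem sizes — 512² height maps, 256² images,
300-sample force curves, 3×3 to 5×5 force grids, 100-replicate Monte
Carlo loops — are chosen so the full chain remains interactive on a
laptop-class single core while keeping Monte-Carlo standard errors well
below the asserted tolerances.
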