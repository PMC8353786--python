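# Methods

## Measurement chain

**Radiometric calibration.** Surface reflectance is assumed linear in the
8-bit digital number per band, ρ_λ = DN_λ·Gain_λ + Offset_λ. Gain and offset
are solved per band by unweighted OLS over the panel-ROI mean DN of eight
near-Lambertian canvases at reflectances 0.03, 0.06, 0.12, 0.24, 0.36, 0.48,
0.56 and 0.80. Fitting on panel means (not per-pixel) mirrors standard
panel-ROI practice; the report carries per-band R² and residual RMS. On
application, negative reflectances are clamped to 0 (physical floor) with a
logged count; values above 1 are kept with a warning because genuinely
specular pixels must remain visible to the bad-pixel filter, which operates
in DN space.

**Quality filters.** A pixel is *bad* iff DN > 250 in **all** 12 bands
(strict inequality, conjunction — water glint saturates every band). A plot
is invalid iff its ROI holds **more than** 100 bad pixels; exactly 100 is
still valid (strict reading of "more than"). Bad pixels are excluded from
reflectance means even in valid plots. Both thresholds are parameters.

**Plot aggregation.** Plot reflectance is the per-band arithmetic mean over
unmasked ROI pixels; canopy height is the ROI mean of DSM − DSM_soil with
negative per-pixel differences clamped to 0 (logged). ROIs are 0-based,
half-open pixel rectangles of equal size (~800 pixels in the multispectral
geometry). Destructive LAI is LA/n × ρ with n = 3 bundles and ρ = 22.5
bundles/m². Stage assignment: a flight on the heading date itself counts as
post-heading (heading opens the reproductive phase); the boundary is a
parameter.

**Indices and models.** Eight indices from the plot-mean reflectance
(indices are computed from plot-level means, not per-pixel then averaged).
Band roles default to green = 550 nm, red = 670 nm, red edge = 720 nm,
NIR = 800 nm — the central candidate within each spectral region of the
12-band set — and are fully configurable; every report logs the assignment.
OSAVI is implemented in its red-edge form,
(1+0.16)(ρ_NIR − ρ_rededge)/(ρ_NIR + ρ_rededge + 0.16), as the default, with
the conventional red-band form available via `osavi_variant="red"`; reports
state which was used. Blue-band indices are excluded (poor sensor SNR near
450 nm). Models are univariate OLS with intercept only — no regularisation —
pooled over all cultivars and dates; `ln` is the natural logarithm. Samples
with VI ≤ −1 under the log form are excluded with a logged count.

**Cross-validation.** Seeded shuffle, contiguous chunking into k = 10 folds
(remainder spread over leading folds); every sample validates exactly once.
Reported Coef/RMSE/CV/Bias are arithmetic means of per-fold values. The CV_i
denominator is the validation fold's own mean measured LAI; the global mean
is available via `cv_denominator="global"` (the choice is stated in every
report). Invalid or domain-excluded samples are dropped before fold
assignment.

**Hysteresis gap.** Pre- and post-heading LAI-vs-predictor relations are fit
separately as lines; the gap is the mean absolute difference of their
predictions over the shared predictor range, normalised by mean measured
LAI. Zero means the stages agree; the statistic is undefined (NaN) when the
ranges do not overlap or a stage is empty.

## Synthetic campaign generator

The generator emulates a 48-cultivar hybrid-rice trial observed on 13 dates
(17–86 days after transplanting, DAT) and exists so the full pipeline —
calibration through cross-validation — runs and is tested without field
data. Cultivar parameters are drawn uniformly: heading 59–73 DAT, peak LAI
2.76–8.53, final height 0.82–1.13 m (the trial's observed ranges), green-up
rate 0.10–0.16 d⁻¹ and senescence rate 0.05–0.10 d⁻¹ (chosen so transplanted
seedlings reach LAI ≈ 0.3–0.8 by the first flight and leaf area declines
gradually through ripening, as in a real paddy).

**Trajectories.** LAI follows a double logistic (green-up × senescence)
with the senescence midpoint placed analytically so the peak falls exactly
10 days before heading, baseline-subtracted so LAI(0) = 0. Height follows a
Gompertz curve (midpoint heading − 35 d, time constant 12 d): rice gains
most height while tillering, so the height curve must rise fast early yet
still be climbing through heading — a symmetric logistic cannot do both
while starting near zero, which is why Gompertz replaced it. Height peaks 5
days after heading, then declines linearly by 0.15 %/day (drooping
panicles), floored at 5 % below peak. These shapes give the opposed
hysteresis the method exploits: argmax(LAI) < heading < argmax(height) for
every cultivar.

**Spectra.** Reflectance mixes a dark flooded-paddy soil endmember and a
canopy endmember through a Beer–Lambert gap fraction e^(−0.6·LAI). After
heading the canopy endmember blends in a panicle/senescent spectrum by a
logistic *panicle fraction* of days since heading (midpoint +5 d, time
constant 3 d): visible reflectance roughly doubles at matched LAI (green and
red ≥ 2× at LAI ≈ 2.9) while NIR drops slightly — so every NIR/visible
index is depressed post-heading by construction. Endmember values are
generator constants calibrated to those qualitative contrasts, not
measurements. Post-heading samples additionally carry seeded jitter in the
panicle fraction (sd 0.25 — plots senesce at different paces) and a common
lognormal fluctuation of the four NIR bands (sd 0.30 scaled by canopy
cover — droopy panicles rearrange the canopy), reproducing the diffuse
post-heading point clouds that make single-index whole-season models fail;
both are scaled so the zero-LAI spectrum is exactly the soil endmember.

**Scenes.** Plot spectra are rendered to pixels with 3 % per-band Gaussian
noise, inverted through a true sensor line (gain ≈ 0.004, offset 0.01) to
8-bit DN; canvas panels are noiseless. The DSM is flat soil plus the
simulated height inside plot ROIs (pixel noise sd 5 mm). Water specular
contamination saturates (DN 255 in all bands) 120 random pixels in each of
24 plots on the first flight, so the validity filter retains exactly half
the plots there. Destructive sampling draws three bundle leaf areas with
multiplicative Gaussian noise (cv 5 %), unbiased for the true LAI. All
randomness flows from explicit integer seeds; identical inputs give
bit-identical scenes.

**What the generator does and does not emulate.** It reproduces the
statistical structure the analysis depends on — stage-dependent spectra,
opposed LAI/height hysteresis, saturation of normalized indices, realistic
artefact rates — but not radiative transfer (no PROSAIL), row geometry,
BRDF/illumination effects, weather, or real panicle optics. Passing tests
therefore demonstrate that the pipeline's mechanics and the direction of
its conclusions are sound, not that its error magnitudes match any
particular field dataset.

## Numerical and design choices

- OLS everywhere via `numpy.linalg.lstsq`; singular designs (constant
  predictor, < 2 samples, < 2 distinct panel DN in a band) raise typed
  errors naming the culprit.
- R² between LAI and a predictor is the squared Pearson correlation;
  undefined (NaN) under zero variance.
- DN quantisation bounds the reflectance round trip by gain/2 per band; the
  end-to-end noiseless test asserts exactly that bound.
- Default problem sizes: 48 plots × 13 dates (624 observations, 600 valid
  for most indices) for campaign-level analyses; 600 samples × 20 replicates
  for the published-equation recovery checks. Both run in seconds and give
  Monte-Carlo errors well inside the assertion tolerances.
- Reports are deterministic functions of (config, seed); reruns are
  bit-identical.

## Known limitations

- The generator's hysteresis is endmember-driven; its *magnitudes* (e.g.
  exact CV reductions) are properties of the chosen constants and should not
  be read as field predictions.
- The printed reference calibrations are used as simulation ground truth for
  recovery checks; the package does not attempt to re-derive their numeric
  values from imagery, which would require the original field data.
- Height and reflectance share one ROI grid in synthetic scenes; the
  resampling questions raised by dual-resolution real imagery (5.5 cm vs
  0.8 cm) are out of scope.
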