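# Methods

This note records the models, algorithms, numerical choices and known
limitations of the package. The pipeline is: scene rendering (or, in a
clinical setting, raw two-channel data) → polarization extraction →
anterior-segment compensation → frame selection, registration, Stokes
averaging → layer segmentation → birefringence estimation → subject and
cohort statistics.

## Forward model (synthetic scenes)

**Scene.** A `Phantom` stores angular profiles on a uniform TSNIT grid
(φ = 0° temporal, T→S→N→I): RNFL thickness d(φ), birefringence Δn(φ) in
°/µm, slow-axis orientation θ(φ), vessel wedges, and optional focal
defects. The axial layer stack is fixed in absolute depth: ILM at 120 µm,
RPE top at 420 µm (12 µm thick), two bright photoreceptor bands 50 and
26 µm above the RPE, non-birefringent inner retina in between. With the
default 2 µm/px axial pitch the 30-pixel photoreceptor readout band spans
60 µm and contains both bright bands.

**Presets.** Group presets set the mean superior/inferior birefringence:
healthy 0.135, diabetic 0.103, glaucoma 0.129 °/µm. The angular profile is
b(φ) = 0.6·L + a·h(φ) with raised Gaussian humps h at 90° and 270°
(σ = 45°) and a chosen so that the mean over the superior+inferior half
circle equals the preset level L exactly. Thickness is base + two Gaussian
humps (healthy: 70 + 80/85 µm, σ = 40°), giving a mean of ~115 µm and
well over 200 of 2048 A-scans above the 100 µm analysis threshold. The
glaucoma preset flattens the humps and punches two 5°-wide, 50%-deep holes
in the superior quadrant. Eight vessels (4–9° wide) are placed with
seeded jitter around fixed angles. `flat` is a constant analytic scene
(125 µm, 0.135 °/µm, no vessels).

**Rendering.** Light enters circularly polarized. At pixel z of an A-scan
the cumulative round-trip retardation is δ(z) = Δn·min((z−z_ILM+1)·pitch,
d), i.e. δ is referenced to the *bottom edge* of each pixel and clamps at
Δn·d below the RNFL. This convention makes the deepest RNFL pixel — and
the entire photoreceptor band — carry exactly the full layer retardation
despite integer quantization of the boundaries. The detected channels are
A_H = √R·cos δ and A_V = √R·sin δ·e^{i(π−2θ)} with R the local
reflectivity; the standard extraction δ = arctan(|A_V|/|A_H|),
θ = (180°−ΔΦ)/2 inverts this exactly. RPE pixels are assigned
independent uniform-random pure polarization states at full intensity
(drawn once per rendered sequence so that noise-free repeats are
bit-identical); this is simpler than a Mueller depolarizer but produces
spatially scrambled states whose windowed resultant — the DOPU — is low,
which is all the segmentation needs. An optional corneal retarder
(a Jones unitary) is applied to every pixel to exercise compensation.

**Noise.** Speckle multiplies both channels by a common circular complex
Gaussian factor per pixel and repeat — per-pixel intensity over repeats is
exponential, and the polarization state of a pure speckle pixel is
preserved (channel-common speckle; cross-channel decorrelation is not
modeled). Retardation noise therefore enters through additive complex
detector noise (default 30 dB SNR relative to the unit-reflectivity RNFL),
which dominates wherever speckle dims a pixel; dropout and shifts of
corrupted frames are applied to the signal before detector noise is added.
Motion jitter is an integer axial/lateral shift per repeat (SD 2 px);
a configurable fraction (default 5%) of repeats is corrupted: 70%
intensity dropout plus a 30 px axial shift. Vessel wedges attenuate all
signal below the vessel to 8%.

## Analysis chain

**Polarization.** Reflectivity is dB relative to the image maximum with a
−100 dB floor. Stokes components are I = |H|²+|V|², Q = |H|²−|V|²,
U+iV = 2H*V; the averaged-data inverse is δ = ½·arccos(Q/√(Q²+U²+V²)),
ΔΦ = atan2(V, U). Anterior-segment compensation estimates the
intensity-weighted mean Stokes state in a 3-pixel band under the retinal
surface (one state per acquisition — corneal birefringence varies slowly
over a 1.5 mm-radius circle) and applies the minimal Poincaré-sphere
rotation taking it to the ideal zero-retarder return state +Q. The
residual degree of freedom is a rotation about +Q, which leaves Q — and
hence retardation — untouched, so retardation recovery is exact on
noise-free data even though the axis image is only determined up to that
rotation.

**DOPU.** Per-pixel normalized Stokes vectors are averaged over a window
(default 4 depth × 8 lateral pixels; lateral axis periodic) and the
resultant length is the DOPU. Two guards matter in practice: pixels at or
below 4× the lower-quartile intensity carry no polarization information
(vitreous, sub-RPE shadow) and are assigned DOPU 1; and the window mean is
taken over bright pixels only, otherwise zero-signal neighbors dilute the
resultant and every tissue boundary acquires a spurious low-DOPU rim. The
4-px depth window matches the ~6 px RPE band; a deeper window smears the
detected band by several pixels.

**Frame selection and averaging.** Scores are Pearson correlations of
linear intensity (central 80% of depth rows) against a reference frame
after coarse registration; the default reference policy picks the medoid
(maximal median correlation to 10 evenly spaced probes). The best
min(50, n) frames are registered by integer shifts maximizing the FFT
cross-correlation — lateral shifts wrap around the closed circle, axial
shifts clamp at ±50 px and zero-fill — and the Stokes components are
averaged unnormalized (intensity-weighted). Retardation, reflectivity and
DOPU are computed from the averaged components. Sub-pixel registration is
not performed; with speckle-dominated noise the benefit would be
negligible next to the averaging itself.

**Segmentation.** The noise floor is the 25th percentile of the
reflectivity image (robust both to noise-free backgrounds and to
zero-filled registration edges); the ILM is the first pixel 15 dB above
it, median-filtered over 15 A-scans (circularly) with >10 px outliers
snapped back. The RPE band is the lowest-DOPU contiguous run (threshold
0.70) of maximal summed intensity per A-scan. The RNFL lower boundary is
a dynamic program over the (A-scan, depth) trellis: node cost
exp(−6·g) with g the bright-to-dark backward difference of the laterally
Gaussian-smoothed (σ = 2 A-scans, periodic) log-intensity image, capped
at 20 dB and normalized. The backward difference makes a step edge peak
at the first dark pixel (matching the half-open [ilm, lower) layer
convention); the log-domain contrast is invariant to the uniform
attenuation under vessel shadows, and the lateral smoothing suppresses
speckle gradients, which at moderate frame counts otherwise rival the
true edge. Transition cost is 0.1·|Δz| with |Δz| ≤ 4, ties toward the
shallower depth. The search band runs from ILM+2 down to
RPE−40 px: the 30-px photoreceptor complex plus margin is excluded
because its edges are stronger than the RNFL base and would capture any
gradient-cost shortest path. The circular seam is closed by a second DP
pass anchored at the free pass's depth in column 0 and constrained to
return within one step of it. Vessels are A-scans whose mean RPE-band
intensity falls below 0.6× the median, dilated by 2 A-scans per side.
Programmatic boundary overrides (the counterpart of the manual adjustment
a clinical operator would perform) replace ranges verbatim and re-check
the ordering invariant.

**Birefringence.** δ_PR is the center of the maximal bin of the
intensity-weighted retardation histogram over the 30-px band above the
RPE. The default bin width is 0.25°: the estimator's quantization error is
half a bin, and at typical RNFL retardations (~17°) a 1° bin alone costs
2–3% relative accuracy, incompatible with the ~1% noise-free recovery the
estimators otherwise achieve; 0.25° keeps quantization below the
segmentation-induced error while the intensity weighting and averaging
keep the histogram stable under noise. The regression estimator fits
retardation against physical depth over the deepest ⌈2N/3⌉ of the N RNFL
pixels (minimum span 6 px, minimum 4 points), free intercept. Validity
requires thickness above the threshold (default 100 µm), no vessel, and
defined segmentation; undefined values propagate as NaN, never silently
dropped, and a count below 200 (scaled by lateral sampling) warns that
the subject would fail the inclusion rule.

**Statistics.** Subject means follow the two masking conventions:
thickness over all segmentation-valid A-scans, retardation/birefringence
over the validity mask only (so mean birefringence is *not* mean
retardation / mean thickness). Repeatability is the n−1 sample SD over
repeated acquisitions, averaged across subjects. Group comparisons use
the two-tailed t-test from summary statistics; the unequal-variance
(Welch–Satterthwaite) variant is the default — from the published group
summaries it yields p ≈ 7.6·10⁻⁴ for healthy-vs-diabetic, matching the
printed 7·10⁻⁴, whereas the pooled test gives ≈ 2.6·10⁻⁴ — and the pooled
variant is available. Raw p-values, no multiple-testing correction
(noted in output metadata). Profile smoothing (10-A-scan circular sliding
mean followed by tricube-weighted local linear regression, span 5%) is
for display only; statistics use unsmoothed values. Quadrants are equal
90° sectors centered on T/S/N/I; left eyes mirror laterally (T↔N).

## Simulated experiments

Between-subject variability in simulated cohorts is a normal draw of the
subject's superior/inferior birefringence level with the group's
between-subject SD (the published SDs are across-subject SDs);
within-subject variation comes only from noise, jitter, frame corruption
and re-selection. Each simulated subject also receives a random corneal
retarder (0–25°, random axis), so compensation is exercised end to end.
The repeatability experiment re-renders one phantom with fresh noise per
repeat, emulating repositioning and reacquisition.

## Problem sizes

Defaults follow the clinical protocol (2048 A-scans × 100 repeats,
512 depth px). The test suite and the acceptance script run the same
scenes at reduced sampling — typically 512 A-scans × 16 repeats ×
320 depth px, with 12 of 16 frames selected — which preserves every scene
feature (the vessel-mask false-positive check runs at the native 2048
A-scans because the mask dilation is defined in A-scan units). The
direction-of-effect experiment uses 384 A-scans × 10 repeats per subject,
7 + 7 subjects per cohort replicate.

## What passing tests do and do not show

The simulator reproduces the features the estimators rely on — cumulative
retardation in a birefringent layer under circular illumination, a
depolarizing RPE, speckle statistics, vessel shadows, motion jitter,
corrupted frames, corneal birefringence — so the tests demonstrate that
the measurement chain recovers known ground truth through realistic
nuisance processes. They do not validate instrument-specific effects that
are deliberately out of scope: wavelength-dependent dispersion, multiple
scattering, cross-channel speckle decorrelation, axis-orientation banding,
tracker dynamics, or biological variability beyond the modeled profiles.
Absolute agreement with clinical values cannot be established from
synthetic data; the published group statistics enter only as inputs to
the summary-statistics t-tests.

## Known limitations

* Channel-common speckle preserves pure polarization states; real PS-OCT
  speckle partially decorrelates the channels, so the simulated
  retardation noise floor is optimistic at high SNR.
* The anterior-segment compensation is a surface-state method with one
  rotation per acquisition; it is validated against this package's own
  forward model, not against the instrument's algorithm.
* The quotient method inherits the ceil-quantization of segmented
  thickness (≤ 1 px), a ~1% bias at 100 µm thickness and 2 µm pitch.
* Raster rendering gives each (x, y) the circumpapillary profile at its
  polar angle with no radial dependence; en-face maps are
  demonstration-grade.
* Manual segmentation editing is replaced by programmatic overrides.
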