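# psoct-rnfl

Quantification of retinal nerve fiber layer (RNFL) birefringence from
circumpapillary polarization-sensitive OCT (PS-OCT) scans, together with a
Jones-calculus scan simulator that stands in for the clinical instrument.

## The problem

The RNFL is form-birefringent: the ordered microtubule bundles of retinal
ganglion cell axons retard light polarized along the fiber axis relative to
light polarized across it. Diseases that damage these axons — glaucoma,
diabetic retinopathy — may change the tissue's birefringence *before* the
layer visibly thins, which makes birefringence Δn (reported here in °/µm of
single-pass tissue depth) a candidate early biomarker.

A PS-OCT instrument illuminates the retina with circularly polarized light
and records two orthogonal complex detection channels (A_H, A_V) per depth
pixel. From these the per-pixel reflectivity, retardation
δ = arctan(|A_V| / |A_H|) ∈ [0°, 90°] and axis orientation are extracted.
Around the optic nerve head a circular scan of 2048 A-scans at 1.5 mm
radius is repeated 100 times; the 50 repeats best correlated to a reference
frame are registered and averaged in the Stokes representation
(I, Q, U, V), which strongly suppresses speckle noise in the polarization
data before retardation is read out.

Two estimators convert the averaged tomogram into per-A-scan birefringence:

* **quotient method** — Δn = δ_PR / d, where δ_PR is the retardation at the
  photoreceptor layer (intensity-weighted histogram peak over a 30-pixel
  band above the RPE; the layers between the RNFL and the photoreceptors
  are non-birefringent) and d is the RNFL thickness from segmentation;
* **linear-regression method** — Δn = slope of δ(z) against physical depth
  inside the RNFL, fitted on the deepest two thirds of the layer's pixels
  so a surface retardation offset is absorbed by the free intercept.

Supporting steps: ILM by intensity thresholding, RPE by its depolarizing
signature (low degree of polarization uniformity, DOPU), RNFL lower
boundary by a smoothness-regularized shortest path on the axial gradient,
vessel-shadow exclusion, and a 100 µm thickness threshold restricting the
analysis to A-scans where both estimators are reliable. Cohort analysis
compares group means with a two-tailed Welch t-test.

Because clinical PS-OCT raw data are proprietary, the package ships a
first-class synthetic-data module: a ground-truth `Phantom` (TSNIT
double-hump thickness profile, angularly varying birefringence, vessels,
depolarizing RPE, optional focal defects) rendered into noisy two-channel
complex B-scan sequences via Jones calculus, with speckle, detector noise,
motion jitter and corrupted frames.

## Worked example

```python
import numpy as np
from psoct_rnfl import (ScanGeometry, make_phantom,
                        render_circular_sequence, run_subject,
                        PipelineConfig)

geometry = ScanGeometry(n_ascans_per_bscan=512, n_bscans=16,
                        n_depth_pixels=320)
phantom = make_phantom("healthy", seed=7, n_phi=512)
pairs, truth = render_circular_sequence(phantom, geometry, seed=107)

config = PipelineConfig(geometry=geometry, n_select=12)
avg, seg, profile, summary = run_subject(pairs, config, "demo")
print(f"mean thickness      : {summary.mean_thickness_um:.1f} um")
print(f"biref (quotient)    : {summary.mean_biref_quotient:.4f} deg/um")
print(f"biref (regression)  : {summary.mean_biref_regression:.4f} deg/um")
print(f"valid A-scans       : {summary.n_valid}")
v = profile.valid_mask
print(f"ground truth (valid): {truth.biref_deg_per_um[v].mean():.4f} deg/um")
```

prints

```
mean thickness      : 116.8 um
biref (quotient)    : 0.1299 deg/um
biref (regression)  : 0.1302 deg/um
valid A-scans       : 253
ground truth (valid): 0.1306 deg/um
```

The healthy scene's superior/inferior birefringence level is 0.135 °/µm;
the mean over the *valid* region (which includes parts of the
lower-birefringence temporal/nasal flanks) is 0.1306 °/µm, and both
estimators recover it to well under 0.005 °/µm despite speckle, 30 dB
detector noise, motion jitter and a corrupted frame.

The same pipeline is available from the shell:

```
psoct-rnfl simulate --preset healthy --seed 1 --out scan.h5
psoct-rnfl analyze --in scan.h5
psoct-rnfl ttest 0.135 0.007 7 0.103 0.015 7
```

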