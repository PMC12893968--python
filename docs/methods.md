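# Methods

`ulmkit` implements the computational chain of super-resolution ultrasound
(ultrasound localization microscopy, ULM) for tumour microvasculature, the
contrast-enhanced ultrasound (CEUS) time–intensity-curve descriptors, and
the two-group diagnostic statistics used to separate HER2-positive from
HER2-negative breast lesions.  Because no patient data ship with the
package, every stage is validated against a synthetic phantom generator
whose ground truth is known by construction.  This note records the models,
the defaults and why, the numerical choices, and what the synthetic
validation does and does not establish.

## Super-resolution reconstruction

**Clutter model and SVD filter.**  A frame stack (frame × axial × lateral)
is reshaped to the Casorati matrix with pixels as rows and frames as
columns, and decomposed with an economy-size SVD.  Slow tissue signal
concentrates in the low-order singular components; the filter rebuilds the
stack from components with 1-based index in `(low_cut, high_cut]`.
`low_cut=0, high_cut=n_frames` is the identity to machine precision, and
the retained/removed bands partition the Frobenius energy exactly — both
are asserted in tests.  The synthetic clutter is a static speckle image
(correlation length ≈ 2 px, as in B-mode tissue speckle) modulated by an
optional sinusoidal gain drift; that product is exactly rank 1 in the
Casorati matrix, so `low_cut=1` removes it analytically.  `suggest_rank_cut`
offers a spectrum-gap heuristic (last singular-value ratio above a
configurable factor, default 4) for data whose clutter rank is not known.

**Detection and localization.**  Candidate microbubbles are 8-connected
components above a per-frame threshold (default `mean + 3·sd` of the
filtered frame; an absolute override exists because the relative rule is
deliberately scale-free and therefore sensitive to how much of the frame is
signal).  Gates: area in [2, 60] px at 50 µm pixels, eccentricity ≤ 0.9
from the component's principal second moments; border-touching components
are kept but flagged.  Accepted components are localized by the
intensity-weighted centroid in micrometres (origin at the top-left pixel
centre; axial row index grows with depth).  On the phantom at 20 dB peak
SNR the localization RMSE is ≈ 9 µm — below a quarter pixel — and falls
monotonically with SNR.

**Density map.**  Localizations accumulate on a grid upsampled 10× (5 µm
bins at 50 µm pixels); each localization increments exactly one bin, so the
map total equals the localization count (conservation is asserted).

## Tracking

For each localization in frame F, candidates in frame F+1 within a circular
700 µm search radius are scored by the zero-lag, zero-mean normalized
cross-correlation of 9 × 9-pixel patches of the filtered frames.  Patches
are sampled at the exact sub-pixel position by bilinear interpolation:
pixel-phase mismatch alone perturbs the NCC of a σ = 3 px Gaussian by up to
~0.08, which would make scores of true and rival pairs incomparable.
Pairs with NCC < 0.9 or displacement > radius are rejected.  Assignment is
greedy in descending NCC with scores quantized at 0.01 (differences finer
than the residual sampling noise carry no information), ties broken by
smaller displacement, then by lower frame-F index — fully deterministic.
On phantoms with ≤ 6 bubbles per frame this greedy matcher reproduces the
exhaustive optimal (Hungarian) assignment on ≥ 95 % of frames.

Chained pairs become tracks (minimum length 5 localizations).  Step speed
is |displacement µm| × frame rate × 10⁻³ mm/s; the geometry of the gates
caps measurable speed at radius × rate / 1000 (56 mm/s at 700 µm and
80 Hz), and no larger speed can be produced.  Velocity/direction maps
average step speed and signed axial velocity (positive = deeper = away from
the transducer) in the SR bin containing each step midpoint; unvisited bins
are NaN, never zero.

Two constants deserve a caveat: the 700 µm window and an "up to 40 mm/s"
tracking range circulate together in the clinical protocol this package
mirrors, yet 700 µm at 80 Hz implies a 56 mm/s cap.  The radius is exposed
as configuration rather than resolved.

## Vascular metrics

* **Velocity** — per-track mean speed over in-ROI steps; ROI mean is the
  average over tracks, ROI max the largest per-track mean (robust to
  single-step outliers).  No in-ROI track yields NaN, not zero.
* **Tortuosity** — path length / chord length per track (distance metric;
  1 ⇔ collinear, asserted as an invariant).  Closed loops (zero chord) are
  flagged NaN and excluded.  Published per-lesion tables in this field
  sometimes print tortuosity magnitudes (≈ 3 mean, ≈ 60–120 max) that the
  distance metric cannot reach on plausible vessels; the definition behind
  those values is not public, and no attempt is made to match them.
* **Diameter** — the binarized SR map (counts ≥ 1, isolated single bins
  removed) is skeletonized; diameter at each skeleton pixel is twice the
  Euclidean distance transform times the grid spacing.
* **Fractal dimension** — box counting over dyadic scales; the dimension is
  the least-squares slope of log N(s) vs log(1/s).  Exact on constructed
  sets (line 1.0, filled square 2.0, Sierpinski triangle log 3/log 2).
  In the pipeline the raster is the vessel network at *frame* resolution:
  at desk-scale acquisition lengths the 5 µm SR grid is localization-sparse
  and box counting there measures the sampling dust, not the network.
* **MVD** — unique SR pixels visited by tracked bubbles / ROI area × 100.
* **Distribution** — each localization gets a normalized radial position
  r ∈ [0, 1] (0 = ROI centroid, 1 = boundary), by ray casting on simply
  connected ROIs and by a distance-transform fallback otherwise.  Labels:
  peripheral if ≥ 60 % have r > 0.7, central if ≥ 60 % have r < 0.5, else
  diffuse.  The peripheral cut must satisfy 1 − r² < 0.6 so that a uniform
  fill of a convex ROI is *not* called peripheral (a uniform disc has 64 %
  of its mass beyond r = 0.6); r = 0.7 leaves 51 %.  All three cuts are
  configuration, since the underlying clinical feature is reader-assessed.
* **Flow direction** — length-weighted mean of signed axial step
  velocities over in-ROI steps; positive → away, negative → toward, exact
  zero → indeterminate.

## Time–intensity curves

`extract_tic` averages intensity over the ROI per frame; the baseline is
the mean of the first 10 frames and contrast arrival is the first time the
curve exceeds baseline + 2 sd sustained for ≥ 3 frames.  `tic_parameters`
computes PI = (peak − baseline)/baseline (dimensionless; a 10·log10 variant
is reported alongside because clinical software often prints dB), TTP =
peak time − arrival, AUC by trapezoid over the whole record on the *raw*
curve, wash-in as the least-squares slope of the ascending limb between
10 % and 90 % of the rise, and wash-out as the chord from the peak to 50 %
decay (or the end of record, flagged).  Peak finding, the peak value and
the decay crossing use a moving-average-smoothed curve (default window 5;
the raw maximum is noise-biased upward and a raw crossing is biased steep).
All five descriptors are exact to 1e−9 on a noiseless triangular bolus, and
PI/TTP are recovered within 5 % on average at 20 dB bolus SNR.

The synthetic bolus is a flat baseline, a linear wash-in over TTP, and an
exponential wash-out; closed-form truths for all descriptors are stored
with the curve.  The linear/exponential shape was chosen over a
gamma-variate because every descriptor then has an elementary closed form;
it does not emulate recirculation.

## Diagnostics layer

Standard tests are delegated to scipy/statsmodels behind this module's
interface; quantities central to the validation story are computed
explicitly.  Pearson chi-square is uncorrected (no Yates) — the choice is
verified, not assumed: the seven published contingency statistics
(6.770, 5.554, 2.510, 0.888, 42.933, 6.509, 13.064) are reproduced exactly
from their published counts, which ship with the package.  Fisher's exact
p matches a full hypergeometric enumeration to 1e−12.  The t-test uses the
pooled variant unless Levene's test rejects equal variances at p < 0.1
(both variants retained in the result); its type-I error is calibrated at
0.05 ± 0.01 over 10⁴ null replicates.  Mann–Whitney U uses the
tie-corrected normal approximation with continuity correction (without it
the asymptotic p misses the exact enumeration by > 0.01 at n = 8).
Cohen's kappa carries the large-sample SE CI.  Logistic regression is the
statsmodels ML fit with Wald = (β/SE)², OR = exp(β), and explicit
separation/non-convergence flags.  The ROC AUC is computed via the
Mann–Whitney identity on midranks (equal to the identity to 1e−12, by
construction), with a DeLong 95 % CI implemented here; operating points
maximize the Youden index with ties broken toward higher specificity.
`combine_modalities` fits an in-sample logistic score per modality subset
(all seven combinations of CUS/CEUS/SRUS) and reports
sensitivity/specificity/accuracy/AUC — explicitly labeled in-sample, with
no validation split, because that matches the published analysis shape.

## Synthetic cohort

`default_cohort_spec` reproduces the published two-group summaries of a
72-lesion cohort (23 HER2-positive, 49 HER2-negative): continuous features
as group normals with the published mean ± sd (sd ≈ IQR/1.35 where only
medians with quartiles are published), categorical features as group
multinomials with the published proportions.  It emulates marginal group
structure only — features are drawn independently within groups, so
between-feature correlations of real lesions are absent, and in-sample
AUCs on this cohort characterize the statistics layer, not clinical
performance.

## Phantom realism and its limits

The frame generator emulates: diffraction-limited imaging (isotropic
Gaussian PSF, σ = 150 µm ≈ the mid-band beam width of a 3–10 MHz linear
probe), static speckle clutter with optional gain drift, additive white
noise, and advection of point scatterers along vessel centerlines at the
segment flow speed with respawn at the segment start (stationary density).
Bubble seeding is stratified along each segment: bubbles sharing one
advection speed keep their spacing forever, so uniform seeding could leave
two bubbles permanently inside one PSF width, which no amount of downstream
processing can separate.  Defaults: 128 × 128 pixels at 50 µm, 80 Hz,
1000 frames (tests and the acceptance script use 60–300 frames to stay
desk-sized; problem sizes are printed with every result).

Not emulated: acoustic wave propagation, nonlinear bubble oscillation,
out-of-plane motion, tissue motion beyond gain drift, bubble velocity
dispersion across the lumen, and finite-bolus kinetics.  Passing the
phantom suite therefore demonstrates the correctness of the *computational
chain* under the stated image-formation model, not clinical-grade
performance on patient data.

## Reproducibility

Every random stage takes an explicit seed; identical seeds give
bit-identical outputs (asserted end-to-end).  Artifacts embed the
configuration hash (scientific parameters only, paths excluded) and seed.
Units are explicit in key and column names (µm, mm/s, Hz) because the
domain mixes µm, mm/s and cm/s; any cm/s presentation is an explicit
conversion at the output layer.
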