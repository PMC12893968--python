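# ulmkit

Super-resolution ultrasound (ULM) microvasculature analysis for
contrast-enhanced breast imaging: clutter filtering, microbubble
localization and tracking, quantitative vascular metrics,
time–intensity-curve descriptors, and the two-group diagnostic statistics
that separate HER2-positive from HER2-negative lesions.

## The problem

Ultrasound localization microscopy reconstructs vasculature far below the
acoustic diffraction limit by localizing individual microbubble contrast
agents across thousands of high-frame-rate frames and tracking them between
frames.  The resulting microvascular descriptors — flow velocity,
tortuosity, vessel diameter, fractal dimension, microvascular density,
spatial distribution and dominant flow direction — differ between breast
cancer molecular subtypes, and combined with conventional (CUS) and
contrast-enhanced (CEUS) features they feed a logistic/ROC diagnostic model
for HER2 status.  `ulmkit` implements this whole chain as a tested library
with a synthetic phantom generator, so every stage can be validated against
known ground truth without patient data.

## The method in brief

1. **SVD clutter filter** — the frame stack becomes a Casorati matrix
   (pixels × frames); rebuilding from singular components in
   `(low_cut, high_cut]` removes slow tissue signal.
2. **Localization** — supra-threshold blobs pass area/eccentricity gates
   and are localized by the intensity-weighted centroid,
   `x̂ = Σ Iᵢxᵢ / Σ Iᵢ`, to sub-pixel precision.
3. **Tracking** — localizations in consecutive frames are paired within a
   700 µm search radius when the normalized cross-correlation of their
   image patches is ≥ 0.9; step speed is `|Δx| · f · 10⁻³` mm/s.
4. **Metrics** — tortuosity = path/chord per track; diameters from
   skeleton + distance transform of the super-resolved map; fractal
   dimension from box counting (slope of log N(s) vs log 1/s);
   MVD = tracked-bubble area / ROI area.
5. **TIC analysis** — PI = (peak − baseline)/baseline, TTP = t(peak) −
   t(arrival), AUC, wash-in/wash-out slopes.
6. **Diagnostics** — chi-square / Fisher / t / Mann–Whitney group
   comparisons, Cohen's kappa, logistic regression (Wald, OR, CI), ROC with
   AUC by the Mann–Whitney identity and DeLong CI, per-modality-combination
   models.

## Worked example

```python
from ulmkit import (VesselTreeConfig, accumulate_density_map, localize_stack,
                    make_vessel_tree, render_frames, simulate_mb_flow,
                    svd_clutter_filter)

tree = make_vessel_tree(VesselTreeConfig(n_segments=3, seed=1))
gt = simulate_mb_flow(tree, density=2, n_frames=300, frame_rate_hz=80.0, seed=2)
stack = render_frames(gt, clutter_amplitude=5.0, noise_sd=0.02, seed=3)

filtered = svd_clutter_filter(stack, low_cut=1)
locs = localize_stack(filtered, threshold="mean+3sd")
sr = accumulate_density_map(locs, stack.fov_um, stack.pixel_size_um, 10)
print(len(locs), (sr.counts > 0).sum())
```

Running `examples/01_phantom_and_reconstruction.py` (which adds a
distance-to-centerline check) prints:

```
rendered 300 frames of (128, 128) at 80 Hz, 50 um pixels
1531 sub-pixel localizations (5.1 per frame)
SR map: (1280, 1280) bins at 5 um, 1529 occupied
median localization distance to nearest centerline: 24.4 um (vessel radii 20-60 um)
```

1531 microbubbles were localized on a 5 µm super-resolution grid — a 10×
finer lattice than the 50 µm pixels — and their median distance to the true
vessel centerlines (24.4 µm) sits inside the vessel lumina, i.e. the
reconstruction resolves structure well below the diffraction-limited PSF
(σ = 150 µm).  The other scripts in `examples/` walk through tracking and
velocity recovery, the per-lesion metrics record, TIC descriptors, and the
diagnostic statistics; each prints the numbers it computes and what they
mean.

A thin CLI wraps the same library for shell use:

```bash
ulmkit simulate --seed 1 --out out/
ulmkit reconstruct --input out/phantom.tif --out out/
ulmkit stats --table microcalcification --out out/   # chi2 = 6.770
```

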