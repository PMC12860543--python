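# ctless

Transmission-less attenuation compensation (AC) for myocardial perfusion
SPECT, with a complete task-based evaluation framework on synthetic digital
phantoms.

Attenuation compensation improves the clinical interpretation of cardiac
SPECT, but conventionally requires a co-registered CT scan — extra dose,
extra cost, and misregistration artifacts, and most SPECT systems have no CT
at all. This package implements an AC method that needs only the emission
data: because the probability of scatter at a location is proportional to
the attenuation there, an OSEM reconstruction of the *scatter*-energy-window
projections (`f_sc = R(g_sc)`) carries contrast between attenuation regions.
A multi-channel-input, multi-decoder 3-D U-net segments that initial
estimate — assisted by the photopeak reconstruction `f_pp = R(g_pp)` — into
K = 6 attenuation regions `{Phi_k}` (skin/adipose, muscles and organs,
lungs, bones, patient table, background), and the attenuation map is
assembled with predefined per-region coefficients,

    mu_hat = sum_k  mu_k * Phi_hat_k ,      mu_k = [0.13, 0.16, 0.03, 0.22, 0.09, 0] cm^-1,

then used for attenuation-compensated reconstruction `f_hat = R_mu(g_pp)`.

For whom: researchers in emission-tomography reconstruction and model-observer
evaluation who want a self-contained, CPU-scale testbed of the method — the
forward model, the network, and the entire defect-detection study
(projection-domain defect insertion, channelized Hotelling observer with
rotationally symmetric frequency channels, cluster-aware ROC/AUC inference,
non-inferiority testing, RMSE/SSIM) are all here and run on synthetic
subjects generated by the package itself.

## Worked example

```python
import numpy as np
from ctless.phantom import PhantomParams, generate_phantom
from ctless.projector import (AcquisitionGeometry, SpectProjector,
                              add_poisson_noise, make_projection_set)
from ctless.recon import osem, butterworth_filter, extract_cardiac_roi
from ctless.defects import DefectSpec, insert_defect, defect_centroid
from ctless.mumap import segment_groundtruth, assemble_mu
from ctless.observer import make_rsf_channels, apply_channels

params = PhantomParams.for_grid(48)            # 48-voxel grid, 0.68 cm voxels
phantom = generate_phantom(params, seed=7)
geom = AcquisitionGeometry(n_bins=48, bin_size_cm=0.68)
proj = make_projection_set(phantom, geometry=geom)   # photopeak + scatter windows
print(f"views x bins x slices: {proj.photopeak.shape}, "
      f"scatter/photopeak counts: {proj.scatter.sum() / proj.photopeak.sum():.2f}")

system = SpectProjector(geom, 48, 0.68, mu=phantom.mu)         # AC system model
defect = DefectSpec(extent_deg=60, severity_frac=0.25, location="inferior")
lesioned = insert_defect(proj, phantom, defect, projector=system)
noisy = add_poisson_noise(lesioned.photopeak, 1e6 / proj.photopeak.sum(), seed=1)

recon = osem(noisy, system, n_iterations=8, n_subsets=6)       # AC reconstruction
smooth = butterworth_filter(recon, order=5, cutoff_cycles_per_cm=0.44)
roi = extract_cardiac_roi(smooth, defect_centroid(phantom, defect),
                          phantom.lv_wall_mask())
channels = make_rsf_channels(grid=32, pixel_cm=0.68)
print(f"ROI range: [{roi.pixels.min():.0f}, {roi.pixels.max():.0f}], "
      f"channel features: {np.round(apply_channels(roi, channels), 1)}")

seg = segment_groundtruth(phantom.mu, table=phantom.table)     # exact on noiseless mu
mu_hat = assemble_mu(seg, phantom.table).mu_hat
print(f"attenuation-map RMSE after segmentation round trip: "
      f"{np.sqrt(np.mean((mu_hat - phantom.mu) ** 2)):.4f} cm^-1")
```

Output:

```
views x bins x slices: (30, 48, 48), scatter/photopeak counts: 0.53
ROI range: [0, 242], channel features: [297.1  -9.7  -4.2  -2.5]
attenuation-map RMSE after segmentation round trip: 0.0000 cm^-1
```

The projection set follows the clinical acquisition (30 views over 180
degrees, 45-degree RAO to 45-degree LPO; Tc-99m photopeak 126-154 keV and
scatter window 114-126 keV; system resolution 0.74 cm FWHM at 10 cm); the
scatter-to-photopeak count ratio of ~0.5 is typical for this isotope. The
25%-severity inferior defect lowers counts inside the extracted 32x32
cardiac region, which the four octave-spaced frequency channels summarize as
a feature vector for the Hotelling observer. The noiseless segmentation
round trip is exact because the phantom's attenuation values equal the
predefined coefficients.

## End-to-end observer study

```bash
ctless run --out results/ --seed 5          # train + 3-arm study + report
```

trains the segmentation network on its own synthetic cohort and compares
three reconstruction arms — AC with the phantom's true attenuation map, AC
with the scatter-window-estimated map, and no AC — on the defect-detection
task (27 defect types x 10 defect-present subjects + 10 defect-absent
subjects), writing `report.json`, per-sample scores and ROC curves. The
report carries each arm's AUC with a cluster-aware 95% CI, the AUC
differences with CIs, the non-inferiority decision at a margin of 5% of the
reference-arm AUC, Bonferroni-corrected superiority tests against the no-AC
arm, AUCs stratified by defect extent and severity, and RMSE/SSIM of each
arm against the true-map arm with bootstrap CIs.

Individual stages are also exposed on the command line: `ctless phantom`,
`ctless project`, `ctless recon`, `ctless mumap assemble`,
`ctless defects insert`, `ctless train`, `ctless infer`, `ctless observe`.
Volumes are NIfTI; projection sets are HDF5 containers with datasets
`/photopeak` and `/scatter` (views x bins x slices) and the acquisition
geometry in root attributes.

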