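# cardioem

Quantitative analysis of correlative multiscale cardiac imaging: serial
block-face scanning electron microscopy (SBF-SEM) volumes of embryonic heart
tissue, and the whole-heart micro-CT context they were sampled from.

The package is aimed at microscopists and cardiac-development researchers who
have (a) aligned 3D EM stacks with organelle segmentations — produced by any
external tool — and (b) micro-CT-scale label volumes of whole hearts, and who
want reproducible, scriptable versions of the standard quantifications:

* **Stereological volume fractions.** Per image (or cropped image portion)
  the total evaluated area *S*<sub>T</sub> and the areas of extracellular
  space (*S*<sub>E</sub>), nuclei (*S*<sub>N</sub>), mitochondria
  (*S*<sub>Mit</sub>) and myofibrils (*S*<sub>Myo</sub>) are exact voxel
  tallies; derived quantities are the extracellular fraction
  *S*<sub>E</sub>/*S*<sub>T</sub> and the organelle fractions
  *S*<sub>i</sub>/(*S*<sub>T</sub> − *S*<sub>E</sub>), i ∈ {N, Mit, Myo},
  which normalize organelle content to the cellular area. Stacks are
  subsampled with an every-*k*th-slice rule and aggregated to mean ± SD.
* **Myofibril orientation.** The myofibril mask is split into connected
  components; each object's axis is the principal eigenvector of the
  covariance of its voxel *physical* coordinates (the 4× anisotropy of the
  sectioning axis is corrected before any angle is measured). The transmural
  angle θ is the axis's x–y projection angle against the circumferential
  (+x) direction (θ = 0° wall-parallel, θ = 90° radial); the elliptical
  angle Φ is the x–z projection angle (Φ = 90° longitudinal). Angles are
  folded axial quantities on [0°, 180°), binned into 18 × 10° histograms,
  and summarized with linear or circular-axial mean/SD.
* **Ventricular morphometry.** LV/RV lumen volumes and their RV/LV ratio
  from micro-CT-scale label volumes.
* **Preprocessing.** Translation-only stack alignment by chained
  cross-correlation, per-slice non-local-means denoising, and affine
  grayscale matching between samples.
* **Segmentation utilities.** Intensity thresholding of the extracellular
  phase, morphological cleanup, ingestion of externally produced label
  volumes, and a pixelwise per-class accuracy evaluator.
* **Correlative registration.** Landmark-based least-squares similarity
  transforms (scale, rotation, translation) chaining EM sub-ROI frames back
  into the micro-CT frame.
* **Synthetic phantoms.** Seeded generators for EM-like volumes (cylindrical
  myofibrils with controlled folded-normal θ/Φ distributions, ellipsoidal
  nuclei, mitochondrial blobs, an extracellular phase of controlled volume
  fraction, realistic intensities and noise) with exact ground-truth labels
  and angle tables, and for two-chamber heart label volumes with controlled
  RV/LV lumen ratios. Every analysis operation is validated against these
  ground truths.

## Worked example

```python
import cardioem as ce

# a seeded EM-like phantom: 60 myofibrils, theta ~ folded-N(45, 32),
# phi ~ folded-N(70, 36), 20% extracellular space
params = ce.EmPhantomParams(seed=42, n_myofibrils=60,
                            theta_mean=45, theta_sd=32,
                            phi_mean=70, phi_sd=36)
phantom = ce.generate_em_volume(params)

# area fractions on every 10th slice, aggregated
agg = ce.aggregate(ce.fractions_over_stack(phantom.labels, stride=10))
for q, s in agg.stats.items():
    print(f"{q:20s} mean {s['mean']:.3f}  sd {s['sd']:.3f}  (n={s['n']} slices)")

# per-myofibril transmural angles
objects = ce.split_objects(phantom.labels.mask(ce.CLASS_MYOFIBRIL),
                           phantom.labels.geometry)
theta = ce.angle_table(objects)["theta_deg"].to_numpy()
summary = ce.angle_summary(theta, mode="circular-axial")
print(f"transmural angle: axial mean {summary.mean_deg:.1f} deg, "
      f"SD {summary.sd_deg:.1f} deg over {summary.n_objects} myofibrils")

# a two-chamber heart phantom built at RV/LV = 0.6
heart = ce.generate_heart_phantom(ce.HeartPhantomParams(seed=42))
print("RV/LV lumen ratio:", round(ce.ventricle_volume_ratio(heart)["rv_over_lv"], 3))
```

prints

```
ec_fraction          mean 0.215  sd 0.041  (n=11 slices)
nucleus_fraction     mean 0.020  sd 0.040  (n=11 slices)
mito_fraction        mean 0.010  sd 0.006  (n=11 slices)
myofibril_fraction   mean 0.012  sd 0.008  (n=11 slices)
transmural angle: axial mean 48.1 deg, SD 23.7 deg over 60 myofibrils
RV/LV lumen ratio: 0.6
```

The extracellular fraction tracks the generator's 0.20 target; the recovered
axial mean/SD track the sampling distribution (45°, 32°) at n = 60; the
measured lumen ratio matches the phantom's analytic ellipsoid ratio of 0.6.

## Command line

Each pipeline stage is also a subcommand taking `--config` (YAML with a
mandatory `seed`), `--seed` (override) and `--out`:

```sh
cardioem simulate   --config config.yaml --out sim/
cardioem preprocess --config config.yaml --stack sim/intensity.tif --out pre/
cardioem segment    --config config.yaml --stack sim/intensity.tif \
                    --method quantile --quantile 0.2 --truth sim/labels.nrrd --out seg/
cardioem fractions  --config config.yaml --labels sim/labels.nrrd --stride 50 --out frac/
cardioem orient     --config config.yaml --labels sim/labels.nrrd --out orient/
cardioem heartratio --config config.yaml --labels sim/heart_labels.nrrd --out hr/
cardioem register   --config config.yaml --source em.csv --target ct.csv --out reg/
```

Intensity stacks are multi-page TIFF; label volumes are NRRD (or uint8 TIFF);
angle tables and landmark files are CSV; summaries are JSON. Every run logs
its config hash, seed, package versions and input digests.

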