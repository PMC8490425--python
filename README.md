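# hsifuse

Registration and spectral fusion of dual-camera hyperspectral images.

Broadband hyperspectral imaging of biological tissue needs two sensor
technologies: a silicon (CCD/CMOS) push-broom camera for the
visible/near-infrared range (**VNIR**, ~400–1000 nm) and an InGaAs camera
for the near-infrared (**NIR**, ~900–1700 nm). The two cubes differ in
spatial resolution, viewing geometry and per-band reliability, so merging
them into one wide-spectrum cube — e.g. to delineate tissue structures
during surgery, where some chromophores absorb in the visible range and
others only reveal themselves in the NIR — takes three steps, all
implemented here:

1. **Spatial registration.** The NIR image (*moving*) is mapped onto the
   VNIR frame (*fixed*). Both intensity-based registration (mean-squares
   over a multi-resolution pyramid) and feature-based registration
   (scale-covariant blob or stable-extremal-region detectors, ratio-test
   matching, and **MSAC** — an M-estimator Sample Consensus with truncated
   squared-error cost — for robust estimation of translation / similarity
   / affine / projective models) are provided, along with a coarse-to-fine
   search over spectral band pairs scored by SSIM, mutual information or
   Pearson correlation.
2. **Operating-bandwidth selection.** Push-broom sensors are noisy at
   their spectral extremes. From two repeat captures *a, b* of a static
   scene the per-band **relative difference**
   `RD = 100·|a − b| / ((a + b)/2)` is averaged over pixels; the band
   mean of that curve is the threshold, and the first/last bands that stay
   below it for a run of consecutive bands become the initial/final
   cutoff wavelengths of each camera.
3. **Spectral fusion.** Each cube is cropped to its operating bandwidth,
   the NIR cube is bilinearly upsampled to the VNIR raster, a per-pixel
   **reflectance offset** (edge-band mean difference) levels the NIR
   segment onto the VNIR segment, and the two segments are concatenated
   with an explicit wavelength **gap** that is never interpolated across.
   Finally each pixel spectrum is min-max normalized to [0, 1].

A synthetic dual-camera scene generator (`hsifuse.synthetic_scenes`)
provides registration targets with known projective misalignment, flat
reference panels with injected bathtub-shaped sensor noise, and
plastic-like scenes whose *color* structure lives below 900 nm and whose
*material* absorption features live above 956 nm — so the whole pipeline,
including the segmentation/classification harness
(`hsifuse.evaluation`: K-means / K-medoids / hierarchical K-means with
Jaccard cluster selection; SVM / random forest / KNN with validation-set
hyperparameter search; paired Student's t-tests), is testable without any
proprietary data.

## Worked example

```python
from hsifuse import SceneSpec, make_plastic_scene, compare_modalities
from hsifuse.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(scene_kind="plastic", scene_seed=1, technique="true",
                     cutoff_mode="fixed", vnir_cut_nm=(430.0, 901.0),
                     nir_cut_nm=(956.0, 1650.0), output_dir="demo_out")
manifest = run_pipeline(cfg)
fuse = manifest["stages"]["fuse"]
print(f"fused bands: {fuse['band_count']} "
      f"(boundary at {fuse['segment_boundary']}), gap {fuse['gap_nm']} nm, "
      f"mean offset {fuse['mean_offset']:+.3f}")

scene = make_plastic_scene(SceneSpec(seed=1))
report = compare_modalities(scene, method="svm", seeds=(1,))
for problem, means in report.means.items():
    print(problem + ": " + "  ".join(f"{d}={v:.3f}" for d, v in means.items()))
```

prints

```
fused bands: 145 (boundary at 94), gap [899.1596638655462, 967.7966101694915] nm, mean offset +0.029
color: VNIR=1.000  NIR=0.490  FUSED=1.000
material: VNIR=0.307  NIR=1.000  FUSED=1.000
material_color: VNIR=0.312  NIR=0.641  FUSED=1.000
```

The fused cube keeps 94 VNIR bands and 51 NIR bands of the desk-scale
grids with the excluded interval recorded as metadata, and the benchmark
reproduces the designed structure of the scene: color is only resolvable
from the VNIR range, material only from the NIR range, and the joint
material-color problem needs the fused spectrum — the classifier on
either single modality collapses to the colliding classes (0.31 / 0.64
accuracy) while the fused data separates all combinations.

The same stages are scriptable from a shell:

```sh
hsifuse simulate plastic --seed 1 --out-dir scenes
hsifuse register scenes/plastic_0001/vnir.raw scenes/plastic_0001/nir.raw
hsifuse fuse vnir_roi.raw nir_roi.raw --out fused.raw
hsifuse compare --seed 1 --method svm
hsifuse run --config pipeline.yaml
```

Cubes are read and written as ENVI raw + text header (BSQ/BIL/BIP,
little-endian); label maps as palette PNG + JSON sidecar; transforms and
manifests as JSON.

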