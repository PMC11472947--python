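# vascprint

Whole-organ vascular quantification for contrast-perfused micro-CT.

Organs perfused with a radiopaque casting agent (Microfil, Vascupaint) show
their blood vessels as bright tubular networks in μCT volumes. `vascprint`
turns such a volume into three quantities:

1. **Total organ volume** — inclusive intensity thresholding, selection of
   the largest connected object, filling of interior pores ("black
   speckles"), morphological closing, and voxel counting.
2. **Vascular volume** — denoising, vessel binarization (global intensity
   range or locally adaptive mean-offset threshold), restriction to the
   organ, removal of noise islands ("white speckles"), closing, counting.
3. **The vascular fingerprint** — the distribution of vascular volume over
   vessel diameter. Each vessel voxel is assigned a local diameter: the
   diameter of the largest sphere fully inscribed in the vessel mask that
   covers the voxel (structure thickness in the sense of Hildebrand &
   Rüegsegger). Voxel volumes are binned by diameter in uniform bins
   (default 10 μm at 5 μm voxels, half-open `(edge−w, edge]`); the summed
   volume of vessels up to a 400 μm diameter cap defines the organ's total
   vascular volume (100%), and per-bin fractions of that total form an
   organ-characteristic curve: its **peak diameter** and **half-volume
   diameter** (smallest diameter containing half the vascular volume)
   differ markedly between heart, brain, kidney, eye, and tongue.

Because real perfused-organ scans are large and rarely redistributable, the
package ships a first-class synthetic-data module: packed tube beds whose
ground-truth diameter distributions match the published per-organ anchors,
branching-tree phantoms with exact per-branch volume tables, a bar-pattern
resolution phantom, and a degradation model (Gaussian PSF for the focal
spot, radial cupping, additive noise) that reproduces, in silico, how lower
scan resolution depletes the small-diameter end of a fingerprint.

Intended users: preclinical imaging labs quantifying vascular remodelling,
and method developers who need a tested, oracle-verified local-thickness
implementation with controllable ground truth.

## Worked example

Generate a synthetic eye phantom, image it with a 4 μm PSF and mild noise,
and run the full analysis:

```python
import vascprint as vp

spec = vp.organ_preset("eye")                       # ground-truth geometry
vessels_true, true_diam, branches = vp.make_tree_phantom(spec)
tissue = vp.ellipsoid_mask(spec.grid_shape, spec.voxel_size_um,
                           spec.organ_envelope_um)
scan = vp.render_scan(vessels_true, tissue,
                      vp.ImagingSpec(psf_sigma_um=4.0, gaussian_noise_sd=8.0,
                                     seed=1))

cfg = vp.OrganConfig(organ_name="eye", total_threshold=(30, 255),
                     vessel_threshold_mode=("global", 130, 255),
                     white_speckle_min_voxels=27)
summary, fp, parts = vp.analyze_organ(scan, cfg)
print(f"organ volume        : {summary.total_organ_volume_mm3:.3f} mm^3")
print(f"vascular volume     : {summary.total_vascular_volume_mm3:.4f} mm^3 "
      f"({summary.vascular_fraction_pct:.2f}% of the organ)")
print(f"peak diameter       : {summary.peak_diameter_um:.0f} um "
      f"({summary.peak_fraction_pct:.1f}% of vascular volume)")
print(f"half-volume diameter: {summary.half_volume_diameter_um:.0f} um")
print(fp.to_frame().head(6).to_string(index=False))
```

Output:

```
organ volume        : 0.419 mm^3
vascular volume     : 0.0136 mm^3 (3.25% of the organ)
peak diameter       : 30 um (20.8% of vascular volume)
half-volume diameter: 40 um
 bin_upper_um  volume_mm3  fraction_pct
         10.0    0.000333      2.445136
         20.0    0.002242     16.464282
         30.0    0.002834     20.805683
         40.0    0.001871     13.738286
         50.0    0.002068     15.182972
         60.0    0.001472     10.804857
```

The recovered peak sits at 30 μm — the diameter where ocular vasculature
concentrates its volume — and half the vascular volume lies in vessels of
40 μm or less, despite blur and noise. `fp.excluded_volume_mm3` holds any
volume thicker than the 400 μm cap, which never enters the 100%
denominator.

The same pipeline is available from the shell:

```sh
vascprint simulate --preset eye --psf 4 --noise 8 --seed 1 \
    --out-volume eye.nii --out-truth truth.csv
vascprint segment --input eye.nii --config organ.yaml \
    --out-vessels vessels.tif --report report.csv
vascprint thickness --mask vessels.tif --voxel 5 --out thick.tif
vascprint fingerprint --thickness thick.tif --vessels vessels.tif \
    --voxel 5 --out fingerprint.csv
```

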