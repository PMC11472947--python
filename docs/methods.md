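# Methods

## The analysis model

`vascprint` quantifies contrast-perfused organs in reconstructed μCT
volumes. A volume is a 3-D scalar grid in fixed (slice, row, column) order
with one isotropic voxel size in μm; anisotropic input is rejected rather
than resampled. Intensities are treated as arbitrary units — vendor
calibration differs between systems, and every threshold in the pipeline is
a configuration parameter, not a constant.

The pipeline is a fixed composition with no hidden reordering:

1. **Total organ**: inclusive range threshold → largest 26-connected
   component → fill small interior background components ("black
   speckles", 6-connected, never filling components that touch the volume
   border — exterior air is not a pore) → morphological closing with a
   discrete Euclidean ball → volume = voxel count × (voxel size/1000)³ mm³.
2. **Vessels**: denoise (Gaussian with σ in voxels, or median with
   half-width in voxels, or none) → binarize (global inclusive range, or
   locally adaptive: voxel ≥ clipped-window mean + offset) → intersect
   with the organ mask → remove small foreground components ("white
   speckles", 26-connected) → closing → clip to the organ again → volume.
3. **Diameters**: per-voxel local thickness (below) → volume-weighted
   diameter histogram → fingerprint summary.

The thresholds are inclusive at both ends so boundary behaviour is exactly
testable. The vessel mask is forcibly a subset of the organ mask; this both
excludes bright wrapping material outside the tissue and keeps
`vascular volume ≤ organ volume` an invariant. An empty vessel mask is a
warning, not an error: failed perfusion is a valid biological outcome.

Closing is computed on a padded copy of the mask, so it equals the closing
in an unbounded background and is therefore genuinely extensive, including
at volume borders.

### Choice of thresholding mode per organ

Organs in which vessels of all calibres mix homogeneously segment well with
one global range (brain; the bundled tongue and eye presets follow it).
Organs with regions dominated by either large or small vessels (heart,
kidney) defeat any single cutoff, and their presets use the adaptive
mean-offset mode. The adaptive rule is deliberately the simplest defensible
one — local mean over a cubic window, clipped at borders, plus a signed
offset — and is parameterized so other variants can be added without
touching the pipeline.

The numeric values in the bundled presets (threshold ranges, despeckle
sizes, closing radii) are calibration starting points for 8-bit scans, not
measured constants; real studies must tune them per protocol. Only the
global/adaptive split per organ is treated as settled.

## Local thickness

The diameter of a vessel voxel is defined as the diameter of the largest
sphere fully contained in the vessel mask that covers the voxel — structure
thickness in the sense of Hildebrand & Rüegsegger, the definition vendor
3-D analysis suites compute, and the only one that yields a per-voxel
diameter distribution.

Discretization: a sphere of radius r centred on voxel c is the set of voxel
centres within Euclidean distance r of c; it is inside the mask iff every
covered voxel is foreground (voxel centres outside the grid are not
covered, so structures meeting the volume border keep their interior
thickness). Radii are quantized at half-voxel steps. Consequences: a single
isolated voxel has thickness one voxel; thickness is ≥ 1 voxel inside the
mask and exactly 0 outside; tube ends taper with no end-correction
(documented behaviour, visible as a small sub-peak one bin below a tube's
nominal bin).

Implementation: the Euclidean distance transform gives each foreground
voxel's distance d to the nearest background centre; the largest admissible
quantized radius is the biggest k/2 < d (squared grid distances are
integers, so the comparison is exact in floating point). For each distinct
radius, largest first, the centre set is dilated by the discrete ball —
with an explicit structuring element for r ≤ 3, via a distance transform on
the centre set's bounding box for larger r — and the diameter 2r is
propagated with a running per-voxel maximum.

A brute-force oracle (`thickness_oracle`) evaluates the definition directly
from explicit pairwise distances, sharing no code path with the distance
transform route, and the two are asserted **exactly equal** on hundreds of
random masks up to 32³. This equality, not the shape identities, is the
central correctness property: the identities (digital balls report their
diameter to within one voxel; cylinder cores report theirs) then only
confirm that the definition matches geometric intuition.

## The fingerprint

Bins are uniform, half-open `(edge−w, edge]`, labelled by the upper edge,
with default width 2 × voxel size (10 μm at 5 μm voxels) — the lattice on
which the organ peaks are conventionally reported. The 400 μm diameter cap
is then an exact bin boundary. Voxels thicker than the cap accumulate in
`excluded_volume_mm3` and never enter the 100% denominator (excluding, not
clamping, is the direct reading of the cap convention). Binned volume plus
excluded volume equals the vessel-mask volume exactly, and fractions sum to
100% whenever any sub-cap volume exists; both are enforced by tests, along
with exact re-summation under bin refinement.

Summary statistics: the peak is the fullest bin, ties resolved toward the
smaller diameter; the half-volume diameter is the smallest upper edge whose
cumulative fraction reaches 50% (a cumulative of exactly 50.0 counts).
Group aggregation uses the per-bin arithmetic mean and the sample (n−1)
standard deviation; with one subject the deviation is reported absent, not
zero. Fingerprint comparison returns per-bin differences (test − reference)
plus their summed absolute value as a scalar divergence.

## Synthetic data

The generator exists so that every stage is testable against known ground
truth without any scan download; its defaults emulate the study conditions
the pipeline targets — 5 μm isotropic voxels, vessels of ~15–400 μm inside
a darker ellipsoidal tissue envelope, 8-bit-scale intensity levels
(background 0, tissue 60, vessel 200).

**Geometry.** Straight cylinders (voxel centres within d/2 of the axis);
packed tube beds whose per-diameter target volumes follow organ-specific
weight tables; and recursive bifurcating trees with a fixed child/parent
diameter ratio (Murray-type exponents would change nothing in the
fingerprint math and are omitted), sinusoidal tortuosity, and branch length
10 × diameter, clamped to the envelope. Every voxel is claimed by exactly
one branch (parents first), so the per-branch table's summed volume equals
the mask volume exactly — the conservation the recovery tests rely on. Tube
axes snap to voxel centres so a tube carries its nominal diameter rather
than losing half a voxel to rasterization chance.

**Organ presets.** The five preset weight tables are anchored to the
published per-organ statistics: volume peaks at 20 (heart), 50 (brain),
110 (kidney), 30 (eye), 40 (tongue) μm, with half-volume diameters
respecting the printed bounds (< 80, ≤ 130, ≤ 110, ≤ 50, ≤ 100 μm
respectively). The full published curves are not reproduced — only these
anchors are claimed, and the tests assert exactly them, both on the ground
truth tables and end-to-end through the rendered pipeline. At the default
desk-scale grid (160×200×200 voxels, i.e. a 0.8×1×1 mm tissue block) the
largest diameter classes of a real organ cannot be represented — a single
400 μm vessel would exceed the whole phantom's vascular volume budget — so
the realized distributions are truncated above ~150–200 μm and the absolute
per-bin fractions renormalize accordingly. Peak location and half-volume
bounds survive this truncation; absolute fractions are not claimed.

**Imaging model.** Reconstructed-volume-level degradation: Gaussian blur
with σ in μm (the focal-spot PSF), an optional multiplicative radial
cupping bias that dims the centre by the given fraction, and additive
Gaussian noise from a seeded generator. This is deliberately not a
projection/reconstruction simulator: the fingerprint bias of interest —
PSF washout pushing thin vessels below the segmentation threshold — lives
entirely at the volume level. Beam hardening and ring artifacts are out of
scope. Consequently, passing tests demonstrate the pipeline's behaviour
under blur, noise, and smooth bias, but not under streak or ring artifacts,
motion, or contrast-agent inhomogeneity in real casts.

**Resolution phantom.** Bar groups with bar width = gap width. The physical
pattern is continuous, so for modulation experiments it is rasterized on a
5× finer grid, blurred there, and block-averaged to the detector voxel size
(partial-volume integration); binarizing at detector resolution first would
alias beat patterns into the profile and fake residual modulation. Guard
bars (2 + ⌈3σ/period⌉ per side) keep the pattern's blurred edge out of the
measured window. Modulation is Michelson-style, (peak−trough)/(peak+trough)
of the mean profile with one period trimmed at each end, and "resolved"
means modulation ≥ 0.1 — an explicit numeric convention standing in for
the visual judgement used with physical phantoms. With these conventions a
4 μm PSF resolves the 10 μm group and degrades the 8 μm group, and a 12 μm
PSF loses the 10 μm group, reproducing the qualitative resolution ordering
of low- vs high-power μCT protocols.

## Numerical conventions and degenerate inputs

- Foreground connectivity 26, background/hole connectivity 6 (the standard
  dual pair avoiding topological paradoxes); both overridable per call.
- Largest-component ties break toward the component met first in C-order
  scan; fingerprint peak ties toward the smaller diameter. Both are
  deterministic and tested.
- A mask with no background voxel gets distances capped at the grid
  diagonal + 1 in both thickness routes, keeping them consistent.
- Bin assignment uses `ceil(t/w − 1e−9)` so values landing exactly on an
  edge go to that edge's bin despite floating-point division.
- Analysis is fully deterministic: repeated runs on the same volume are
  bit-identical; all generator randomness flows from explicit seeds.

## Problem sizes in the test and acceptance runs

Oracle-equivalence checks use 100 random masks ≤ 32³ (the brute-force
oracle is cubic-time); recovery runs one 256³ rendered tree; the
degradation sweep a 128×160×160 tube bed at four PSF widths; morphological
contract properties 1000 random masks ≤ 12³; organ presets render at
160×200×200. These sizes keep the full suite under a minute of compute for
the property tests and a few tens of seconds for the end-to-end runs while
leaving every assertion at full strength.

## Known limitations

- Arteries and veins are indistinguishable in cast-perfused μCT; nothing
  here attempts it.
- No centerline/branching/tortuosity analysis — diameters only.
- Thickness at tube ends is genuinely smaller; studies comparing organs
  with very different vessel-length-to-diameter ratios should note the
  resulting leakage into the next-lower bin.
- The adaptive threshold is mean-offset only; Niblack/Sauvola-style
  variance terms are not implemented.
- Preset parameter values are placeholders pending calibration on real
  scans; only the global/adaptive mode assignment is asserted.
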