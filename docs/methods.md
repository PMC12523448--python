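# Methods

This note records the models, procedures and design choices behind
`cardiofab`, in the order the pipeline runs them.

## Scope and intent

The package reimplements a patient-specific cardiac modeling chain at
desk scale: labeled cardiac-CT-like phantoms, a coarse-to-fine
segmentation cascade with anatomical-prior fusion and spatial-channel
co-attention, Dice evaluation with a four-arm ablation, label-map to
STL surface extraction, dimensional-fidelity measurement of digital
versus (simulated) printed models, and embedded-printing G-code with
catalyst-ink accounting.  Everything runs on one desktop CPU core; no
GPU, no clinical data, and no printer hardware are involved.  The point
of the tests is therefore *mechanistic*: they show that each documented
effect (prior fusion helping small-vessel segmentation, ink accounting
closing at 25:1, fidelity arithmetic, slicing geometry) is reproduced
by this implementation under controlled synthetic conditions — not that
clinical-scale accuracy is attained.

## Phantoms

Chambers (LA, RA, LV, RV) are ellipsoids, vessels (SVC, IVC, PA, PV,
AA, DA) are capped cylinders; the layout keeps each vessel 6-connected
to its anatomical chamber (SVC/IVC→RA, PV→LA, PA→RV, AA→LV; DA is a
free posterior tube) by letting the tube penetrate two voxels into the
chamber and claim those voxels.  Default landmark diameters are the
reference digital-model values (e.g. LV 45.63 mm, SVC 18.38 mm); the
SVC length multiplier (1.45 diameters) puts the analytic LV:SVC volume
ratio near 10, the scale disparity that makes small-vein segmentation
hard.  `PhantomSpec.desk()` shrinks all diameters by one common factor
to fit a test grid (48³ by default), preserving every ratio.

Intensities are abstract pseudo-HU in 0–1000: background 150, structure
levels 400 + offset·300·`contrast_separation`.  The offsets are chosen
so that

* large structures are mutually separated by ≥ 0.2 offset units
  (18 pseudo-HU at the default contrast 0.3, ≈ 1.2× the noise SD of
  15) — identifiable, as chambers and arteries are in real CT;
* each small vein is an *intensity twin* of a large structure
  elsewhere in the volume (gap 0.05 ≈ 4.5 pseudo-HU, far below the
  noise floor): SVC and IVC twin the RV, PV twins the LV.  A voxel
  classifier cannot separate them; only spatial context — where the
  atria are — can.  This is the phantom's stand-in for the low-contrast
  small-vessel problem, and it is what makes the anatomical prior
  informative rather than decorative.

Gaussian noise (SD 15) is added, then an isotropic blur (σ 0.6 voxel).
Per-case anatomical variability (5% diameter jitter, sub-voxel position
jitter) is drawn from the case seed, so a seed fully determines a case.
Coordinates are 0-based (z, y, x) voxel indices; world position is
index × spacing in mm; an axial slice is a fixed-z plane.

What the phantoms do *not* model: pathological anatomy, contrast
enhancement, motion artifacts, scanner-specific intensity calibration,
and realistic chamber wall geometry.  Passing tests show the algorithms
behave as documented under the named difficulties (scale disparity, low
contrast, noise), not that they segment real CT.

### Case splitting

`split_cases` normalizes the ratios, gives each partition the floor of
its quota, and assigns leftover cases to the partitions with the
largest ratios first (training absorbs the extra case of a 117-case
6:2:2 split: 71/23/23).  The fractional-remainder variant would send
the extra case to a 23.4-quota partition instead; the largest-ratio
rule matches the published protocol sizes and is deterministic.

## Networks

No deep-learning framework is used: the encoder-decoders are written
directly in numpy (float32) with explicit backward passes, which keeps
training bit-deterministic per seed within a process.  Convolutions use
a shift-and-add formulation (27 small GEMMs over shifted views), which
benchmarked ~5× faster than an im2col matmul at these channel counts on
one CPU core.  Each conv block is conv–instance-norm–ReLU twice;
instance normalization is essential — without it these small nets
underfit catastrophically at any learning rate we tried.  Downsampling
is 2× max-pooling, upsampling nearest-neighbour, and the head a 1×1×1
conv.  Loss is an equally weighted sum of multiclass soft-Dice and
voxel cross-entropy, with the cross-entropy term weighted per class by
inverse square-root frequency — without it the rarest class (the PV,
five voxels across at desk scale) escapes the all-background optimum
only in a seed-dependent fraction of runs.  The optimizer is Adam at
lr 3·10⁻³ (1·10⁻³ demonstrably underfits at the iteration budgets used
here).  Training
samples one 32³ patch per case visit, centred 70% of the time on a
voxel of a uniformly drawn present foreground class, so rare targets
(the veins) are sampled as often as chambers.

### Cascade

* **LS-Net** (coarse): 8 classes (background + LA, RA, LV, RV, PA, AA,
  DA), width 8, depth 2, trained and evaluated on a 2× downsampled
  grid (the classic coarse-stage design; large structures survive
  half-resolution and the cost drops 8-fold).  Its softmax
  probabilities are nearest-neighbour upsampled to the full grid.
* **SS-Net** (fine): 4 classes (background + SVC, IVC, PV), width 6,
  depth 2, full resolution.  With prior fusion its input is the
  normalized image plus the seven coarse probability maps (channels
  ordered by substructure code); probabilities rather than hard labels
  are fused so the fine stage sees the coarse stage's uncertainty.
  Prior channels during training come from the trained LS-Net's own
  predictions on the training cases — the distribution it will see at
  test time — not from ground truth.
* **Merging**: the fine stage's non-background voxels overwrite the
  coarse labels (the refinement stage owns the hardest targets).
  Merged probabilities distribute the fine stage's background mass over
  the coarse classes, so they still sum to 1 per voxel.  Argmax ties
  break toward the lowest class code.

### Spatial-channel co-attention

Applied at the encoder-decoder junction of the fine net (skip tensors
plus bottleneck).  Channel branch: global-average-pooled descriptors of
*all* scales are concatenated, passed through one learned linear map
and a sigmoid, and redistributed, so each scale's channel weights
depend on every scale.  Spatial branch: channel-mean maps are resampled
to the coarsest grid, stacked, passed through a shared 3×3×3 conv and a
sigmoid, and upsampled back.  Output is `x·cw·sw + x`.  Both transforms
are zero-initialized, so an untrained module multiplies by
0.5·0.5 + 1 = 1.25 uniformly, and saturating the sigmoids gives exactly
2× — the two closed-form checks in the test suite.

## Ablation study

Four arms, identical data, seeds and sampler:

1. **baseline** — one full-resolution 11-class net with the fine net's
   width (capacity-matched single stage);
2. **two_stage** — LS-Net + prior-less SS-Net (image-only fine stage);
3. **prior** — + anatomical-prior fusion;
4. **prior_attention** — + co-attention.

Study conditions: 48³ desk phantoms, 20 training / 5 test cases, seeds
{0, 1, 2}, 24 epochs (480 patch iterations per network).  The coarse
net is trained once per seed and shared across the three cascade arms
(its training there is bit-identical; this is memoization, not a design
difference).  Earlier, shorter runs (240 iterations) left the prior
arms short of convergence on the PV — the smallest, rarest class —
while the image-only arm could luck into it through shape cues; the
480-iteration budget is the shortest at which all arms have flattened
loss curves.  Problem sizes were chosen so the full four-arm,
three-seed study runs in roughly a quarter hour on one CPU core.

A caveat the test suite makes explicit: at this fixture scale a 32³
training patch covers most of a 48³ volume, so the image-only fine
stage already sees much of the anatomical context that the prior
channels supply — the two middle arms sit close together, within the
seed noise of three-seed means (between-seed SD of an arm mean is an
order of magnitude larger than the 0.01 tie tolerance the ordering
check uses).  In data-poor probes (8 training cases) the prior arm's
advantage over the image-only cascade is unambiguous, and the full
model (prior + attention) is the strongest arm in the frozen study;
but the strict four-arm ordering at the 0.01 tolerance is not robust
at this scale, and the suite reports it faithfully rather than
averaging over more seeds until it passes.

## Dice evaluation

DSC = 2|G∩P| / (|G| + |P|).  Conventions fixed for stable averages: a
structure absent from both maps of a case scores 1.0, absent from
exactly one scores 0.0; the macro average is the unweighted mean over
the ten structures.  (A denominator of |G∪P| would give 2 for identical
masks and is inconsistent with the metric's stated [0, 1] range; the
standard denominator is used.)

## Meshing

Marching cubes at iso-level 0.5 on the one-voxel-padded binary mask
(padding closes masks that touch the grid boundary; the event is
logged), vertices scaled to mm — the voxel→mm conversion happens
exactly once, here — and reordered to (x, y, z).  Orientation is fixed
so signed volume is positive.  Optional smoothing is an umbrella-
operator Laplacian whose result is rescaled about its centroid to
restore the pre-smoothing volume exactly, so volume drift is nil while
surface area decreases on convex shapes.  STL is read and written at
byte level (80-byte header, uint32 count, 50-byte little-endian facet
records; ASCII dialect as well); reading merges duplicate vertices so
watertightness is checkable on the result, and parse errors carry the
byte offset.

## Dimensional fidelity

One measurement protocol per substructure mirrors the landmark table of
the reference model: maximum transverse (Feret) diameter at mid-atrium
for LA/RA, short-axis width (minimum over in-plane orientations, via
the minimum rotated rectangle) for LV/RV, and tube diameter
(perpendicular cut through the principal axis) for the six vessels.
Prose landmarks ("middle of the atrium", "papillary-muscle level",
"above the entrance") are realized as extent fractions along the cut
axis — 0.5 for mid-level, 0.65 for the basal RV cut — and are exposed
as protocol parameters since the source text gives prose, not
coordinates (parts of it are garbled, e.g. the SVC offset).

Repeats perturb the cut plane by N(0, jitter_sd) mm along its normal
and N(0, jitter_sd) degrees in orientation, emulating inter-observer
variability; mean ± SD is reported.  The "printed" model is simulated
by displacing mesh vertices along their normals with seeded Gaussian
noise (default SD 0.2 mm, the scale of surface irregularity on a
well-tuned embedded print); registering a real scanned print is out of
scope.  MAD = |pre mean − post mean| per landmark; the overall figure
is the unweighted mean of the ten MADs.  Re-deriving the MAD column of
the reference table from its own printed means reproduces 9 of 10
entries to 0.01 mm; the LA row prints 0.35 where the means give 0.34,
an upstream rounding the package does not reproduce — computed values
are reported.

## Slicing and G-code

Planar sections are taken at mid-layer heights z_min + (k + 0.5)·h
(symmetric volume error; standard slicer convention) by exact
mesh-plane intersection; rings are assembled into polygons with
even-odd nesting, exteriors counter-clockwise and holes clockwise.
Concentric infill offsets each perimeter inward by the line width, then
by line_width/density per loop, until the offset region vanishes (mitre
joins, so rectilinear parts offset exactly).  Loops print
outermost-first per island, islands in nearest-neighbour order, and
each loop starts at its lowest-then-leftmost vertex, making the output
deterministic.  No supports, brims or retractions exist — in embedded
printing the matrix is the support and the needle stays immersed.

Ink accounting: an extruding segment of length L deposits a track of
volume L·line_width·layer_height; dispensed ink is `extrusion_rate`
(default 4%) of that, carried in the E word as cumulative mm³ (declared
in the header).  The construct:ink ratio is therefore exactly
1/extrusion_rate = 25:1.  All coordinates are quantized to the printed
precision (4 decimals) *before* totals are accumulated, so
`resimulate` — an independent parser that replays the program text —
reproduces the emitter's totals to round-off.  The preamble lifts the
platform to a configurable clearance height before homing so the needle
cannot strike the matrix container (emission refuses a clearance below
the container height), and the postamble restores it.  Programs whose
ink volume exceeds the reservoir capacity (default 100 mL) emit a
warning with the number of refills required.

Known geometric bias: the perimeter loop runs on the section contour
itself, so half its track width lies outside the ideal solid; for a
10 mm cube at 100% infill the deposited volume reconstructs the solid
volume to about +6%, well within the ±15% band the volume-conservation
check allows for perimeter and corner effects.

## Pipeline

`run_pipeline` executes phantom → split → train → predict → evaluate →
mesh → measure → slice, every stage seeded from the global seed, and
writes a manifest of SHA-256 content hashes; a failed stage aborts
downstream stages but the partial manifest is still written.  All
artifacts are deterministic (uncompressed NIfTI, CSV, STL, G-code,
JSON), so re-running a configuration reproduces identical hashes.
DICOM import reads one series (mixed series are rejected), sorts slices
by position, applies slope/intercept rescaling, and takes spacing from
the PixelSpacing tag and inter-slice distance.

## Numerical and degenerate-input choices

* Soft-Dice epsilon 10⁻⁵; both-empty Dice defined as 1.0.
* Probability maps validated to sum to 1 per voxel within 10⁻⁵.
* Max-pool gradient splits evenly across tied maxima (keeps the
  finite-difference gradient check exact away from ReLU kinks).
* A single isolated voxel meshes to a closed surface of positive
  volume; an empty label raises.
* Layers whose plane misses the mesh are skipped; regions narrower than
  one line width get no infill.
* `epochs = 0`, fewer than 2 training cases, non-binary masks, grid
  mismatches, and clearance below container height are rejected with
  specific errors; a class absent from all training cases warns and is
  kept.

## Known limitations

* The segmentation networks are orders of magnitude smaller than
  clinical models; absolute Dice values at 48³ are not comparable to
  values from GPU-scale training on real data, and the PV — five
  voxels across at desk scale — remains the hardest target.
* The co-attention block's benefit at this scale is small compared to
  seed noise; the ablation asserts ordering with a tie tolerance, not a
  strict gain.
* The simulated print perturbs geometry only along vertex normals; real
  prints also warp globally, which the fidelity protocol would detect
  but the simulator does not generate.
* The slicer handles one mesh per program (substructures print
  separately) and only concentric infill.
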