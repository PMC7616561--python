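# Methods

`echo2vox` is a synthetic workbench for studying 3D whole-heart
reconstruction from 2D echocardiographic standard views. It covers the
whole loop: generating labeled heart-like meshes, extracting the nine
standard view planes and their segmentation masks, synthesizing
pseudo-ultrasound appearance, training multi-view voxel-reconstruction
networks, and scoring them with the thresholded intersection-over-union
(IoU) protocol. This note records the models, the defaults, and the design
choices that were genuinely open.

## Synthetic heart generator (`heartgen`)

Each heart is a set of closed, watertight triangle surfaces with per-face
labels: LV endocardium and epicardium, right ventricle, both atria, and
three valve bodies. Units are millimetres; the long axis is `z` with the
apex toward `-z`.

The LV myocardium is the region between two exact truncated ellipsoids.
The endocardium has semi-axes `(b, b, a)` with `a` = half the LV long axis
(default 90 mm) and `b` = half the short axis (default 50 mm); the
epicardium has semi-axes `(b + w_base, b + w_base, a + w_apex)` with wall
thicknesses `w_base` (default 12 mm) and `w_apex` (default 4 mm),
`w_apex < w_base` enforced. Giving the epicardium its own exact ellipsoid
makes the endo–epi separation taper smoothly from `w_base` at the base to
exactly `w_apex` on the axis, and keeps every epicardial vertex on an
analytic surface for testing. The epicardial truncation plane sits half a
base-wall-thickness above the endocardial one so that rays leaving the
valve region cross the two base caps in epi-then-endo order and are never
mistaken for a wall traverse (see the apex search below).

The LV surfaces are built on a latitude–longitude grid (default 24 x 48)
whose cut ring lies exactly on the truncation plane; the cap is a fan over
the ring with no interior vertices, so the closed surface carries no
off-ellipsoid points. The other structures are icospheres (default
subdivision 3) mapped to ellipsoids. Chamber and valve placement is a fixed
fraction of `a` and `b`, chosen so that all nine view planes are
well-conditioned (no collinear landmark triples).

Shape variation is seeded and two-fold: (1) multiplicative Gaussian jitter
with relative sd `jitter_sd`, clipped at 2 sd, on every length/scale
parameter; (2) a degree-≤2 real-spherical-harmonic radial perturbation per
structure with coefficient sd `0.05 * jitter_sd`. Clipping bounds the
worst-case vertex displacement between two seeds below
`4 * jitter_sd * lv_long_axis`. With `jitter_sd = 0` the seed is
irrelevant and generation is bit-reproducible. Radial perturbation
preserves the surface topology, hence watertightness, for the intended
`jitter_sd ≤ 0.15`.

The generator emulates a virtual cohort of healthy hearts: smooth,
artifact-free, exactly labeled anatomy. It does not emulate diseased
shapes, trabeculation, papillary muscles, valve leaflet geometry, or any
imaging artifact, so passing tests demonstrate pipeline correctness, not
performance on clinical data.

## Landmarks and the LV apex search (`viewslice`)

Landmarks are area-weighted surface centroids per structure (the LV point
uses endo+epi jointly). The LV apex is found by ray casting from the
mitral-valve centroid toward every LV face center (vectorized
Möller–Trumbore over the endo+epi triangles). Along each ray, hits are
sorted and deduplicated (1e-9 mm); the first endocardial crossing that is
*immediately* followed by an epicardial crossing bounds one traverse of
the myocardial wall. The apex is the midpoint of the shortest traverse and
its length is the apical wall thickness; ties within 1e-9 mm resolve to
the smallest face index. Requiring the endo-then-epi order makes the
search insensitive to cap crossings near the valve plane and to the source
sitting between the endocardial and epicardial base caps. If no ray yields
such a pair the geometry is reported as degenerate.

The tapered-wall construction guarantees the thinnest traverse lies near
the apex; tests verify the returned thickness against the configured
apical thickness (2%) and against an exhaustive 10^4-direction sweep using
an independently written intersector, with agreement required within one
mean face diameter (the resolution limit of a faceted surface).

## View planes

Six views are fit through three landmarks each (plane through the points,
origin at their centroid); the three parasternal short-axis levels use the
apex→mitral-centroid axis as normal, with origins at fractions 0.85
(mitral), 0.5 (papillary) and 0.2 (apex level) of that axis — the levels
are conventional anatomy and config-exposed. The landmark-to-view table is
implemented exactly as published, including its anatomically unusual
entries (the apical-2-chamber plane uses the RV centroid; the short-axis
aortic-valve plane uses both atria and the aortic valve). In-plane axes
are deterministic: `u` is the long axis projected into the plane (falling
back to global `x`, then `y`, for short-axis planes where the projection
vanishes) and `v = n x u`, so rasters are bit-reproducible.

## Slicing and rasterization

Each structure's closed surface is intersected with the plane
(`trimesh.intersections.mesh_plane`), giving a soup of 2D segments in
plane coordinates. A pixel is filled iff its center lies inside by the
even–odd (crossing parity) rule, evaluated directly against the segment
soup — no contour assembly is needed and the test is exact for closed
intersections. Binary masks fill the two LV surfaces *jointly*, so the
myocardium rasterizes as an annulus with the blood pool as background —
the echo-like reading of a tissue mask; all other structures fill solid,
and the mask is their union. Label mode paints structure ids in a fixed
order with innermost structures last. Pixels sit at half-integer offsets
on an `image_size`² grid covering `fov_mm` centered on the plane origin;
the default field of view is 1.2x the mesh bounding-sphere diameter so the
anatomy always fits with margin.

## Voxelization

Ground-truth occupancy is the *solid* union of all structures (blood pools
included): the reconstruction target is the whole-heart volume, which is
what the networks predict. The mesh is isotropically scaled into the unit
cube with a 5% margin; a voxel is occupied iff its center `(i + 0.5)/D`
lies inside a closed surface, decided by crossing parity along +z columns,
accumulated per triangle. Grid coordinates are nudged by ~1e-7 (fixed,
irrational-ish offsets) so columns never pass exactly through shared mesh
edges of this axis-aligned construction; the bias is orders of magnitude
below voxel size. Supported grids are 16³, 32³, 64³. A 2D mask and the
64³ grid resampled along the same plane agree on ≥ 90% of tissue pixels
(masks exclude blood pools that the solid target includes, so agreement is
checked on mask-tissue pixels only).

## Pseudo-ultrasound (`pseudous`)

Masks map to base intensities (tissue 0.7, background 0.05), then receive
mean-one lognormal multiplicative speckle (sd 0.3), additive Gaussian
noise (sd 0.05), and a normalized separable Gaussian blur (odd kernel,
default 5 px, sigma = width/4, reflect padding), in a configurable order
(default noise-then-blur), clipped to [0, 1]. No geometric transform is
applied, so the anatomy's centroid is preserved. The defaults are the
package's own, config-exposed choices; no claim is made that they match
any particular scanner's appearance. Style transfer to real ultrasound
texture is out of scope.

## Reconstruction networks (`epivox`)

All four variants share: a 2D residual encoder (depth 18 with basic
blocks for the fast tier, depth 50 with bottleneck blocks for the
accurate tier; channel widths scaled by `base_width`, default 16) applied
with shared weights to each view and reduced to a 256x2x2x2 feature
volume; and a transposed-3D-convolution decoder that doubles the spatial
extent per stage (channel schedule 128-64-32-8-1 for 64³, truncated from
the front for smaller grids), with kernel 3 (fast) or 4 (accurate) and a
sigmoid output. There is no normalization layer — at desk scale plain
conv+ReLU trains stably and keeps the stack small. All weights are
He-initialized from the spec seed; no pretrained weights are used or
required.

* **Parallel variant**: the shared-weight decoder runs per view; a small
  3D conv scorer (1→4→4→1, kernel 3) maps each coarse volume to a score
  volume; per-voxel softmax over views weights the coarse volumes into the
  fused volume (context-aware fusion). With identical duplicated views the
  weights are uniform and fusion is exactly the identity.
* **Efficient variant**: the per-view feature volumes are stacked along a
  view axis and collapsed by a convolution with 3 taps along the view axis
  and a 3³ spatial kernel, zero-padded, with a single kernel shared across
  all 256 feature channels (81 weights, initialized near the identity
  tap), followed by the mean over the view extent — so one decoder branch
  serves any view count up to the declared capacity. Sharing the kernel
  across channels keeps the fusion lighter in parameters than the parallel
  variant's scorer, which is what makes the single-decoder network
  strictly smaller as well as cheaper; channel-mixing fusion was the open
  alternative and was rejected for exactly that reason.
* **Refiner** (accurate tier only, both variants): a 3D encoder–decoder
  (1→8→16 down, 16→8→1 up, kernel 4, stride 2) with a skip connection,
  applied to the fused volume.

The networks run on an in-repo numpy reverse-mode autodiff with
conv2d/conv3d/transposed-conv3d primitives whose gradients are verified
against finite differences in the test suite.

### Cost accounting

`cost_report` counts parameters from the actual weight arrays and
multiply-adds analytically: output elements x kernel volume x input
channels for convolutions, input elements x kernel volume x output
channels for transposed convolutions, plus the per-voxel weighted sum of
context fusion. Encoder cost scales with the view count in both variants;
decoder and scorer cost scale with views only in the parallel variant.
Weights are shared across view branches, so parameter counts do not scale
with views in either variant.

## Training and evaluation protocol (`trainkit`)

Datasets split 70/15/15 train/val/test by seeded shuffle with
floor/floor/remainder rounding (1000 ids → 700/150/150). The loss is mean
voxel-wise binary cross-entropy, optimized by Adam with β₁ = 0.9,
β₂ = 0.999; learning rate 1e-3 and batch size 8 are the package's
config-exposed conventions. Accuracy is thresholded IoU — prediction
binarized at `value > t` against binary ground truth, with both-empty
defined as IoU 1 — reported per threshold (defaults 0.2/0.3/0.4/0.5) and
as the peak over thresholds. Percentage-difference tables are
`100 * (variant - baseline) / baseline` per cell, with zero baselines
flagged undefined; rounding precision is an argument because published
tables mix precisions.

## Desk-scale learning study (`experiments`)

The full published protocol (1000 meshes, 200 epochs, GPU) is replaced by
a fixed desk-scale study: 60 hearts (`jitter_sd = 0.08`, reduced mesh
resolution 18x36 / icosphere subdivision 2), the apical 2- and 4-chamber
binary masks at 32x32, 16³ ground truth, the efficient-fast network
(`base_width` 8, capacity 2 views), 30 epochs. Peak IoU on the held-out
30% is compared against the mean-training-volume predictor evaluated with
the same metric on the same split — the floor any learning method must
beat. Because each mesh is renormalized into the unit cube, the cohort's
targets overlap strongly and that baseline is high (~0.87–0.92); the
trained network exceeds it on every tested seed. These numbers are not
comparable to full-scale results and are not intended to be.

## Known limitations

* Anatomy is stylized (ellipsoidal chambers, disk-like valves); landmark
  geometry is realistic in scale but not statistically matched to any
  published cohort.
* The voxel ground truth is the solid whole heart; tissue-only (hollow)
  targets are not provided.
* Probe physics (sector fan, attenuation, shadowing) and style transfer to
  real ultrasound are out of scope; pseudo-ultrasound is mask + noise +
  blur only.
* The numpy networks are CPU-bound and meant for correctness and
  desk-scale studies, not for full-resolution training.
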