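# Methods

## Problem setting

A widefield (epifluorescence) microscope captures one full frame per
exposure, but its depth of field is much shallower than the relief of a
thick specimen, so any single frame leaves most of the surface out of
focus. Acquiring a z-stack — N co-registered frames at successive focal
planes spaced by less than the depth of field — guarantees every surface
element is in focus in at least one frame. The task is to decide, for
every image region, *which* frame that is: the winning index is both the
recipe for an all-in-focus composite and, via the known focal-plane
spacing, a per-pixel depth estimate of the specimen surface.

Two properties of the optics drive the design. First, a fluorescent
structure is brightest as well as sharpest in its in-focus frame, because
defocus spreads its emission over a larger area. Second, unlike a
confocal instrument there is no pinhole rejecting out-of-focus light, so
a bright structure smears into neighboring regions in frames focused far
from it. The smear is smooth: it raises local intensity but carries
almost no texture.

## Sharpness measure

Each frame is tiled into nonoverlapping rectangular blocks (default
15 × 15 px; the last row/column of blocks may be smaller and statistics
are always taken over the actual pixel count). For frame *i* and block
(*j*, *k*) the patch score is

    s[i,j,k] = m[i,j,k] · var[i,j,k]

where `m` is the maximum pixel value in the patch and `var` the
*population* variance (divide by the pixel count, not count − 1). The
product is the point of the method: out-of-focus spill can make a patch
bright (large `m`) but it is smooth (small `var`), while noise on a dark
patch can produce variance without brightness; only a patch that is
simultaneously bright and textured — i.e. in focus — scores highly. The
measure scales as a³ under an intensity scaling by a and is
translation-invariant in patch content.

Four classical measures are available under the same interface for
comparison (variance, variance/mean, mean |4-neighbour Laplacian| with
reflective borders, plain local maximum), plus the per-pixel maximum
projection used by confocal processing as a baseline. The Laplacian
variant is our own concrete formulation of a measure that is usually
cited without one; it is documented here as such and is swappable. The
normalized variance of an all-dark patch (mean 0) is defined as 0 — a
patch with no light carries no focus evidence.

## Depth map construction

The rough per-block depth is `index[j,k] = argmax_i s[i,j,k]`, with ties
broken toward the smallest frame index (deterministic and order-stable).
A binary confidence map gates everything downstream: a block is
*confident* only when the maximum pixel of its winning patch strictly
exceeds `threshold0` (default 60 on 8-bit data; intensity thresholds
scale with bit depth). Dim blocks fail the test precisely because their
apparent sharpness may be inherited from a neighbor's smeared light.

### Voting adjustment

The specimen surface is assumed continuous at the block scale, so a
block whose depth differs wildly from its confident neighborhood is
treated as contaminated. For every block, the confident blocks in the
(2·kernel+1)² surrounding window (clipped at the grid border, default
kernel 2 → 5 × 5 blocks) vote; a voter is *positive* when its index
differs from the center by more than `threshold1` (default 40 frames).
When positives outnumber `ratio` (0.5) of the voters and there are more
than `threshold2` (4) voters, the center index is replaced by the mean
index of the positive voters, rounded half-up. Design choices the
procedure's plain statement leaves open, fixed here:

* the replacement average is taken over the *positive* voters (the
  disagreeing confident majority is the evidence being trusted), center
  excluded;
* the pass is synchronous — all windows read the pre-pass map and write
  a fresh one — so the result does not depend on block scan order;
* a single pass is made, not an iteration to convergence.

Note `threshold1` is in frame-index units: its default suits stacks of
~80 planes, and a 20-plane stack (where no index pair can differ by more
than 19) needs a proportionally smaller value for the vote ever to fire.

After voting, every *unconfident* block takes the rounded mean index of
the confident blocks in the same window; an unconfident block with no
confident neighbor becomes *void* (sentinel −1 — not 0, which is a valid
frame index; void maps to depth 0 only on export).

### Per-pixel refinement (information filling)

One index per block produces seams wherever an object boundary crosses a
block. Pixels are first initialized to their block's index. Then every
edge-adjacent (4-connected) block pair whose indices differ by more than
`threshold3` (10) and with at least one confident member is examined: a
pixel in either block switches to the other block's index `x` when its
value in its current frame is below `threshold4` (80) *and* below its
value in frame `x`. The rationale mirrors the brightness property: a
pixel that truly belongs to the other side of the boundary is dim in the
frame its block chose and brighter in the neighbor's frame; a pixel
already bright in its own frame (≥ `threshold4`) is in focus where it is
and is never moved. Pairs are processed in raster order (horizontal then
vertical) with immediate updates, matching a sequential reading of the
procedure; pairs involving a void block are skipped, since a void block
has no frame to compare against.

The composite is assembled as `fused[p] = frames[pixindex[p]][p]` (void
pixels render as 0, the same convention as masked-out pixels in the
object-wise step), so before smoothing every non-void output pixel is a
bit-copy of one source pixel — a provenance invariant the tests enforce.

### Seam smoothing

Remaining block seams are softened by a Gaussian of width
`smoothing_sigma` (default 1 px) applied only inside a band of ±2 px
around block-grid lines at which the pixel index changes, in both the
fused image and the physical depth raster. The integer index map is
never smoothed — interpolating indices would invent source frames.
`sigma = 0` disables the step. Whether smoothing acts before or after
depth export is not dictated by the procedure; here it is the final
step and both smoothed and raw rasters are kept on the result object.

### Depth and point cloud

With frame-0 object distance `z0` and spacing `z_step` (µm),
`depth[p] = z0 + pixindex[p] · z_step` (negated stride for a descending
stack); void pixels export as depth 0, and point-cloud export drops them
entirely, writing one ASCII-PLY vertex `(col·pitch, row·pitch, depth)`
per remaining pixel.

## Object-wise fusion (optional)

When the field contains well-separated objects of different scales, one
global block size is a compromise. Objects are detected on the maximum
projection (the brightest evidence across depth) by thresholding and
spatial clustering — DBSCAN, its `min_samples=1` friends-of-friends
special case, or connected components. Each object's block size is the
largest entry of a candidate ladder (5, 10, 15, 20, 25) not exceeding
`max(5, min(bbox_h, bbox_w)/10)`; no principled scale-to-block-size rule
exists in the literature this follows, so this explicit monotone rule is
a documented, configurable stand-in and the module's main open choice.
Objects sharing a block size merge into a class, unassigned pixels join
the nearest class (Euclidean distance, ties to the smaller label, never
reassigning a labeled pixel), and the full pipeline reruns per class on
masked frames (outside pixels → 0) before the results are composited
through the masks and seam-smoothed once. With a single all-image class
the output is bit-identical (pre-smoothing) to the plain pipeline at
that block size. Seam smoothing of the composite uses the global block
grid; seams internal to a class at a different block size are left to
that class's own filling step.

## Synthetic scenes

No public epifluorescence focus-stack benchmark with per-pixel depth
truth exists, so correctness is established on rendered scenes. A scene
is a height map Z(p) in frame-index units plus an emission texture
E(p) ≥ 0; frame *i* renders as

    frame_i = clip( gain(·,i) · GaussianBlur(E, σ(·,i)) + noise ),  8-bit

with σ(p,i) = blur_rate·|i − Z(p)| and gain(p,i) = 1/(1 +
atten_rate·|i − Z(p)|). Blurring the *full* texture at each pixel's
defocus width means light from every structure, in-focus or not, lands
in every frame — the out-of-focus contamination the method must resist.
The spatially varying blur is realized per height level after quantizing
Z to 0.5-frame steps. Defaults, chosen once as plausible for a
high-magnification widefield system imaging at sub-depth-of-field
z-steps: blur_rate 2 px/frame, atten_rate 0.05 /frame (hyperbolic rather
than Gaussian falloff keeps dim regions nonzero at every plane, so
confidence thresholds stay exercisable), additive Gaussian read noise
(σ = 2 DN where a noisy scene is wanted, 0 in exactness fixtures),
Poisson shot noise not modelled. Renders are bit-reproducible from the
scene seed.

Scenes: `two_plane` (block-alignable depth step), `staircase` (four
terraces), `hemisphere` (spherical cap spanning the full depth range
over a dark background), and `blob_and_dim_texture` — a bright disc
(emission 200–255) at a deep plane ringed by a dim textured region
(emission 0–70) ten planes shallower. The ring geometry (24 px wide,
within the disc's defocus spread of σ = 20 px at the ring's in-focus
plane) is chosen from the blur model so that smeared disc light plus the
ring's own blurred texture exceeds most ring pixels' in-focus values in
off-focus frames: per-pixel brightest-frame selection then picks a wrong
frame on well over half the ring, while the block measure — seeing a
smooth bright spill with little variance against a sharp textured
in-focus patch — recovers the true plane on every ring block.

What the renderer does *not* emulate — a physical PSF (defocus is a pure
Gaussian here, no Airy rings or asymmetry), shot noise, registration
drift between frames, photobleaching across the stack, vendor noise —
bounds what passing tests show: they validate the algorithmic contract
(selection, voting, filling, bookkeeping) and the contamination
resistance mechanism, not photometric performance on any particular
instrument.

## Evaluation protocol and problem sizes

The repository's acceptance checks run the pipeline end-to-end on these
scenes at fixed sizes — 128 × 128 × 12 noiseless two-plane (exact
recovery on every confident block), 256 × 256 × 20 noisy hemisphere,
160 × 160 × 20 contamination scene — sizes at which every stage,
including partial edge blocks and all guard branches, is exercised while
a full run stays in seconds.

Depth-recovery error on the hemisphere is reported as RMSE in
frame-index units between the per-block recovered index and the
per-block mean of the true height map, over blocks where a single block
depth is meaningful: confident blocks lying entirely on the specimen
surface whose true height varies by at most one frame within the block.
Blocks off the specimen carry no surface (their nominal height 0 is the
void convention, not a measurable depth), yet a few of them near the rim
become confident purely through out-of-focus spill — the very artifact
the generator is required to produce — so including them would measure
the void convention, not recovery. Steep-slope blocks are excluded
because no single index can represent them; they are exactly the blocks
the information-filling stage exists to refine. Under this protocol the
measured RMSE (~0.4 frames) is dominated by argmax discretization.

## Numerical choices

* Working intensities keep their native integer range; all sharpness
  arithmetic is float64.
* Argmax ties → smallest frame index; voting/filling averages → rounded
  half-up (`floor(x + 0.5)`).
* Block statistics on edge blocks use the true pixel count.
* Window clipping at grid borders truncates the window (no padding).
* The scoring loop evaluates the same scalar measure functions the
  public API exposes, so the tensor is bit-identical to a naive
  per-patch loop — asserted, not assumed, in the tests.

## Known limitations

* Frames are assumed co-registered; there is no alignment step.
* A single voting pass cannot fix clustered contamination (two corrupted
  blocks inside one window can shield each other), and near object
  boundaries confident voters are scarce — block depths there lean on
  filling and smoothing instead.
* Depth resolution is one focal step; no sub-frame interpolation of the
  sharpness peak is attempted.
* Smoothing near void borders blends the depth-0 convention into the
  boundary band of the depth raster (the index map is unaffected).
* Intensity thresholds assume 8-bit-style units and must be rescaled by
  the user for 16-bit acquisitions.
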