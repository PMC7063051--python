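# Methods

This note records the scientific model behind each stage, the defaults and
why they were chosen, what the synthetic data does and does not emulate, and
the numerical choices a maintainer would want to know.

## Density simulation

A map is the sum over atoms of `exp(−‖x − x_atom‖² / 2σ²))` on a regular
grid. One σ is used for every atom regardless of element or B-factor — the
simulation deliberately reproduces the idealized training-data regime, not a
physical scattering model. σ follows the EMAN2-style criterion
σ = resolution/(π√2) (the Fourier amplitude of the Gaussian falls to 1/e at
spatial frequency 1/resolution); the convention is stored in the map
metadata and can be overridden per call. Gaussians are truncated at 4.5 σ
(relative error < 10⁻⁴ of peak). The grid covers the model's bounding box
plus 5 Å so tails are captured. Internal arrays are indexed `(x, y, z)`;
world position of voxel (i, j, k) is `origin + (i, j, k)·voxel_size`. MRC
files with permuted `MAPC/MAPR/MAPS` are normalized to this order on read
(via gemmi); the origin is taken from the `ORIGIN` header words, falling
back to `N*START · voxel`.

Label maps binarize by distance rather than by simulated label density:
a voxel is Cα-positive within 1.0 Å of a Cα, backbone-positive within 1.2 Å
of an N/Cα/C atom. Distance thresholds are resolution-independent and give
crisp cross-entropy targets; the radii roughly match the half-width of the
per-atom Gaussian at the resolutions of interest. SSE classes are assigned
to backbone voxels by the nearest residue's label; off-backbone voxels fall
into the loop class for training purposes (the catch-all "not helix, not
sheet"), which keeps every voxel inside the 3-class softmax.

## Normalization and cubing

Experimental-map preprocessing: resample to exactly 1 Å voxels (trilinear —
exact on linear fields; the new axis length is `floor((n−1)·vs) + 1` so the
sampled extent never leaves the original grid), then (1) zero voxels below
the user threshold, (2) divide by the median of the remaining *positive*
voxels, (3) cap at the 98th percentile of the positive voxels. Median and
percentile are over positive voxels because after thresholding the global
median is typically zero and would make the division meaningless. The
percentile cap is idempotent only up to percentile interpolation at the
clamp value (relative 10⁻³); tests account for this.

Cubes are 64³ with 50³ cores and a 7-voxel margin; cores tile the volume
disjointly (stride 50), the volume is zero padded (zero matches the
background of preprocessed maps), and stitching keeps only cores, making
split→stitch exactly the identity for any shape. Augmentation uses the four
axis-aligned rotations about z applied jointly to density and labels.

## The cascaded network

Three stages, each a four-layer 3D CNN: standard conv, two dilated convs
(rate 2) each followed by leaky-ReLU(0.1), and a standard conv head into a
softmax. Filters 32/64/64/n_classes; kernels 5³ for the SSE and backbone
networks, 4³ for the Cα network; all strides 1 with "same" zero padding so
output volumes are congruent with the input cube (for even effective
extents the extra padding voxel goes on the high side). Stage inputs:
density (1 ch) → SSE; density + 3 SSE confidences (4 ch) → backbone;
density + SSE + backbone (6 ch) → Cα. Both channels of the two-class heads
are forwarded. Confidences forwarded between stages carry gradients, so the
three networks train simultaneously; `stop_gradient=True` cuts them.

The implementation is pure numpy: convolution is evaluated as one GEMM per
kernel tap over shifted views of the zero-padded input, the backward pass
reuses the same loop for input and weight gradients, and training uses Adam
(lr 10⁻³, β = 0.9/0.999, batch = one cube). The learning rate is the
standard Adam default; at toy scale it halves the joint loss within a few
steps, which a much smaller rate does not. The joint loss is the sum of the
three per-voxel cross-entropies with inverse-frequency class weights
computed from the dataset (normalized to mean 1) — Cα-positive voxels are
two to three orders of magnitude rarer than background. The default
training length is 15 epochs.

Gradient correctness is verified against finite differences and the
convolution against `scipy.ndimage.correlate` in the test suite.

## Oracle confidence maps

To validate tracing and refinement independently of training quality, the
oracle generator produces the confidence maps an ideal network would emit:
per-atom Gaussian splats (σ = 0.8 Å, max-combined, each normalized so the
voxel nearest the atom reads exactly 1.0) for Cα and backbone, and one-hot
SSE labels on backbone-positive voxels (uniform 1/3 elsewhere). σ = 0.8 Å
keeps Cα ≥ 2.8 Å apart as separable local maxima. Oracle maps have perfect
contrast and no false density; end-to-end results on them are an upper
bound on real-map behavior, demonstrating that the post-processing chain is
lossless when segmentation is good — not that segmentation of experimental
maps is solved.

## Path walking

Candidates are local maxima of the Cα confidence within 1.5 Å (non-maximum
suppression keeps branching tractable), refined to the confidence-weighted
centroid of surrounding voxels — without sub-voxel refinement a 1 Å grid
bounds RMSD from below at ≈ 0.5 Å. Walks extend bidirectionally from each
seed. Step scoring uses weights (w_conf, w_bb, w_dist, w_angle) =
(1.0, 0.5, 1.0, 0.5): confidence and distance dominate; the angle term
`max(0, cos θ − cos 150°)` on the pseudo-bond angle penalizes
near-backtracking only. The helix-radius bonus is implemented but disabled
by default (weight 0) pending calibration. Thresholds: Cα ≥ 0.50, segment
mean backbone ≥ 0.40 — the same levels used to display the confidence maps.
The tabu set is a permanent visited mask with a 2.0 Å exclusion radius:
< 2.8 Å (the step minimum) so it never blocks a legitimate next residue,
large enough that a trace cannot re-enter its own territory. Ties in seed
and candidate selection break lexicographically by voxel index, making the
tracer fully deterministic.

## Graph refinement

"Depth" of a branch counts nodes beyond the junction (junction itself = 0),
which makes the depth-≤3 side-chain rule and the depth-≤2 dead-end rule
self-consistent. Pass order: endpoint combination (3 Å merge radius, the
endpoint is absorbed by the nearby node) → side chains → loops → dead ends;
each pass iterates to a fixpoint. For junctions of degree ≥ 4 the
side-chain rule generalizes to: remove the *unique* shortest branch of
depth ≤ 3 when all other branches are strictly deeper. Loop resolution
samples all voxel centers within a 1.0 Å cylinder of the branch polyline
and compares mean density; an empty sample set scores −∞ (that branch
loses) and exact ties remove the longer branch. All passes only merge or
delete — node and edge counts never grow — and each is idempotent.

A consequence of the literal side-chain rule worth knowing: a genuine chain
terminus of ≤ 3 nodes hanging off a junction is indistinguishable from a
side chain and will be pruned.

## Helix refinement

The ideal helix about a screw axis: at axis arclength t with unit tangent z,
the local frame is y = normalize(x_global × z), x = normalize(z × y)
(y_global replaces x_global when the tangent is within 10⁻⁶ of parallel),
and the Cα position is `axis(t) + R·(sin θ·x + cos θ·y)` with R = 2.11 Å,
θ = ω(t − s) + r, ω = 1.149 rad/Å. This frame yields a right-handed helix —
the physical chirality of protein α-helices; a left-handed variant cannot
be superimposed on real helices for any (s, r). s and r act as phase/shift
parameters (s ∈ [0, 1.5), r ∈ [0, 2π)): applied as additive Cartesian
offsets they would destroy the constant-radius property.

The screw axis is estimated from sliding windows of 4 consecutive Cα
(≈ one turn), connected into a polyline, smoothed with a 3-point moving
average and end-extrapolated by half a window span. Window centroids use
*phase-cancelling weights*: the plain mean of 4 points of an ideal helix
sits ≈ 0.26 Å off-axis because 4 residues do not close a full turn; the
closest-to-uniform weights whose helical phase sum vanishes put the
centroid exactly on the axis for an ideal straight helix and reduce the
bias to < 0.3 Å on gently bent ones (30 Å radius of curvature).

Refitting places Cα at t = s, s + 1.5, … and minimizes the mean distance
from placed atoms to the original segment over (s, r): a deterministic
coarse grid (s step 0.05 Å, r step 0.05 rad) followed by Nelder-Mead.
Segments whose axis is shorter than one rise are returned unchanged with a
warning. Refit nodes replace the originals in the graph and are re-stitched
to flanking nodes by nearest-endpoint edges when within 4.5 Å.

Note the synthetic generator builds helices at the Cα radius of real
α-helices (2.3 Å) while refitting uses the fixed 2.11 Å model constant; the
0.19 Å radial mismatch is a floor on refit accuracy against generator
helices and is visible in end-to-end RMSD (≈ 0.34 Å after refinement versus
≈ 0.18 Å before, both far under the 1 Å acceptance bound).

## Metrics

Greedy trace-order matching (each prediction claims its nearest unclaimed
native Cα within 3 Å) reproduces the Phenix-style walk semantics; the test
suite holds it against exhaustive optimal assignment on ≤ 8-point instances,
where it agrees in ≈ 98% of chain-like cases and never exceeds the optimum.
`pct_ca_within_3` divides by the native count (a completeness measure);
the predicted-denominator variant is reported alongside. False positives
use the "> 3 Å from any native Cα" definition, which differs from
"unmatched" when a prediction is near an already-claimed native atom; the
error rate is FP / total predicted, 0 by convention for an empty
prediction (with a warning).

## Synthetic data: what it does and does not emulate

The generator produces self-avoiding Cα chains with ideal secondary-
structure geometry (helix: rise 1.5 Å, 100°/residue, radius 2.3 Å,
right-handed; strands: ~3.5 Å rise with a small alternating pleat; loops:
smooth 3.8 Å random walks, rejection-sampled at a 3.0 Å self-avoidance
floor, 1000 attempts), plus pseudo N/C atoms interpolated at thirds of each
Cα–Cα segment so backbone maps form a connected tube. It does not emulate:
side chains (so the side-chain/dead-end passes are exercised by injected
fixtures, not by emergent clutter), B-factor variation, solvent, map
anisotropy, or experimental noise. Passing tests therefore certify the
geometry and bookkeeping of the pipeline and its behavior under idealized
segmentation, not performance on experimental maps.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen so the full suite
completes on a single CPU: toy training is 30 optimizer steps on ten 32³
cubes (each step is a full forward/backward of the three-stage cascade,
≈ 10¹¹ FLOPs); the end-to-end run uses a 120-residue protein on a ≈ 100³
map; matching comparisons use ≤ 8-point instances where exhaustive
assignment is feasible. Full-scale training (thousands of maps, 15 epochs)
is supported by the same code paths via `build_training_set`/`train_ccnn`
but is out of scope for the bundled experiments.

## Known limitations

- The tracer assumes confidence maps with local maxima near true Cα; very
  flat or saturated maps degrade the non-maximum suppression.
- Graph refinement cannot recover a true branch deleted by the literal
  depth rules (short real termini at junctions).
- Trace direction (N→C) is not assigned; sequence mapping is a separate
  problem outside this package.
- The numpy network trains at toy scale only; no GPU path exists.
- β-strands and loops are not idealized; only helices are refit.
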