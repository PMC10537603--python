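# Methods

This note records the model, the numerical choices, and what the synthetic
experiments do and do not establish.

## Skeleton-sphere prediction

The predictor is a function from a normalized surface point cloud to N
medial spheres. Normalization centers the cloud at its centroid and divides
by the maximum absolute coordinate (one isotropic scale, aspect preserved),
so all tolerances below are in units of the shape's half-extent.

The encoder is a two-level set-abstraction hierarchy. Each level samples
centroids by farthest-point sampling, groups all points inside each of two
grouping radii around every centroid (capped at 16 members, subsampled
deterministically when over, padded with the nearest neighbor when under),
applies a shared two-layer perceptron to `[relative coordinates, features]`,
max-pools per group, and concatenates the two radii's outputs. Grouping and
sampling indices depend only on coordinates, so they are computed once per
cloud and cached; per-epoch cost is the network evaluation only. The weight
head maps final features to N logits with a softmax *across the sampled
points*, making each column of `W` a convex combination — centers therefore
live inside the convex hull of `P'` by construction, an invariant the tests
verify with an exact linear-programming hull oracle.

### Losses

- Sampling loss: bidirectional Chamfer sum between `k = 8` uniform samples
  per predicted sphere surface and `P'`. Sphere samples are differentiable
  through centers and radii (directions held fixed per epoch).
- Point-to-sphere loss: implemented as the absolute deviation
  `|min‖p−c‖ − r|` in both terms. The signed difference (available as
  `signed=True`) makes the loss an unbounded reward for radius growth —
  empirically the radii inflate severalfold on tube shapes and the
  overlap-based link prior then produces dense, useless meshes — so the
  absolute form, consistent with the loss's role as a reconstruction error,
  is the default.
- Radius regularizer `−Σ r`, weight 0.004: large enough to break ties
  toward fat spheres under noise, two orders below the reconstruction
  terms so it cannot dominate.
- Norm loss: spoke-to-normal misalignment `1 − n·u`, summed over both
  assignment directions; each term lies in `[0, 2]`. Zero-length spokes
  (surface point coinciding with a center) are skipped and logged rather
  than propagating NaNs.

Default weights `λ_s = 0.3, λ_p = 0.6, λ_r = 0.004, λ_n = 0.1`. Optimization
is Adam at `1e-3`, one cloud per step, 300 epochs for the fixture scale
(512–700 points, M′ = 64, feature width 32, 4–16 spheres). With these sizes a
full fixture training takes a few seconds on one CPU; neuron-scale defaults
(N = 100, feature width 128) are exposed in `TrainConfig` but are not what
the tests run. Training is deterministic given the seed: all stochasticity
(initialization, grouping subsampling, per-epoch sphere-surface directions)
derives from it.

### Rotation behaviour

The encoder consumes raw coordinates as initial features, so the full
predictor is *not* rotation invariant; shapes are analyzed in the frame they
arrive in. Sampled-point positions are translation equivariant (grouping is
relative), which the tests assert; nothing stronger is claimed.

## Links

The prior adjacency joins nearest-center pairs (in either direction) and
overlapping spheres. The GAE is a two-layer graph convolution over the
degree-normalized prior adjacency with self-loops, standardized input
features `[C, R, WᵀF]`, and a symmetric inner-product decoder squashed
through a logistic; it is trained per shape for 400 epochs against the prior
with a masked balanced cross-entropy (mask = all prior positives plus a
4:1 random draw of non-edges, redrawn each epoch). The balanced weighting
multiplies positive entries by the negatives-to-positives ratio inside the
mask and the loss is the weighted mean.

Binarization at τ = 0.5 is followed by two repairs, both this package's
choices: (1) *collinear-skip pruning* — an edge whose endpoints are already
connected through an intermediate linked sphere lying within 5% of the
straight line between them is redundant (its segment runs along the mesh)
and is removed; without it, confident skip links along tubes let the
longest-simple-path length estimator zig-zag and overestimate length by
50–150% on branched-tube fixtures. Genuine triangles and cycles survive,
since their intermediate node sits well off the line. (2) *connectivity
repair* — isolated nodes reattach to their nearest center and remaining
components are bridged through their closest center pair, so downstream
graph analysis sees one structure instead of silently dropping arms.

## Graph morphometry

Neuron length is the exact longest simple path: depth-first backtracking
that marks a node on entry and unmarks it when the search backtracks past
it. The marking is what makes cycles safe; the unmarking is what makes the
search exact rather than greedy — a permanently-marked variant would return
the first spanning walk it found, not the longest simple path. Ties are
broken toward the lexicographically smallest node sequence so results are
reproducible under hash-order changes. Zero-weight edges (coincident
centers) are contracted first. The search is exponential in the worst case;
above 2,000 nodes it refuses and `neuron_length` falls back to exact
searches from the 32 most eccentric nodes, with a warning. Branch counting
follows the main path: each main-path node with an off-path neighbor
contributes the longest simple path from it avoiding the rest of the main
path and the other branching nodes — one branch per branching node,
zero-length branches discarded.

## Metrics

Chamfer distance is exposed in the printed sum form (used by the training
loss) and a per-point mean form; reports use the mean so values are
comparable across cloud sizes. Shape reconstruction from a skeleton mesh —
needed for the reconstruction metrics, which the source representation does
not define — is the union of the skeleton spheres and spheres linearly
interpolated along every link (center and radius), the natural inverse of
the sphere representation; surface samples interior to the union are
rejected, and volume is voxel-counted on a padded grid (128³ default,
within 2% of the analytic ball volume, convergence asserted under grid
doubling). Length/branch/volume errors are relative absolute errors in
percent; a zero truth with zero computed value reports 0, a zero truth with
a nonzero computed value is undefined and raises.

## Graph embedding

Patch representations concatenate the outputs of three graph-convolution
layers (width 64) over node attributes `(x, y, z, r)`; the global vector is
the node-sum projected to 100 dimensions. The discriminator passes patch and
global vectors through separate 3-layer ReLU perceptrons and takes a
rectified dot product, so scores are nonnegative. The mutual-information
objective averages over graphs the per-node Jensen–Shannon terms
`−sp(−T(pos)) − (−sp(−T(neg)))`, `sp(z) = log(1+e^z)`; negatives pair each
graph's global vector with one node drawn uniformly from another graph. The
sign pattern of the negative term is implemented exactly as this estimator
is printed; the more common JSD form `−E[sp(T(neg))]` is available via
`EmbedConfig(negative_term="standard")`. Classification is scikit-learn
K-means++ (K = number of classes, 10 restarts, fixed seed), cluster labels
by majority vote with ties to the smallest class, test assignment by
nearest center in Euclidean embedding space.

## Synthetic shapes and the medial oracle

Five families with area-uniform surface sampling, analytic normals, an
implicit inside/outside function and analytic ground truth: sphere (point
skeleton), capsule (axis segment), ellipsoid a>b>c (planar medial disk with
semi-axes `(a²−c²)/a, (b²−c²)/b`; medial radii measured against a dense
surface sampling since no simple closed form exists), branched Y-tube
(three-segment tree; volume voxel-integrated because the junction overlap
has no clean closed form), and a concave crescent — a tube bent along a
circular arc (volume exact by Pappus plus caps). Gaussian surface jitter
models segmentation noise; normals stay the clean analytic ones. What the
generator does *not* emulate: occlusion and missing data, spatially
correlated segmentation artifacts, touching neighbor cells, and real
neurons' scale range — passing fixtures therefore demonstrates correctness
of the machinery and recovery under controlled noise, not field performance
on EM data.

The brute-force medial oracle grids the interior and keeps points whose
nearest dense-surface samples include two directions more than 30° apart at
equal distance, with a distance slack that is the smaller of 0.15 grid cells
(localizing detections to about one cell) and `0.2·(sec 30° − 1)·d`
(excluding the spurious angular spread a non-medial point at surface
distance `d` exhibits). Interior points closer to the surface than 16 sample
spacings are dropped: below that the nearest-sample direction field is
discretization noise, and the corresponding small-radius medial spikes are
exactly what simplified medial axes remove. The oracle is deliberately
independent of the learned pipeline and is used as ground truth in tests.

## Fixture experiments

- Sphere (N = 4): all learned centers within 0.2 of the true center, mean
  radius within 10%.
- Capsule (N = 12): ≥ 90% of centers within 0.15 of the axis; the
  skeleton-to-truth Chamfer distance more than halves over training.
- Norm-loss efficacy: on crescents (arc 4.8 rad) with surface noise
  σ = 0.08 at an 80-epoch budget — the regime where combination weights are
  still diffuse, which is where the inside-the-shape property is at risk —
  three paired runs (λ_n = 0 vs 0.1, same seed within a pair) are compared
  on mean inside-shape fraction. At full convergence on clean data the
  other losses already keep this fixture's centers inside, so the
  comparison targets the noisy/early regime where the norm loss earns its
  place.
- Branched tube (N = 10): the full chain recovers exactly one branch and
  the neuron length within 15% (typically 2–10%).
- Embedding (3 families × 10 train / 10 test): ≥ 0.9 test accuracy and
  intra-class mean distance below inter-class.

## Known limitations

- Exponential worst case in the exact path search (guarded, see above).
- The mesh priors assume reasonably calibrated radii; gross radius
  overestimation (e.g., the signed point-to-sphere loss) floods the overlap
  prior.
- Per-shape GAE training cannot transfer across shapes; a dataset-level
  mode is left out of scope.
- The embedding uses absolute node positions, so classes are assumed to be
  presented in a canonical orientation, as the synthetic generator does.
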