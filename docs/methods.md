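# Methods

## Problem and model

The package classifies small RGB vegetation patches (nominally 150×150
pixels, one directory per class) with a late-fusion hybrid of two
representations of the same patch:

- **Graph branch.** SIFT keypoints (scale-space extrema of the grey-level
  image) become nodes; each node carries the 128-dimensional SIFT
  descriptor, scaled to [0, 1]. Nodes are joined to their k = 5 nearest
  neighbours in pixel coordinates (Euclidean metric). When fewer than six
  keypoints exist, the effective neighbour count is `k_eff = min(k, N−1)`;
  self-loops are never created. The directed k-NN relation is asymmetric,
  so the edge set is symmetrised — message passing then runs in both
  directions, the standard choice for spatial graphs. Equal-distance ties
  break to the lower node index, which makes construction reproducible and
  oracle-checkable. Every keypoint-graph edge attribute is 1.0. An image
  with no detectable keypoints (e.g. constant colour) yields a fallback
  graph with a single all-zero node and no edges, keeping the graph branch
  total instead of dropping samples.
- **Image branch.** A compact three-block convolutional encoder (3×3
  convolutions, ReLU, 2×2 average pooling after the first two blocks,
  global average pooling) produces a `d_img`-dimensional feature vector.
  The backbone is frozen by default and acts as a fixed, deterministic
  random-feature extractor in front of a learned linear projection;
  setting `backbone_frozen=False` trains it end-to-end through the
  package's own convolution gradients.

Each message-passing layer performs: graph convolution (aggregate,
combine), normalisation, dropout, nonlinearity — in that order. The
default convolution aggregates the edge-weight-scaled mean of neighbour
states and combines it with the node's own state through two learned
linear maps (`H W_self + Agg W_neigh + b`); isolated nodes receive a zero
aggregation term. A single-head attention variant (`layer_type=
"attention"`) replaces the mean with attention-weighted aggregation, with
edge attributes multiplying the attention weights so weighted graphs
(region-adjacency, superpixel) flow through the same code path; for unit
attributes this is a no-op.

Graph-level embeddings come from **global additive pooling** of the third
layer's node embeddings followed by a linear projection `W_g` (Xavier
uniform, zero bias). Additive (rather than mean) pooling deliberately
keeps node count — a structural quantity — in the embedding magnitude.
Fusion concatenates the two d-dimensional embeddings, applies dropout
(p = 0.2), and classifies with a single linear layer of shape C×2d.
Unimodal variants use their own C×d heads with dropout applied before the
classifier in every regime.

## Alternative graph constructors

For ablation, three more constructors share the `ImageGraph` container:

- **Region-adjacency (`rag`)**: SLIC superpixels become nodes (features:
  mean RGB scaled to [0,1], centroid normalised by image size, region area
  fraction — 6 dimensions); edges join 4-connected adjacent regions with
  weight = Euclidean distance between mean colours.
- **Superpixel (`superpixel`)**: same nodes, but the edge weight measures
  boundary connectivity: shared 4-connected boundary length divided by the
  larger region's perimeter (image border included in the perimeter), a
  value in (0, 1].
- **Grid (`grid`)**: one node per pixel (raw RGB in [0,1]), 4-connected
  lattice, unit weights; an optional `downsample_to` keeps pixel graphs
  desk-scale (a 150×150 patch would otherwise have 22,500 nodes).

Per-region colour means accumulate raw 8-bit values exactly, so regions of
identical colour give bitwise-identical means and exactly zero
dissimilarity.

## Training

Categorical cross-entropy on softmax probabilities, with predicted
probabilities clamped at 1e-12 so the loss is always finite. Adam
(η = 1e-3 default, standard moment constants) is the default optimiser; a
plain SGD implementation exists for contract tests where the update must
equal `θ − η∇L` exactly. The checkpoint policy follows the lowest
**training** loss by default (validation-loss selection is available via
config). After the epoch loop the batch-normalisation running statistics
of the checkpointed parameters are recalibrated in one pass over the full
training set: batch statistics seen during optimisation depend on batch
composition (graphs of very different node counts), and without this step
evaluation-mode behaviour measurably lags the fitted model.

**Data-parallel contract.** `shard_dataset` partitions sample indices into
disjoint, covering shards whose sizes differ by at most one;
`sync_gradients` averages per-worker gradient sets element-wise; the
subsequent optimiser step is applied once, identically for all replicas.
With `num_workers > 1`, `train_epoch` splits each batch into contiguous
equal shards, computes each shard's gradient of its local mean loss, and
averages — which reproduces the single-process full-batch gradient exactly
(mean of per-sample gradients) whenever shards are equal-sized and the
model's forward pass is per-sample independent. Batch normalisation in
training mode violates that independence, exactly as real synchronous
data-parallel training with unsynchronised batch-norm statistics does, so
the equivalence tests use normalisation-free configurations. The contract
is simulated in-process (sequential per-shard gradients + explicit
averaging); no multi-process execution is required for correctness.

## Data pipeline

Classes are ordered alphabetically for dense, deterministic indices.
Splitting is stratified 60/20/20 by default with largest-remainder
rounding per class; exact per-class proportionality holds to within one
sample. Augmentation — rotation in ±30°, horizontal/vertical flips with
probability 0.5, zoom in [0.8, 1.2] with reflect padding or centre
cropping back to size — is applied on the fly to the *training* split only
(split-then-augment, so no augmented copy of an evaluation image can leak
into training), and is deterministic per seed. The rotation/zoom ranges
are conventional defaults; they are parameters of `augment`, not fixed
constants of the method.

## Synthetic benchmark data

Real heathland patch corpora are not redistributable, so tests and the
acceptance benchmark run on procedural patches. Each class renders:

- a **structural signal**: Poisson-many (expected `blob_density`)
  centre-surround luminance blobs of radius `blob_scale` = 4 px. The blob
  profile is a difference of Gaussians with zero integral, so blobs create
  strong local contrast (reliably detected as keypoints) without shifting
  the patch's global intensity statistics;
- an **appearance signal**: a vegetation-like base colour plus a
  sinusoidal texture, both constructed to be *isoluminant* — the red and
  blue modulations cancel exactly in the grayscale projection the keypoint
  detector sees;
- Gaussian pixel noise (σ = 5/255).

The default class grid alternates base colour with class parity while blob
density steps up every second class, so consecutive classes form
appearance-only pairs and alternating classes form structure-only pairs.
By construction the graph branch is blind to appearance and the (frozen)
image branch is largely blind to structure, giving the two unimodal models
distinct failure modes — the fusion gain is then a measurable property,
not an assumption. Noise does produce spurious low-contrast keypoints, so
keypoint counts are an overlapping (not separable) density signal;
descriptors disambiguate.

What the generator does **not** emulate: real class imbalance, viewpoint
and illumination variation, occlusion, inter-class texture similarity, and
spatial autocorrelation between patches cut from one orthomosaic. Passing
the synthetic benchmark therefore demonstrates that the pipeline can
discover and fuse modality-specific signals at small scale — not that it
attains any particular accuracy on real aerial data.

## Benchmark protocol

`run_ablation_benchmark` uses 3 classes × (20 train + 10 test) patches of
150×150 at a fixed seed; training images are complemented by two augmented
copies each (the augmentation step of the training method; graphs are
rebuilt from augmented pixels so both branches see the same data). The
compact model uses d = 32, layer widths (64, 32, 32), backbone channels
(8, 16, 32) with 48×48 input, batch normalisation, dropout 0.2; training
runs 20 epochs of Adam at η = 3e-3 with batch size 6. One model is trained
per mode (hybrid, graph-only, image-only) from the same initialisation
seed. These sizes keep a full ablation under ~two minutes on one CPU core
while leaving the hybrid a clear margin over both unimodal ceilings.

## Numerical choices

- float64 throughout; evaluation-mode forward passes are bit-reproducible
  for fixed parameters.
- k-NN ties: stable argsort on distances ⇒ lower index wins; the oracle
  tests use the identical rule.
- Batch-norm: biased variance with ε = 1e-5, running-statistic momentum
  0.1, one-shot recalibration at checkpoint time (above).
- Attention softmax subtracts a per-target detached maximum; an ε = 1e-16
  guards empty denominators.
- Dropout is inverted (surviving units scaled by 1/(1−p)) and draws from a
  model-owned generator reseeded at the start of `fit`, making loss
  histories exactly reproducible per seed.
- Checkpoints are single-file `.npz` archives holding every parameter,
  batch-norm running statistics and the model configuration as embedded
  JSON; loading restores bit-identical evaluation behaviour.
- Serialized graph datasets are JSON Lines; float64 values round-trip
  exactly through the shortest-repr JSON encoding.

## Known limitations

- The keypoint detector's parameters (scikit-image SIFT defaults,
  upsampling factor 2) are fixed in code; a contrast-free patch yields the
  single-node fallback graph, which carries no structural information.
- The image backbone is a small generic encoder, not a large pretrained
  network; with the backbone frozen, image-branch capacity is limited to
  what a linear map of random convolutional features can express.
- Graph construction is static; adaptive neighbour counts or learned
  construction are out of scope.
- Multi-label classification, attention-map visualisation and wall-clock
  multi-device scaling measurements are out of scope; the data-parallel
  implementation asserts the correctness contract only.
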