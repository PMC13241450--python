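# plantgraphnet

Hybrid graph + image classification of vegetation patches.

Fine-grained classification of heathland vegetation from aerial image
patches is hard for purely convolutional models: species identity often
lives in *structure* — the arrangement and density of shoots, tussocks and
bare-ground specks — rather than in colour and texture alone. This package
implements a hybrid classifier that represents each patch twice: as a
**spatial graph** built from the image's own salient points, and as a
**raw image** seen by a convolutional encoder. The two representations are
fused for classification, and the whole pipeline (graph construction →
training → evaluation → data-parallel training contract) is testable
end-to-end on procedurally generated, class-separable patches.

## The model

Each RGB patch is converted to a graph `G = (V, E)`: SIFT keypoints become
nodes carrying their 128-dimensional descriptors (`h⁰ᵢ = xᵢ`), and each
node is connected to its `k = 5` nearest neighbours in pixel space
(Euclidean metric; `k_eff = min(k, N−1)` when fewer nodes exist; the edge
set is symmetrised and every edge attribute is 1.0). Alternative
constructors — region-adjacency graphs with mean-colour-dissimilarity
weights, superpixel graphs with boundary-connectivity weights, and dense
4-connected pixel grids — support ablation of the graph-construction
choice.

The graph encoder stacks three message-passing layers, each computing

    hᵏᵢ = σ( ∂( Norm( Comb(hᵏ⁻¹ᵢ, Agg({hᵏ⁻¹ⱼ : j ∈ N(i)})) ) ) )

(aggregate neighbours, combine with self, normalise, dropout, nonlinearity),
followed by global additive pooling over each graph's nodes and a linear
projection `z_graph = W_g h_graph + b_g`. The image branch is a compact
convolutional encoder (frozen by default, acting as a fixed feature
extractor) whose globally average-pooled features are projected to
`z_img = W_i F_img + b_i`. The fused representation

    z = Dropout([z_graph ‖ z_img]),   y = W_c z + b_c,   W_c ∈ R^{C×2d}

is classified linearly (dropout rate p = 0.2). Graph-only and image-only
variants classify a single modality through their own `C×d` heads. All
weight matrices use Xavier-uniform initialisation with zero biases.

Training minimises categorical cross-entropy `L(y, ŷ) = −Σ_c y_c log ŷ_c`
with Adam, checkpointing the lowest-training-loss epoch. Data-parallel
training follows the synchronous contract: shard the batch over N workers,
compute local gradients `∇L_i(θ)`, average `∇L(θ) = (1/N) Σᵢ ∇L_i(θ)` and
apply one identical update `θ ← θ − η ∇L(θ)` — simulated in-process and
verified against single-worker training.

The neural core (reverse-mode autodiff over numpy arrays, message-passing
layers, convolution, Adam) is implemented inside the package; SIFT and SLIC
come from scikit-image.

## Worked example

```python
import numpy as np
from plantgraphnet import (
    SyntheticSpec, generate_synthetic_dataset, keypoint_graph,
    run_ablation_benchmark,
)

# a class-separable synthetic patch corpus (structure + appearance signals)
spec = SyntheticSpec(num_classes=3, samples_per_class=30, seed=0)

# one patch -> one graph
from plantgraphnet.synthetic_fixtures import generate_class_image
img = generate_class_image(spec, class_index=2, instance_seed=0)
g = keypoint_graph(img, k=5)
print(g.num_nodes, g.node_features.shape, np.unique(g.edge_attr))

# the hybrid-vs-unimodal ablation on 60 train / 30 test patches
results = run_ablation_benchmark(seed=0)
for mode, res in results["modes"].items():
    print(f"{mode:>11}: test accuracy {res['test_accuracy']:.3f}")
```

prints

```
48 (48, 128) [1.]
     hybrid: test accuracy 0.933
 graph_only: test accuracy 0.500
 image_only: test accuracy 0.667
```

The graph-only model separates blob-density (structural) classes but is
blind to the isoluminant colour classes; the image-only model is the
mirror image; the hybrid model exploits both signals and exceeds either
branch — the qualitative ordering the architecture is designed to produce.

## Command line

```bash
plantgraphnet synth --classes 3 --per-class 50 --size 150 --seed 7 --out patches/
plantgraphnet build-graphs --input patches/ --output graphs.jsonl --method keypoint --k 5
plantgraphnet train --config config.yaml --out-dir run/
plantgraphnet evaluate --checkpoint run/checkpoint.npz --data graphs.jsonl \
    --images-root patches/ --out report.json
plantgraphnet benchmark --seed 0 --out benchmark.json
```

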