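"""The hybrid graph + image classifier.

A three-layer message-passing encoder turns a batch of image graphs into
graph-level embeddings (global additive pooling followed by a linear
projection W_g); a convolutional backbone with global average pooling and a
linear projection W_i embeds the raw image; the two d-dimensional embeddings
are concatenated, passed through dropout and a linear classifier W_c (shape
C x 2d). Graph-only and image-only variants classify a single modality
through their own C x d heads, with dropout applied before the classifier in
every regime. All weight matrices are Xavier-uniform at construction and all
biases start at zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .autograd import Tensor, concat
from .graph_construction import GraphBatch
from .layers import (
    BatchNorm,
    ConvBackbone,
    GraphAttentionLayer,
    GraphConvLayer,
    IdentityNorm,
    LayerNorm,
    Linear,
    Module,
    dropout,
    global_add_pool,
)

__all__ = ["ModelConfig", "HybridModel", "global_add_pool"]

MODES = ("hybrid", "graph_only", "image_only")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``d`` is the shared embedding width of both modalities; ``d_img`` the
    backbone output width (defaults to the last backbone channel count);
    ``p_drop`` the dropout rate used both inside message-passing layers and
    before every classifier head.
    """

    in_features: int = 128
    d: int = 128
    C: int = 2
    d_img: int | None = None
    p_drop: float = 0.2
    gnn_hidden: tuple[int, ...] = (128, 128, 128)
    layer_type: str = "conv"  # or "attention"
    norm_type: str = "batch"  # "batch", "layer" or "none"
    activation: str = "relu"  # or "identity"
    backbone_frozen: bool = True
    backbone_channels: tuple[int, int, int] = (16, 32, 64)
    image_size: int = 64

    def __post_init__(self) -> None:
        self.gnn_hidden = tuple(self.gnn_hidden)
        self.backbone_channels = tuple(self.backbone_channels)
        if self.d_img is None:
            self.d_img = self.backbone_channels[-1]
        if min(self.d, self.d_img, self.C) < 1:
            raise ValueError("d, d_img and C must all be >= 1")
        if not 0.0 <= self.p_drop < 1.0:
            raise ValueError("p_drop must lie in [0, 1)")
        if len(self.gnn_hidden) != 3:
            raise ValueError("exactly three message-passing layer widths are required")
        if self.layer_type not in ("conv", "attention"):
            raise ValueError(f"unknown layer_type {self.layer_type!r}")
        if self.norm_type not in ("batch", "layer", "none"):
            raise ValueError(f"unknown norm_type {self.norm_type!r}")
        if self.activation not in ("relu", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")


_NORMS = {"batch": BatchNorm, "layer": LayerNorm, "none": IdentityNorm}


class HybridModel(Module):
    """GNN encoder + convolutional image encoder + fusion classifier."""

    num_message_passing_layers = 3

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        layer_cls = GraphConvLayer if config.layer_type == "conv" else GraphAttentionLayer
        widths = (config.in_features,) + config.gnn_hidden
        self.gnn_layers = [
            self.add_child(f"gnn{i + 1}", layer_cls(widths[i], widths[i + 1], rng))
            for i in range(3)
        ]
        self.norms = [
            self.add_child(f"norm{i + 1}", _NORMS[config.norm_type](config.gnn_hidden[i]))
            for i in range(3)
        ]
        self.graph_proj = self.add_child("graph_proj", Linear(config.gnn_hidden[-1], config.d, rng))
        self.backbone = self.add_child(
            "backbone",
            ConvBackbone(
                channels=config.backbone_channels,
                frozen=config.backbone_frozen,
                seed=int(rng.integers(0, 2**31 - 1)),
            ),
        )
        self.image_proj = self.add_child("image_proj", Linear(config.d_img, config.d, rng))
        self.fusion_head = self.add_child("fusion_head", Linear(2 * config.d, config.C, rng))
        self.graph_head = self.add_child("graph_head", Linear(config.d, config.C, rng))
        self.image_head = self.add_child("image_head", Linear(config.d, config.C, rng))
        self.rng = np.random.default_rng(seed + 1)

    # ------------------------------------------------------------------ misc
    def reseed_dropout(self, seed: int) -> None:
        self.rng = np.random.default_rng(seed)

    def _activate(self, x: Tensor) -> Tensor:
        return x.relu() if self.config.activation == "relu" else x

    # ------------------------------------------------------------- GNN branch
    def gnn_layer_forward(
        self, h_prev: Tensor, batch: GraphBatch, layer_index: int, training: bool = False
    ) -> Tensor:
        """One message-passing stage: convolution, Norm, dropout, activation."""
        if not 1 <= layer_index <= 3:
            raise ValueError("layer_index must be 1, 2 or 3")
        if h_prev.data.shape[0] != batch.num_nodes:
            raise ValueError("node embedding row count does not match the batch")
        layer = self.gnn_layers[layer_index - 1]
        h = layer(h_prev, batch.edge_index, batch.edge_attr)
        h = self.norms[layer_index - 1](h, training)
        h = dropout(h, self.config.p_drop, self.rng, training)
        return self._activate(h)

    def gnn_encode(self, batch: GraphBatch, training: bool = False) -> Tensor:
        """Three message-passing layers, additive pooling, projection W_g."""
        h = Tensor(batch.node_features)
        for layer_index in (1, 2, 3):
            h = self.gnn_layer_forward(h, batch, layer_index, training)
        pooled = global_add_pool(h, batch.batch_vector, batch.num_graphs)
        return self.graph_proj(pooled)

    # ----------------------------------------------------------- image branch
    def preprocess_images(self, images: np.ndarray) -> np.ndarray:
        """Resize to the backbone input size and standardise to zero mean."""
        images = np.asarray(images)
        if images.ndim == 3:
            images = images[None]
        if images.ndim != 4 or images.shape[3] != 3:
            raise ValueError("expected images of shape (B, H, W, 3)")
        s = self.config.image_size
        out = np.empty((images.shape[0], 3, s, s))
        for i, img in enumerate(images):
            arr = img.astype(np.float64)
            if np.issubdtype(img.dtype, np.integer):
                arr = arr / 255.0
            if arr.shape[:2] != (s, s):
                arr = resize(arr, (s, s, 3), anti_aliasing=True, preserve_range=True)
            out[i] = ((arr - 0.5) / 0.25).transpose(2, 0, 1)
        return out

    def image_encode(self, images: np.ndarray, training: bool = False) -> Tensor:
        """Backbone features (global average pooled) through projection W_i."""
        x = Tensor(self.preprocess_images(images))
        feats = self.backbone(x)
        return self.image_proj(feats)

    # ---------------------------------------------------------------- heads
    def forward_hybrid(self, batch: GraphBatch, images: np.ndarray, training: bool = False) -> Tensor:
        """Concatenate the two embeddings, apply dropout, classify (C x 2d)."""
        z_graph = self.gnn_encode(batch, training)
        z_img = self.image_encode(images, training)
        if z_graph.data.shape[0] != z_img.data.shape[0]:
            raise ValueError("graph batch and image batch sizes differ")
        z = concat([z_graph, z_img], axis=1)
        z = dropout(z, self.config.p_drop, self.rng, training)
        return self.fusion_head(z)

    def forward_unimodal(self, inputs, mode: str, training: bool = False) -> Tensor:
        """Single-modality classification through a C x d head."""
        if mode == "graph_only":
            if not isinstance(inputs, GraphBatch):
                raise TypeError("graph_only mode requires a GraphBatch input")
            z = self.gnn_encode(inputs, training)
            head = self.graph_head
        elif mode == "image_only":
            if isinstance(inputs, GraphBatch):
                raise TypeError("image_only mode requires an image array input")
            z = self.image_encode(inputs, training)
            head = self.image_head
        else:
            raise ValueError(f"unknown unimodal mode {mode!r}")
        z = dropout(z, self.config.p_drop, self.rng, training)
        return head(z)

    def forward(self, batch, images, mode: str = "hybrid", training: bool = False) -> Tensor:
        if mode == "hybrid":
            return self.forward_hybrid(batch, images, training)
        if mode == "graph_only":
            return self.forward_unimodal(batch, mode, training)
        if mode == "image_only":
            return self.forward_unimodal(images, mode, training)
        raise ValueError(f"unknown mode {mode!r}")

    def calibrate_norms(self, batch=None, images=None, mode: str = "hybrid") -> None:
        """Recompute batch-normalisation statistics from one reference batch.

        Batch statistics seen during training depend on batch composition;
        this one-shot pass (dropout off) pins the running statistics to the
        given data — typically the full training set — so evaluation-mode
        behaviour matches what the classifier was fitted against.
        """
        from .layers import BatchNorm

        bns = [n for n in self.norms if isinstance(n, BatchNorm)]
        if not bns:
            return
        for n in bns:
            n.calibrating = True
        try:
            self.forward(batch, images, mode=mode, training=False)
        finally:
            for n in bns:
                n.calibrating = False

    # ------------------------------------------------------------ state (de)ser
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.parameters().items()}
        for i, norm in enumerate(self.norms):
            if isinstance(norm, BatchNorm):
                for key, arr in norm.state_arrays().items():
                    state[f"norm{i + 1}.{key}"] = arr.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        for name, p in params.items():
            p.data = np.array(state[name], copy=True)
        for i, norm in enumerate(self.norms):
            if isinstance(norm, BatchNorm):
                norm.load_state_arrays(
                    {
                        "running_mean": state[f"norm{i + 1}.running_mean"],
                        "running_var": state[f"norm{i + 1}.running_var"],
                    }
                )

    def save_checkpoint(self, path, extra: dict | None = None) -> None:
        """Single-file archive: all parameters plus the config as JSON."""
        meta = {"model_config": asdict(self.config), "extra": extra or {}}
        arrays = {k.replace(".", "__"): v for k, v in self.state_dict().items()}
        np.savez(Path(path), __meta__=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load_checkpoint(cls, path, seed: int = 0) -> tuple["HybridModel", dict]:
        with np.load(Path(path), allow_pickle=False) as archive:
            meta = json.loads(str(archive["__meta__"]))
            state = {
                k.replace("__", "."): archive[k] for k in archive.files if k != "__meta__"
            }
        cfg_dict = meta["model_config"]
        cfg_dict["gnn_hidden"] = tuple(cfg_dict["gnn_hidden"])
        cfg_dict["backbone_channels"] = tuple(cfg_dict["backbone_channels"])
        model = cls(ModelConfig(**cfg_dict), seed=seed)
        model.load_state_dict(state)
        return model, meta.get("extra", {})
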