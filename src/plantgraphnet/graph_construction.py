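"""Convert RGB image patches into spatial graphs.

Four constructors are provided:

``keypoint``
    SIFT keypoints become nodes carrying their 128-d descriptor (scaled to
    [0, 1]); each node is joined to its k nearest neighbours in pixel space
    (Euclidean metric, k = 5 by default, reduced to N - 1 when fewer nodes
    exist), the edge set is symmetrised, and every edge attribute is 1.0.
``rag``
    SLIC superpixels become nodes; spatially adjacent regions are connected
    and the edge weight is the Euclidean distance between their mean colours.
``superpixel``
    As ``rag`` but the edge weight is the shared boundary length normalised
    by the larger region's perimeter.
``grid``
    One node per pixel with its RGB value, 4-connected lattice edges.

Coordinates are 0-based with x = column, y = row, origin at the top-left.
Graph datasets round-trip through a JSON-Lines format, one record per image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import SIFT
from skimage.segmentation import slic
from skimage.transform import resize

__all__ = [
    "Keypoint",
    "ImageGraph",
    "GraphBatch",
    "detect_keypoints",
    "build_knn_edge_index",
    "keypoint_graph",
    "rag_graph",
    "superpixel_graph",
    "grid_graph",
    "build_graph",
    "save_graph_dataset",
    "load_graph_dataset",
    "validate_graph",
]

GRAPH_METHODS = ("keypoint", "rag", "superpixel", "grid")


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    if image.shape[0] < 8 or image.shape[1] < 8:
        raise ValueError("image too small: height and width must be >= 8")
    return image


@dataclass
class Keypoint:
    """A salient image location with its local descriptor."""

    position: np.ndarray  # (x, y) pixel coordinates
    descriptor: np.ndarray  # 128-vector, scaled to [0, 1]

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=np.float64)
        self.descriptor = np.asarray(self.descriptor, dtype=np.float64)
        if self.descriptor.shape != (128,):
            raise ValueError("keypoint descriptor must have length 128")


@dataclass
class ImageGraph:
    """One image's graph: features, positions, directed edges and a label."""

    node_features: np.ndarray  # (N, F)
    node_positions: np.ndarray  # (N, 2) as (x, y)
    edge_index: np.ndarray  # (E, 2) ordered (source, target) pairs
    edge_attr: np.ndarray  # (E,)
    label: int = -1
    method: str = "keypoint"
    graph_id: str = ""

    def __post_init__(self) -> None:
        self.node_features = np.atleast_2d(np.asarray(self.node_features, dtype=np.float64))
        self.node_positions = np.atleast_2d(np.asarray(self.node_positions, dtype=np.float64))
        self.edge_index = np.asarray(self.edge_index, dtype=np.int64).reshape(-1, 2)
        self.edge_attr = np.asarray(self.edge_attr, dtype=np.float64).reshape(-1)

    @property
    def num_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def num_edges(self) -> int:
        return self.edge_index.shape[0]


def validate_graph(graph: ImageGraph) -> None:
    """Raise ValueError when a structural invariant is violated."""
    n = graph.num_nodes
    if graph.node_positions.shape[0] != n:
        raise ValueError("node_features and node_positions row counts differ")
    if graph.edge_attr.shape[0] != graph.edge_index.shape[0]:
        raise ValueError("edge_attr length differs from edge count")
    if graph.num_edges:
        if graph.edge_index.min() < 0 or graph.edge_index.max() >= n:
            raise ValueError("edge endpoint out of range")
        if np.any(graph.edge_index[:, 0] == graph.edge_index[:, 1]):
            raise ValueError("self-loop found")
    if graph.method not in GRAPH_METHODS:
        raise ValueError(f"unknown construction method {graph.method!r}")
    if graph.method == "keypoint" and graph.num_edges and not np.all(graph.edge_attr == 1.0):
        raise ValueError("keypoint graphs must have all edge attributes equal to 1.0")


@dataclass
class GraphBatch:
    """Several graphs packed into one node-feature tensor.

    ``batch_vector[i]`` gives the graph index of node row ``i``; edge indices
    are offset so they address rows of the packed feature matrix.
    """

    node_features: np.ndarray
    edge_index: np.ndarray
    edge_attr: np.ndarray
    batch_vector: np.ndarray
    num_graphs: int
    labels: np.ndarray

    @classmethod
    def from_graphs(cls, graphs: list[ImageGraph]) -> "GraphBatch":
        if not graphs:
            raise ValueError("cannot batch zero graphs")
        widths = {g.node_features.shape[1] for g in graphs}
        if len(widths) > 1:
            raise ValueError(f"inconsistent node feature widths: {sorted(widths)}")
        feats, edges, attrs, assign = [], [], [], []
        offset = 0
        for gi, g in enumerate(graphs):
            feats.append(g.node_features)
            if g.num_edges:
                edges.append(g.edge_index + offset)
                attrs.append(g.edge_attr)
            assign.append(np.full(g.num_nodes, gi, dtype=np.int64))
            offset += g.num_nodes
        return cls(
            node_features=np.concatenate(feats, axis=0),
            edge_index=(
                np.concatenate(edges, axis=0) if edges else np.zeros((0, 2), dtype=np.int64)
            ),
            edge_attr=np.concatenate(attrs) if attrs else np.zeros(0),
            batch_vector=np.concatenate(assign),
            num_graphs=len(graphs),
            labels=np.array([g.label for g in graphs], dtype=np.int64),
        )

    @property
    def num_nodes(self) -> int:
        return self.node_features.shape[0]


# --------------------------------------------------------------------------
# keypoint graphs
# --------------------------------------------------------------------------

def detect_keypoints(image: np.ndarray, upsampling: int = 2) -> list[Keypoint]:
    """Detect SIFT keypoints with 128-d descriptors on the grey-level image.

    Returns an empty list when no scale-space extremum passes the contrast
    test (e.g. a constant image). Detection is deterministic for a fixed
    image and detector settings.
    """
    image = _check_image(image)
    gray = rgb2gray(image)
    detector = SIFT(upsampling=upsampling)
    try:
        detector.detect_and_extract(gray)
    except RuntimeError:
        return []
    keypoints = []
    h, w = gray.shape
    for (row, col), desc in zip(detector.keypoints, detector.descriptors):
        x = float(np.clip(col, 0, w - 1))
        y = float(np.clip(row, 0, h - 1))
        keypoints.append(Keypoint(position=(x, y), descriptor=desc.astype(np.float64) / 255.0))
    return keypoints


def build_knn_edge_index(positions: np.ndarray, k: int, symmetrize: bool = True) -> np.ndarray:
    """k-nearest-neighbour edges on 2-D positions.

    Each node gets ``k_eff = min(k, N - 1)`` outgoing edges to its nearest
    other nodes (Euclidean metric); ties are broken by the lower node index.
    With ``symmetrize=True`` (default) the union with all reversed edges is
    returned, so message passing runs in both directions. No self-loops.
    """
    if k <= 0:
        raise ValueError("k must be a positive integer")
    positions = np.atleast_2d(np.asarray(positions, dtype=np.float64))
    n = positions.shape[0]
    k_eff = min(k, n - 1)
    if k_eff <= 0:
        return np.zeros((0, 2), dtype=np.int64)
    diff = positions[:, None, :] - positions[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=2))
    np.fill_diagonal(dist, np.inf)
    # stable argsort on distance keeps the lower index first among ties
    order = np.argsort(dist, axis=1, kind="stable")[:, :k_eff]
    src = np.repeat(np.arange(n), k_eff)
    tgt = order.reshape(-1)
    directed = set(zip(src.tolist(), tgt.tolist()))
    edges = directed | {(j, i) for (i, j) in directed} if symmetrize else directed
    return np.array(sorted(edges), dtype=np.int64).reshape(-1, 2)


_FALLBACK_DIM = 128


def keypoint_graph(image: np.ndarray, k: int = 5, label: int = -1, graph_id: str = "") -> ImageGraph:
    """Build the keypoint graph of an image (all edge attributes 1.0).

    When no keypoint is detected the graph degenerates to a single all-zero
    node with no edges, so every image still yields a usable graph.
    """
    keypoints = detect_keypoints(image)
    if not keypoints:
        return ImageGraph(
            node_features=np.zeros((1, _FALLBACK_DIM)),
            node_positions=np.zeros((1, 2)),
            edge_index=np.zeros((0, 2), dtype=np.int64),
            edge_attr=np.zeros(0),
            label=label,
            method="keypoint",
            graph_id=graph_id,
        )
    positions = np.stack([kp.position for kp in keypoints])
    features = np.stack([kp.descriptor for kp in keypoints])
    edge_index = build_knn_edge_index(positions, k)
    return ImageGraph(
        node_features=features,
        node_positions=positions,
        edge_index=edge_index,
        edge_attr=np.ones(edge_index.shape[0]),
        label=label,
        method="keypoint",
        graph_id=graph_id,
    )


# --------------------------------------------------------------------------
# segmentation-based graphs
# --------------------------------------------------------------------------

def _segment_image(image: np.ndarray, n_segments: int) -> np.ndarray:
    if n_segments <= 0:
        raise ValueError("n_segments must be a positive integer")
    labels = slic(image, n_segments=n_segments, start_label=0)
    # relabel densely in case SLIC drops segment ids
    _, dense = np.unique(labels, return_inverse=True)
    return dense.reshape(labels.shape)


def _region_features(image: np.ndarray, labels: np.ndarray):
    """Per-region mean colour (in [0,1]), normalised centroid and size."""
    h, w = labels.shape
    n = labels.max() + 1
    flat = labels.reshape(-1)
    counts = np.bincount(flat, minlength=n).astype(np.float64)
    # accumulate raw 8-bit values (exact in float64) so equal-colour regions
    # get bitwise-identical means regardless of their pixel counts
    mean_rgb = np.stack(
        [
            np.bincount(flat, weights=image[:, :, c].reshape(-1).astype(np.float64), minlength=n)
            / counts
            for c in range(3)
        ],
        axis=1,
    ) / 255.0
    yy, xx = np.mgrid[0:h, 0:w]
    cx = np.bincount(flat, weights=xx.reshape(-1), minlength=n) / counts
    cy = np.bincount(flat, weights=yy.reshape(-1), minlength=n) / counts
    features = np.column_stack([mean_rgb, cx / w, cy / h, counts / (h * w)])
    positions = np.column_stack([cx, cy])
    return features, positions, mean_rgb, counts


def _adjacency_pairs(labels: np.ndarray):
    """4-connected straddle pairs between regions.

    Returns the set of unordered adjacent region pairs and, per pair, the
    shared boundary length (count of 4-adjacent pixel pairs on the border).
    """
    pairs: dict[tuple[int, int], int] = {}
    for a, b in ((labels[:, :-1], labels[:, 1:]), (labels[:-1, :], labels[1:, :])):
        mask = a != b
        lo = np.minimum(a[mask], b[mask])
        hi = np.maximum(a[mask], b[mask])
        for i, j in zip(lo.tolist(), hi.tolist()):
            pairs[(i, j)] = pairs.get((i, j), 0) + 1
    return pairs


def _region_perimeters(labels: np.ndarray) -> np.ndarray:
    """Perimeter per region: boundary pixel-pair count, image border included."""
    n = labels.max() + 1
    perim = np.zeros(n)
    for a, b in ((labels[:, :-1], labels[:, 1:]), (labels[:-1, :], labels[1:, :])):
        mask = a != b
        perim += np.bincount(a[mask].reshape(-1), minlength=n)
        perim += np.bincount(b[mask].reshape(-1), minlength=n)
    for border in (labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]):
        perim += np.bincount(border, minlength=n)
    return perim


def _symmetrise(pairs: list[tuple[int, int]], weights: list[float]):
    edge_index, edge_attr = [], []
    for (i, j), wgt in zip(pairs, weights):
        edge_index.extend([(i, j), (j, i)])
        edge_attr.extend([wgt, wgt])
    if not edge_index:
        return np.zeros((0, 2), dtype=np.int64), np.zeros(0)
    order = np.lexsort((np.array(edge_index)[:, 1], np.array(edge_index)[:, 0]))
    return np.array(edge_index, dtype=np.int64)[order], np.array(edge_attr)[order]


def rag_graph(image: np.ndarray, n_segments: int = 64, label: int = -1, graph_id: str = "") -> ImageGraph:
    """Region-adjacency graph with mean-colour-dissimilarity edge weights."""
    image = _check_image(image)
    labels = _segment_image(image, n_segments)
    features, positions, mean_rgb, _ = _region_features(image, labels)
    pairs = sorted(_adjacency_pairs(labels))
    weights = [float(np.linalg.norm(mean_rgb[i] - mean_rgb[j])) for i, j in pairs]
    edge_index, edge_attr = _symmetrise(pairs, weights)
    return ImageGraph(features, positions, edge_index, edge_attr, label, "rag", graph_id)


def superpixel_graph(
    image: np.ndarray, n_segments: int = 64, label: int = -1, graph_id: str = ""
) -> ImageGraph:
    """Superpixel graph whose edge weights measure boundary connectivity.

    The weight of an adjacency is the shared 4-connected boundary length
    divided by the larger region's perimeter (a value in (0, 1]).
    """
    image = _check_image(image)
    labels = _segment_image(image, n_segments)
    features, positions, _, _ = _region_features(image, labels)
    perim = _region_perimeters(labels)
    boundary = _adjacency_pairs(labels)
    pairs = sorted(boundary)
    weights = [boundary[(i, j)] / max(perim[i], perim[j]) for i, j in pairs]
    edge_index, edge_attr = _symmetrise(pairs, weights)
    return ImageGraph(features, positions, edge_index, edge_attr, label, "superpixel", graph_id)


def grid_graph(
    image: np.ndarray,
    downsample_to: int | None = None,
    label: int = -1,
    graph_id: str = "",
) -> ImageGraph:
    """Pixel-lattice graph: raw RGB node features, 4-connected topology."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    if downsample_to is not None:
        if downsample_to <= 0:
            raise ValueError("downsample_to must be a positive integer")
        image = (
            resize(image, (downsample_to, downsample_to, 3), anti_aliasing=True, preserve_range=True)
        ).astype(np.float64)
    h, w = image.shape[:2]
    features = image.reshape(h * w, 3).astype(np.float64) / 255.0
    yy, xx = np.mgrid[0:h, 0:w]
    positions = np.column_stack([xx.reshape(-1), yy.reshape(-1)]).astype(np.float64)
    idx = np.arange(h * w).reshape(h, w)
    pairs = []
    if w > 1:
        pairs.append(np.column_stack([idx[:, :-1].reshape(-1), idx[:, 1:].reshape(-1)]))
    if h > 1:
        pairs.append(np.column_stack([idx[:-1, :].reshape(-1), idx[1:, :].reshape(-1)]))
    if pairs:
        und = np.concatenate(pairs, axis=0)
        edge_index = np.concatenate([und, und[:, ::-1]], axis=0)
        order = np.lexsort((edge_index[:, 1], edge_index[:, 0]))
        edge_index = edge_index[order]
    else:
        edge_index = np.zeros((0, 2), dtype=np.int64)
    return ImageGraph(
        features, positions, edge_index, np.ones(edge_index.shape[0]), label, "grid", graph_id
    )


def build_graph(
    image: np.ndarray,
    method: str = "keypoint",
    k: int = 5,
    n_segments: int = 64,
    downsample_to: int | None = None,
    label: int = -1,
    graph_id: str = "",
) -> ImageGraph:
    """Dispatch to one of the four constructors by name."""
    if method == "keypoint":
        return keypoint_graph(image, k=k, label=label, graph_id=graph_id)
    if method == "rag":
        return rag_graph(image, n_segments=n_segments, label=label, graph_id=graph_id)
    if method == "superpixel":
        return superpixel_graph(image, n_segments=n_segments, label=label, graph_id=graph_id)
    if method == "grid":
        return grid_graph(image, downsample_to=downsample_to, label=label, graph_id=graph_id)
    raise ValueError(f"unknown graph construction method {method!r}")


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def save_graph_dataset(graphs: list[ImageGraph], path) -> None:
    """Write a graph dataset as JSON Lines, one record per image."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for g in graphs:
            record = {
                "id": g.graph_id,
                "label": int(g.label),
                "method": g.method,
                "nodes": g.node_features.tolist(),
                "pos": g.node_positions.tolist(),
                "edges": g.edge_index.tolist(),
                "edge_attr": g.edge_attr.tolist(),
            }
            fh.write(json.dumps(record) + "\n")


def load_graph_dataset(path) -> list[ImageGraph]:
    """Read a JSON-Lines graph dataset; malformed lines raise with a line number."""
    path = Path(path)
    graphs: list[ImageGraph] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                graphs.append(
                    ImageGraph(
                        node_features=np.array(rec["nodes"], dtype=np.float64),
                        node_positions=np.array(rec["pos"], dtype=np.float64),
                        edge_index=np.array(rec["edges"], dtype=np.int64).reshape(-1, 2),
                        edge_attr=np.array(rec["edge_attr"], dtype=np.float64),
                        label=int(rec["label"]),
                        method=rec["method"],
                        graph_id=rec["id"],
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(f"malformed graph record at line {lineno}: {exc}") from exc
    return graphs
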