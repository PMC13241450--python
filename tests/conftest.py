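import numpy as np
import pytest


def make_blob_image(n_blobs: int = 10, size: int = 128, sigma: float = 2.0, amp: float = 180.0,
                    seed: int = 42):
    """Grey background with well-separated high-contrast Gaussian blobs.

    Returns (image, centres) with centres as (row, col) pairs.
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    img = np.full((size, size, 3), 60.0)
    centres = []
    separation = 20.0
    attempts = 0
    while len(centres) < n_blobs:
        c = rng.uniform(12, size - 12, 2)
        if all(np.hypot(c[0] - a, c[1] - b) > separation for a, b in centres):
            centres.append((c[0], c[1]))
        attempts += 1
        if attempts % 200 == 0:  # dense configurations: relax the spacing
            separation *= 0.8
    for cy, cx in centres:
        img += (amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)))[:, :, None]
    return np.clip(img, 0, 255).astype(np.uint8), centres


@pytest.fixture(scope="session")
def blob_image():
    return make_blob_image()


@pytest.fixture(scope="session")
def constant_image():
    return np.full((64, 64, 3), 117, dtype=np.uint8)


@pytest.fixture(scope="session")
def two_half_image():
    img = np.zeros((40, 60, 3), dtype=np.uint8)
    img[:, :30] = (255, 0, 0)
    img[:, 30:] = (0, 0, 255)
    return img


def knn_bruteforce(positions: np.ndarray, k: int, symmetrize: bool = True) -> set:
    """Independent O(N^2) k-NN oracle with the lower-index tie rule."""
    n = len(positions)
    k_eff = min(k, n - 1)
    edges = set()
    for i in range(n):
        cand = sorted(
            (float(np.hypot(*(positions[j] - positions[i]))), j)
            for j in range(n)
            if j != i
        )
        for _, j in cand[:k_eff]:
            edges.add((i, j))
    if symmetrize:
        edges |= {(j, i) for i, j in edges}
    return edges
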