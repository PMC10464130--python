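"""LBP texture features on Radon images, and class dissimilarity.

The descriptor is the rotation-invariant *uniform* local binary pattern
histogram at P = 8 neighbors, radius 1 (the immediate 8-neighborhood).
Each interior pixel gets an 8-bit code: bit i is set when the i-th
neighbor — counted counterclockwise from the east neighbor — is >= the
center (ties set the bit, so a constant image deterministically codes
255). A code whose circular bit pattern has at most two 0<->1 transitions
is *uniform* and is keyed by its number of set bits (labels 0..8); the
remaining non-uniform codes pool into label 9. That yields exactly ten
labels, hence the 10-bin normalized histogram used as the feature vector.

Because the codes depend only on the ordering of intensities, the feature
is invariant under any strictly increasing transform of the image — in
particular under the linear rescale that turns a sinogram into a Radon
image.

Class dissimilarity is the first Wasserstein (earth mover's) distance
between the two class-mean histograms on the ordered bin index with unit
ground distance: sum_k |CDF_p(k) - CDF_q(k)|, in bin-index units,
bounded by 9 for 10 bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    ImageTooSmallError,
    LBPCodeRangeError,
    MissingLabelError,
    NeighborCountError,
    UnnormalizedHistogramError,
)
from . import radon as _radon

N_BINS = 10

# neighbor offsets (dr, dc), counterclockwise from east, row axis down
NEIGHBOR_OFFSETS = (
    (0, 1),    # E
    (-1, 1),   # NE
    (-1, 0),   # N
    (-1, -1),  # NW
    (0, -1),   # W
    (1, -1),   # SW
    (1, 0),    # S
    (1, 1),    # SE
)


@dataclass
class FeatureVector:
    """10-bin normalized LBP label histogram of one Radon image."""

    bins: np.ndarray
    patch_id: str = ""
    label: str = ""


def lbp_code(center: float, neighbors) -> int:
    """8-bit LBP code; bit i set iff neighbors[i] >= center."""
    neighbors = list(neighbors)
    if len(neighbors) != 8:
        raise NeighborCountError(f"need exactly 8 neighbors, got {len(neighbors)}")
    code = 0
    for i, nb in enumerate(neighbors):
        if nb >= center:
            code |= 1 << i
    return code


def riu2_label(code: int) -> int:
    """Rotation-invariant uniform mapping of an 8-bit code to [0, 9].

    Uniform codes (<= 2 circular transitions) map to their set-bit count;
    everything else maps to 9.
    """
    if not (0 <= code <= 255):
        raise LBPCodeRangeError(f"code {code} outside [0, 255]")
    bits = [(code >> i) & 1 for i in range(8)]
    transitions = sum(bits[i] != bits[(i + 1) % 8] for i in range(8))
    if transitions <= 2:
        return sum(bits)
    return 9


_RIU2_TABLE = np.array([riu2_label(c) for c in range(256)], dtype=np.int64)


def lbp_feature(image: np.ndarray, patch_id: str = "", label: str = "") -> FeatureVector:
    """10-bin riu2 LBP histogram over all interior pixels, normalized to 1.

    Vectorized over the image; border pixels (which lack a full
    8-neighborhood) are not coded.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] < 3 or image.shape[1] < 3:
        raise ImageTooSmallError(f"need at least 3x3, got {image.shape}")
    center = image[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.int64)
    for i, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        nb = image[1 + dr : image.shape[0] - 1 + dr, 1 + dc : image.shape[1] - 1 + dc]
        codes |= (nb >= center).astype(np.int64) << i
    labels = _RIU2_TABLE[codes]
    hist = np.bincount(labels.ravel(), minlength=N_BINS).astype(np.float64)
    return FeatureVector(bins=hist / hist.sum(), patch_id=patch_id, label=label)


def class_mean_histogram(features: list[FeatureVector], label: str) -> np.ndarray:
    """Per-bin arithmetic mean over all features carrying ``label``."""
    rows = [f.bins for f in features if f.label == label]
    if not rows:
        raise MissingLabelError(f"no feature vectors with label {label!r}")
    return np.mean(np.stack(rows), axis=0)


def _check_histogram(h, name: str) -> np.ndarray:
    h = np.asarray(h, dtype=np.float64)
    if np.any(h < 0):
        raise UnnormalizedHistogramError(f"{name} has negative mass")
    if abs(h.sum() - 1.0) > 1e-6:
        raise UnnormalizedHistogramError(f"{name} sums to {h.sum()}, expected 1")
    return h


def wasserstein_1d(p, q) -> float:
    """First Wasserstein distance between histograms on the bin index.

    Unit ground distance between adjacent bins; equals the integrated
    absolute difference of the two CDFs. For 10-bin histograms the value
    lies in [0, 9], with 9 attained by opposite one-hot histograms.
    """
    p = _check_histogram(p, "p")
    q = _check_histogram(q, "q")
    if p.shape != q.shape:
        raise UnnormalizedHistogramError(f"bin counts differ: {p.shape} vs {q.shape}")
    return float(np.abs(np.cumsum(p - q)).sum())


def class_dissimilarity(features: list[FeatureVector]) -> float:
    """Wasserstein distance between the scar and normal mean histograms."""
    p = class_mean_histogram(features, "scar")
    q = class_mean_histogram(features, "normal")
    return wasserstein_1d(p, q)


def radon_lbp_features(patch_list, angles=None) -> list[FeatureVector]:
    """Full descriptor chain patch -> sinogram -> Radon image -> LBP histogram."""
    out = []
    for p in patch_list:
        sino = _radon.radon_transform(p, angles=angles)
        img = _radon.sinogram_to_image(sino)
        out.append(lbp_feature(img, patch_id=p.patch_id, label=p.label))
    return out
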