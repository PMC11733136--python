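"""Mapping droplet signatures onto the 8-color droplet palette.

Two routes are provided: unsupervised recovery of the population structure
with k-means (centroids are labeled by thresholding each channel at the
midpoint of its centroid range), and a supervised per-channel high/low
threshold classifier calibrated from known low/high channel means.  Both
emit indices into the fixed 8-member palette (2 levels x 3 channels).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .peak_detection import DropletSignature

__all__ = [
    "PaletteColor",
    "PALETTE",
    "palette_index",
    "ClassifierModel",
    "fit_kmeans",
    "fit_thresholds",
    "classify",
    "classify_many",
]

N_CHANNELS = 3  # detection order: blue (405 nm), green (488 nm), red (561 nm)

# display levels for rendering a palette color as 8-bit RGB
_LEVEL_LOW = 0
_LEVEL_HIGH = 255


@dataclass(frozen=True)
class PaletteColor:
    """One of the 8 droplet colors: high/low levels over (blue, green, red)."""

    levels: tuple[bool, bool, bool]
    index: int
    display_rgb: tuple[int, int, int]


def palette_index(levels: Sequence[bool]) -> int:
    """Binary encoding of (blue, green, red) high/low levels: blue is MSB."""
    b, g, r = (bool(x) for x in levels)
    return (b << 2) | (g << 1) | int(r)


def _build_palette() -> tuple[PaletteColor, ...]:
    colors = []
    for idx in range(8):
        levels = (bool(idx & 4), bool(idx & 2), bool(idx & 1))
        b, g, r = levels
        rgb = (
            _LEVEL_HIGH if r else _LEVEL_LOW,
            _LEVEL_HIGH if g else _LEVEL_LOW,
            _LEVEL_HIGH if b else _LEVEL_LOW,
        )
        colors.append(PaletteColor(levels, idx, rgb))
    return tuple(colors)


#: The complete droplet palette: all 2^3 = 8 level combinations, ordered by index.
PALETTE: tuple[PaletteColor, ...] = _build_palette()


@dataclass(frozen=True)
class ClassifierModel:
    """Fitted signature classifier.

    Exactly one of ``centroids`` (k-means route, with ``centroid_labels``
    giving each centroid's palette index) or ``thresholds`` (per-channel
    volt cut between low and high) is set.
    """

    centroids: Optional[np.ndarray] = None
    centroid_labels: Optional[tuple[int, ...]] = None
    thresholds: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if (self.centroids is None) == (self.thresholds is None):
            raise ValueError("model must have either centroids or thresholds")
        if self.centroids is not None:
            cents = np.asarray(self.centroids, dtype=float)
            if cents.ndim != 2 or cents.shape[1] != N_CHANNELS:
                raise ValueError("centroids must be (k, 3)")
            if self.centroid_labels is None or len(self.centroid_labels) != len(cents):
                raise ValueError("centroid_labels must match centroids")
            object.__setattr__(self, "centroids", cents)

    @property
    def kind(self) -> str:
        return "kmeans" if self.centroids is not None else "threshold"


def _label_centroids(centroids: np.ndarray) -> tuple[int, ...]:
    # per channel: high iff the centroid exceeds the midpoint of the
    # centroid range on that channel
    mid = (centroids.min(axis=0) + centroids.max(axis=0)) / 2.0
    labels = []
    for c in centroids:
        levels = tuple(bool(v > m) for v, m in zip(c, mid))
        labels.append(palette_index(levels))
    return tuple(labels)


def fit_kmeans(
    signatures: Sequence[DropletSignature],
    k: int = 8,
    seed: int = 0,
    n_restarts: int = 10,
) -> ClassifierModel:
    """Fit k-means to complete signatures and label centroids on the palette."""
    data = np.array([s.magnitudes for s in signatures if s.complete], dtype=float)
    if len(data) < k:
        raise ValueError(
            f"need at least k={k} complete signatures, got {len(data)}"
        )
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    km.fit(data)
    centroids = km.cluster_centers_
    return ClassifierModel(
        centroids=centroids, centroid_labels=_label_centroids(centroids)
    )


def fit_thresholds(
    low_means: Sequence[float], high_means: Sequence[float]
) -> ClassifierModel:
    """Calibrate per-channel cuts at the midpoint between low and high means."""
    lows = np.asarray(low_means, dtype=float)
    highs = np.asarray(high_means, dtype=float)
    if lows.shape != (N_CHANNELS,) or highs.shape != (N_CHANNELS,):
        raise ValueError("low/high means must each have 3 entries")
    if np.any(highs <= lows):
        raise ValueError("high means must exceed low means on every channel")
    cuts = (lows + highs) / 2.0
    return ClassifierModel(thresholds=tuple(float(c) for c in cuts))


def classify(
    signature: DropletSignature, model: ClassifierModel
) -> Optional[PaletteColor]:
    """Assign a signature to a palette color; None for incomplete signatures.

    An incomplete signature is refused (returned as None): it marks a
    droplet the sorter must not deflect.  Nearest-centroid ties break to the
    lowest palette index.
    """
    if not signature.complete:
        return None
    mags = np.asarray(signature.magnitudes, dtype=float)
    if model.kind == "threshold":
        levels = tuple(bool(m > t) for m, t in zip(mags, model.thresholds))
        return PALETTE[palette_index(levels)]
    dists = np.linalg.norm(model.centroids - mags, axis=1)
    best = np.flatnonzero(dists == dists.min())
    label = min(model.centroid_labels[i] for i in best)
    return PALETTE[label]


def classify_many(
    signatures: Sequence[DropletSignature], model: ClassifierModel
) -> list[Optional[PaletteColor]]:
    return [classify(s, model) for s in signatures]
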