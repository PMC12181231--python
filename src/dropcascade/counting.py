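"""K-Means binarization of probability maps and connected-object counting.

A predicted probability map has two natural intensity clusters — white
(foreground) and black (background) — so a two-cluster K-Means on pixel
intensities separates them without a hand-picked threshold.  Counting then
reduces to connected-component labeling of the binary mask: cluster centers
alone cannot yield object counts, so components (optionally filtered by a
minimum area) are what gets counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

#: Minimum K-Means center separation below which a map is treated as
#: containing no foreground at all (degenerate, near-constant input).
DEGENERATE_SEPARATION = 0.1

#: Default minimum component areas (px). Droplets span hundreds of pixels;
#: crystals occupy at most a few, so they are never area-filtered.
MIN_AREA_DROPLET = 50
MIN_AREA_CRYSTAL = 1


@dataclass
class ObjectCount:
    """Connected objects in one binary mask."""

    n_objects: int
    centroids: list[tuple[float, float]]  # (row, col)
    areas: list[int]


def binarize_kmeans(prob_map: np.ndarray, seed: int = 0) -> np.ndarray:
    """Two-cluster K-Means binarization of a probability map.

    Pixels are clustered on intensity (k-means++ init, fixed seed); the
    cluster with the higher center becomes white (255).  Near-constant maps
    whose centers are separated by less than ``DEGENERATE_SEPARATION`` are
    returned as all background — an all-grey map has no foreground cluster.
    """
    p = np.asarray(prob_map, dtype=float)
    if p.size == 0:
        raise ValueError("empty probability map")
    if p.min() < -1e-9 or p.max() > 1 + 1e-9:
        raise ValueError("probability map values must lie in [0, 1]")
    flat = p.reshape(-1, 1)
    km = KMeans(n_clusters=2, init="k-means++", n_init=10, random_state=seed)
    km.fit(flat if flat.shape[0] <= 200_000 else
           flat[np.random.default_rng(seed).choice(flat.shape[0], 200_000,
                                                   replace=False)])
    centers = np.sort(km.cluster_centers_.ravel())
    if centers[1] - centers[0] < DEGENERATE_SEPARATION:
        return np.zeros(p.shape, dtype=np.uint8)
    # 1-D two-means assignment is a threshold at the center midpoint
    thr = centers.mean()
    return np.where(p > thr, 255, 0).astype(np.uint8)


def count_objects(
    mask: np.ndarray, min_area: int = 1, connectivity: int = 8
) -> ObjectCount:
    """Count connected white objects in a {0, 255} binary mask.

    Components smaller than ``min_area`` pixels are discarded; centroids
    are component pixel means in (row, col).  ``connectivity`` is 4
    (edge-adjacent) or 8 (edge- or corner-adjacent, the default).
    """
    m = np.asarray(mask)
    vals = np.unique(m)
    if not np.all(np.isin(vals, (0, 1, 255))):
        raise ValueError("mask must be binary {0, 255}")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    labels, n = ndimage.label(m > 0, structure=structure)
    if n == 0:
        return ObjectCount(0, [], [])
    areas = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(areas >= min_area) + 1
    centroids = ndimage.center_of_mass(m > 0, labels, keep)
    return ObjectCount(
        n_objects=len(keep),
        centroids=[(float(r), float(c)) for r, c in centroids],
        areas=[int(areas[i - 1]) for i in keep],
    )
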