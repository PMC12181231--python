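"""Per-droplet content classification and ACC counting.

Every droplet initially contains amorphous calcium carbonate (ACC), so a
droplet "contains ACC" exactly when no vaterite or calcite crystal is found
inside it.  Droplet regions are delimited by the minimum enclosing circle
of each connected component in the droplet mask (computed with Welzl's
algorithm over the component's convex hull); each crystal component's
centroid is assigned to the circle that contains it, inflated by a small
margin so 1–3 px crystals near a circle edge are not lost to discretization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .counting import MIN_AREA_CRYSTAL, MIN_AREA_DROPLET, count_objects

logger = logging.getLogger(__name__)

DEFAULT_MARGIN_PX = 2.0


@dataclass
class DropletDetection:
    """One detected droplet and its classified contents."""

    center: tuple[float, float]  # (row, col)
    radius: float
    has_vaterite: bool = False
    has_calcite: bool = False
    truncated_at_border: bool = False

    @property
    def has_acc(self) -> bool:
        return not (self.has_vaterite or self.has_calcite)


@dataclass
class TimePointCount:
    """Pooled droplet-content counts at one acquisition timestep."""

    location_id: int | str
    timestep_index: int
    mean_time_min: float
    time_span_min: tuple[float, float]
    n_droplets: int
    n_vaterite_droplets: int
    n_calcite_droplets: int
    n_acc: int

    def __post_init__(self) -> None:
        transformed = self.n_vaterite_droplets + self.n_calcite_droplets
        # conservation holds unless a droplet hosts both polymorphs
        if self.n_acc > self.n_droplets:
            raise ValueError("ACC count exceeds droplet count")


# ----------------------------------------------------- min enclosing circle

def _circle_from(points: list[np.ndarray]) -> tuple[np.ndarray, float]:
    if not points:
        return np.zeros(2), 0.0
    if len(points) == 1:
        return points[0], 0.0
    if len(points) == 2:
        c = (points[0] + points[1]) / 2.0
        return c, float(np.linalg.norm(points[0] - c))
    (ax, ay), (bx, by), (cx, cy) = points
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        # collinear: fall back to the widest pair
        pairs = [(points[i], points[j]) for i in range(3) for j in range(i + 1, 3)]
        p, q = max(pairs, key=lambda pq: np.linalg.norm(pq[0] - pq[1]))
        c = (p + q) / 2.0
        return c, float(np.linalg.norm(p - c))
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    c = np.array([ux, uy])
    return c, float(np.linalg.norm(points[0] - c))


def _in_circle(p: np.ndarray, c: np.ndarray, r: float) -> bool:
    return np.linalg.norm(p - c) <= r + 1e-9


def minimum_enclosing_circle(
    points: np.ndarray, seed: int = 0
) -> tuple[tuple[float, float], float]:
    """Smallest circle containing all ``points`` (Welzl's algorithm).

    ``points`` is an (n, 2) array of (row, col) coordinates.  Runs on the
    convex hull, so it is fast even for large components.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) >= 4:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (collinear) point sets: use raw points
    rng = np.random.default_rng(seed)
    shuffled = [pts[i] for i in rng.permutation(len(pts))]
    c, r = np.zeros(2), -1.0
    for i, p in enumerate(shuffled):
        if r >= 0 and _in_circle(p, c, r):
            continue
        c, r = p.copy(), 0.0
        for j in range(i):
            q = shuffled[j]
            if _in_circle(q, c, r):
                continue
            c, r = _circle_from([p, q])
            for k in range(j):
                s = shuffled[k]
                if _in_circle(s, c, r):
                    continue
                c, r = _circle_from([p, q, s])
    return (float(c[0]), float(c[1])), float(r)


def find_droplet_circles(
    droplet_mask: np.ndarray, min_area: int = MIN_AREA_DROPLET
) -> list[DropletDetection]:
    """Minimum enclosing circle of every droplet component in the mask.

    Components under ``min_area`` px are dropped; components touching the
    frame border are kept but flagged as truncated.
    """
    m = np.asarray(droplet_mask) > 0
    structure = ndimage.generate_binary_structure(2, 2)
    labels, n = ndimage.label(m, structure=structure)
    h, w = m.shape
    out: list[DropletDetection] = []
    for obj_slice, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        region = labels[obj_slice] == lab
        if region.sum() < min_area:
            continue
        rr, cc = np.nonzero(region)
        rr = rr + obj_slice[0].start
        cc = cc + obj_slice[1].start
        center, radius = minimum_enclosing_circle(np.column_stack([rr, cc]))
        touches = (rr.min() == 0 or cc.min() == 0
                   or rr.max() == h - 1 or cc.max() == w - 1)
        out.append(DropletDetection(center=center, radius=max(radius, 0.5),
                                    truncated_at_border=touches))
    return out


def assign_crystals(
    circles: list[DropletDetection],
    vaterite_mask: np.ndarray,
    calcite_mask: np.ndarray,
    margin_px: float = DEFAULT_MARGIN_PX,
) -> tuple[list[DropletDetection], int]:
    """Flag each droplet with the crystal phases found inside its circle.

    Each crystal component's centroid is tested against the droplet circles
    inflated by ``margin_px``.  A centroid inside several circles goes to
    the nearest center; one inside none is logged as an orphan and ignored.
    Returns ``(detections, n_orphans)``; the detections are the input
    circles with content flags set.
    """
    if vaterite_mask.shape != calcite_mask.shape:
        raise ValueError("crystal masks differ in shape")
    n_orphans = 0
    centers = np.array([d.center for d in circles]) if circles else np.zeros((0, 2))
    radii = np.array([d.radius for d in circles])
    for mask, attr in ((vaterite_mask, "has_vaterite"),
                       (calcite_mask, "has_calcite")):
        counted = count_objects(np.where(np.asarray(mask) > 0, 255, 0),
                                min_area=MIN_AREA_CRYSTAL)
        for centroid in counted.centroids:
            if len(circles) == 0:
                n_orphans += 1
                continue
            d = np.hypot(centers[:, 0] - centroid[0], centers[:, 1] - centroid[1])
            inside = np.flatnonzero(d <= radii + margin_px)
            if inside.size == 0:
                n_orphans += 1
                logger.warning("orphan %s crystal at %s", attr[4:], centroid)
                continue
            target = inside[np.argmin(d[inside])]
            setattr(circles[target], attr, True)
    return circles, n_orphans


def count_timepoint(
    detections: list[DropletDetection],
    location_id: int | str = 0,
    timestep_index: int = 0,
    mean_time_min: float = 0.0,
    time_span_min: tuple[float, float] | None = None,
) -> TimePointCount:
    """Aggregate per-droplet detections into one timestep's count row.

    ``n_acc = n_droplets - |droplets with vaterite or calcite|`` — the
    conservation identity that makes ACC counts derivable from crystal
    detections alone.
    """
    n = len(detections)
    n_v = sum(d.has_vaterite for d in detections)
    n_c = sum(d.has_calcite for d in detections)
    n_transformed = sum(d.has_vaterite or d.has_calcite for d in detections)
    return TimePointCount(
        location_id=location_id,
        timestep_index=timestep_index,
        mean_time_min=mean_time_min,
        time_span_min=time_span_min or (mean_time_min, mean_time_min),
        n_droplets=n,
        n_vaterite_droplets=n_v,
        n_calcite_droplets=n_c,
        n_acc=n - n_transformed,
    )


def detect_frame(
    droplet_mask: np.ndarray,
    vaterite_mask: np.ndarray,
    calcite_mask: np.ndarray,
    min_area: int = MIN_AREA_DROPLET,
    margin_px: float = DEFAULT_MARGIN_PX,
) -> tuple[list[DropletDetection], int]:
    """Convenience: circles + crystal assignment for one frame's masks."""
    circles = find_droplet_circles(droplet_mask, min_area=min_area)
    return assign_crystals(circles, vaterite_mask, calcite_mask, margin_px)
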