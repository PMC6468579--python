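"""Organelle and cytoplasm segmentation, and Euclidean distance representations.

Coordinate convention (used throughout the package): (row, col), 0-based,
pixel centers at integer coordinates. All physical distances are in
nanometers; masks carry their pixel size (nm/px) so that distance logic
never depends on the sampling chosen.

The punctum-to-organelle distance is defined as the exact Euclidean distance
from the (subpixel) punctum centroid to the nearest organelle-positive pixel
center, and 0 when the centroid falls on a mask-positive pixel. Subpixel
queries are answered by exact nearest-neighbor search over positive pixel
centers, not by interpolating the per-pixel distance map, so the value is
exact rather than grid-approximate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

__all__ = [
    "Mask",
    "DistanceMap",
    "segment_organelle",
    "segment_cytoplasm",
    "distance_map",
    "point_to_mask_distances",
    "EmptyMaskError",
    "SegmentationError",
]


class SegmentationError(ValueError):
    """Raised when a segmentation precondition fails (e.g. constant image)."""


class EmptyMaskError(ValueError):
    """Raised when an operation requires a nonempty mask."""


@dataclass
class Mask:
    """Binary 2-D mask with physical pixel size.

    Parameters
    ----------
    pixels : bool array, shape (rows, cols)
    pixel_size : float
        Physical size of one pixel in nm.
    frame_index : int, optional
        Time-lapse frame the mask belongs to (None for static masks).
    """

    pixels: np.ndarray
    pixel_size: float
    frame_index: int | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (nm/px)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def _tree(self) -> cKDTree:
        """KD-tree over positive pixel centers, built lazily and cached.

        Mask pixels are treated as immutable once queried.
        """
        tree = getattr(self, "_kdtree", None)
        if tree is None:
            tree = cKDTree(np.argwhere(self.pixels))
            object.__setattr__(self, "_kdtree", tree)
        return tree

    def area_px(self) -> int:
        return int(self.pixels.sum())

    def is_empty(self) -> bool:
        return not self.pixels.any()


@dataclass
class DistanceMap:
    """Per-pixel Euclidean distance (nm) to the nearest mask-positive pixel."""

    distances: np.ndarray
    pixel_size: float


def segment_organelle(frame: np.ndarray, pixel_size: float,
                      method: str = "otsu", threshold: float | None = None,
                      min_object_px: int = 0,
                      frame_index: int | None = None) -> Mask:
    """Threshold an organelle channel into a binary mask.

    method="otsu" picks the threshold maximizing between-class variance;
    method="fixed_threshold" uses the supplied ``threshold``. Connected
    components smaller than ``min_object_px`` are removed.
    """
    img = np.asarray(frame, dtype=float)
    if method == "otsu":
        if np.ptp(img) == 0:
            raise SegmentationError("otsu threshold undefined on constant image")
        thr = threshold_otsu(img)
    elif method == "fixed_threshold":
        if threshold is None:
            raise ValueError("fixed_threshold requires a threshold value")
        thr = threshold
    else:
        raise ValueError(f"unknown method {method!r}")
    mask = img > thr
    if min_object_px > 1:
        mask = remove_small_objects(mask, max_size=min_object_px - 1)
    return Mask(mask, pixel_size, frame_index=frame_index)


def segment_cytoplasm(membrane_frame: np.ndarray, pixel_size: float,
                      method: str = "otsu",
                      threshold: float | None = None) -> Mask:
    """Delimit the cytoplasm from a plasma-membrane stain.

    The stain outlines the cell boundary; the mask is the filled interior of
    the largest closed contour (a single connected component, membrane ring
    included). Raises :class:`SegmentationError` when no closed boundary is
    found (filling changes nothing).
    """
    img = np.asarray(membrane_frame, dtype=float)
    if np.ptp(img) == 0:
        raise SegmentationError("blank membrane frame: no boundary to segment")
    if method == "otsu":
        thr = threshold_otsu(img)
    else:
        if threshold is None:
            raise ValueError("fixed threshold value required")
        thr = threshold
    ring = img > thr
    filled = ndi.binary_fill_holes(ring)
    if filled.sum() == ring.sum():
        raise SegmentationError("membrane stain does not form a closed contour")
    labels, n = ndi.label(filled)
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        filled = labels == (1 + int(np.argmax(sizes)))
    return Mask(filled, pixel_size)


def distance_map(mask: Mask) -> DistanceMap:
    """Per-pixel Euclidean distance transform of a mask, in nm.

    Zero exactly on mask-positive pixels; elsewhere the distance to the
    nearest positive pixel center scaled by the pixel size.
    """
    if mask.is_empty():
        raise EmptyMaskError("distance to an empty mask is undefined")
    dt = ndi.distance_transform_edt(~mask.pixels)
    return DistanceMap(dt * mask.pixel_size, mask.pixel_size)


def point_to_mask_distances(points: np.ndarray, mask: Mask) -> np.ndarray:
    """Exact Euclidean distance (nm) from subpixel points to a mask.

    ``points`` is an (n, 2) array of (row, col) coordinates in px. A point
    whose containing pixel (nearest integer coordinate) is mask-positive is
    at distance 0; otherwise the exact distance to the nearest positive
    pixel center is returned.
    """
    if mask.is_empty():
        raise EmptyMaskError("distance to an empty mask is undefined")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d, _ = mask._tree().query(pts)
    rr = np.clip(np.rint(pts[:, 0]).astype(int), 0, mask.shape[0] - 1)
    cc = np.clip(np.rint(pts[:, 1]).astype(int), 0, mask.shape[1] - 1)
    inside = mask.pixels[rr, cc]
    d = np.where(inside, 0.0, d)
    return d * mask.pixel_size
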