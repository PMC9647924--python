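"""Preprocessing and mask postprocessing.

Segmentation models (plugged in through :class:`SegmentationAdapter`)
emit raw tooth / bone-area / CEJ-line masks.  This module cleans them up:
resize + heatmap preprocessing, noise removal, outer-contour detection,
and sliding-window connection of fragmented CEJ lines into a single
polyline usable as the bone-loss reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
from matplotlib import colormaps
from scipy import ndimage
from skimage import measure, transform

__all__ = [
    "HEATMAP_COLORMAP",
    "Mask",
    "CEJPolyline",
    "SegmentationAdapter",
    "preprocess_image",
    "clean_mask",
    "extract_contours",
    "connect_cej",
]

#: Perceptual colormap used by the heatmap conversion; fixed so runs are
#: reproducible (luminance is monotone in intensity for this map).
HEATMAP_COLORMAP = "magma"

MaskKind = str  # {"tooth", "bone_area", "cej"}


@dataclass
class Mask:
    """A strictly binary raster tied to its parent image dimensions."""

    pixels: np.ndarray
    kind: MaskKind = "tooth"
    source_size: tuple[int, int] | None = None  # (width, height) of original

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.source_size is None:
            h, w = self.pixels.shape
            self.source_size = (w, h)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class CEJPolyline:
    """Ordered CEJ polyline, one point per column (x strictly increasing)."""

    points: np.ndarray  # (N, 2) int array of (x, y)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=int).reshape(-1, 2)
        if len(self.points) > 1 and not np.all(np.diff(self.points[:, 0]) > 0):
            raise ValueError("CEJ polyline x coordinates must be strictly increasing")

    def y_at(self, x: float) -> float:
        """Row of the polyline at column x (linear interpolation, clamped)."""
        xs, ys = self.points[:, 0], self.points[:, 1]
        return float(np.interp(x, xs, ys))

    @property
    def mean_row(self) -> float:
        return float(self.points[:, 1].mean())


class SegmentationAdapter(Protocol):
    """Contact point for a user-plugged segmentation model.

    Implementations take a grayscale image and return raw rasters (values
    in [0, 1]) keyed ``"tooth"``, ``"bone_area"``, ``"cej"``.
    """

    def segment(self, image: np.ndarray) -> dict[str, np.ndarray]: ...


def preprocess_image(
    image: np.ndarray,
    target_size: tuple[int, int] = (512, 512),
    heatmap: bool = False,
) -> np.ndarray:
    """Resize a radiograph to the working resolution, optionally as a heatmap.

    The heatmap conversion maps grayscale through a fixed perceptual
    colormap (:data:`HEATMAP_COLORMAP`) to 3 channels; the mapping is a
    function of intensity only.
    """
    image = np.asarray(image)
    if image.size == 0 or min(image.shape[:2]) == 0:
        raise ValueError("cannot preprocess a zero-dimension image")
    if image.ndim == 3:  # collapse incidental color input to grayscale
        image = image.mean(axis=2)
    w, h = target_size
    if image.shape != (h, w):
        out = transform.resize(image.astype(float), (h, w), order=1,
                               anti_aliasing=True, preserve_range=True)
    else:
        out = image.astype(float, copy=True)
    if not heatmap:
        if np.issubdtype(np.asarray(image).dtype, np.integer):
            return np.rint(out).astype(np.uint8)
        return out
    lo, hi = float(out.min()), float(out.max())
    norm = np.zeros_like(out) if hi == lo else (out - lo) / (hi - lo)
    rgba = colormaps[HEATMAP_COLORMAP](norm)
    return np.rint(rgba[..., :3] * 255).astype(np.uint8)


def clean_mask(
    raw: np.ndarray,
    threshold: float = 0.5,
    sigma: float = 1.0,
    min_area: int = 50,
    kind: MaskKind = "tooth",
) -> Mask:
    """Denoise and binarize a raw segmentation raster.

    Probability rasters are Gaussian-smoothed (``sigma``) before
    thresholding; strictly binary inputs skip the smoothing (there is no
    sub-threshold noise to suppress, and skipping it makes the operation
    idempotent).  Connected components smaller than ``min_area`` pixels
    are dropped.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size and (raw.min() < 0 or raw.max() > 1):
        raise ValueError("raw mask values must lie in [0, 1]")
    is_binary = bool(np.isin(raw, (0.0, 1.0)).all())
    if sigma > 0 and not is_binary:
        raw = ndimage.gaussian_filter(raw, sigma)
    binary = raw > threshold if not is_binary else raw >= 0.5
    if min_area > 0 and binary.any():
        labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
        if n:
            areas = np.bincount(labels.ravel())[1:]
            keep = np.flatnonzero(areas >= min_area) + 1
            binary = np.isin(labels, keep)
    return Mask(pixels=binary, kind=kind)


def extract_contours(mask: Mask) -> list[np.ndarray]:
    """Outer contour of each connected component, largest component first.

    Returns one closed contour per 8-connected component as an (N, 2)
    float array of (x, y) points; interior holes are ignored.
    """
    pixels = np.asarray(mask.pixels, dtype=bool)
    labels, n = ndimage.label(pixels, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []
    areas = np.bincount(labels.ravel())[1:]
    order = np.argsort(-areas, kind="stable") + 1
    contours: list[np.ndarray] = []
    for lab in order:
        comp = ndimage.binary_fill_holes(labels == lab)
        # pad so components touching the border still yield closed curves
        padded = np.pad(comp, 1).astype(float)
        traced = measure.find_contours(padded, 0.5)
        if not traced:
            continue
        rc = max(traced, key=len) - 1.0  # (row, col), undo padding
        contours.append(rc[:, ::-1].copy())  # -> (x, y)
    return contours


def connect_cej(
    raw_cej: Mask,
    window: int = 8,
    gap_factor: int = 3,
) -> CEJPolyline:
    """Connect a fragmented CEJ mask into a single polyline.

    A window of ``window`` columns slides across the mask; each window
    with foreground contributes the centroid row of its pixels.  Windows
    with no pixels are bridged by linear interpolation provided the gap
    does not exceed ``window * gap_factor`` columns; longer gaps split the
    line and only the longest connected segment is kept (with a warning).
    The result has one point per column, x strictly increasing.
    """
    pixels = np.asarray(raw_cej.pixels, dtype=bool)
    if not pixels.any():
        raise ValueError("no CEJ pixels")
    cols = np.flatnonzero(pixels.any(axis=0))
    col_lo, col_hi = int(cols[0]), int(cols[-1])

    centers, rows, starts = [], [], []
    for start in range(col_lo, col_hi + 1, window):
        block = pixels[:, start:min(start + window, col_hi + 1)]
        ys, xs = np.nonzero(block)
        if len(ys):
            centers.append(start + xs.mean())
            rows.append(ys.mean())
            starts.append(start)
    centers = np.asarray(centers)
    rows = np.asarray(rows)
    starts = np.asarray(starts)

    # split where consecutive populated windows are further apart than the
    # bridgeable gap, keep the longest run
    max_gap = window * gap_factor
    breaks = np.flatnonzero(np.diff(centers) > max_gap)
    segments = np.split(np.arange(len(centers)), breaks + 1)
    if len(segments) > 1:
        warnings.warn(
            f"CEJ mask has {len(segments)} fragments separated by more than "
            f"{max_gap} columns; keeping the longest", stacklevel=2)
    seg = max(segments, key=lambda idx: centers[idx[-1]] - centers[idx[0]]
              if len(idx) else -1)
    centers, rows = centers[seg], rows[seg]

    # emit one point per pixel column covered by the kept segment's windows
    seg_cols = cols[(cols >= starts[seg[0]]) & (cols < starts[seg[-1]] + window)]
    xs = np.arange(int(seg_cols[0]), int(seg_cols[-1]) + 1)
    ys = np.rint(np.interp(xs, centers, rows)).astype(int)
    return CEJPolyline(points=np.stack([xs, ys], axis=1))
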