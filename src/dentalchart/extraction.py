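"""Per-tooth bounding boxes and crops from cleaned masks.

Panoramic teeth get plain contour-extent boxes.  Intraoral teeth
(periapical / bitewing) are boxed by four landmarks per tooth: the
leftmost and rightmost points where the tooth contour meets the CEJ
polyline, and the root apex (the contour's rootward extreme) — so the
box spans the root from CEJ to apex, the region bone-loss measurement
cares about.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .masks import CEJPolyline, Mask, extract_contours

__all__ = [
    "ToothBox",
    "ToothCrop",
    "boxes_from_panoramic",
    "boxes_from_intraoral",
    "crop_teeth",
]

#: Rows of tolerance when testing whether a contour point lies on the CEJ.
CEJ_TOLERANCE = 3
#: Padding (px) added around the landmark extent.
BOX_PAD = 2


@dataclass(frozen=True)
class ToothBox:
    """Half-open axis-aligned box ``[x0, x1) x [y0, y1)``."""

    x0: int
    y0: int
    x1: int
    y1: int
    source_kind: str = "panoramic"  # panoramic | periapical | bitewing

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"degenerate box {(self.x0, self.y0, self.x1, self.y1)}")

    @property
    def extent(self) -> tuple[int, int, int, int]:
        return (self.x0, self.y0, self.x1, self.y1)

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)


@dataclass
class ToothCrop:
    patch: np.ndarray
    box: ToothBox
    provenance: str = ""

    def __post_init__(self) -> None:
        h, w = self.patch.shape[:2]
        if (w, h) != (self.box.x1 - self.box.x0, self.box.y1 - self.box.y0):
            raise ValueError("crop patch dimensions do not match its box")


def _clip_box(x0: float, y0: float, x1: float, y1: float,
              shape: tuple[int, int], kind: str) -> ToothBox:
    h, w = shape
    return ToothBox(x0=max(0, int(np.floor(x0))), y0=max(0, int(np.floor(y0))),
                    x1=min(w, int(np.ceil(x1))), y1=min(h, int(np.ceil(y1))),
                    source_kind=kind)


def boxes_from_panoramic(tooth_mask: Mask) -> list[ToothBox]:
    """Axis-aligned extent of each tooth contour, ordered left to right."""
    boxes = []
    for contour in extract_contours(tooth_mask):
        boxes.append(_clip_box(contour[:, 0].min(), contour[:, 1].min(),
                               contour[:, 0].max() + 1, contour[:, 1].max() + 1,
                               tooth_mask.shape, "panoramic"))
    return sorted(boxes, key=lambda b: b.x0)


def _contour_cej_crossings(contour: np.ndarray, cej: CEJPolyline,
                           tol: int) -> np.ndarray:
    """(x, y) points where the closed contour crosses the CEJ polyline.

    Crossings are linearly interpolated between consecutive contour
    vertices whose signed distance to the polyline changes sign; vertices
    within ``tol`` rows of the line count as touching it.  Only crossings
    inside the polyline's column span (± tol) are kept.
    """
    xs, ys = contour[:, 0], contour[:, 1]
    d = ys - np.array([cej.y_at(x) for x in xs])
    points = []
    for i in range(len(contour) - 1):
        d0, d1 = d[i], d[i + 1]
        if abs(d0) <= 0.5:
            points.append((xs[i], ys[i]))
        if d0 * d1 < 0:
            t = d0 / (d0 - d1)
            points.append((xs[i] + t * (xs[i + 1] - xs[i]),
                           ys[i] + t * (ys[i + 1] - ys[i])))
    if not points:  # grazing contact: fall back to the tolerance band
        near = np.abs(d) <= tol
        points = list(zip(xs[near], ys[near]))
    if not points:
        return np.empty((0, 2))
    pts = np.asarray(points)
    lo, hi = cej.points[0, 0] - tol, cej.points[-1, 0] + tol
    return pts[(pts[:, 0] >= lo) & (pts[:, 0] <= hi)]


def _intraoral_box_for_contour(
    contour: np.ndarray, cej: CEJPolyline, rootward: str,
    shape: tuple[int, int], kind: str, tol: int, pad: int,
) -> ToothBox | None:
    xs, ys = contour[:, 0], contour[:, 1]
    crossings = _contour_cej_crossings(contour, cej, tol)
    if len(crossings) == 0:
        return None
    left = crossings[:, 0].min()
    right = crossings[:, 0].max()
    if rootward == "up":
        apex_idx = int(np.argmin(ys))
        y0 = ys[apex_idx]
        y1 = max(cej.y_at(left), cej.y_at(right)) + 1
    else:
        apex_idx = int(np.argmax(ys))
        y0 = min(cej.y_at(left), cej.y_at(right))
        y1 = ys[apex_idx] + 1
    # box = extent of {left crossing, right crossing, apex}
    left = min(left, xs[apex_idx])
    right = max(right, xs[apex_idx])
    return _clip_box(left - pad, y0 - pad, right + 1 + pad, y1 + pad, shape, kind)


def boxes_from_intraoral(
    tooth_mask: Mask,
    cej: CEJPolyline | tuple[CEJPolyline, CEJPolyline],
    position: str,
    tol: int = CEJ_TOLERANCE,
    pad: int = BOX_PAD,
) -> list[ToothBox]:
    """Four-point (CEJ crossings + root apex) boxes for intraoral teeth.

    ``position`` is ``maxilla`` (roots up), ``mandible`` (roots down) or
    ``bitewing`` (``cej`` must then be the (upper, lower) polyline pair;
    the image is split at the midline between the two CEJ branches and
    each half treated as the corresponding single arch).  Contours that
    never meet the CEJ within ``tol`` rows are skipped with a warning.
    """
    if position not in ("maxilla", "mandible", "bitewing"):
        raise ValueError(f"unknown position {position!r}")
    shape = tooth_mask.shape
    contours = extract_contours(tooth_mask)
    kind = "bitewing" if position == "bitewing" else "periapical"

    if position == "bitewing":
        cej_u, cej_l = cej
        midline = (cej_u.mean_row + cej_l.mean_row) / 2.0
        plan = [(cej_u, "up", lambda c: c[:, 1].mean() < midline),
                (cej_l, "down", lambda c: c[:, 1].mean() >= midline)]
    else:
        rootward = "up" if position == "maxilla" else "down"
        plan = [(cej, rootward, lambda c: True)]

    boxes = []
    for contour in contours:
        matched = False
        for polyline, rootward, selector in plan:
            if not selector(contour):
                continue
            box = _intraoral_box_for_contour(contour, polyline, rootward,
                                             shape, kind, tol, pad)
            if box is not None:
                boxes.append(box)
                matched = True
            break
        if not matched:
            warnings.warn("tooth contour with no CEJ crossing skipped",
                          stacklevel=2)
    return sorted(boxes, key=lambda b: b.x0)


def crop_teeth(image: np.ndarray, boxes: list[ToothBox],
               provenance: str = "") -> list[ToothCrop]:
    """Pixel-exact crops for each box, order preserved."""
    image = np.asarray(image)
    h, w = image.shape[:2]
    crops = []
    for i, box in enumerate(boxes):
        if box.x0 < 0 or box.y0 < 0 or box.x1 > w or box.y1 > h:
            raise ValueError(f"box {i} out of image bounds: {box.extent}")
        crops.append(ToothCrop(patch=image[box.y0:box.y1, box.x0:box.x1].copy(),
                               box=box, provenance=provenance))
    return crops
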