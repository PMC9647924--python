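"""Radiograph position detection and full-mouth-series arrangement.

Position follows the bone/CEJ geometry rules: two vertically separated
bone areas mean a bitewing; otherwise bone above the CEJ line means
maxillary and bone below means mandibular.  A set of positioned,
numbered radiographs is then arranged into the standard 3-row FMS
template (top maxillary, middle bitewing, bottom mandibular), each row
ordered from the patient's right to left.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .masks import CEJPolyline, Mask
from .matching import Assignment
from .repository import arch_order

__all__ = ["Position", "FMSSlot", "FMSTemplate", "detect_position", "arrange_fms"]

#: Bone components count as two separate areas (bitewing) when their
#: centroid rows differ by at least this fraction of the image height.
BITEWING_SEPARATION = 0.20
MIN_BONE_AREA = 50


@dataclass(frozen=True)
class Position:
    value: str  # maxilla | mandible | bitewing

    def __post_init__(self) -> None:
        if self.value not in ("maxilla", "mandible", "bitewing"):
            raise ValueError(f"invalid position {self.value!r}")


@dataclass
class FMSSlot:
    radiograph_id: str
    fdi_set: frozenset[int]
    order_key: float


@dataclass
class FMSTemplate:
    top: list[FMSSlot] = field(default_factory=list)  # maxillary
    middle: list[FMSSlot] = field(default_factory=list)  # bitewing
    bottom: list[FMSSlot] = field(default_factory=list)  # mandibular
    unplaced: list[str] = field(default_factory=list)
    overlaps: list[tuple[str, str]] = field(default_factory=list)

    @property
    def rows(self) -> dict[str, list[FMSSlot]]:
        return {"top": self.top, "middle": self.middle, "bottom": self.bottom}


def detect_position(
    bone_mask: Mask,
    cej: CEJPolyline | tuple[CEJPolyline, CEJPolyline] | None = None,
    min_area: int = MIN_BONE_AREA,
    separation: float = BITEWING_SEPARATION,
) -> Position:
    """Classify a radiograph as maxilla / mandible / bitewing.

    The two-bone-areas test runs first; the above/below-CEJ comparison
    (largest bone component centroid row vs. CEJ mean row) only applies
    to single-arch images and requires ``cej``.
    """
    pixels = np.asarray(bone_mask.pixels, dtype=bool)
    labels, n = ndimage.label(pixels, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise ValueError("position undeterminable: empty bone mask")
    areas = np.bincount(labels.ravel())[1:]
    big = np.flatnonzero(areas >= min_area) + 1
    if len(big) == 0:
        big = np.array([int(np.argmax(areas)) + 1])
    centroids = np.array([ndimage.center_of_mass(labels == lab)[0] for lab in big])
    if len(big) >= 2:
        height = pixels.shape[0]
        if centroids.max() - centroids.min() >= separation * height:
            return Position("bitewing")
    bone_row = float(centroids[np.argmax(areas[big - 1])])
    if cej is None:
        raise ValueError("position undeterminable: single bone area but no CEJ line")
    if isinstance(cej, tuple):
        cej_row = float(np.mean([p.mean_row for p in cej]))
    else:
        cej_row = cej.mean_row
    return Position("maxilla" if bone_row < cej_row else "mandible")


def arrange_fms(
    radiographs: list[tuple[str, Position, list[Assignment]]],
) -> FMSTemplate:
    """Arrange positioned, numbered radiographs into the 3-row template.

    Within a row, radiographs are ordered by the mean arch-order index of
    their assigned FDI numbers (0 at the patient's right for both arches,
    so every row runs patient-right to patient-left).  Radiographs with no
    assignments land in ``unplaced``; overlapping tooth coverage within a
    row is kept but flagged in ``overlaps``.
    """
    template = FMSTemplate()
    row_of = {"maxilla": template.top, "bitewing": template.middle,
              "mandible": template.bottom}
    for image_id, position, assignments in radiographs:
        fdis = frozenset(a.fdi for a in assignments)
        if not fdis:
            template.unplaced.append(image_id)
            continue
        key = float(np.mean([arch_order(f) for f in fdis]))
        row_of[position.value].append(
            FMSSlot(radiograph_id=image_id, fdi_set=fdis, order_key=key))
    for row in (template.top, template.middle, template.bottom):
        row.sort(key=lambda slot: (slot.order_key, slot.radiograph_id))
        for a, b in zip(row, row[1:]):
            if a.fdi_set & b.fdi_set:
                template.overlaps.append((a.radiograph_id, b.radiograph_id))
    return template
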