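"""Radiographic bone loss (RBL) measurement and periodontal staging.

RBL expresses the CEJ-to-alveolar-crest distance as a percentage of the
CEJ-to-root-apex length:

    RBL% = 100 * |CEJ -> bone level| / |CEJ -> root apex|

with the bone point projected onto the CEJ->apex axis.  Stages follow
the 2018 periodontitis classification: Stage 1 for RBL < 15%, Stage 2
for 15% <= RBL <= 33%, Stage 3 for RBL > 33%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .extraction import ToothBox
from .masks import CEJPolyline, Mask
from .matching import Assignment

__all__ = [
    "STAGE1_MAX_RBL",
    "STAGE2_MAX_RBL",
    "ToothLandmarks",
    "RBLRecord",
    "compute_rbl",
    "assign_stage",
    "tooth_report",
    "landmarks_from_masks",
]

STAGE1_MAX_RBL = 15.0  # below this: Stage 1 (coronal third of the root)
STAGE2_MAX_RBL = 33.0  # 15..33 inclusive: Stage 2; beyond: Stage 3


@dataclass(frozen=True)
class ToothLandmarks:
    """Three collinear-ish landmarks on one side (mesial/distal) of a tooth."""

    cej_point: tuple[float, float]
    bone_point: tuple[float, float]
    apex_point: tuple[float, float]
    side: str = "mesial"
    provenance: str = ""

    def __post_init__(self) -> None:
        pts = {self.cej_point, self.bone_point, self.apex_point}
        if self.cej_point == self.apex_point:
            raise ValueError("zero root length: CEJ and apex coincide")
        if self.side not in ("mesial", "distal"):
            raise ValueError(f"invalid side {self.side!r}")


def compute_rbl(landmarks: ToothLandmarks) -> float:
    """RBL percentage: bone-point offset along the CEJ->apex axis, as a
    percentage of root length, clipped to [0, 100]."""
    cej = np.asarray(landmarks.cej_point, dtype=float)
    bone = np.asarray(landmarks.bone_point, dtype=float)
    apex = np.asarray(landmarks.apex_point, dtype=float)
    axis = apex - cej
    root_len = float(np.linalg.norm(axis))
    if root_len == 0:
        raise ValueError("zero root length: CEJ and apex coincide")
    t = float(np.dot(bone - cej, axis)) / root_len
    return float(np.clip(100.0 * t / root_len, 0.0, 100.0))


def assign_stage(rbl_percent: float) -> int:
    """2018-classification stage for an RBL percentage in [0, 100]."""
    if not 0.0 <= rbl_percent <= 100.0:
        raise ValueError(f"RBL percentage out of range: {rbl_percent}")
    if rbl_percent < STAGE1_MAX_RBL:
        return 1
    if rbl_percent <= STAGE2_MAX_RBL:
        return 2
    return 3


@dataclass
class RBLRecord:
    fdi: int
    rbl_percent: float
    stage: int
    side: str = "mesial"

    def __post_init__(self) -> None:
        if self.stage != assign_stage(self.rbl_percent):
            raise ValueError("stage inconsistent with rbl_percent")


def tooth_report(assignment: Assignment, landmarks: ToothLandmarks,
                 provenance: str = "") -> RBLRecord:
    """Per-tooth-side diagnostic record combining number and bone loss."""
    if provenance and landmarks.provenance and provenance != landmarks.provenance:
        raise ValueError(
            f"assignment and landmarks refer to different crops: "
            f"{provenance!r} vs {landmarks.provenance!r}")
    rbl = compute_rbl(landmarks)
    return RBLRecord(fdi=assignment.fdi, rbl_percent=rbl,
                     stage=assign_stage(rbl), side=landmarks.side)


def landmarks_from_masks(
    box: ToothBox,
    cej: CEJPolyline,
    bone_mask: Mask,
    tooth_mask: Mask,
    position: str,
    side: str = "mesial",
    provenance: str = "",
) -> ToothLandmarks:
    """Rule-based landmark localization from masks for one tooth box.

    The CEJ point sits on the polyline at the box's mesial/distal edge;
    the bone point is the alveolar-crest pixel (the bone-mask boundary
    row closest to the CEJ on the rootward side) in that column; the apex
    is the tooth's rootward pixel extreme inside the box.
    """
    rootward_up = position == "maxilla"
    inset = 2
    x = box.x0 + inset if side == "mesial" else box.x1 - 1 - inset
    x = int(np.clip(x, 0, bone_mask.shape[1] - 1))
    cej_y = cej.y_at(x)

    sub = np.asarray(tooth_mask.pixels, dtype=bool)[box.y0:box.y1, box.x0:box.x1]
    ys, xs = np.nonzero(sub)
    if len(ys) == 0:
        raise ValueError("no tooth pixels inside box")
    # use the apex on this side's half of the tooth (mesial site -> mesial
    # root apex) so the measurement axis stays near-parallel to the root
    mid = (box.x1 - box.x0) / 2.0
    half = xs <= mid if side == "mesial" else xs >= mid
    if half.any():
        ys, xs = ys[half], xs[half]
    apex_idx = np.argmin(ys) if rootward_up else np.argmax(ys)
    apex = (float(box.x0 + xs[apex_idx]), float(box.y0 + ys[apex_idx]))

    # bone point: first bone pixel met walking the CEJ->apex ray (the
    # alveolar crest boundary nearest the CEJ on the rootward side)
    bone = np.asarray(bone_mask.pixels, dtype=bool)
    h, w = bone.shape
    start = np.array([float(x), float(cej_y)])
    axis = np.asarray(apex) - start
    length = float(np.linalg.norm(axis))
    bone_point = None
    for t in np.linspace(0.0, 1.0, max(3, int(2 * length) + 1)):
        px, py = start + t * axis
        xi, yi = int(round(px)), int(round(py))
        if 0 <= yi < h and 0 <= xi < w and bone[yi, xi]:
            bone_point = (float(px), float(py))
            break
    if bone_point is None:
        raise ValueError(f"no bone pixels along the CEJ->apex axis at column {x}")
    return ToothLandmarks(cej_point=(float(x), float(cej_y)),
                          bone_point=bone_point,
                          apex_point=apex, side=side, provenance=provenance)
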