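"""FDI number assignment by multi-scale template matching.

Each extracted tooth crop is resized over a grid of scales and scored
against every repository entry with zero-normalized cross-correlation
(ZNCC); the entry's score is its best over scales and shifts.  The crop's
FDI number is decided by majority vote over the top-k (default 10)
scoring entries, with ties broken by the larger mean score among tied
labels, then by the single best score.

Two modes mirror clinical availability: ``repository`` matches against a
persistent labeled repository; ``panoramic_view`` builds a transient
repository from the patient's own panoramic radiograph, whose teeth are
labeled by their order along each arch.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from skimage import exposure, transform
from skimage.feature import match_template

from .extraction import ToothCrop, boxes_from_panoramic, crop_teeth
from .masks import Mask
from .repository import (ARCH_MANDIBLE, ARCH_MAXILLA, Repository,
                         RepositoryEntry)

__all__ = [
    "DEFAULT_SCALES",
    "MatchScore",
    "Assignment",
    "match_score",
    "assign_number",
    "assign_numbers_via_panoramic",
    "label_panoramic_boxes",
]

#: Scale grid 0.5-1.5, step 0.1.
DEFAULT_SCALES: tuple[float, ...] = tuple(np.round(np.arange(0.5, 1.51, 0.1), 2))

#: A gap wider than this multiple of the median inter-box gap marks one or
#: more missing teeth when labeling a panoramic arch.
MISSING_GAP_FACTOR = 1.5


@dataclass(frozen=True)
class MatchScore:
    entry_ref: int  # index into the repository's entry list
    scale: float
    score: float


@dataclass
class Assignment:
    fdi: int
    votes: dict[int, int]
    top_scores: list[MatchScore]
    mode: str = "repository"  # repository | panoramic_view

    @property
    def best_score(self) -> float:
        return self.top_scores[0].score if self.top_scores else float("nan")


def _as_float(patch: np.ndarray) -> np.ndarray:
    patch = np.asarray(patch, dtype=float)
    if patch.ndim == 3:
        patch = patch.mean(axis=2)
    return patch


def _zncc_direct(template: np.ndarray, image: np.ndarray) -> float:
    """Direct sliding-window ZNCC; fast for the small patches teeth give."""
    th, tw = template.shape
    windows = np.lib.stride_tricks.sliding_window_view(image, (th, tw))
    tz = template - template.mean()
    t_norm = np.sqrt((tz * tz).sum())
    n = th * tw
    s1 = windows.sum(axis=(2, 3))
    s2 = np.einsum("ijkl,ijkl->ij", windows, windows)
    cross = np.einsum("ijkl,kl->ij", windows, tz)
    var = np.maximum(s2 - s1 * s1 / n, 0.0)
    denom = np.sqrt(var) * t_norm
    with np.errstate(divide="ignore", invalid="ignore"):
        ncc = np.where(denom > np.finfo(float).eps * n * 10,
                       cross / denom, 0.0)
    return float(np.clip(ncc, -1.0, 1.0).max())


def _zncc_max(template: np.ndarray, image: np.ndarray) -> float:
    """Max zero-normalized cross-correlation of template slid over image;
    the image is padded with its minimum when smaller than the template."""
    if template.std() == 0 or image.std() == 0:
        warnings.warn("degenerate (constant) patch in match_score; score = 0",
                      stacklevel=3)
        return 0.0
    th, tw = template.shape
    ih, iw = image.shape
    if ih < th or iw < tw:
        pad_h = max(0, th - ih)
        pad_w = max(0, tw - iw)
        image = np.pad(image,
                       ((pad_h // 2, pad_h - pad_h // 2),
                        (pad_w // 2, pad_w - pad_w // 2)),
                       constant_values=float(image.min()))
        ih, iw = image.shape
    # direct evaluation beats FFT-based matching for tooth-sized patches
    if (ih - th + 1) * (iw - tw + 1) * th * tw <= 5_000_000:
        return _zncc_direct(template, image)
    return float(np.clip(match_template(image, template), -1.0, 1.0).max())


def _resize_by(patch: np.ndarray, scale: float) -> np.ndarray:
    if scale == 1.0:
        return patch
    h = max(2, round(patch.shape[0] * scale))
    w = max(2, round(patch.shape[1] * scale))
    return transform.resize(patch, (h, w), order=1, anti_aliasing=scale < 1,
                            preserve_range=True)


def match_score(crop: ToothCrop | np.ndarray, entry: RepositoryEntry | np.ndarray,
                scale: float = 1.0) -> MatchScore:
    """ZNCC similarity of a crop (resized by ``scale``) against one entry."""
    crop_patch = _as_float(crop.patch if isinstance(crop, ToothCrop) else crop)
    entry_patch = _as_float(entry.crop if isinstance(entry, RepositoryEntry)
                            else entry)
    if crop_patch.size == 0 or entry_patch.size == 0:
        raise ValueError("empty patch in match_score")
    template = _resize_by(crop_patch, scale)
    return MatchScore(entry_ref=-1, scale=scale,
                      score=_zncc_max(template, entry_patch))


def _prep(patch: np.ndarray, equalize: bool) -> np.ndarray:
    patch = _as_float(patch)
    if equalize and patch.std() > 0:
        patch = exposure.equalize_hist(patch)
    return patch


def assign_number(
    crop: ToothCrop | np.ndarray,
    repo: Repository,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    k: int = 10,
    mode: str = "repository",
    equalize: bool = True,
) -> Assignment:
    """Assign an FDI number by top-k majority voting over best match scores."""
    if len(repo) == 0:
        raise ValueError("cannot assign numbers against an empty repository")
    if k < 1:
        raise ValueError("k must be >= 1")
    crop_patch = _prep(crop.patch if isinstance(crop, ToothCrop) else crop,
                       equalize)
    entries = [_prep(e.crop, equalize) for e in repo.entries]
    best = np.full(len(entries), -np.inf)
    best_scale = np.ones(len(entries))
    for scale in scales:
        template = _resize_by(crop_patch, scale)
        for i, entry_patch in enumerate(entries):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                s = _zncc_max(template, entry_patch)
            if s > best[i]:
                best[i] = s
                best_scale[i] = scale
    order = np.argsort(-best, kind="stable")[:k]
    top = [MatchScore(entry_ref=int(i), scale=float(best_scale[i]),
                      score=float(best[i])) for i in order]
    votes = Counter(repo.entries[s.entry_ref].fdi for s in top)
    max_votes = max(votes.values())
    tied = [fdi for fdi, v in votes.items() if v == max_votes]
    if len(tied) > 1:
        def tiebreak(fdi: int) -> tuple[float, float]:
            scores = [s.score for s in top if repo.entries[s.entry_ref].fdi == fdi]
            return (float(np.mean(scores)), float(np.max(scores)))
        tied.sort(key=tiebreak, reverse=True)
    return Assignment(fdi=tied[0], votes=dict(votes), top_scores=top, mode=mode)


def label_panoramic_boxes(
    boxes: list, *, missing_gap_factor: float = MISSING_GAP_FACTOR,
) -> list[int]:
    """Label panoramic tooth boxes with FDI numbers by arch order.

    Boxes are split into maxillary and mandibular rows at the widest
    vertical gap between box centers, each row is ordered left to right
    and mapped onto the arch sequence (18..11, 21..28 / 48..41, 31..38);
    an inter-box gap wider than ``missing_gap_factor`` times the median
    gap advances the sequence past the estimated number of missing teeth.
    """
    if not boxes:
        raise ValueError("no panoramic tooth boxes to label")
    centers_y = np.array([b.center[1] for b in boxes])
    order_y = np.argsort(centers_y)
    if len(boxes) > 1:
        gaps = np.diff(centers_y[order_y])
        split_at = int(np.argmax(gaps)) + 1
        if gaps.max() < 0.1 * (centers_y.max() - centers_y.min() + 1):
            split_at = len(boxes)  # effectively one row
    else:
        split_at = 1
    upper_idx = set(order_y[:split_at].tolist())

    labels = [0] * len(boxes)
    for row_idx, sequence in ((upper_idx, ARCH_MAXILLA),
                              (set(range(len(boxes))) - upper_idx, ARCH_MANDIBLE)):
        idx = sorted(row_idx, key=lambda i: boxes[i].x0)
        if not idx:
            continue
        widths = [boxes[i].x1 - boxes[i].x0 for i in idx]
        gaps = [max(0, boxes[b].x0 - boxes[a].x1) for a, b in zip(idx, idx[1:])]
        median_gap = float(np.median(gaps)) if gaps else 0.0
        median_width = float(np.median(widths))
        pos = 0
        prev_x1 = None
        for i in idx:
            if prev_x1 is not None:
                gap = boxes[i].x0 - prev_x1
                if median_gap >= 0 and gap > missing_gap_factor * max(median_gap, 1.0):
                    skipped = max(1, round((gap - median_gap)
                                           / (median_width + max(median_gap, 1.0))))
                    pos += skipped
            labels[i] = sequence[min(pos, len(sequence) - 1)]
            pos += 1
            prev_x1 = boxes[i].x1
    return labels


def assign_numbers_via_panoramic(
    crops: list[ToothCrop],
    panoramic_image: np.ndarray,
    panoramic_tooth_mask: Mask,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    k: int = 10,
    equalize: bool = True,
) -> list[Assignment]:
    """Number crops against a transient repository built from the patient's
    own panoramic radiograph (teeth labeled by arch order)."""
    boxes = boxes_from_panoramic(panoramic_tooth_mask)
    if not boxes:
        raise ValueError("panoramic image yielded no extracted teeth")
    labels = label_panoramic_boxes(boxes)
    pano_crops = crop_teeth(panoramic_image, boxes, provenance="panoramic")
    repo = Repository(entries=[
        RepositoryEntry(crop=c.patch, fdi=fdi, source_id="panoramic")
        for c, fdi in zip(pano_crops, labels)])
    return [assign_number(c, repo, scales=scales, k=k, mode="panoramic_view",
                          equalize=equalize) for c in crops]
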