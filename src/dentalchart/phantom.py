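"""Seeded generator of synthetic radiograph-like cases with gold annotations.

Every downstream stage (mask cleanup, tooth extraction, numbering,
arrangement, bone-loss staging, evaluation) is exercised against phantom
cases: images composed of per-FDI tooth glyphs placed along an arch, with
gold tooth / bone-area / CEJ masks, boxes, labels, positions, and known
bone-level fractions.  No claim of photorealism is made — glyphs only
need the class-level discriminability real teeth give the matcher.

Glyphs come in four archetypes (incisor, canine, premolar, molar)
parameterized by crown width, root count, and crown notching; each
position in the arch additionally carries a fixed smooth texture field so
the eight positions within a quadrant are pairwise distinguishable under
normalized cross-correlation.  Left/right quadrants are horizontal mirror
images; mandibular quadrants are vertically flipped (roots point down).

Coordinate conventions (used across the whole package): origin top-left,
x right, y down, 0-based, boxes half-open ``[x0, x1) x [y0, y1)``.
Gray levels: background 0, bone band mid-gray, teeth bright; the CEJ is
encoded only in its gold mask, never burned into the image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
from PIL import Image
from skimage import measure, transform

from .repository import ARCH_MANDIBLE, ARCH_MAXILLA, VALID_FDI, check_fdi

__all__ = [
    "PhantomConfig",
    "GoldTooth",
    "PhantomImage",
    "ToothStatus",
    "PhantomCase",
    "ToothGlyph",
    "generate_tooth_glyph",
    "generate_phantom_case",
    "write_case",
    "read_case",
    "PERIAPICAL_GROUPS",
    "BITEWING_GROUPS",
]

# ---------------------------------------------------------------------------
# glyph geometry (base scale, pixels)

_CROWN_W = {1: 20, 2: 22, 3: 22, 4: 26, 5: 28, 6: 38, 7: 40, 8: 36}
_ROOT_LEN = {1: 56, 2: 52, 3: 64, 4: 52, 5: 50, 6: 50, 7: 48, 8: 46}
_CROWN_LEN = {1: 24, 2: 24, 3: 28, 4: 22, 5: 22, 6: 26, 7: 26, 8: 24}

PAN_SCALE = 0.75
INTRAORAL_SCALE = 1.2

TOOTH_GRAY = 0.80
BONE_GRAY = 0.40

#: Standard full-mouth-series partition: 7 periapicals per arch.
PERIAPICAL_GROUPS = {
    "maxilla": [[18, 17, 16], [15, 14], [13, 12], [11, 21],
                [22, 23], [24, 25], [26, 27, 28]],
    "mandible": [[48, 47, 46], [45, 44], [43, 42], [41, 31],
                 [32, 33], [34, 35], [36, 37, 38]],
}

#: 4 bitewings: (maxillary teeth, mandibular teeth), image left to right.
BITEWING_GROUPS = [
    ([18, 17, 16], [48, 47, 46]),
    ([15, 14], [45, 44]),
    ([24, 25], [34, 35]),
    ([26, 27, 28], [36, 37, 38]),
]


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters; identical config (incl. seed) regenerates
    bit-identical cases."""

    image_size: tuple[int, int] = (512, 512)  # (width, height)
    quadrants_present: frozenset[int] = frozenset({1, 2, 3, 4})
    missing_fdi: frozenset[int] = frozenset()
    scale_jitter: float = 0.0
    position_jitter: int = 0
    bone_level_fraction: float | Mapping[int, float] = 0.10
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "quadrants_present",
                           frozenset(self.quadrants_present))
        object.__setattr__(self, "missing_fdi", frozenset(self.missing_fdi))
        if not self.quadrants_present <= {1, 2, 3, 4}:
            raise ValueError(f"invalid quadrants: {set(self.quadrants_present)}")
        bad = self.missing_fdi - VALID_FDI
        if bad:
            raise ValueError(f"missing_fdi contains invalid FDI numbers: {sorted(bad)}")
        if not 0 <= self.scale_jitter <= 0.5:
            raise ValueError("scale_jitter must be in [0, 0.5]")
        if self.position_jitter < 0 or self.noise_sigma < 0:
            raise ValueError("position_jitter and noise_sigma must be >= 0")
        for f in self._fraction_map().values():
            if not 0.0 <= f <= 1.0:
                raise ValueError("bone_level_fraction values must be in [0, 1]")

    def _fraction_map(self) -> dict[int, float]:
        if isinstance(self.bone_level_fraction, Mapping):
            base = {check_fdi(k): float(v)
                    for k, v in self.bone_level_fraction.items()}
            return {fdi: base.get(fdi, 0.10) for fdi in sorted(VALID_FDI)}
        return {fdi: float(self.bone_level_fraction) for fdi in sorted(VALID_FDI)}

    def tooth_present(self, fdi: int) -> bool:
        return fdi // 10 in self.quadrants_present and fdi not in self.missing_fdi


@dataclass
class GoldTooth:
    fdi: int
    box: tuple[int, int, int, int]  # half-open [x0, x1) x [y0, y1)
    bone_level_fraction: float | None = None


@dataclass
class PhantomImage:
    image_id: str
    kind: str  # panoramic | periapical | bitewing
    image: np.ndarray  # uint8 HxW
    tooth_mask: np.ndarray  # bool
    bone_mask: np.ndarray | None = None
    cej_mask: np.ndarray | None = None
    cej_rows: tuple[int, ...] = ()
    position: str | None = None  # maxilla | mandible | bitewing
    teeth: list[GoldTooth] = field(default_factory=list)


@dataclass
class ToothStatus:
    present: bool
    bone_level_fraction: float


@dataclass
class PhantomCase:
    panoramic: PhantomImage
    periapicals: list[PhantomImage]
    bitewings: list[PhantomImage]
    gold_chart: dict[int, ToothStatus]
    config: PhantomConfig

    @property
    def intraoral(self) -> list[PhantomImage]:
        return [*self.periapicals, *self.bitewings]


@dataclass
class ToothGlyph:
    """A rendered tooth patch in its quadrant orientation."""

    fdi: int
    scale: float
    patch: np.ndarray  # float in [0, 1], 0 outside the tooth
    mask: np.ndarray  # bool
    outline: np.ndarray  # (N, 2) float (x, y) closed polygon
    neck_offset: int  # rows from patch top to the CEJ level
    root_px: int  # root length in pixels at this scale


# ---------------------------------------------------------------------------
# glyph rendering

_base_cache: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  cells: tuple[int, int]) -> np.ndarray:
    """Unit-variance smooth random field via coarse noise upsampling."""
    coarse = rng.standard_normal(cells)
    fieldv = transform.resize(coarse, shape, order=3, mode="reflect",
                              anti_aliasing=False)
    std = fieldv.std()
    return fieldv / std if std > 0 else fieldv


def _base_glyph(index: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Quadrant-1 oriented glyph (root up) at unit scale: (patch, mask)."""
    key = (index, seed)
    if key in _base_cache:
        return _base_cache[key]
    w = _CROWN_W[index]
    root_len = _ROOT_LEN[index]
    crown_len = _CROWN_LEN[index]
    W = w + 2
    H = root_len + crown_len
    cx = (W - 1) / 2.0
    mask = np.zeros((H, W), dtype=bool)
    xs = np.arange(W)

    is_molar = index >= 6
    for r in range(root_len):  # apex (r=0) to neck
        t = r / root_len
        drift = 0.06 * w * (1 - t)  # asymmetric root curvature
        if is_molar and t < 0.80:
            hw = w * (0.05 + 0.10 * t)
            for c in (cx - 0.20 * w + drift, cx + 0.20 * w + drift):
                mask[r, np.abs(xs - c) <= hw] = True
        else:
            hw = w * (0.09 + 0.22 * t) if not is_molar else 0.34 * w
            mask[r, np.abs(xs - (cx + drift)) <= hw] = True

    for r in range(root_len, H):
        u = (r - root_len) / crown_len
        hw = w * (0.31 + 0.19 * min(u / 0.35, 1.0))
        if index == 3 and u > 0.45:  # canine point
            hw *= (1.0 - u) / 0.55
            c = cx + 0.08 * w
        else:
            c = cx
        row = np.abs(xs - c) <= hw
        if index in (4, 5) and u > 0.70:  # premolar notch
            row &= np.abs(xs - (cx + 0.05 * w)) > 0.10 * w * (u - 0.70) / 0.30
        if is_molar and u > 0.65:  # molar cusps
            nw = 0.08 * w * (u - 0.65) / 0.35
            row &= (np.abs(xs - (cx - 0.22 * w)) > nw) & \
                   (np.abs(xs - (cx + 0.22 * w)) > nw)
        mask[r, row] = True

    yy, xx = np.mgrid[0:H, 0:W]
    class_rng = np.random.default_rng(0xD5C0 + index)
    tex = 0.13 * _smooth_field(class_rng, (H, W), (9, 5))
    seed_rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0xA11, index])
    tex += 0.04 * _smooth_field(seed_rng, (H, W), (6, 4))
    ramps = 0.09 * (xx / W - 0.5) + 0.07 * (yy / H - 0.5)
    patch = np.clip(TOOTH_GRAY + tex + ramps, 0.55, 1.0) * mask
    _base_cache[key] = (patch, mask)
    return patch, mask


def _outline(mask: np.ndarray) -> np.ndarray:
    padded = np.pad(mask, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    rc = max(contours, key=len) - 1.0
    return rc[:, ::-1].copy()


def generate_tooth_glyph(fdi: int, scale: float, seed: int) -> ToothGlyph:
    """Render the glyph for one FDI tooth at the given scale.

    The shape is a deterministic function of (position in quadrant,
    quadrant mirroring, scale, seed).  Left quadrants (2, 3) are
    horizontal mirrors of right ones; mandibular quadrants (3, 4) are
    vertically flipped so roots point down.
    """
    check_fdi(fdi)
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    quadrant, index = divmod(fdi, 10)
    patch, mask = _base_glyph(index, seed)
    if scale != 1.0:
        H = max(2, round(patch.shape[0] * scale))
        W = max(2, round(patch.shape[1] * scale))
        patch = transform.resize(patch, (H, W), order=1, anti_aliasing=scale < 1,
                                 preserve_range=True)
        mask = transform.resize(mask.astype(float), (H, W), order=1,
                                anti_aliasing=False) > 0.5
        patch = patch * mask
    if quadrant in (2, 3):
        patch, mask = patch[:, ::-1], mask[:, ::-1]
    root_px = round(_ROOT_LEN[index] * scale)
    neck = root_px
    if quadrant in (3, 4):
        patch, mask = patch[::-1, :], mask[::-1, :]
        neck = patch.shape[0] - root_px
    return ToothGlyph(fdi=fdi, scale=scale, patch=np.ascontiguousarray(patch),
                      mask=np.ascontiguousarray(mask), outline=_outline(mask),
                      neck_offset=neck, root_px=root_px)


# ---------------------------------------------------------------------------
# case composition

def _place_glyph(canvas: np.ndarray, tooth_mask: np.ndarray, glyph: ToothGlyph,
                 x: int, cej_row: int) -> tuple[int, int, int, int]:
    """Paint a glyph with its CEJ level aligned to ``cej_row``; return the
    half-open extent box of its rendered pixels."""
    h, w = glyph.patch.shape
    top = cej_row - glyph.neck_offset
    H, W = canvas.shape
    y0c, x0c = max(top, 0), max(x, 0)
    y1c, x1c = min(top + h, H), min(x + w, W)
    sub = (slice(y0c - top, y1c - top), slice(x0c - x, x1c - x))
    region = (slice(y0c, y1c), slice(x0c, x1c))
    m = glyph.mask[sub]
    canvas[region] = np.where(m, glyph.patch[sub], canvas[region])
    tooth_mask[region] |= m
    ys, xs_ = np.nonzero(m)
    return (x0c + int(xs_.min()), y0c + int(ys.min()),
            x0c + int(xs_.max()) + 1, y0c + int(ys.max()) + 1)


def _root_side_box(tooth_mask: np.ndarray, box: tuple[int, int, int, int],
                   cej_row: int, rootward: str,
                   pad: int = 2) -> tuple[int, int, int, int]:
    """Extent of a tooth's pixels on the rootward side of the CEJ row,
    padded like the extractor's CEJ/apex boxes so gold and detected boxes
    share one convention."""
    x0, y0, x1, y1 = box
    sub = tooth_mask[y0:y1, x0:x1]
    rows = np.arange(y0, y1)
    keep = rows <= cej_row if rootward == "up" else rows >= cej_row
    sub = sub & keep[:, None]
    ys, xs = np.nonzero(sub)
    H, W = tooth_mask.shape
    return (max(0, x0 + int(xs.min()) - pad), max(0, y0 + int(ys.min()) - pad),
            min(W, x0 + int(xs.max()) + 1 + pad),
            min(H, y0 + int(ys.max()) + 1 + pad))


def _arch_layout(fdis: list[int], scale: float, width: int,
                 rng: np.random.Generator, cfg: PhantomConfig,
                 gap: int = 5) -> list[tuple[int, int, float, int, bool]]:
    """Left-to-right slot layout: (fdi, x, tooth_scale, dy, present)."""
    seq = []
    widths = []
    for fdi in fdis:
        s = scale
        if cfg.scale_jitter > 0:
            s = scale * (1.0 + rng.uniform(-cfg.scale_jitter, cfg.scale_jitter))
        widths.append(max(2, round((_CROWN_W[fdi % 10] + 2) * s)))
        seq.append(s)
    total = sum(widths) + gap * (len(fdis) - 1)
    x = max(2, (width - total) // 2)
    out = []
    for fdi, s, wpx in zip(fdis, seq, widths):
        dx = dy = 0
        if cfg.position_jitter > 0:
            dx = int(rng.integers(-cfg.position_jitter, cfg.position_jitter + 1))
            dy = int(rng.integers(-cfg.position_jitter, cfg.position_jitter + 1))
        out.append((fdi, x + dx, s, dy, cfg.tooth_present(fdi)))
        x += wpx + gap
    return out


def _finalize(img: np.ndarray, rng: np.random.Generator,
              noise_sigma: float) -> np.ndarray:
    if noise_sigma > 0:
        img = np.clip(img + rng.normal(0.0, noise_sigma / 255.0, img.shape), 0, 1)
    return np.rint(img * 255).astype(np.uint8)


def _render_panoramic(cfg: PhantomConfig, image_index: int) -> PhantomImage:
    W, H = cfg.image_size
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, image_index])
    noise_rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, image_index, 1])
    img = np.zeros((H, W))
    tooth = np.zeros((H, W), dtype=bool)
    teeth: list[GoldTooth] = []
    rows = {"maxilla": (ARCH_MAXILLA, round(H * 0.38)),
            "mandible": (ARCH_MANDIBLE, round(H * 0.63))}
    for arch, (seq, cej_row) in rows.items():
        for fdi, x, s, dy, present in _arch_layout(list(seq), PAN_SCALE, W, rng,
                                                   cfg, gap=4):
            if not present:
                continue
            glyph = generate_tooth_glyph(fdi, s, cfg.seed)
            box = _place_glyph(img, tooth, glyph, x, cej_row + dy)
            teeth.append(GoldTooth(fdi=fdi, box=box))
    return PhantomImage(image_id="pan", kind="panoramic",
                        image=_finalize(img, noise_rng, cfg.noise_sigma),
                        tooth_mask=tooth, teeth=teeth)


def _paint_bone_band(img: np.ndarray, bone: np.ndarray, tooth: np.ndarray,
                     crest: np.ndarray, cej_row: int, rootward: str,
                     depth: int) -> None:
    H, W = img.shape
    rows = np.arange(H)[:, None]
    if rootward == "up":
        band = (rows >= cej_row - depth) & (rows <= crest[None, :])
    else:
        band = (rows <= cej_row + depth) & (rows >= crest[None, :])
    bone |= band
    img[band & ~tooth] = BONE_GRAY


def _render_arch_intraoral(
    cfg: PhantomConfig, image_id: str, image_index: int,
    groups: list[tuple[list[int], int, str]],
    position: str, kind: str,
) -> PhantomImage | None:
    """Render one intraoral image; ``groups`` lists (fdis, cej_row, rootward)."""
    W, H = cfg.image_size
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, image_index])
    noise_rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, image_index, 1])
    frac = cfg._fraction_map()
    img = np.zeros((H, W))
    tooth = np.zeros((H, W), dtype=bool)
    bone = np.zeros((H, W), dtype=bool)
    cej = np.zeros((H, W), dtype=bool)
    teeth: list[GoldTooth] = []
    cej_rows: list[int] = []
    any_present = any(cfg.tooth_present(f) for fdis, _, _ in groups for f in fdis)
    if not any_present:
        return None

    band_depth = round(1.35 * _ROOT_LEN[3] * INTRAORAL_SCALE)
    for fdis, cej_row, rootward in groups:
        cej_rows.append(cej_row)
        sign = -1 if rootward == "up" else 1
        crest_default = cej_row + sign * round(0.10 * 55 * INTRAORAL_SCALE)
        crest = np.full(W, crest_default)
        placed = []
        layout = _arch_layout(fdis, INTRAORAL_SCALE, W, rng, cfg)
        for fdi, x, s, dy, present in layout:
            if not present:
                continue
            glyph = generate_tooth_glyph(fdi, s, cfg.seed)
            row = cej_row + dy
            full_box = _place_glyph(img, tooth, glyph, x, row)
            f = frac[fdi]
            crest_row = row + sign * max(1, round(f * glyph.root_px)) \
                if f > 0 else row + sign
            placed.append((fdi, full_box, row, crest_row, f))
        if not placed:
            continue
        # per-column crest: each tooth's slot (box +/- 4 px) carries its crest
        for fdi, (x0, _, x1, _), row, crest_row, f in placed:
            crest[max(0, x0 - 4):min(W, x1 + 4)] = crest_row
        _paint_bone_band(img, bone, tooth, crest, cej_row, rootward, band_depth)
        # CEJ line spans the rendered tooth region
        lo = max(0, min(b[1][0] for b in placed) - 8)
        hi = min(W, max(b[1][2] for b in placed) + 8)
        cej[cej_row, lo:hi] = True
        for fdi, full_box, row, crest_row, f in placed:
            box = _root_side_box(tooth, full_box, row, rootward)
            teeth.append(GoldTooth(fdi=fdi, box=box, bone_level_fraction=f))

    if not teeth:
        return None
    return PhantomImage(image_id=image_id, kind=kind,
                        image=_finalize(img, noise_rng, cfg.noise_sigma),
                        tooth_mask=tooth, bone_mask=bone, cej_mask=cej,
                        cej_rows=tuple(cej_rows), position=position, teeth=teeth)


def generate_phantom_case(config: PhantomConfig) -> PhantomCase:
    """Generate a full phantom case: 1 panoramic, up to 14 periapicals
    (7 maxillary + 7 mandibular) and 4 bitewings, plus the gold chart."""
    W, H = config.image_size
    pan = _render_panoramic(config, 0)
    periapicals: list[PhantomImage] = []
    idx = 1
    pa_cej = {"maxilla": (round(H * 0.59), "up"),
              "mandible": (round(H * 0.41), "down")}
    for arch in ("maxilla", "mandible"):
        cej_row, rootward = pa_cej[arch]
        for g, fdis in enumerate(PERIAPICAL_GROUPS[arch], start=1):
            image = _render_arch_intraoral(
                config, f"pa_{arch[:3]}_{g}", idx,
                [(fdis, cej_row, rootward)], arch, "periapical")
            idx += 1
            if image is not None:
                periapicals.append(image)
    bitewings: list[PhantomImage] = []
    cej_u, cej_l = round(H * 0.35), round(H * 0.65)
    for g, (upper, lower) in enumerate(BITEWING_GROUPS, start=1):
        image = _render_arch_intraoral(
            config, f"bw_{g}", idx,
            [(upper, cej_u, "up"), (lower, cej_l, "down")],
            "bitewing", "bitewing")
        idx += 1
        if image is not None:
            bitewings.append(image)
    frac = config._fraction_map()
    chart = {fdi: ToothStatus(config.tooth_present(fdi), frac[fdi])
             for fdi in sorted(VALID_FDI)}
    return PhantomCase(panoramic=pan, periapicals=periapicals,
                       bitewings=bitewings, gold_chart=chart, config=config)


# ---------------------------------------------------------------------------
# persistence

def _save_png(arr: np.ndarray, path: Path) -> None:
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    Image.fromarray(arr).save(path)


def _load_png(path: Path, binary: bool = False) -> np.ndarray:
    arr = np.asarray(Image.open(path))
    return arr > 127 if binary else arr.astype(np.uint8)


def _image_record(pi: PhantomImage, directory: Path) -> dict:
    rec = {
        "id": pi.image_id, "kind": pi.kind, "position": pi.position,
        "image": f"{pi.image_id}.png", "tooth_mask": f"{pi.image_id}_tooth.png",
        "cej_rows": list(pi.cej_rows),
        "teeth": [{"fdi": t.fdi, "box": list(t.box),
                   "bone_level_fraction": t.bone_level_fraction}
                  for t in pi.teeth],
    }
    _save_png(pi.image, directory / rec["image"])
    _save_png(pi.tooth_mask, directory / rec["tooth_mask"])
    for name in ("bone_mask", "cej_mask"):
        arr = getattr(pi, name)
        if arr is not None:
            fname = f"{pi.image_id}_{name.split('_')[0]}.png"
            rec[name] = fname
            _save_png(arr, directory / fname)
        else:
            rec[name] = None
    return rec


def write_case(case: PhantomCase, directory: str | Path) -> Path:
    """Write a case as PNGs + ``case_manifest.json`` (lossless round-trip)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = case.config
    manifest = {
        "schema": "dentalchart-case/1",
        "config": {
            "image_size": list(cfg.image_size),
            "quadrants_present": sorted(cfg.quadrants_present),
            "missing_fdi": sorted(cfg.missing_fdi),
            "scale_jitter": cfg.scale_jitter,
            "position_jitter": cfg.position_jitter,
            "bone_level_fraction": (
                {str(k): v for k, v in cfg.bone_level_fraction.items()}
                if isinstance(cfg.bone_level_fraction, Mapping)
                else cfg.bone_level_fraction),
            "noise_sigma": cfg.noise_sigma,
            "seed": cfg.seed,
        },
        "panoramic": _image_record(case.panoramic, directory),
        "periapicals": [_image_record(p, directory) for p in case.periapicals],
        "bitewings": [_image_record(b, directory) for b in case.bitewings],
        "gold_chart": {str(fdi): {"present": st.present,
                                  "bone_level_fraction": st.bone_level_fraction}
                       for fdi, st in sorted(case.gold_chart.items())},
    }
    path = directory / "case_manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def _read_image(rec: dict, directory: Path) -> PhantomImage:
    return PhantomImage(
        image_id=rec["id"], kind=rec["kind"], position=rec["position"],
        image=_load_png(directory / rec["image"]),
        tooth_mask=_load_png(directory / rec["tooth_mask"], binary=True),
        bone_mask=(_load_png(directory / rec["bone_mask"], binary=True)
                   if rec.get("bone_mask") else None),
        cej_mask=(_load_png(directory / rec["cej_mask"], binary=True)
                  if rec.get("cej_mask") else None),
        cej_rows=tuple(rec.get("cej_rows", ())),
        teeth=[GoldTooth(fdi=t["fdi"], box=tuple(t["box"]),
                         bone_level_fraction=t["bone_level_fraction"])
               for t in rec["teeth"]],
    )


def read_case(directory: str | Path) -> PhantomCase:
    """Reload a case written by :func:`write_case`."""
    directory = Path(directory)
    manifest = json.loads((directory / "case_manifest.json").read_text())
    c = manifest["config"]
    blf = c["bone_level_fraction"]
    if isinstance(blf, dict):
        blf = {int(k): v for k, v in blf.items()}
    cfg = PhantomConfig(
        image_size=tuple(c["image_size"]),
        quadrants_present=frozenset(c["quadrants_present"]),
        missing_fdi=frozenset(c["missing_fdi"]),
        scale_jitter=c["scale_jitter"], position_jitter=c["position_jitter"],
        bone_level_fraction=blf, noise_sigma=c["noise_sigma"], seed=c["seed"])
    chart = {int(k): ToothStatus(v["present"], v["bone_level_fraction"])
             for k, v in manifest["gold_chart"].items()}
    return PhantomCase(
        panoramic=_read_image(manifest["panoramic"], directory),
        periapicals=[_read_image(r, directory) for r in manifest["periapicals"]],
        bitewings=[_read_image(r, directory) for r in manifest["bitewings"]],
        gold_chart=chart, config=cfg)
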