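"""FDI-labeled tooth repository used as the matching reference.

The FDI (Fédération Dentaire Internationale) two-digit code is
``10 * quadrant + index`` with quadrant 1 = patient's upper right,
2 = upper left, 3 = lower left, 4 = lower right, and index 1 (central
incisor) through 8 (third molar).  A repository is a collection of
labeled tooth crops; unknown teeth are numbered by matching against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "VALID_FDI",
    "check_fdi",
    "fdi_to_universal",
    "arch_order",
    "ARCH_MAXILLA",
    "ARCH_MANDIBLE",
    "RepositoryEntry",
    "Repository",
    "build_repository",
    "save_repository",
    "load_repository",
]

VALID_FDI = frozenset(10 * q + i for q in (1, 2, 3, 4) for i in range(1, 9))

#: Left-to-right tooth sequence as seen on a correctly oriented radiograph
#: (patient's right appears on the image's left).
ARCH_MAXILLA: tuple[int, ...] = tuple(range(18, 10, -1)) + tuple(range(21, 29))
ARCH_MANDIBLE: tuple[int, ...] = tuple(range(48, 40, -1)) + tuple(range(31, 39))


def check_fdi(fdi: int) -> int:
    """Validate an FDI tooth number, returning it unchanged."""
    if fdi not in VALID_FDI:
        raise ValueError(f"invalid FDI tooth number: {fdi!r}")
    return int(fdi)


def fdi_to_universal(fdi: int) -> int:
    """Convert an FDI code to the US universal number (1-32).

    Universal numbering starts at the upper-right third molar (18 -> 1),
    runs across the maxilla to 28 -> 16, then continues on the mandible
    from the lower-left third molar (38 -> 17) back to 48 -> 32.
    """
    check_fdi(fdi)
    quadrant, index = divmod(fdi, 10)
    if quadrant == 1:
        return 9 - index
    if quadrant == 2:
        return 8 + index
    if quadrant == 3:
        return 25 - index
    return 24 + index


def arch_order(fdi: int) -> int:
    """Position of a tooth along its arch counted from the patient's right.

    0..15 within each arch; on a correctly oriented radiograph this runs
    left to right across the image for both arches.
    """
    universal = fdi_to_universal(fdi)
    if fdi // 10 in (1, 2):  # maxilla
        return universal - 1
    return 32 - universal  # mandible


@dataclass
class RepositoryEntry:
    """A single labeled tooth crop."""

    crop: np.ndarray
    fdi: int
    source_id: str = ""

    def __post_init__(self) -> None:
        check_fdi(self.fdi)
        self.crop = np.asarray(self.crop)
        if self.crop.size == 0:
            raise ValueError(f"empty crop for entry {self.source_id!r}")


@dataclass
class Repository:
    """Collection of FDI-labeled tooth crops matched against."""

    entries: list[RepositoryEntry] = field(default_factory=list)
    manifest_version: str = "1"

    def __len__(self) -> int:
        return len(self.entries)

    def missing_fdi_coverage(self) -> set[int]:
        """FDI numbers with no entry (must be empty for repository-mode matching)."""
        present = {e.fdi for e in self.entries}
        return set(VALID_FDI) - present

    def extend(self, other: "Repository") -> None:
        self.entries.extend(other.entries)


def _polygon_bbox(polygon: Sequence[Sequence[float]]) -> tuple[int, int, int, int]:
    pts = np.asarray(polygon, dtype=float)
    x0 = int(np.floor(pts[:, 0].min()))
    y0 = int(np.floor(pts[:, 1].min()))
    x1 = int(np.ceil(pts[:, 0].max())) + 1
    y1 = int(np.ceil(pts[:, 1].max())) + 1
    return x0, y0, x1, y1


def build_repository(
    panoramics: Iterable[tuple[np.ndarray, Sequence[dict], str]],
) -> Repository:
    """Build a repository from annotated panoramic images.

    Parameters
    ----------
    panoramics
        Iterable of ``(image, annotations, source_id)``; each annotation is
        a dict ``{"polygon": [[x, y], ...], "fdi": int}``.  The crop stored
        per tooth is the polygon's tight axis-aligned bounding-box crop.
    """
    repo = Repository()
    for image, annotations, source_id in panoramics:
        image = np.asarray(image)
        h, w = image.shape[:2]
        for ann in annotations:
            fdi = check_fdi(int(ann["fdi"]))
            x0, y0, x1, y1 = _polygon_bbox(ann["polygon"])
            if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
                raise ValueError(
                    f"polygon for FDI {fdi} outside image bounds in {source_id!r}"
                )
            repo.entries.append(
                RepositoryEntry(crop=image[y0:y1, x0:x1].copy(), fdi=fdi,
                                source_id=source_id)
            )
    return repo


def save_repository(repo: Repository, directory: str | Path) -> Path:
    """Persist a repository as ``manifest.json`` + ``crops/*.png``."""
    directory = Path(directory)
    crops_dir = directory / "crops"
    crops_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for i, entry in enumerate(repo.entries):
        fname = f"crops/{i:05d}_fdi{entry.fdi}.png"
        Image.fromarray(np.asarray(entry.crop, dtype=np.uint8)).save(directory / fname)
        records.append({"file": fname, "fdi": entry.fdi, "source_id": entry.source_id})
    manifest = {"manifest_version": repo.manifest_version, "entries": records}
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def load_repository(directory: str | Path) -> Repository:
    """Load a repository previously written by :func:`save_repository`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    entries = []
    for rec in manifest["entries"]:
        crop_path = directory / rec["file"]
        if not crop_path.exists():
            raise FileNotFoundError(f"manifest references missing crop: {crop_path}")
        crop = np.asarray(Image.open(crop_path), dtype=np.uint8)
        entries.append(RepositoryEntry(crop=crop, fdi=int(rec["fdi"]),
                                       source_id=rec.get("source_id", "")))
    return Repository(entries=entries,
                      manifest_version=str(manifest.get("manifest_version", "1")))
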