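"""Annotation and detection I/O for the camera-trap pipeline.

Handles the formats the pipeline touches at its boundaries: MegaDetector-style
batch JSON (read, as semi-automatic draft labels), YOLO label text files
(read/write, the training currency of the detectors), species list files, and
split manifests.  Also builds the per-group training sets for expert models
(class indices remapped to be contiguous within each group), computes inverse
frequency class weights for imbalanced species distributions, and partitions
records by camera site so that test images come from locations never seen in
training.

All boxes are kept in the normalised, center-based YOLO convention
(cx, cy, w, h as fractions of image size); corner-based dialects are converted
at the boundary so image dimensions are never needed internally.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .grouping import GroupAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "BoundingBox",
    "AnnotationRecord",
    "GroupDatasetSpec",
    "read_megadetector_detections",
    "write_yolo_labels",
    "read_yolo_labels",
    "read_class_list",
    "write_class_list",
    "remap_for_group",
    "class_weights",
    "site_heldout_split",
]


@dataclass(frozen=True)
class BoundingBox:
    """Normalised center-based box: center (cx, cy) and size (w, h), all as
    fractions of the image dimensions."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        for name in ("cx", "cy", "w", "h"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box must have positive size, got w={self.w}, h={self.h}")

    @classmethod
    def from_corner(cls, x_min: float, y_min: float, w: float, h: float,
                    clip: bool = False) -> "BoundingBox":
        """Build from the corner-based (x_min, y_min, w, h) dialect.

        With ``clip=True`` an out-of-range box is clipped to the unit square
        (a warning is emitted); otherwise it raises.
        """
        if clip:
            x0, y0 = max(x_min, 0.0), max(y_min, 0.0)
            x1, y1 = min(x_min + w, 1.0), min(y_min + h, 1.0)
            if (x0, y0, x1, y1) != (x_min, y_min, x_min + w, y_min + h):
                warnings.warn(
                    f"box ({x_min}, {y_min}, {w}, {h}) clipped to unit square",
                    stacklevel=2,
                )
            x_min, y_min, w, h = x0, y0, x1 - x0, y1 - y0
        return cls(x_min + w / 2, y_min + h / 2, w, h)

    def to_corner(self) -> tuple[float, float, float, float]:
        return (self.cx - self.w / 2, self.cy - self.h / 2, self.w, self.h)


@dataclass(frozen=True)
class AnnotationRecord:
    """One labelled image: its id, the camera site it came from, and the
    detected animals (possibly none — an empty/background image)."""

    image_id: str
    site_id: str
    detections: tuple[tuple[str, BoundingBox], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "detections", tuple(self.detections))

    @property
    def is_empty(self) -> bool:
        return len(self.detections) == 0

    @property
    def species(self) -> frozenset[str]:
        return frozenset(lab for lab, _ in self.detections)


@dataclass(frozen=True)
class GroupDatasetSpec:
    """Training set for one expert group: the group's records with species
    remapped to contiguous group-local class indices."""

    group_id: int
    class_map: dict[str, int]
    records: tuple[AnnotationRecord, ...]
    excluded_image_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        idx = sorted(self.class_map.values())
        if idx != list(range(len(idx))):
            raise ValueError(f"class indices must be contiguous from 0, got {idx}")
        for rec in self.records:
            foreign = rec.species - self.class_map.keys()
            if foreign:
                raise ValueError(
                    f"record {rec.image_id} contains out-of-group species {sorted(foreign)}"
                )


def read_megadetector_detections(
    path: str | Path,
    confidence_floor: float = 0.25,
    category_names: Mapping[str, str] | None = None,
) -> list[AnnotationRecord]:
    """Read a MegaDetector-style batch output file into annotation records.

    Each image entry carries detections as ``{"category", "conf",
    "bbox": [x_min, y_min, w, h]}`` with normalised corner-based boxes; these
    are converted to the center-based convention.  Detections below
    ``confidence_floor`` are dropped, and images with no surviving detection
    become empty records (no animal present).  Category ids are resolved
    through the file's ``detection_categories`` map unless ``category_names``
    overrides it.  The site id is the image path's parent directory, the
    usual one-folder-per-camera layout.
    """
    payload = json.loads(Path(path).read_text())
    if "images" not in payload:
        raise ValueError(f"{path}: not a detector batch file (no 'images' key)")
    categories = dict(category_names or payload.get("detection_categories", {}))
    records: list[AnnotationRecord] = []
    for idx, entry in enumerate(payload["images"]):
        try:
            image_id = entry["file"]
            detections = []
            for det in entry.get("detections", []):
                conf = float(det["conf"])
                if conf < confidence_floor:
                    continue
                label = categories.get(str(det["category"]), str(det["category"]))
                box = BoundingBox.from_corner(*det["bbox"], clip=True)
                detections.append((label, box))
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed image entry {idx}: {exc}") from exc
        site = str(Path(image_id).parent) if Path(image_id).parent != Path(".") else ""
        records.append(AnnotationRecord(image_id, site, tuple(detections)))
    return records


def _label_path(directory: Path, image_id: str) -> Path:
    return directory / (Path(image_id).stem + ".txt")


def write_yolo_labels(
    records: Iterable[AnnotationRecord],
    directory: str | Path,
    class_list: Sequence[str],
) -> list[Path]:
    """Write one YOLO label file per record: lines ``class_idx cx cy w h``
    with 6-decimal fixed-point coordinates.  Empty images produce empty
    (zero-byte) files, which is how YOLO training encodes background."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = {lab: i for i, lab in enumerate(class_list)}
    written = []
    for rec in records:
        lines = []
        for label, box in rec.detections:
            if label not in index:
                raise KeyError(f"label {label!r} not in class list")
            lines.append(
                f"{index[label]} {box.cx:.6f} {box.cy:.6f} {box.w:.6f} {box.h:.6f}"
            )
        path = _label_path(directory, rec.image_id)
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        written.append(path)
    return written


def read_yolo_labels(
    directory: str | Path,
    class_list: Sequence[str],
    site_of: Mapping[str, str] | None = None,
) -> list[AnnotationRecord]:
    """Read every ``*.txt`` YOLO label file in a directory back into records.

    The inverse of :func:`write_yolo_labels` up to 1e-6 per coordinate.
    Site ids are filled from ``site_of`` (image id -> site) when given.
    """
    directory = Path(directory)
    records = []
    for path in sorted(directory.glob("*.txt")):
        detections = []
        for ln, line in enumerate(path.read_text().splitlines()):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"{path}:{ln + 1}: expected 5 fields, got {len(parts)}")
            idx = int(parts[0])
            if not 0 <= idx < len(class_list):
                raise ValueError(f"{path}:{ln + 1}: class index {idx} out of range")
            cx, cy, w, h = map(float, parts[1:])
            detections.append((class_list[idx], BoundingBox(cx, cy, w, h)))
        image_id = path.stem
        site = site_of.get(image_id, "") if site_of else ""
        records.append(AnnotationRecord(image_id, site, tuple(detections)))
    return records


def read_class_list(path: str | Path) -> list[str]:
    """Species list file: one code per line, order defines class indices."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_class_list(classes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(classes) + "\n")


def remap_for_group(
    records: Iterable[AnnotationRecord],
    assignment: GroupAssignment,
    group_id: int,
) -> GroupDatasetSpec:
    """Build one expert group's training set.

    Records whose species all belong to the group are kept with class indices
    remapped to 0..n_group-1 (alphabetical within the group).  Empty images
    are shared into every group's set — each expert must be able to answer
    "background".  Images mixing species from different groups fit no single
    expert; they are excluded and reported.
    """
    if not 0 <= group_id < assignment.k:
        raise ValueError(f"group_id {group_id} out of range [0, {assignment.k})")
    group_species_ = sorted(assignment.members(group_id))
    class_map = {lab: i for i, lab in enumerate(group_species_)}
    known = set(assignment.labels)
    kept: list[AnnotationRecord] = []
    excluded: list[str] = []
    for rec in records:
        unknown = rec.species - known
        if unknown:
            raise KeyError(
                f"record {rec.image_id}: species {sorted(unknown)} not in assignment"
            )
        rec_groups = {assignment.group_of(lab) for lab in rec.species}
        if rec.is_empty:
            kept.append(rec)
        elif len(rec_groups) > 1:
            excluded.append(rec.image_id)
        elif rec_groups == {group_id}:
            kept.append(rec)
    if excluded:
        logger.info(
            "group %d: excluded %d mixed-group images: %s",
            group_id, len(excluded), excluded[:10],
        )
    return GroupDatasetSpec(group_id, class_map, tuple(kept), tuple(excluded))


def class_weights(counts: Mapping[str, int]) -> dict[str, float]:
    """Inverse-frequency class weights w_i = T / (K * n_i).

    T is the total count and K the number of classes, so balanced counts give
    every class weight 1 and the weighted total sum(n_i * w_i) always equals
    T.  Rare species receive proportionally larger weights, countering the
    heavy abundance imbalance of camera-trap datasets.
    """
    if not counts:
        raise ValueError("no classes given")
    for lab, n in counts.items():
        if n <= 0:
            raise ValueError(
                f"class {lab!r} has count {n}; merge it into another class or drop it"
            )
    total = sum(counts.values())
    k = len(counts)
    return {lab: total / (k * n) for lab, n in counts.items()}


def site_heldout_split(
    records: Sequence[AnnotationRecord],
    test_fraction: float,
    seed: int,
    by_image: bool = False,
) -> tuple[list[AnnotationRecord], list[AnnotationRecord]]:
    """Partition records by camera site into train and test sets.

    Whole sites go to one side or the other, so every test image comes from a
    location never seen in training.  ``by_image=True`` falls back to a plain
    per-image random split for comparison.  Deterministic for a fixed seed.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if by_image:
        n_test = max(1, round(test_fraction * len(records)))
        test_idx = set(rng.choice(len(records), size=n_test, replace=False).tolist())
        train = [r for i, r in enumerate(records) if i not in test_idx]
        test = [r for i, r in enumerate(records) if i in test_idx]
        return train, test
    sites = sorted({r.site_id for r in records})
    if len(sites) < 2:
        raise ValueError(f"need at least 2 sites for a held-out split, got {len(sites)}")
    n_test = min(max(1, round(test_fraction * len(sites))), len(sites) - 1)
    test_sites = set(rng.choice(sites, size=n_test, replace=False).tolist())
    train = [r for r in records if r.site_id not in test_sites]
    test = [r for r in records if r.site_id in test_sites]
    return train, test
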