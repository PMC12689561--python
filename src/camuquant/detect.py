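"""Reference fruit detector and ripeness stager.

A deliberately simple, fully deterministic front-end so the measurement
pipeline runs end-to-end without trained deep-learning weights: fruits on a
neutral (low-saturation) background are segmented by thresholding HSV
saturation and taking connected components; each region is staged by
nearest-prototype matching of its mean color against a four-stage palette.

Externally produced detections (e.g. from a transformer detector) enter the
same pipeline through :func:`load_external_detections`, which reads
COCO-style JSON whose category names are the stage names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import color as skcolor
from skimage import measure

from .calibration import CalibrationConfig, StageLabel

__all__ = [
    "FruitDetection",
    "StagePalette",
    "default_palette",
    "segment_fruits",
    "classify_stage",
    "load_external_detections",
    "write_detections_coco",
]


@dataclass
class FruitDetection:
    """One detected fruit region.

    ``bbox`` is COCO-convention ``(x, y, w, h)`` in pixels, top-left
    origin, half-open.  ``mask`` (optional) is a full-image boolean array
    marking the instance's pixels.
    """

    bbox: tuple[float, float, float, float]
    mask: np.ndarray | None = None
    confidence: float = 1.0
    stage: StageLabel | None = None


@dataclass(frozen=True)
class StagePalette:
    """Prototype colors (RGB, 0-255) for the four ripeness stages.

    Matching happens in a hue/saturation embedding (see
    :func:`classify_stage`), not raw RGB, for robustness to brightness
    changes.  ``tolerance`` is the advisory maximum prototype distance in
    that embedding; palettes whose prototypes sit closer than twice the
    tolerance risk ambiguous staging.
    """

    colors: dict[StageLabel, tuple[int, int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_COLORS)
    )
    tolerance: float = 0.25

    def __post_init__(self) -> None:
        if set(self.colors) != set(StageLabel):
            raise ValueError("palette must define all four stages")
        if len({c for c in self.colors.values()}) != 4:
            raise ValueError("palette prototypes must be pairwise distinct")


# Greens darken and redden as camu-camu ripens: deep green -> yellowish
# green -> orange-red -> dark purplish red.
_DEFAULT_COLORS = {
    StageLabel.GREEN: (70, 140, 60),
    StageLabel.PINTON_GREEN: (155, 170, 60),
    StageLabel.RIPE_PINTON: (190, 90, 60),
    StageLabel.RIPE: (120, 25, 45),
}


def default_palette() -> StagePalette:
    return StagePalette()


def _hs_embedding(rgb01: np.ndarray) -> np.ndarray:
    """Embed RGB in (S cos 2*pi*H, S sin 2*pi*H, V): Euclidean-comparable, no hue wrap."""
    hsv = skcolor.rgb2hsv(rgb01.reshape(1, 1, 3)).reshape(3)
    h, s, v = hsv
    return np.array([s * np.cos(2 * np.pi * h), s * np.sin(2 * np.pi * h), v])


def segment_fruits(
    image: np.ndarray,
    palette: StagePalette | None = None,
    min_area_px: float | None = None,
    cfg: CalibrationConfig | None = None,
    saturation_threshold: float = 0.15,
) -> list[FruitDetection]:
    """Segment fruits from a neutral background by saturation thresholding.

    Foreground = pixels whose HSV saturation exceeds ``saturation_threshold``
    (the neutral background is near-gray, saturation ~0).  Connected
    components with at least ``min_area_px`` pixels become detections with
    an instance mask and tight bounding box, confidence 1.0.  When a
    ``palette`` is given, each detection is staged immediately.

    ``min_area_px`` defaults to the pixel equivalent of 0.1 cm^2 at the
    configured scale — small enough to keep every fruit, large enough to
    drop specks.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    if min_area_px is None:
        scale = (cfg or CalibrationConfig()).px_per_cm
        min_area_px = 0.1 * scale**2
    img01 = _as_float01(image)
    sat = skcolor.rgb2hsv(img01)[..., 1]
    labels = measure.label(sat > saturation_threshold, connectivity=2)
    detections: list[FruitDetection] = []
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        r0, c0, r1, c1 = region.bbox
        det = FruitDetection(
            bbox=(float(c0), float(r0), float(c1 - c0), float(r1 - r0)),
            mask=labels == region.label,
            confidence=1.0,
        )
        if palette is not None:
            det.stage = classify_stage(image, det, palette)
        detections.append(det)
    return detections


def classify_stage(
    image: np.ndarray, detection: FruitDetection, palette: StagePalette
) -> StageLabel:
    """Stage a detection by nearest palette prototype to its mean color.

    The mean RGB over the detection's mask (or bounding box when no mask
    exists) and each prototype are embedded as
    ``(S cos 2*pi*H, S sin 2*pi*H, V)``; the stage with the smallest
    Euclidean distance wins, ties broken toward the lower ordinal.
    """
    img01 = _as_float01(image)
    if detection.mask is not None:
        pixels = img01[detection.mask]
    else:
        x, y, w, h = (int(round(v)) for v in detection.bbox)
        pixels = img01[y : y + h, x : x + w].reshape(-1, 3)
    if pixels.size == 0:
        raise ValueError("detection covers no pixels")
    feat = _hs_embedding(pixels.mean(axis=0))
    best: StageLabel | None = None
    best_d = np.inf
    for stage in sorted(StageLabel, key=lambda s: s.ordinal):
        proto = _hs_embedding(np.asarray(palette.colors[stage], dtype=float) / 255.0)
        d = float(np.linalg.norm(feat - proto))
        if d < best_d:  # strict: ties keep the lower ordinal
            best, best_d = stage, d
    assert best is not None
    return best


def _as_float01(image: np.ndarray) -> np.ndarray:
    if image.dtype == np.uint8:
        return image.astype(np.float64) / 255.0
    return np.asarray(image, dtype=np.float64)


# ---------------------------------------------------------------------------
# COCO-style JSON adapter


def stage_categories() -> list[dict]:
    """COCO category list: ids are stage ordinals + 1, names the stage names."""
    return [
        {"id": s.ordinal + 1, "name": s.value, "supercategory": "fruit"}
        for s in sorted(StageLabel, key=lambda s: s.ordinal)
    ]


def load_external_detections(path: str | Path) -> list[FruitDetection]:
    """Read detections from a COCO-style JSON annotation file.

    Category names must be ripeness stage names; anything else is rejected
    with an error naming the offending category or annotation.  Returns
    detections with bbox, stage and confidence (annotation ``score``,
    default 1.0).
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict) or "annotations" not in doc:
        raise ValueError(f"{path}: missing 'annotations' section")
    cat_to_stage: dict[int, StageLabel] = {}
    for cat in doc.get("categories", []):
        try:
            cat_to_stage[cat["id"]] = StageLabel.from_name(cat["name"])
        except ValueError:
            raise ValueError(
                f"{path}: category id={cat.get('id')} name={cat.get('name')!r} "
                "is not a ripeness stage"
            ) from None
    detections = []
    for ann in doc["annotations"]:
        cat_id = ann.get("category_id")
        if cat_id not in cat_to_stage:
            raise ValueError(
                f"{path}: annotation id={ann.get('id')} references unknown "
                f"category_id={cat_id}"
            )
        bbox = ann.get("bbox")
        if not (isinstance(bbox, (list, tuple)) and len(bbox) == 4):
            raise ValueError(f"{path}: annotation id={ann.get('id')} has malformed bbox")
        detections.append(
            FruitDetection(
                bbox=tuple(float(v) for v in bbox),
                confidence=float(ann.get("score", 1.0)),
                stage=cat_to_stage[cat_id],
            )
        )
    return detections


def write_detections_coco(
    detections: list[FruitDetection],
    path: str | Path,
    image_size: tuple[int, int],
    file_name: str = "image.png",
) -> None:
    """Write staged detections as a single-image COCO-style JSON file."""
    h, w = image_size
    annotations = []
    for i, det in enumerate(detections):
        if det.stage is None:
            raise ValueError(f"detection {i} has no stage; stage before writing")
        x, y, bw, bh = det.bbox
        annotations.append(
            {
                "id": i + 1,
                "image_id": 1,
                "category_id": det.stage.ordinal + 1,
                "bbox": [x, y, bw, bh],
                "area": bw * bh,
                "iscrowd": 0,
                "score": det.confidence,
            }
        )
    doc = {
        "images": [{"id": 1, "width": w, "height": h, "file_name": file_name}],
        "categories": stage_categories(),
        "annotations": annotations,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
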