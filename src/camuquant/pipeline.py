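"""End-to-end glue: image -> detections -> staged records -> image report."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .ascorbate import (
    FruitRecord,
    ImageReport,
    aggregate_image,
    estimate_concentration,
    fruit_total_ascorbate,
)
from .calibration import CalibrationConfig, StageLabel, px_area_to_cm2, region_area_px
from .detect import FruitDetection, StagePalette, classify_stage, default_palette, segment_fruits
from .pulp import estimate_pulp

__all__ = ["quantify_detections", "analyze_image", "load_image"]


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG image as an RGB uint8 array."""
    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"))


def quantify_detections(
    detections: list[FruitDetection],
    cfg: CalibrationConfig,
    pulp_estimator: str = "quadratic",
    shape_model: str = "auto",
) -> list[FruitRecord]:
    """Turn staged detections into quantified fruit records.

    Green fruits are flagged excluded and carry no pulp/ascorbate values;
    each commercial fruit gets a pulp mass (selected estimator), a
    concentration R2 = R1 * m_pulp / b1 and a total ascorbate in mg.
    """
    records = []
    for i, det in enumerate(detections):
        if det.stage is None:
            raise ValueError(f"detection {i} has no ripeness stage")
        area_px = region_area_px(det, shape_model)
        area_cm2 = px_area_to_cm2(area_px, cfg)
        if det.stage is StageLabel.GREEN:
            records.append(
                FruitRecord(
                    stage=det.stage,
                    area_px=area_px,
                    area_cm2=area_cm2,
                    pulp_g=None,
                    ascorbate_mg_per_100g=None,
                    ascorbate_total_mg=None,
                    excluded=True,
                )
            )
            continue
        pulp = estimate_pulp(area_cm2, det.stage, cfg, estimator=pulp_estimator)
        conc = estimate_concentration(
            cfg.stage_reference_conc[det.stage], pulp, cfg.reference_mass_g
        )
        records.append(
            FruitRecord(
                stage=det.stage,
                area_px=area_px,
                area_cm2=area_cm2,
                pulp_g=pulp,
                ascorbate_mg_per_100g=conc,
                ascorbate_total_mg=fruit_total_ascorbate(conc, pulp),
                excluded=False,
            )
        )
    return records


def analyze_image(
    image: np.ndarray | str | Path,
    cfg: CalibrationConfig | None = None,
    palette: StagePalette | None = None,
    detections: list[FruitDetection] | None = None,
    pulp_estimator: str = "quadratic",
) -> ImageReport:
    """Full pipeline for one image.

    With ``detections`` given (e.g. from an external detector via COCO
    JSON), the reference detector is skipped; unstaged detections are
    staged against the palette when pixel data is available.
    """
    cfg = cfg or CalibrationConfig()
    palette = palette or default_palette()
    if isinstance(image, (str, Path)):
        image = load_image(image)
    if detections is None:
        detections = segment_fruits(image, palette=palette, cfg=cfg)
    else:
        for det in detections:
            if det.stage is None:
                det.stage = classify_stage(image, det, palette)
    records = quantify_detections(detections, cfg, pulp_estimator=pulp_estimator)
    return aggregate_image(records, cfg)
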