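"""Synthetic scene generation with exact ground truth.

Emulates the study's acquisition geometry — a top-down camera at fixed
distance over ~15 camu-camu fruits on a neutral background — as rendered
rotated ellipses in the four stage colors.  Every generative parameter
(placement, size, stage, noise) derives from a single seeded RNG, so scenes
are byte-reproducible, and the ground truth carries each fruit's analytic
geometry plus the pulp mass and ascorbate concentration the calibrated
pipeline is expected to report for it.

The default canvas is 1024x1024, a scaled stand-in for the 3024x3024
capture: the px/cm scale shrinks by the same factor, so physical areas —
and therefore every downstream quantity — are preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from pydantic import BaseModel, ConfigDict, Field, field_validator
from skimage import draw as skdraw
from skimage import filters as skfilters

from .ascorbate import estimate_concentration
from .calibration import CalibrationConfig, StageLabel
from .detect import FruitDetection, StagePalette, default_palette, write_detections_coco
from .pulp import pulp_from_area

__all__ = [
    "NoiseSpec",
    "SceneSpec",
    "GroundTruthFruit",
    "SceneGroundTruth",
    "generate_scene",
    "write_ground_truth",
    "CapacityError",
]

REFERENCE_IMAGE_SIZE_PX = 3024
REFERENCE_PX_PER_CM = 143.79
BACKGROUND_RGB = (200, 200, 200)


class CapacityError(RuntimeError):
    """Raised when non-overlapping placement of all fruits fails."""


class NoiseSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    gaussian_sigma: float = Field(default=0.0, ge=0.0)  # additive, 0-1 intensity scale
    highlight_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    blur_sigma: float = Field(default=0.0, ge=0.0)  # px
    color_jitter: float = Field(default=0.0, ge=0.0)  # per-channel, 0-1 scale


class SceneSpec(BaseModel):
    """Generative parameters of one synthetic scene."""

    model_config = ConfigDict(frozen=True)

    image_size_px: tuple[int, int] = (1024, 1024)
    px_per_cm: float | None = None  # None: 143.79 scaled from the 3024 px reference
    n_fruits: int = Field(default=15, ge=0)
    stage_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    fruit_diameter_range_cm: tuple[float, float] = (2.0, 3.0)
    overlap_allowed: bool = False
    noise: NoiseSpec = Field(default_factory=NoiseSpec)
    seed: int = 0

    @field_validator("stage_mix")
    @classmethod
    def _mix_is_distribution(cls, v):
        if any(p < 0 for p in v) or not math.isclose(sum(v), 1.0, abs_tol=1e-9):
            raise ValueError("stage_mix must be a probability vector over the 4 stages")
        return v

    @field_validator("fruit_diameter_range_cm")
    @classmethod
    def _diameters_positive(cls, v):
        if not 0 < v[0] <= v[1]:
            raise ValueError("fruit diameter range must be positive and ordered")
        return v

    @property
    def scale_px_per_cm(self) -> float:
        if self.px_per_cm is not None:
            return self.px_per_cm
        return REFERENCE_PX_PER_CM * min(self.image_size_px) / REFERENCE_IMAGE_SIZE_PX


@dataclass(frozen=True)
class GroundTruthFruit:
    """Analytic geometry and expected pipeline outputs for one rendered fruit."""

    center_px: tuple[float, float]  # (x, y)
    semi_axes_px: tuple[float, float]  # (row radius, col radius)
    rotation_rad: float
    stage: StageLabel
    area_px: float  # analytic, pi * a * b
    area_cm2: float
    pulp_g: float | None  # None for Green (excluded from quantification)
    r2_mg_per_100g: float | None

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        """Tight (x, y, w, h) box of the rotated ellipse."""
        a, b = self.semi_axes_px
        th = self.rotation_rad
        half_r = math.hypot(a * math.cos(th), b * math.sin(th))
        half_c = math.hypot(a * math.sin(th), b * math.cos(th))
        cx, cy = self.center_px
        return (cx - half_c, cy - half_r, 2 * half_c, 2 * half_r)


@dataclass(frozen=True)
class SceneGroundTruth:
    fruits: tuple[GroundTruthFruit, ...]
    image_size_px: tuple[int, int]
    px_per_cm: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "center_x_px": f.center_px[0],
                    "center_y_px": f.center_px[1],
                    "semi_axis_row_px": f.semi_axes_px[0],
                    "semi_axis_col_px": f.semi_axes_px[1],
                    "rotation_rad": f.rotation_rad,
                    "stage": f.stage.value,
                    "area_px": f.area_px,
                    "area_cm2": f.area_cm2,
                    "pulp_g": f.pulp_g,
                    "r2_mg_per_100g": f.r2_mg_per_100g,
                }
                for f in self.fruits
            ],
            columns=[
                "center_x_px",
                "center_y_px",
                "semi_axis_row_px",
                "semi_axis_col_px",
                "rotation_rad",
                "stage",
                "area_px",
                "area_cm2",
                "pulp_g",
                "r2_mg_per_100g",
            ],
        )


def generate_scene(
    spec: SceneSpec,
    cfg: CalibrationConfig | None = None,
    palette: StagePalette | None = None,
) -> tuple[np.ndarray, SceneGroundTruth]:
    """Render a scene and return (RGB uint8 image, ground truth).

    Fruits are rejection-placed until non-overlapping (unless
    ``spec.overlap_allowed``); placement failure after a bounded number of
    attempts raises :class:`CapacityError`.  All stochastic draws come from
    one RNG seeded with ``spec.seed``.
    """
    cfg = cfg or CalibrationConfig()
    palette = palette or default_palette()
    rng = np.random.default_rng(spec.seed)
    height, width = spec.image_size_px[1], spec.image_size_px[0]
    scale = spec.scale_px_per_cm

    stages = sorted(StageLabel, key=lambda s: s.ordinal)
    placed: list[tuple[float, float, float]] = []  # (cx, cy, max radius)
    fruits: list[GroundTruthFruit] = []
    for _ in range(spec.n_fruits):
        stage = stages[int(rng.choice(4, p=spec.stage_mix))]
        d_cm = rng.uniform(*spec.fruit_diameter_range_cm)
        a = d_cm / 2.0 * scale  # row semi-axis, px
        b = a * rng.uniform(0.85, 1.0)  # near-spherical fruit
        rot = rng.uniform(0.0, math.pi)
        rmax = max(a, b)
        margin = rmax + 2.0
        if margin * 2 >= min(width, height):
            raise CapacityError("fruit larger than the canvas")
        for attempt in range(2000):
            cx = rng.uniform(margin, width - margin)
            cy = rng.uniform(margin, height - margin)
            if spec.overlap_allowed or all(
                math.hypot(cx - px, cy - py) > rmax + pr + 4.0
                for px, py, pr in placed
            ):
                break
        else:
            raise CapacityError(
                f"could not place {spec.n_fruits} non-overlapping fruits "
                f"on a {width}x{height} canvas"
            )
        placed.append((cx, cy, rmax))
        area_px = math.pi * a * b
        area_cm2 = area_px / scale**2
        if stage.is_commercial:
            pulp = pulp_from_area(area_cm2, cfg.maturity_factor[stage], cfg.pulp_poly)
            r2 = estimate_concentration(
                cfg.stage_reference_conc[stage], pulp, cfg.reference_mass_g
            )
        else:
            pulp = r2 = None
        fruits.append(
            GroundTruthFruit(
                center_px=(cx, cy),
                semi_axes_px=(a, b),
                rotation_rad=rot,
                stage=stage,
                area_px=area_px,
                area_cm2=area_cm2,
                pulp_g=pulp,
                r2_mg_per_100g=r2,
            )
        )

    image = np.empty((height, width, 3), dtype=np.float64)
    image[:] = np.asarray(BACKGROUND_RGB, dtype=np.float64) / 255.0
    for fruit in fruits:
        base = np.asarray(palette.colors[fruit.stage], dtype=np.float64) / 255.0
        if spec.noise.color_jitter > 0:
            base = base + rng.uniform(
                -spec.noise.color_jitter, spec.noise.color_jitter, size=3
            )
        cx, cy = fruit.center_px
        a, b = fruit.semi_axes_px
        rr, cc = skdraw.ellipse(
            cy, cx, a, b, shape=(height, width), rotation=fruit.rotation_rad
        )
        image[rr, cc] = np.clip(base, 0.0, 1.0)
        if spec.noise.highlight_prob > 0 and rng.random() < spec.noise.highlight_prob:
            # specular spot well inside the fruit
            off = rng.uniform(-0.3, 0.3, size=2) * min(a, b)
            hr, hc = skdraw.ellipse(
                cy + off[0], cx + off[1], 0.18 * a, 0.18 * b, shape=(height, width)
            )
            image[hr, hc] = 1.0

    if spec.noise.gaussian_sigma > 0:
        image = image + rng.normal(0.0, spec.noise.gaussian_sigma, size=image.shape)
    if spec.noise.blur_sigma > 0:
        image = skfilters.gaussian(image, sigma=spec.noise.blur_sigma, channel_axis=-1)
    image_u8 = (np.clip(image, 0.0, 1.0) * 255.0).round().astype(np.uint8)

    gt = SceneGroundTruth(
        fruits=tuple(fruits),
        image_size_px=(width, height),
        px_per_cm=scale,
        seed=spec.seed,
    )
    return image_u8, gt


def write_ground_truth(
    gt: SceneGroundTruth,
    coco_path: str | Path,
    csv_path: str | Path | None = None,
    file_name: str = "scene.png",
) -> None:
    """Write ground truth as COCO-style JSON (boxes + stages) and optional CSV."""
    detections = [
        FruitDetection(bbox=f.bbox, stage=f.stage, confidence=1.0) for f in gt.fruits
    ]
    width, height = gt.image_size_px
    write_detections_coco(detections, coco_path, (height, width), file_name=file_name)
    if csv_path is not None:
        gt.to_frame().to_csv(csv_path, index=False)


def save_image(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(image, mode="RGB").save(path)
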