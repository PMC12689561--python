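"""Physical calibration constants and pixel <-> physical-unit conversions.

Every constant of the measurement chain lives in :class:`CalibrationConfig`:
the linear camera scale (px/cm, valid only for the calibrated 30 cm capture
distance), the pulp thickness/density used by the slab-volume pulp estimator,
the certified per-stage ascorbic acid reference concentrations (mg AA/100 g,
DCPIP titration by an accredited laboratory), the coefficients of the
quadratic pulp-yield calibration, and the maturity-factor mapping for the
three commercial ripeness stages.

Nothing downstream hard-codes these numbers; they arrive through a config
object so that a differently calibrated rig only has to supply a new file.
"""

from __future__ import annotations

import enum
import json
import math
from pathlib import Path
from typing import Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "StageLabel",
    "PulpCalibration",
    "CalibrationConfig",
    "px_area_to_cm2",
    "region_area_px",
    "pulp_mass_from_thickness",
]


class StageLabel(enum.Enum):
    """The four ripeness stages of the Peruvian standard NTP-NA 0085:2011.

    Ordered from unripe to ripe.  ``GREEN`` is the only non-commercial
    stage: green fruits are set aside to ripen and are excluded from
    ascorbate accounting.
    """

    GREEN = "Green"
    PINTON_GREEN = "Pinton Green"
    RIPE_PINTON = "Ripe Pinton"
    RIPE = "Ripe"

    @property
    def ordinal(self) -> int:
        """Position in ripeness order, 0 (Green) .. 3 (Ripe)."""
        return _ORDINALS[self]

    @property
    def is_commercial(self) -> bool:
        return self is not StageLabel.GREEN

    @classmethod
    def from_name(cls, name: str) -> "StageLabel":
        """Resolve a stage from its display name or enum member name.

        Accepts a few spellings seen in field data ("Pinton Ripe" is the
        same stage as "Ripe Pinton"; "Turn-Green"/"Turn-Ripe" are the
        certified-analysis labels for the two turning stages).
        """
        key = name.strip().lower().replace("_", " ").replace("-", " ").replace("–", " ")
        try:
            return _NAME_ALIASES[key]
        except KeyError:
            raise ValueError(f"unknown ripeness stage: {name!r}") from None


_ORDINALS = {
    StageLabel.GREEN: 0,
    StageLabel.PINTON_GREEN: 1,
    StageLabel.RIPE_PINTON: 2,
    StageLabel.RIPE: 3,
}

_NAME_ALIASES = {
    "green": StageLabel.GREEN,
    "pinton green": StageLabel.PINTON_GREEN,
    "turn green": StageLabel.PINTON_GREEN,
    "ripe pinton": StageLabel.RIPE_PINTON,
    "pinton ripe": StageLabel.RIPE_PINTON,
    "turn ripe": StageLabel.RIPE_PINTON,
    "ripe": StageLabel.RIPE,
}


class PulpCalibration(BaseModel):
    """Coefficients of the quadratic pulp-yield model P(A, M).

    ``P = a2*A^2 + a1*A + a0 + a_m*M`` with P in grams, A the projected
    fruit area in cm^2 and M the integer maturity factor (0, 1 or 2).
    """

    model_config = ConfigDict(frozen=True)

    a2: float = 0.084
    a1: float = -0.252
    a0: float = 6.292
    a_m: float = 0.63


class CalibrationConfig(BaseModel):
    """All physical and model constants of the estimation pipeline."""

    model_config = ConfigDict(frozen=True)

    px_per_cm: float = Field(default=143.79, gt=0.0)
    pulp_thickness_cm: float = Field(default=0.8, gt=0.0)
    pulp_density_g_per_cm3: float = Field(default=1.0, gt=0.0)
    reference_mass_g: float = Field(default=100.0, gt=0.0)
    stage_reference_conc: dict[StageLabel, float] = Field(
        default_factory=lambda: {
            StageLabel.GREEN: 1539.40,
            StageLabel.PINTON_GREEN: 1790.37,
            StageLabel.RIPE_PINTON: 2033.32,
            StageLabel.RIPE: 2187.50,
        }
    )
    pulp_poly: PulpCalibration = Field(default_factory=PulpCalibration)
    maturity_factor: dict[StageLabel, int] = Field(
        default_factory=lambda: {
            StageLabel.PINTON_GREEN: 0,
            StageLabel.RIPE_PINTON: 1,
            StageLabel.RIPE: 2,
        }
    )
    area_class_bounds_cm2: tuple[float, float] = (5.0, 8.0)
    reference_area_interval_cm2: float = Field(default=2.5, gt=0.0)

    @field_validator("stage_reference_conc", mode="before")
    @classmethod
    def _coerce_conc_keys(cls, v: Mapping) -> dict:
        return _coerce_stage_keys(v)

    @field_validator("maturity_factor", mode="before")
    @classmethod
    def _coerce_mf_keys(cls, v: Mapping) -> dict:
        return _coerce_stage_keys(v)

    @field_validator("stage_reference_conc")
    @classmethod
    def _conc_positive(cls, v: dict[StageLabel, float]) -> dict[StageLabel, float]:
        if any(c <= 0 for c in v.values()):
            raise ValueError("reference concentrations must be positive")
        return v

    @field_validator("maturity_factor")
    @classmethod
    def _mf_valid(cls, v: dict[StageLabel, int]) -> dict[StageLabel, int]:
        if StageLabel.GREEN in v:
            raise ValueError("Green fruits carry no maturity factor (non-commercial stage)")
        if not set(v.values()) <= {0, 1, 2}:
            raise ValueError("maturity factors must lie in {0, 1, 2}")
        return v

    @model_validator(mode="after")
    def _bounds_increasing(self) -> "CalibrationConfig":
        lo, hi = self.area_class_bounds_cm2
        if not 0 < lo < hi:
            raise ValueError("area_class_bounds_cm2 must be positive and strictly increasing")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "CalibrationConfig":
        """Load a config from YAML or JSON; unset fields take the defaults."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        return cls.model_validate(data or {})


def _coerce_stage_keys(v: Mapping) -> dict:
    out = {}
    for k, val in dict(v).items():
        out[k if isinstance(k, StageLabel) else StageLabel.from_name(str(k))] = val
    return out


def px_area_to_cm2(area_px: float, cfg: CalibrationConfig) -> float:
    """Convert a pixel area to physical area (cm^2) via the linear scale.

    A linear scale of ``s`` px/cm makes one cm^2 cover ``s**2`` pixels,
    so the conversion is ``area_px / s**2``.
    """
    if area_px < 0:
        raise ValueError(f"pixel area must be non-negative, got {area_px}")
    return area_px / cfg.px_per_cm**2


def region_area_px(detection, shape_model: str = "auto") -> float:
    """Pixel area of a detected fruit region.

    Parameters
    ----------
    detection
        A :class:`~camuquant.detect.FruitDetection` (anything with ``bbox``
        and optional ``mask`` attributes).
    shape_model
        ``"mask"``: count foreground pixels of the instance mask.
        ``"ellipse"``: area of the ellipse inscribed in the bounding box,
        ``pi * w * h / 4`` — appropriate for near-spherical fruit, where a
        bare box overestimates the silhouette by a factor 4/pi.
        ``"auto"`` (default): mask when present, else ellipse.
    """
    x, y, w, h = detection.bbox
    if w <= 0 or h <= 0:
        raise ValueError(f"degenerate bounding box (w={w}, h={h})")
    if shape_model not in ("auto", "mask", "ellipse"):
        raise ValueError(f"unknown shape model {shape_model!r}")
    mask = getattr(detection, "mask", None)
    if shape_model == "mask" and mask is None:
        raise ValueError("shape_model='mask' but the detection has no mask")
    if mask is not None and shape_model in ("auto", "mask"):
        return float(mask.sum())
    return math.pi * w * h / 4.0


def pulp_mass_from_thickness(area_cm2: float, cfg: CalibrationConfig) -> float:
    """Pulp mass (g) from projected area via the slab-volume approximation.

    Treats the pulp as a slab of the configured mean thickness and density:
    ``m = A * t * rho``.
    """
    if area_cm2 < 0:
        raise ValueError(f"area must be non-negative, got {area_cm2}")
    return area_cm2 * cfg.pulp_thickness_cm * cfg.pulp_density_g_per_cm3
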