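"""Ascorbic acid estimation from staged, pulp-quantified fruits.

The proportional estimator scales a certified laboratory concentration R1
(mg AA/100 g, measured by DCPIP titration on a reference sample of mass b1)
by the ratio of system-estimated mass b2 to the reference mass:

    R2 = R1 * b2 / b1        [mg AA / 100 g]

Per fruit, the total ascorbate in milligrams is the concentration applied
to that fruit's pulp mass.  Per image, totals are accumulated over the
commercial stages only: green fruits are reserved for ripening and carry
no ascorbate estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .calibration import CalibrationConfig, StageLabel

__all__ = [
    "FruitRecord",
    "ImageReport",
    "estimate_concentration",
    "fruit_total_ascorbate",
    "aggregate_image",
]

SCHEMA_VERSION = 1


def estimate_concentration(r1: float, b2: float, b1: float) -> float:
    """Scale a certified concentration by the estimated-to-reference mass ratio.

    Parameters
    ----------
    r1
        Certified laboratory concentration for the stage, mg AA per 100 g.
    b2
        System-estimated pulp mass, grams.
    b1
        Mass of the laboratory reference sample, grams.

    Returns
    -------
    float
        Estimated concentration R2 in mg AA per 100 g.  Equals ``r1``
        exactly when ``b2 == b1``.
    """
    if r1 <= 0:
        raise ValueError(f"reference concentration must be positive, got {r1}")
    if b1 <= 0:
        raise ValueError(f"reference mass must be positive, got {b1}")
    if b2 < 0:
        raise ValueError(f"estimated mass must be non-negative, got {b2}")
    return r1 * b2 / b1


def fruit_total_ascorbate(conc_mg_per_100g: float, m_pulp_g: float) -> float:
    """Total ascorbate of one fruit (mg): concentration applied to its pulp mass."""
    if conc_mg_per_100g < 0 or m_pulp_g < 0:
        raise ValueError("concentration and pulp mass must be non-negative")
    return conc_mg_per_100g / 100.0 * m_pulp_g


@dataclass
class FruitRecord:
    """One staged and quantified fruit.

    ``excluded`` is true exactly for Green fruits, which carry no pulp or
    ascorbate estimates (``None``).
    """

    stage: StageLabel
    area_px: float
    area_cm2: float
    pulp_g: float | None
    ascorbate_mg_per_100g: float | None
    ascorbate_total_mg: float | None
    excluded: bool

    def __post_init__(self) -> None:
        if self.excluded != (self.stage is StageLabel.GREEN):
            raise ValueError("excluded must hold exactly for Green fruits")
        if self.excluded and any(
            v is not None
            for v in (self.pulp_g, self.ascorbate_mg_per_100g, self.ascorbate_total_mg)
        ):
            raise ValueError("excluded records carry no pulp/ascorbate values")
        if self.area_px < 0 or self.area_cm2 < 0:
            raise ValueError("areas must be non-negative")


@dataclass
class ImageReport:
    """Per-image summary: totals over non-excluded fruits plus per-stage R2."""

    records: list[FruitRecord]
    n_fruits: int
    n_excluded: int
    total_area_cm2: float
    total_pulp_g: float
    total_ascorbate_mg: float
    per_stage_concentration: dict[StageLabel, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "n_fruits": self.n_fruits,
            "n_excluded": self.n_excluded,
            "total_area_cm2": self.total_area_cm2,
            "total_pulp_g": self.total_pulp_g,
            "total_ascorbate_mg": self.total_ascorbate_mg,
            "per_stage_concentration_mg_per_100g": {
                s.value: c for s, c in self.per_stage_concentration.items()
            },
            "fruits": [
                {
                    "stage": r.stage.value,
                    "area_px": r.area_px,
                    "area_cm2": r.area_cm2,
                    "pulp_g": r.pulp_g,
                    "ascorbate_mg_per_100g": r.ascorbate_mg_per_100g,
                    "ascorbate_total_mg": r.ascorbate_total_mg,
                    "excluded": r.excluded,
                }
                for r in self.records
            ],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_frame(self) -> pd.DataFrame:
        """Flat one-row-per-fruit view for CSV export."""
        return pd.DataFrame(
            [
                {
                    "stage": r.stage.value,
                    "area_px": r.area_px,
                    "area_cm2": r.area_cm2,
                    "pulp_g": r.pulp_g,
                    "ascorbate_mg_per_100g": r.ascorbate_mg_per_100g,
                    "ascorbate_total_mg": r.ascorbate_total_mg,
                    "excluded": r.excluded,
                }
                for r in self.records
            ],
            columns=[
                "stage",
                "area_px",
                "area_cm2",
                "pulp_g",
                "ascorbate_mg_per_100g",
                "ascorbate_total_mg",
                "excluded",
            ],
        )


def aggregate_image(
    records: list[FruitRecord], cfg: CalibrationConfig
) -> ImageReport:
    """Summarize one image's fruit records.

    Totals (area, pulp, ascorbate) run over non-excluded records only.
    The per-stage concentration for stage ``s`` applies the proportional
    estimator to the summed pulp mass of that stage's fruits:
    ``R2(s) = estimate_concentration(R1(s), sum pulp, b1)``.

    An empty record list yields a report of zeros, not an error.
    """
    included = [r for r in records if not r.excluded]
    per_stage: dict[StageLabel, float] = {}
    for stage in StageLabel:
        if not stage.is_commercial:
            continue
        pulp = sum(r.pulp_g for r in included if r.stage is stage)
        if pulp > 0:
            per_stage[stage] = estimate_concentration(
                cfg.stage_reference_conc[stage], pulp, cfg.reference_mass_g
            )
    return ImageReport(
        records=list(records),
        n_fruits=len(records),
        n_excluded=sum(r.excluded for r in records),
        total_area_cm2=float(sum(r.area_cm2 for r in included)),
        total_pulp_g=float(sum(r.pulp_g for r in included)),
        total_ascorbate_mg=float(sum(r.ascorbate_total_mg for r in included)),
        per_stage_concentration=per_stage,
    )
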