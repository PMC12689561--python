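"""Pulp-yield estimation from projected fruit area and ripeness.

Two estimators are available.  The default is the quadratic calibration
fitted against manual depulping measurements,

    P = a2*A^2 + a1*A + a0 + a_m*M     [grams]

where A is the projected area (cm^2) and M is the maturity factor, an
integer covariate over the commercial stages (Pinton Green -> 0,
Ripe Pinton -> 1, Ripe -> 2) that shifts the yield by ``a_m`` grams per
step.  The alternative estimator (`camuquant.calibration.pulp_mass_from_thickness`)
converts area to a slab volume via a mean pulp thickness and density.

The empirical depulping table behind the calibration — mean pulp recovered
per 100 g sample, stratified by stage and projected-area class — ships as a
CSV fixture and is exposed through :func:`empirical_pulp_lookup`.
"""

from __future__ import annotations

import enum
from functools import lru_cache
from importlib import resources

import pandas as pd

from .calibration import CalibrationConfig, PulpCalibration, StageLabel

__all__ = [
    "AreaClass",
    "pulp_from_area",
    "area_class",
    "empirical_pulp_lookup",
    "pulp_yield_table",
]

_VALID_M = (0, 1, 2)


class AreaClass(enum.Enum):
    """Projected-area strata of the depulping calibration (cm^2).

    Boundaries are half-open: [0, lo), [lo, hi), [hi, inf) with the
    default bounds lo=5, hi=8.
    """

    LESS_THAN_5 = "less_than_5"
    BETWEEN_5_AND_8 = "between_5_and_8"
    MORE_THAN_8 = "more_than_8"


def pulp_from_area(
    area_cm2: float, maturity: int, cal: PulpCalibration | None = None
) -> float:
    """Evaluate the quadratic pulp-yield model at (A, M).

    Parameters
    ----------
    area_cm2
        Projected fruit area in cm^2; must be non-negative.  The model is
        evaluated as printed over its whole domain (the vertex of the
        default quadratic sits at A = 1.5 cm^2, below which yield is flat
        to slightly decreasing).
    maturity
        Maturity factor, one of {0, 1, 2}.
    cal
        Coefficients; the default calibration when omitted.

    Returns
    -------
    float
        Estimated pulp mass in grams.
    """
    if cal is None:
        cal = PulpCalibration()
    if area_cm2 < 0:
        raise ValueError(f"area must be non-negative, got {area_cm2}")
    if maturity not in _VALID_M:
        raise ValueError(f"maturity factor must be one of {_VALID_M}, got {maturity}")
    return cal.a2 * area_cm2**2 + cal.a1 * area_cm2 + cal.a0 + cal.a_m * maturity


def area_class(
    area_cm2: float, bounds: tuple[float, float] = (5.0, 8.0)
) -> AreaClass:
    """Assign a projected area to its calibration stratum."""
    if area_cm2 < 0:
        raise ValueError(f"area must be non-negative, got {area_cm2}")
    lo, hi = bounds
    if area_cm2 < lo:
        return AreaClass.LESS_THAN_5
    if area_cm2 < hi:
        return AreaClass.BETWEEN_5_AND_8
    return AreaClass.MORE_THAN_8


@lru_cache(maxsize=1)
def pulp_yield_table() -> pd.DataFrame:
    """The empirical depulping table (stage, pulp_g, sample_weight_g, area_class)."""
    with resources.files("camuquant.data").joinpath(
        "pulp_yield_by_stage_and_area.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def empirical_pulp_lookup(stage: StageLabel, cls: AreaClass) -> float:
    """Mean pulp mass (g) measured by manual depulping for a stage/area cell.

    Only commercial stages were depulped; Green fruits are not supported.
    """
    if not stage.is_commercial:
        raise ValueError("no depulping calibration exists for Green fruits")
    table = pulp_yield_table()
    row = table[
        (table["stage"] == stage.value) & (table["area_class"] == cls.value)
    ]
    if len(row) != 1:
        raise KeyError(f"no unique table entry for ({stage.value}, {cls.value})")
    return float(row["pulp_g"].iloc[0])


def estimate_pulp(
    area_cm2: float,
    stage: StageLabel,
    cfg: CalibrationConfig,
    estimator: str = "quadratic",
) -> float:
    """Pulp mass for a staged fruit under the selected estimator.

    ``"quadratic"`` uses the depulping calibration with the configured
    maturity factor for the stage; ``"thickness"`` uses the slab-volume
    model (thickness x density), which also covers Green fruits.
    """
    from .calibration import pulp_mass_from_thickness

    if estimator == "quadratic":
        try:
            m = cfg.maturity_factor[stage]
        except KeyError:
            raise ValueError(
                f"stage {stage.value!r} has no maturity factor; "
                "the quadratic estimator covers commercial stages only"
            ) from None
        return pulp_from_area(area_cm2, m, cfg.pulp_poly)
    if estimator == "thickness":
        return pulp_mass_from_thickness(area_cm2, cfg)
    raise ValueError(f"unknown pulp estimator {estimator!r}")
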