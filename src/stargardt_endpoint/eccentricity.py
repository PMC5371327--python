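"""Standardization of retinal measurements to degrees of eccentricity.

Progression in Stargardt disease is a centrifugal expansion of atrophy from
the foveal center outward.  All biomarkers are therefore expressed as the
retinal eccentricity (``ε``, degrees from the foveal center) that their raw
measurement corresponds to, so that functional and structural modalities live
on one spatial scale:

* best-corrected visual acuity (decimal fraction) — acuity shrinks by a
  factor of 1/1.2 for each degree of eccentricity, so
  ``ε = log_{1/1.2}(BCVA)``;
* atrophy areas on fundus autofluorescence (mm²) — the radius of the circular
  equivalent, with 1° ≈ 0.3 mm on the retina, so ``ε = sqrt(area/π) / 0.3``;
* transverse loss of OCT bands (mm) — the loss spans a diameter, so
  ``ε = loss / (2 · 0.3)``.

All transforms are strictly monotone with exact algebraic inverses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import BIOMARKERS, EyeVisitRecord

__all__ = [
    "ConversionConstants",
    "EccentricityVector",
    "ecc_from_bcva",
    "bcva_from_ecc",
    "ecc_from_area",
    "area_from_ecc",
    "ecc_from_transverse",
    "transverse_from_ecc",
    "visit_to_ecc_vector",
    "standardize_cohort",
]


@dataclass(frozen=True)
class ConversionConstants:
    """Geometric and psychophysical conversion factors.

    mm_per_degree
        Retinal distance subtended by one degree of eccentricity (~0.3 mm).
    acuity_decay_factor
        Per-degree acuity attenuation: decimal acuity falls by 1/1.2 for each
        degree away from the fovea.
    """

    mm_per_degree: float = 0.3
    acuity_decay_factor: float = 1.2

    def __post_init__(self) -> None:
        if self.mm_per_degree <= 0 or self.acuity_decay_factor <= 0:
            raise ValueError("conversion constants must be strictly positive")


DEFAULT_CONSTANTS = ConversionConstants()


@dataclass(frozen=True)
class EccentricityVector:
    """The five standardized eccentricities (degrees) for one eye-visit.

    Missing raw measurements propagate to ``None``; a provenance link to the
    source record is retained.
    """

    eps_bcva: float | None
    eps_qdaf: float | None
    eps_ddaf: float | None
    eps_ez: float | None
    eps_elm: float | None
    source: EyeVisitRecord | None = field(default=None, compare=False)

    def as_dict(self) -> dict[str, float | None]:
        return {
            "bcva": self.eps_bcva,
            "qdaf": self.eps_qdaf,
            "ddaf": self.eps_ddaf,
            "ez": self.eps_ez,
            "elm": self.eps_elm,
        }


def ecc_from_bcva(bcva: float, constants: ConversionConstants = DEFAULT_CONSTANTS) -> float:
    """Eccentricity equivalent of a decimal acuity: log base (1/1.2) of BCVA.

    Acuity better than 1.0 (20/20) is clamped to ε = 0 with a warning, since
    eccentricity is a nonnegative spatial extent.
    """
    if not np.isfinite(bcva) or bcva <= 0:
        raise ValueError(f"decimal acuity must be > 0, got {bcva!r}")
    if bcva > 1.0:
        warnings.warn(
            f"acuity {bcva:g} better than 1.0 clamped to eccentricity 0",
            stacklevel=2,
        )
        return 0.0
    return math.log(bcva) / math.log(1.0 / constants.acuity_decay_factor)


def bcva_from_ecc(deg: float, constants: ConversionConstants = DEFAULT_CONSTANTS) -> float:
    """Decimal acuity at a given eccentricity: (1/1.2) ** ε."""
    _check_degrees(deg)
    return (1.0 / constants.acuity_decay_factor) ** deg


def ecc_from_area(area_mm2: float, constants: ConversionConstants = DEFAULT_CONSTANTS) -> float:
    """Radius, in degrees, of the circular equivalent of an atrophy area."""
    if not np.isfinite(area_mm2) or area_mm2 < 0:
        raise ValueError(f"area must be >= 0 mm², got {area_mm2!r}")
    return math.sqrt(area_mm2 / math.pi) / constants.mm_per_degree


def area_from_ecc(deg: float, constants: ConversionConstants = DEFAULT_CONSTANTS) -> float:
    """Area (mm²) of the circle whose radius is the given eccentricity."""
    _check_degrees(deg)
    return math.pi * (constants.mm_per_degree * deg) ** 2


def ecc_from_transverse(loss_mm: float, constants: ConversionConstants = DEFAULT_CONSTANTS) -> float:
    """Eccentricity of a transverse band loss, read as a circular diameter."""
    if not np.isfinite(loss_mm) or loss_mm < 0:
        raise ValueError(f"transverse loss must be >= 0 mm, got {loss_mm!r}")
    return loss_mm / (2.0 * constants.mm_per_degree)


def transverse_from_ecc(deg: float, constants: ConversionConstants = DEFAULT_CONSTANTS) -> float:
    """Transverse extent (mm, a diameter) at the given eccentricity."""
    _check_degrees(deg)
    return 2.0 * constants.mm_per_degree * deg


def _check_degrees(deg: float) -> None:
    if not np.isfinite(deg) or deg < 0:
        raise ValueError(f"eccentricity must be >= 0 degrees, got {deg!r}")


_FORWARD = {
    "bcva": ecc_from_bcva,
    "qdaf": ecc_from_area,
    "ddaf": ecc_from_area,
    "ez": ecc_from_transverse,
    "elm": ecc_from_transverse,
}

_RAW_COLUMNS = {
    "bcva": "bcva",
    "qdaf": "qdaf_area_mm2",
    "ddaf": "ddaf_area_mm2",
    "ez": "ez_loss_mm",
    "elm": "elm_loss_mm",
}


def visit_to_ecc_vector(
    record: EyeVisitRecord, constants: ConversionConstants = DEFAULT_CONSTANTS
) -> EccentricityVector:
    """Apply the three transforms field-wise; missing in, missing out."""
    values: dict[str, float | None] = {}
    raw = {
        "bcva": record.bcva,
        "qdaf": record.qdaf_area,
        "ddaf": record.ddaf_area,
        "ez": record.ez_loss,
        "elm": record.elm_loss,
    }
    for marker in BIOMARKERS:
        x = raw[marker]
        values[marker] = None if x is None else _FORWARD[marker](x, constants)
    return EccentricityVector(
        eps_bcva=values["bcva"],
        eps_qdaf=values["qdaf"],
        eps_ddaf=values["ddaf"],
        eps_ez=values["ez"],
        eps_elm=values["elm"],
        source=record,
    )


def standardize_cohort(
    frame: pd.DataFrame, constants: ConversionConstants = DEFAULT_CONSTANTS
) -> pd.DataFrame:
    """Append the five ``eps_*`` columns (degrees) to a cohort table.

    NaN raw cells yield NaN eccentricities.  The input frame is not modified.
    """
    out = frame.copy()
    for marker in BIOMARKERS:
        raw_col = _RAW_COLUMNS[marker]
        fn = _FORWARD[marker]
        out[f"eps_{marker}"] = [
            fn(v, constants) if pd.notna(v) else np.nan for v in out[raw_col]
        ]
    return out
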