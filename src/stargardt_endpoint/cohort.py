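"""Longitudinal cohort data model, table I/O, and inter-grader agreement.

A cohort is a per-eye, per-visit table of raw clinical measurements: decimal
best-corrected visual acuity, questionably/definitely decreased
autofluorescence areas (mm²), and transverse ellipsoid-zone / external
limiting membrane loss (mm).  Time is years since that eye's baseline visit.
Any measurement may be missing; missingness is preserved, never imputed.

The canonical on-disk format is a CSV (or XLSX with the same header):

    patient_id, eye, t_years, bcva, qdaf_area_mm2, ddaf_area_mm2,
    ez_loss_mm, elm_loss_mm

with ``eye`` in {OD, OS}, empty cells meaning missing, and acuity given
either as a decimal or a Snellen fraction ``"N/D"``.

Quantitative image measurements are made twice by independent graders; this
module also reconciles grader pairs (arithmetic mean, with flags when the
discrepancy exceeds a consensus threshold) and computes agreement statistics
(mean absolute difference and the two-way absolute-agreement single-rater
intraclass correlation coefficient).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BIOMARKERS",
    "COHORT_COLUMNS",
    "EyeVisitRecord",
    "CohortTable",
    "GraderPair",
    "AgreementResult",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "parse_acuity",
    "reconcile_graders",
    "agreement_stats",
    "read_grader_pairs",
]

#: Canonical biomarker order used for weights and eccentricity vectors.
BIOMARKERS = ("bcva", "qdaf", "ddaf", "ez", "elm")

COHORT_COLUMNS = [
    "patient_id",
    "eye",
    "t_years",
    "bcva",
    "qdaf_area_mm2",
    "ddaf_area_mm2",
    "ez_loss_mm",
    "elm_loss_mm",
]

_MEASUREMENT_COLUMNS = COHORT_COLUMNS[3:]

GRADER_LABELS = ("QDAF", "DDAF", "EZ", "ELM")


class CohortValidationError(ValueError):
    """A cohort table violates the schema or its invariants."""


@dataclass(frozen=True)
class EyeVisitRecord:
    """One eye at one visit, in raw clinical units."""

    patient_id: str
    eye: Literal["OD", "OS"]
    t_years: float
    bcva: float | None = None
    qdaf_area: float | None = None
    ddaf_area: float | None = None
    ez_loss: float | None = None
    elm_loss: float | None = None

    def __post_init__(self) -> None:
        if self.eye not in ("OD", "OS"):
            raise CohortValidationError(f"eye must be OD or OS, got {self.eye!r}")
        if not math.isfinite(self.t_years) or self.t_years < 0:
            raise CohortValidationError(f"t_years must be >= 0, got {self.t_years!r}")
        if self.bcva is not None and self.bcva <= 0:
            raise CohortValidationError(f"bcva must be > 0, got {self.bcva!r}")
        for name in ("qdaf_area", "ddaf_area", "ez_loss", "elm_loss"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise CohortValidationError(f"{name} must be >= 0, got {v!r}")
        if all(
            getattr(self, n) is None
            for n in ("bcva", "qdaf_area", "ddaf_area", "ez_loss", "elm_loss")
        ):
            raise CohortValidationError(
                f"record ({self.patient_id}, {self.eye}, t={self.t_years}) has no measurements"
            )


@dataclass
class CohortTable:
    """An ordered collection of eye-visit records with a cohort label."""

    records: list[EyeVisitRecord]
    cohort_label: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, float]] = set()
        for rec in self.records:
            key = (rec.patient_id, rec.eye, rec.t_years)
            if key in seen:
                raise CohortValidationError(f"duplicate (patient, eye, time): {key}")
            seen.add(key)
        for pid, eye in {(r.patient_id, r.eye) for r in self.records}:
            times = [r.t_years for r in self.records if (r.patient_id, r.eye) == (pid, eye)]
            if 0.0 not in times:
                raise CohortValidationError(f"eye ({pid}, {eye}) has no baseline (t=0) visit")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def patients(self) -> list[str]:
        return sorted({r.patient_id for r in self.records})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": r.patient_id,
                "eye": r.eye,
                "t_years": r.t_years,
                "bcva": np.nan if r.bcva is None else r.bcva,
                "qdaf_area_mm2": np.nan if r.qdaf_area is None else r.qdaf_area,
                "ddaf_area_mm2": np.nan if r.ddaf_area is None else r.ddaf_area,
                "ez_loss_mm": np.nan if r.ez_loss is None else r.ez_loss,
                "elm_loss_mm": np.nan if r.elm_loss is None else r.elm_loss,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=COHORT_COLUMNS)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, cohort_label: str = "") -> "CohortTable":
        records = []
        for _, row in frame.iterrows():
            records.append(
                EyeVisitRecord(
                    patient_id=str(row["patient_id"]),
                    eye=str(row["eye"]),
                    t_years=float(row["t_years"]),
                    bcva=None if pd.isna(row["bcva"]) else float(row["bcva"]),
                    qdaf_area=None if pd.isna(row["qdaf_area_mm2"]) else float(row["qdaf_area_mm2"]),
                    ddaf_area=None if pd.isna(row["ddaf_area_mm2"]) else float(row["ddaf_area_mm2"]),
                    ez_loss=None if pd.isna(row["ez_loss_mm"]) else float(row["ez_loss_mm"]),
                    elm_loss=None if pd.isna(row["elm_loss_mm"]) else float(row["elm_loss_mm"]),
                )
            )
        return cls(records=records, cohort_label=cohort_label)


def parse_acuity(value: object) -> float | None:
    """Parse an acuity cell: decimal, Snellen ``"N/D"``, or missing.

    Non-numeric acuity categories (counting fingers, hand motion, ...) are
    rejected: no standard decimal mapping is assumed.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip()
    if not text:
        return None
    if "/" in text:
        parts = text.split("/")
        if len(parts) != 2:
            raise CohortValidationError(f"malformed Snellen fraction: {text!r}")
        try:
            num, den = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise CohortValidationError(f"malformed Snellen fraction: {text!r}") from exc
        if den <= 0:
            raise CohortValidationError(f"Snellen denominator must be > 0: {text!r}")
        return num / den
    try:
        return float(text)
    except ValueError as exc:
        raise CohortValidationError(
            f"unparseable acuity {text!r} (categorical acuities are not mapped)"
        ) from exc


def read_cohort(
    path: str | Path,
    format: str | None = None,
    cohort_label: str | None = None,
    column_map: dict[str, str] | None = None,
) -> CohortTable:
    """Read and validate a cohort table from CSV or XLSX.

    Parameters
    ----------
    path
        File to read.  Format is inferred from the suffix unless ``format``
        ("csv" or "xlsx") is given.
    column_map
        Optional mapping from source column names to the canonical schema,
        for ingesting deposited spreadsheets whose headers differ.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv")
    if fmt == "xlsx":
        frame = pd.read_excel(path)
    else:
        frame = pd.read_csv(path)
    if column_map:
        frame = frame.rename(columns=column_map)
    missing_cols = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise CohortValidationError(f"missing columns: {missing_cols}")
    if len(frame) == 0:
        raise CohortValidationError("no records")

    records: list[EyeVisitRecord] = []
    errors: list[str] = []
    for i, row in frame.iterrows():
        rownum = int(i) + 2  # 1-based with header
        try:
            records.append(
                EyeVisitRecord(
                    patient_id=str(row["patient_id"]).strip(),
                    eye=str(row["eye"]).strip(),
                    t_years=float(row["t_years"]),
                    bcva=parse_acuity(row["bcva"]),
                    qdaf_area=_parse_float(row["qdaf_area_mm2"]),
                    ddaf_area=_parse_float(row["ddaf_area_mm2"]),
                    ez_loss=_parse_float(row["ez_loss_mm"]),
                    elm_loss=_parse_float(row["elm_loss_mm"]),
                )
            )
        except (CohortValidationError, ValueError, TypeError) as exc:
            errors.append(f"row {rownum}: {exc}")
    if errors:
        raise CohortValidationError("malformed rows:\n  " + "\n  ".join(errors))
    label = cohort_label if cohort_label is not None else path.stem
    return CohortTable(records=records, cohort_label=label)


def _parse_float(value: object) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if not value:
            return None
    return float(value)  # type: ignore[arg-type]


def write_cohort(table: CohortTable, path: str | Path, format: str | None = None) -> None:
    """Write a cohort table to CSV or XLSX (canonical schema, empty = missing)."""
    path = Path(path)
    fmt = format or ("xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv")
    frame = table.to_frame()
    if fmt == "xlsx":
        frame.to_excel(path, index=False)
    else:
        frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Grader reconciliation and agreement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GraderPair:
    """One measurement graded independently by two blinded graders (degrees)."""

    label: str
    value_a: float
    value_b: float

    def __post_init__(self) -> None:
        if self.label not in GRADER_LABELS:
            raise ValueError(f"label must be one of {GRADER_LABELS}, got {self.label!r}")
        if self.value_a < 0 or self.value_b < 0:
            raise ValueError("grader values must be >= 0 degrees")


@dataclass(frozen=True)
class AgreementResult:
    """Inter-grader agreement: absolute differences and ICC.

    ``icc`` is the two-way random-effects, absolute-agreement, single-rater
    intraclass correlation (ICC(2,1)) unless ``form='consistency'`` was
    requested, in which case it is ICC(3,1).
    """

    mean_abs_diff: float
    sd_abs_diff: float
    icc: float
    icc_ci: tuple[float, float]
    n_pairs: int
    form: str = "absolute_agreement"


def reconcile_graders(
    pairs: Sequence[GraderPair], threshold_deg: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Average each grader pair; flag pairs needing consensus review.

    Returns ``(means, flags)``: the arithmetic mean per pair (used for all
    downstream analyses) and a boolean flag marking pairs whose absolute
    discrepancy exceeds ``threshold_deg`` (default 1°), for which graders are
    asked to reach consensus.
    """
    if threshold_deg <= 0:
        raise ValueError("threshold_deg must be > 0")
    a = np.array([p.value_a for p in pairs], dtype=float)
    b = np.array([p.value_b for p in pairs], dtype=float)
    return (a + b) / 2.0, np.abs(a - b) > threshold_deg


def agreement_stats(
    pairs: Sequence[GraderPair],
    form: str = "absolute_agreement",
    ci_level: float = 0.95,
) -> AgreementResult:
    """Mean ± SD of absolute inter-grader differences, and ICC with CI.

    Raises
    ------
    ValueError
        For fewer than 3 pairs, or when total variance is zero across both
        graders and all subjects (the ICC is then undefined).
    """
    import pingouin as pg

    if len(pairs) < 3:
        raise ValueError(f"need >= 3 grader pairs, got {len(pairs)}")
    if form not in ("absolute_agreement", "consistency"):
        raise ValueError(f"unknown ICC form {form!r}")
    a = np.array([p.value_a for p in pairs], dtype=float)
    b = np.array([p.value_b for p in pairs], dtype=float)
    diffs = np.abs(a - b)

    values = np.concatenate([a, b])
    if np.allclose(values, values[0]):
        raise ValueError("ICC undefined: zero total variance across subjects and graders")

    long = pd.DataFrame(
        {
            "subject": np.tile(np.arange(len(pairs)), 2),
            "rater": np.repeat(["A", "B"], len(pairs)),
            "value": values,
        }
    )
    icc_table = pg.intraclass_corr(
        data=long, targets="subject", raters="rater", ratings="value"
    ).set_index("Type")
    # two-way random single-rater: labelled ICC2/ICC(A,1) (absolute agreement)
    # or ICC3/ICC(C,1) (consistency) depending on the pingouin version
    keys = ("ICC2", "ICC(A,1)") if form == "absolute_agreement" else ("ICC3", "ICC(C,1)")
    key = next(k for k in keys if k in icc_table.index)
    row = icc_table.loc[key]
    ci_col = "CI95%" if "CI95%" in icc_table.columns else "CI95"
    lo, hi = row[ci_col]
    return AgreementResult(
        mean_abs_diff=float(diffs.mean()),
        sd_abs_diff=float(diffs.std(ddof=1)),
        icc=float(row["ICC"]),
        icc_ci=(float(lo), float(hi)),
        n_pairs=len(pairs),
        form=form,
    )


def read_grader_pairs(path: str | Path) -> list[GraderPair]:
    """Read a grader file with columns label, value_a_deg, value_b_deg."""
    frame = pd.read_csv(path)
    needed = ["label", "value_a_deg", "value_b_deg"]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise CohortValidationError(f"grader file missing columns: {missing}")
    return [
        GraderPair(str(r["label"]).strip(), float(r["value_a_deg"]), float(r["value_b_deg"]))
        for _, r in frame.iterrows()
    ]
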