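"""Synthetic longitudinal Stargardt cohorts with the assumed data structure.

The generator emulates the statistical shape of the real cohorts so that
every pipeline stage is testable without patient data: per-biomarker linear
eccentricity trajectories with patient-level and eye-level random slopes and
biomarker-specific residual noise, baselines drawn from the published cohort
ranges, visit schedules shared by both eyes of a patient, and
ellipsoid-zone missingness when the lesion outgrows the OCT scan.

Trajectories are built on the eccentricity scale — the scale on which the
progression model lives — and then inverted to raw clinical units (decimal
acuity, mm² atrophy areas, mm transverse loss), so a generated table
exercises the full transform path.  Residual noise is added at follow-up
visits only: baselines are noise-free so that changes-from-baseline follow
the fitted model's iid-residual assumption exactly, which is what makes the
generator usable as a parameter-recovery oracle.

Default slopes and residual scales are the development cohort's published
univariable values; between-eye baseline correlation (not quantified in the
source study) defaults to 0.8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import BIOMARKERS, CohortTable, EyeVisitRecord
from .eccentricity import (
    DEFAULT_CONSTANTS,
    ConversionConstants,
    area_from_ecc,
    bcva_from_ecc,
    transverse_from_ecc,
)

__all__ = ["GeneratorParams", "generate_cohort", "paper_preset", "generate_delta_table"]

# published univariable progression rates (deg/year) and residual SDs (deg)
_DEV_SLOPES = {"bcva": 0.31, "qdaf": 0.32, "ddaf": 0.58, "elm": 0.34, "ez": 0.38}
_DEV_RESID = {"bcva": 3.77, "qdaf": 0.14, "ddaf": 0.33, "elm": 0.17, "ez": 0.20}

# published baseline eccentricity ranges (deg), development / validation
_DEV_BASE = {
    "bcva": (9.85, 24.00),
    "qdaf": (1.68, 7.67),
    "ddaf": (0.0, 5.60),
    "elm": (2.50, 10.71),
    "ez": (2.99, 7.83),
}
_VAL_BASE = {
    "bcva": (6.31, 18.94),
    "qdaf": (1.44, 9.98),
    "ddaf": (0.0, 6.41),
    "elm": (2.06, 7.71),
    "ez": (3.86, 8.58),
}


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic cohort generator.

    Slopes and residual SDs are per biomarker on the eccentricity scale
    (°/year and degrees).  ``sd_patient_slope`` / ``sd_eye_slope`` are the
    random-slope SDs shared across biomarkers.  ``ez_scan_halfwidth_deg``
    truncates EZ: the band loss becomes unmeasurable once its eccentricity
    exceeds the half-width of the OCT scan (~9° for a typical 20°-wide
    macular B-scan).  ``eye_baseline_corr`` is the between-eye correlation of
    baseline severity.
    """

    n_patients: int = 14
    visits_range: tuple[int, int] = (2, 4)
    follow_up_range: tuple[float, float] = (1.1, 9.7)
    slopes: dict[str, float] = field(default_factory=lambda: dict(_DEV_SLOPES))
    residual_sd: dict[str, float] = field(default_factory=lambda: dict(_DEV_RESID))
    sd_patient_slope: float = 0.15
    sd_eye_slope: float = 0.05
    baseline_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEV_BASE)
    )
    ez_scan_halfwidth_deg: float = 9.0
    eye_baseline_corr: float = 0.8
    seed: int = 0
    cohort_label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        lo, hi = self.visits_range
        if not (2 <= lo <= hi):
            raise ValueError(f"visits_range must satisfy 2 <= lo <= hi, got {self.visits_range}")
        flo, fhi = self.follow_up_range
        if not (0 < flo <= fhi):
            raise ValueError(f"infeasible follow_up_range {self.follow_up_range}")
        if self.sd_patient_slope < 0 or self.sd_eye_slope < 0:
            raise ValueError("random-slope SDs must be >= 0")
        if any(v < 0 for v in self.residual_sd.values()):
            raise ValueError("residual SDs must be >= 0")
        for m, (a, b) in self.baseline_ranges.items():
            if not (0 <= a <= b):
                raise ValueError(f"ill-ordered baseline range for {m}: {(a, b)}")
        if not 0 <= self.eye_baseline_corr <= 1:
            raise ValueError("eye_baseline_corr must be in [0, 1]")


def paper_preset(cohort_label: str) -> GeneratorParams:
    """Generator presets mirroring the two published cohorts.

    ``"development"``: 14 patients, 2–4 visits per eye, 1.1–9.7 years of
    follow-up, development-cohort baseline ranges.  ``"validation"``: 18
    patients, 2–6 visits, 1.0–11.0 years, validation-cohort baselines.
    """
    if cohort_label == "development":
        return GeneratorParams(cohort_label="development")
    if cohort_label == "validation":
        return GeneratorParams(
            n_patients=18,
            visits_range=(2, 6),
            follow_up_range=(1.0, 11.0),
            baseline_ranges=dict(_VAL_BASE),
            cohort_label="validation",
        )
    raise ValueError(f"unknown cohort preset {cohort_label!r}")


def _mix_weight(corr: float) -> float:
    """Convex mixing weight on the shared patient draw giving the requested
    between-eye correlation: corr = w² / (w² + (1-w)²)."""
    if corr >= 1.0:
        return 1.0
    sr, sc = math.sqrt(corr), math.sqrt(1.0 - corr)
    return sr / (sr + sc)


def generate_cohort(
    params: GeneratorParams,
    constants: ConversionConstants = DEFAULT_CONSTANTS,
) -> CohortTable:
    """Draw one synthetic cohort in raw clinical units.

    Per patient: a visit schedule shared by both eyes (baseline plus 1+
    follow-ups, the last at least one year out); per biomarker: a patient
    random slope, eye random slopes, and correlated eye baselines; per
    follow-up visit: additive Gaussian residual on the eccentricity scale.
    Eccentricities are floored at 0 and inverted to raw units; EZ is set
    missing whenever its eccentricity exceeds the scan half-width.
    Reproducible: the same params (including seed) give an identical table.
    """
    rng = np.random.default_rng(params.seed)
    w = _mix_weight(params.eye_baseline_corr)
    records: list[EyeVisitRecord] = []

    for ip in range(params.n_patients):
        pid = f"S{ip + 1:02d}"
        n_visits = int(rng.integers(params.visits_range[0], params.visits_range[1] + 1))
        flo, fhi = params.follow_up_range
        span = float(rng.uniform(flo, fhi))
        extra = sorted(rng.uniform(0.5, span, size=n_visits - 2)) if n_visits > 2 else []
        times = [0.0, *[round(t, 2) for t in extra], round(span, 2)]
        times = sorted(set(times))  # collisions after rounding just drop a visit

        p_slope = {m: rng.normal(0.0, params.sd_patient_slope) for m in BIOMARKERS}
        shared = {m: rng.uniform(*params.baseline_ranges[m]) for m in BIOMARKERS}
        for eye in ("OD", "OS"):
            e_slope = {m: rng.normal(0.0, params.sd_eye_slope) for m in BIOMARKERS}
            base = {}
            for m in BIOMARKERS:
                indep = rng.uniform(*params.baseline_ranges[m])
                base[m] = w * shared[m] + (1.0 - w) * indep
            for t in times:
                eps = {}
                for m in BIOMARKERS:
                    drift = (params.slopes[m] + p_slope[m] + e_slope[m]) * t
                    noise = rng.normal(0.0, params.residual_sd[m]) if t > 0 else 0.0
                    eps[m] = max(base[m] + drift + noise, 0.0)
                ez_val = eps["ez"]
                ez_missing = ez_val > params.ez_scan_halfwidth_deg
                records.append(
                    EyeVisitRecord(
                        patient_id=pid,
                        eye=eye,
                        t_years=float(t),
                        bcva=bcva_from_ecc(eps["bcva"], constants),
                        qdaf_area=area_from_ecc(eps["qdaf"], constants),
                        ddaf_area=area_from_ecc(eps["ddaf"], constants),
                        ez_loss=None if ez_missing else transverse_from_ecc(ez_val, constants),
                        elm_loss=transverse_from_ecc(eps["elm"], constants),
                    )
                )
    return CohortTable(records=records, cohort_label=params.cohort_label)


def generate_delta_table(
    n_patients: int,
    slope: float,
    sd_patient: float,
    sd_eye: float,
    resid_sd: float,
    visits_range: tuple[int, int] = (2, 4),
    follow_up_range: tuple[float, float] = (1.1, 9.7),
    seed: int = 0,
):
    """Draw composite-change records directly from the progression model.

    A minimal generator on the ΔC scale — no transforms, no baselines —
    used for parameter-recovery experiments against the fitted model:
    ΔC = (s + s_i + s_ij)·Δt + E with the given variance components.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for ip in range(n_patients):
        pid = f"S{ip + 1:02d}"
        s_i = rng.normal(0.0, sd_patient)
        n_visits = int(rng.integers(visits_range[0], visits_range[1] + 1))
        span = float(rng.uniform(*follow_up_range))
        extra = sorted(rng.uniform(0.5, span, size=n_visits - 2)) if n_visits > 2 else []
        times = sorted({0.0, *[round(t, 2) for t in extra], round(span, 2)})
        for eye in ("OD", "OS"):
            s_ij = rng.normal(0.0, sd_eye)
            for t in times:
                y = (slope + s_i + s_ij) * t + (rng.normal(0.0, resid_sd) if t > 0 else 0.0)
                rows.append(
                    {"patient_id": pid, "eye": eye, "dt_years": t, "delta_c": y}
                )
    return pd.DataFrame(rows)
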