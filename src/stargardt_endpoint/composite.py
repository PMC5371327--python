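"""Weighted composite change score and the weight grid for its optimization.

The composite change ΔC for an eye at follow-up time Δt is the weighted mean
of the five per-biomarker eccentricity changes from baseline.  When a
biomarker is missing (at baseline or follow-up), ΔC is formed from the
remaining biomarkers with their respective weights, i.e. the weighted mean is
renormalized over the available weights.  A weight of zero excludes that
biomarker.

Weights live on a fixed grid (default 5% steps) and are held internally as
integer grid units so that enumerating all C(n+a-1, n) compositions of n
units over a biomarkers is exact — with five biomarkers at 5% steps, 10,626
combinations.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .cohort import BIOMARKERS

__all__ = [
    "WeightVector",
    "enumerate_weight_grid",
    "deltas_from_baseline",
    "composite_change",
    "composite_column",
    "DELTA_COLUMNS",
]

#: Per-biomarker delta columns in a delta table, canonical order.
DELTA_COLUMNS = [f"d_{m}" for m in BIOMARKERS]


@dataclass(frozen=True)
class WeightVector:
    """Non-negative biomarker weights as integer multiples of a grid step.

    ``units`` are integer grid counts in the canonical biomarker order
    (bcva, qdaf, ddaf, ez, elm); the normalized fractional weights are
    ``units / sum(units)``.  Any positive-sum vector is admissible because
    the composite divides by the weight total.
    """

    units: tuple[int, ...]
    grid_step: float = 0.05

    def __post_init__(self) -> None:
        if len(self.units) == 0:
            raise ValueError("empty weight vector")
        if any((not isinstance(u, (int, np.integer))) or u < 0 for u in self.units):
            raise ValueError(f"weights must be non-negative integers of grid units: {self.units}")
        if sum(self.units) == 0:
            raise ValueError("weights must not all be zero")
        if not 0 < self.grid_step <= 1:
            raise ValueError(f"grid_step must be in (0, 1], got {self.grid_step}")

    @property
    def fractions(self) -> np.ndarray:
        """Normalized weights summing to 1."""
        u = np.asarray(self.units, dtype=float)
        return u / u.sum()

    @property
    def percents(self) -> tuple[float, ...]:
        return tuple(round(100 * f, 10) for f in self.fractions)

    @classmethod
    def from_percents(cls, percents: Sequence[float], grid_step: float = 0.05) -> "WeightVector":
        """Build from percentages (e.g. ``(0, 25, 5, 55, 15)``)."""
        step_pct = grid_step * 100
        units = []
        for p in percents:
            u = p / step_pct
            if abs(u - round(u)) > 1e-9:
                raise ValueError(f"percent {p} is not a multiple of the {step_pct}% grid step")
            units.append(int(round(u)))
        return cls(units=tuple(units), grid_step=grid_step)

    def __str__(self) -> str:
        pct = "/".join(f"{p:g}" for p in self.percents)
        return f"WeightVector({pct}%)"


#: The study's optimal development-cohort weighting, (BCVA, QDAF, DDAF, EZ, ELM)%.
OPTIMAL_WEIGHTS = WeightVector.from_percents((0, 25, 5, 55, 15))

#: Equal weights over the four structural biomarkers (BCVA excluded).
UNWEIGHTED_STRUCTURAL = WeightVector.from_percents((0, 25, 25, 25, 25))

#: Equal weights over all five biomarkers.
UNWEIGHTED_ALL = WeightVector.from_percents((20, 20, 20, 20, 20))

#: Acuity as the single outcome.
BCVA_ONLY = WeightVector.from_percents((100, 0, 0, 0, 0))


def enumerate_weight_grid(n_biomarkers: int = 5, grid_step: float = 0.05) -> list[WeightVector]:
    """All weight vectors on the grid, in deterministic lexicographic order.

    Enumerates every composition of ``n = 1/grid_step`` units into
    ``n_biomarkers`` ordered non-negative parts — C(n + a - 1, n) vectors.
    The order is lexicographically ascending on the unit tuples (the first
    biomarker varies slowest), which fixes optimization tie-breaking.
    """
    n_units_f = 1.0 / grid_step
    if abs(n_units_f - round(n_units_f)) > 1e-9:
        raise ValueError(f"1/grid_step must be a positive integer, got step {grid_step}")
    n_units = int(round(n_units_f))
    if n_biomarkers < 1:
        raise ValueError("need at least one biomarker")

    out: list[WeightVector] = []

    def compose(prefix: tuple[int, ...], remaining: int, slots: int) -> None:
        if slots == 1:
            out.append(WeightVector(units=prefix + (remaining,), grid_step=grid_step))
            return
        for u in range(remaining + 1):
            compose(prefix + (u,), remaining - u, slots - 1)

    compose((), n_units, n_biomarkers)
    assert len(out) == comb(n_units + n_biomarkers - 1, n_biomarkers - 1)
    return out


def deltas_from_baseline(ecc_frame: pd.DataFrame) -> pd.DataFrame:
    """Per-biomarker eccentricity changes from each eye's baseline visit.

    Expects a standardized cohort table with ``eps_*`` columns (see
    :func:`stargardt_endpoint.eccentricity.standardize_cohort`).  Returns one
    row per eye-visit with columns ``patient_id, eye, dt_years, d_<marker>``;
    a delta is present only when the biomarker is measured at both baseline
    and the follow-up visit.  Baseline rows (dt = 0) are produced with zero
    deltas for the biomarkers present at baseline.
    """
    eps_cols = [f"eps_{m}" for m in BIOMARKERS]
    missing = [c for c in eps_cols if c not in ecc_frame.columns]
    if missing:
        raise ValueError(f"not a standardized table, missing columns: {missing}")

    rows = []
    for (pid, eye), grp in ecc_frame.groupby(["patient_id", "eye"], sort=True):
        grp = grp.sort_values("t_years")
        base = grp[grp["t_years"] == 0.0]
        if len(base) == 0:
            raise ValueError(f"eye ({pid}, {eye}) has no baseline (t=0) visit")
        base_eps = base.iloc[0][eps_cols].to_numpy(dtype=float)
        for _, visit in grp.iterrows():
            eps = visit[eps_cols].to_numpy(dtype=float)
            deltas = eps - base_eps  # NaN at either end -> NaN delta
            row = {"patient_id": pid, "eye": eye, "dt_years": float(visit["t_years"])}
            row.update({f"d_{m}": deltas[i] for i, m in enumerate(BIOMARKERS)})
            rows.append(row)
    return pd.DataFrame(rows, columns=["patient_id", "eye", "dt_years", *DELTA_COLUMNS])


def composite_change(delta_eps: Sequence[float], weights: WeightVector) -> float:
    """Weighted mean of the available per-biomarker deltas.

    Missing deltas (NaN/None) drop out and the remaining weights are
    renormalized.  Returns NaN when the available weights sum to zero
    (nothing to average) — by design not an error.
    """
    d = np.asarray(
        [np.nan if v is None else float(v) for v in delta_eps], dtype=float
    )
    w = weights.fractions
    if d.shape != w.shape:
        raise ValueError(f"expected {len(w)} deltas, got {len(d)}")
    avail = ~np.isnan(d)
    denom = w[avail].sum()
    if denom == 0:
        return float("nan")
    return float((w[avail] * d[avail]).sum() / denom)


def composite_column(delta_frame: pd.DataFrame, weights: WeightVector) -> np.ndarray:
    """Vectorized :func:`composite_change` over a delta table.

    Returns the ΔC column (degrees) aligned with ``delta_frame`` rows; rows
    where no weighted biomarker is available get NaN.
    """
    d = delta_frame[DELTA_COLUMNS].to_numpy(dtype=float)
    w = weights.fractions
    avail = ~np.isnan(d)
    denom = (avail * w).sum(axis=1)
    num = np.nansum(d * w, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, num / denom, np.nan)
    return out
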