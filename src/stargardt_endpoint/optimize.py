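"""Exhaustive MSDR search over the composite weight grid.

For every weight vector on the grid (10,626 combinations with five
biomarkers at 5% steps), the composite change column is formed from the
cached per-biomarker deltas (missing biomarkers renormalized away), the
random-slope model is refit, and the mean-to-standard-deviation ratio is
recorded.  The combination with the highest MSDR among converged fits wins;
ties break to the first vector in lexicographic grid order, so the search is
fully deterministic.  Successive fits warm-start from the previous optimum's
variance ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import BIOMARKERS
from .composite import WeightVector, composite_column, enumerate_weight_grid
from .mixedmodel import (
    ConvergenceError,
    ModelBlocks,
    ProgressionFit,
    fit_prepared,
    msdr,
)

__all__ = ["OptimizationResult", "optimize_weights", "msdr_profile"]


@dataclass
class OptimizationResult:
    """Outcome of the exhaustive weight search.

    ``table`` has one row per grid combination: the five weight percentages,
    slope, rmse, msdr, and a convergence flag, in enumeration order.
    """

    table: pd.DataFrame
    best: WeightVector
    best_msdr: float
    best_fit: ProgressionFit
    grid_step: float

    @property
    def n_combinations(self) -> int:
        return len(self.table)


def optimize_weights(
    delta_frame: pd.DataFrame,
    grid: list[WeightVector] | None = None,
    grid_step: float = 0.05,
    reml: bool = True,
    min_records: int = 3,
) -> OptimizationResult:
    """Evaluate MSDR for every weight combination and pick the best.

    Parameters
    ----------
    delta_frame
        Per-biomarker delta table from
        :func:`stargardt_endpoint.composite.deltas_from_baseline`.
    grid
        Weight vectors to evaluate; defaults to the full grid at
        ``grid_step``.
    min_records
        Combinations yielding fewer usable composite records are recorded as
        non-converged rather than fitted.
    """
    if grid is None:
        grid = enumerate_weight_grid(len(BIOMARKERS), grid_step)
    if not grid:
        raise ValueError("empty weight grid")

    work = delta_frame.copy()
    dt = work["dt_years"].to_numpy(dtype=float)
    pids = work["patient_id"].to_numpy(dtype=str)
    eyes = work["eye"].to_numpy(dtype=str)
    followup = dt > 0
    # the design blocks depend only on which rows enter the fit, so cache one
    # ModelBlocks per missingness pattern across the grid
    block_cache: dict[bytes, ModelBlocks] = {}

    rows = []
    best: WeightVector | None = None
    best_val = -np.inf
    best_fit: ProgressionFit | None = None
    warm: tuple[float, float] | None = None

    for wv in grid:
        delta_c = composite_column(work, wv)
        keep = followup & ~np.isnan(delta_c)
        usable = int(keep.sum())
        slope = rmse = ratio = np.nan
        converged = False
        fit = None
        if usable >= min_records:
            try:
                key = keep.tobytes()
                blocks = block_cache.get(key)
                if blocks is None:
                    blocks = ModelBlocks(pids[keep], eyes[keep], dt[keep])
                    block_cache[key] = blocks
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = fit_prepared(blocks, delta_c[keep], reml=reml, start=warm)
                m = msdr(fit)
                slope, rmse = fit.slope, fit.rmse
                ratio = m.msdr if not m.infinite else np.nan
                converged = fit.converged and not m.infinite
            except (ConvergenceError, ValueError, np.linalg.LinAlgError):
                converged = False
        pct = wv.percents
        rows.append(
            {
                **{f"w_{m}_pct": pct[i] for i, m in enumerate(BIOMARKERS)},
                "slope": slope,
                "rmse": rmse,
                "msdr": ratio,
                "converged": converged,
                "n_records": usable,
            }
        )
        if converged and np.isfinite(ratio):
            warm = fit.gamma
            if ratio > best_val:  # strict: ties keep the earlier (lexicographic) vector
                best_val = float(ratio)
                best = wv
                best_fit = fit

    if best is None or best_fit is None:
        raise RuntimeError("no weight combination produced a converged fit")
    table = pd.DataFrame(rows)
    step = grid[0].grid_step
    return OptimizationResult(
        table=table, best=best, best_msdr=best_val, best_fit=best_fit, grid_step=step
    )


def msdr_profile(result: OptimizationResult, biomarker: str) -> pd.DataFrame:
    """Best attainable MSDR at each weight level of one biomarker.

    For each grid value *w* of ``biomarker``, the maximum MSDR over all
    converged combinations in which that biomarker has weight *w* — the
    per-biomarker envelope used to read off how much weight an outcome
    measure tolerates before it degrades the composite.
    """
    if biomarker not in BIOMARKERS:
        raise ValueError(f"unknown biomarker {biomarker!r}; expected one of {BIOMARKERS}")
    col = f"w_{biomarker}_pct"
    tab = result.table[result.table["converged"]]
    prof = (
        tab.groupby(col)["msdr"]
        .max()
        .rename("max_msdr")
        .reset_index()
        .rename(columns={col: "weight_pct"})
        .sort_values("weight_pct", ignore_index=True)
    )
    return prof
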