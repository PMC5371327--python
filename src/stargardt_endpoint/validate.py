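"""Hold-out validation: predict the final visit and calibrate against it.

For patients with three or more visits, the chronologically last visit of
each eye is withheld; the model is fit on the remaining visits and the
withheld composite change is predicted from the eye's conditional (BLUP)
slope.  Calibration regresses measured on predicted change by ordinary least
squares; a well-calibrated endpoint has R² near 1, slope near 1, and
intercept near 0.  Replication freezes the development-cohort weights and
repeats the exercise on an external cohort (its own model fit, no
re-optimization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .composite import WeightVector, composite_column, deltas_from_baseline
from .mixedmodel import ProgressionFit, adjusted_rmse, fit_progression, predict_change

__all__ = [
    "CalibrationResult",
    "holdout_last_visit",
    "calibrate",
    "holdout_validation",
]


@dataclass
class CalibrationResult:
    """Predicted-vs-measured calibration of composite change."""

    pairs: pd.DataFrame  # patient_id, eye, dt_years, predicted, measured
    r_squared: float
    ols_slope: float
    ols_slope_ci: tuple[float, float]
    ols_intercept: float
    ols_intercept_ci: tuple[float, float]
    n_pairs: int


def holdout_last_visit(
    ecc_frame: pd.DataFrame, min_visits: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a standardized cohort into training and held-out last visits.

    Only patients with at least ``min_visits`` visits (per eye) qualify for
    hold-out; for each qualifying eye the chronologically last visit moves to
    the test set.  Everything else — including both visits of two-visit
    eyes — stays in training.  Tied visit times are ambiguous and rejected.
    """
    train_parts: list[pd.DataFrame] = []
    test_parts: list[pd.DataFrame] = []
    n_qualifying = 0
    for (pid, eye), grp in ecc_frame.groupby(["patient_id", "eye"], sort=True):
        times = grp["t_years"].to_numpy(dtype=float)
        if len(np.unique(times)) != len(times):
            raise ValueError(f"eye ({pid}, {eye}) has tied visit times; disambiguate input")
        if len(grp) >= min_visits:
            n_qualifying += 1
            order = np.argsort(times)
            last = order[-1]
            test_parts.append(grp.iloc[[last]])
            train_parts.append(grp.drop(grp.index[last]))
        else:
            train_parts.append(grp)
    if n_qualifying == 0:
        raise ValueError(f"no eye has >= {min_visits} visits; nothing to hold out")
    train = pd.concat(train_parts, ignore_index=True)
    test = pd.concat(test_parts, ignore_index=True)
    return train, test


def calibrate(predicted: np.ndarray, measured: np.ndarray) -> CalibrationResult:
    """OLS calibration of measured on predicted composite change.

    ``r_squared`` is the squared Pearson correlation; slope and intercept
    carry Wald 95% confidence intervals.
    """
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.size != measured.size:
        raise ValueError("predicted and measured must have equal length")
    if predicted.size < 3:
        raise ValueError(f"need >= 3 pairs for calibration, got {predicted.size}")
    if np.ptp(predicted) == 0:
        raise ValueError("zero variance in predictions; calibration undefined")
    X = sm.add_constant(predicted)
    res = sm.OLS(measured, X).fit()
    ci = res.conf_int(alpha=0.05)
    r = np.corrcoef(predicted, measured)[0, 1]
    pairs = pd.DataFrame({"predicted": predicted, "measured": measured})
    return CalibrationResult(
        pairs=pairs,
        r_squared=float(r * r),
        ols_slope=float(res.params[1]),
        ols_slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        ols_intercept=float(res.params[0]),
        ols_intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
        n_pairs=int(predicted.size),
    )


def holdout_validation(
    ecc_frame: pd.DataFrame,
    weights: WeightVector,
    min_visits: int = 3,
) -> tuple[CalibrationResult, ProgressionFit, float]:
    """End-to-end hold-out validation of a weighting on one cohort.

    Returns the calibration result, the training fit, and its adjusted RMSE.
    The weights are taken as given (frozen), so the same routine serves both
    the development cohort and external replication.
    """
    train, test = holdout_last_visit(ecc_frame, min_visits=min_visits)
    train_deltas = deltas_from_baseline(train)
    train_deltas["delta_c"] = composite_column(train_deltas, weights)
    fit = fit_progression(train_deltas)
    adj = adjusted_rmse(fit, train_deltas)

    # measured ΔC of held-out visits uses each eye's training baseline
    full_deltas = deltas_from_baseline(ecc_frame)
    full_deltas["delta_c"] = composite_column(full_deltas, weights)
    held = test.merge(
        full_deltas, on=["patient_id", "eye"], suffixes=("", "_d")
    )
    held = held[np.isclose(held["dt_years"], held["t_years"])]
    held = held[held["delta_c"].notna()]
    if len(held) < 3:
        raise ValueError("fewer than 3 held-out visits have a measurable composite")
    preds = np.array(
        [
            predict_change(fit, p, e, d)
            for p, e, d in zip(held["patient_id"], held["eye"], held["dt_years"])
        ]
    )
    cal = calibrate(preds, held["delta_c"].to_numpy(dtype=float))
    cal.pairs.insert(0, "patient_id", held["patient_id"].to_numpy())
    cal.pairs.insert(1, "eye", held["eye"].to_numpy())
    cal.pairs.insert(2, "dt_years", held["dt_years"].to_numpy())
    return cal, fit, adj
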