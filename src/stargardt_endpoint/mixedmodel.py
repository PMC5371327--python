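"""Zero-intercept random-slope mixed model for composite progression.

The composite change from baseline for patient *i*, eye *j*, follow-up *k* is
modelled as

    ΔC_ij(Δt_ik) = (s + s_i + s_ij) · Δt_ik + E_ijk

with a fixed population slope ``s`` (°/year), independent patient-level slope
deviations ``s_i ~ N(0, σ_p²)``, independent eye-within-patient deviations
``s_ij ~ N(0, σ_e²)``, and iid residuals ``E_ijk ~ N(0, σ²)``.  The intercept
is identically zero because the response is a difference from baseline;
baseline rows (Δt = 0), whose response is deterministically zero, are
excluded from fitting so they cannot deflate the residual variance.

Estimation is (restricted) maximum likelihood with the scale profiled out:
writing γ_p = σ_p²/σ², γ_e = σ_e²/σ², the marginal covariance is σ²·W(γ)
with W block-diagonal by patient, each block a small rank-≤3 update of the
identity whose constituent outer products are precomputed once.  The two
variance ratios are optimized on the log scale (Nelder-Mead, objective
tolerance 1e-8) from fixed deterministic starting values; the weight-grid
search reuses the block structure and warm-starts the ratios, which is what
makes thousands of refits cheap.  The responsiveness criterion is the
mean-to-standard-deviation ratio MSDR = s / RMSE, where RMSE is the residual
standard deviation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "ProgressionFit",
    "MsdrResult",
    "ConvergenceError",
    "fit_progression",
    "msdr",
    "predict_change",
    "adjusted_rmse",
]

_Z_95 = 1.959964  # two-sided 95% normal quantile (Wald interval on s)
_LOG_GAMMA_MIN, _LOG_GAMMA_MAX = -30.0, 15.0
_PINNED_GAMMA = 1e-8


class ConvergenceError(RuntimeError):
    """The variance-ratio optimizer failed; carries optimizer diagnostics."""


@dataclass
class ProgressionFit:
    """Fitted progression model.

    Attributes
    ----------
    slope
        Population slope ``s`` (°/year).
    ci_slope
        Wald 95% confidence interval on ``s``.
    sd_patient, sd_eye
        Standard deviations of the patient- and eye-level slope deviations
        (°/year).
    rmse
        Residual standard deviation of ``E_ijk`` (degrees).
    conditional_slopes
        Best-linear-unbiased-predicted slope ``s + ŝ_i + ŝ_ij`` for every
        fitted (patient, eye).
    """

    slope: float
    ci_slope: tuple[float, float]
    se_slope: float
    sd_patient: float
    sd_eye: float
    rmse: float
    conditional_slopes: dict[tuple[str, str], float]
    n_obs: int
    n_patients: int
    n_eyes: int
    loglik: float
    method: str = "reml"
    converged: bool = True
    gamma: tuple[float, float] = (0.0, 0.0)
    pinned: tuple[bool, bool] = (False, False)
    n_iter: int = 0


@dataclass(frozen=True)
class MsdrResult:
    """Mean-to-standard-deviation ratio of a fitted model."""

    msdr: float
    slope: float
    rmse: float
    infinite: bool = False


class ModelBlocks:
    """Per-patient design blocks of the random-slope model, precomputed.

    Holds, for each patient, the follow-up times ``t_i``, the patient-level
    outer product ``t_i t_iᵀ``, the summed eye-level outer products, and the
    per-eye masked time vectors used for BLUPs.  Depends only on which rows
    enter the fit — not on the response — so the weight-grid search caches
    one instance per missingness pattern.
    """

    def __init__(self, patient_ids: np.ndarray, eyes: np.ndarray, dt: np.ndarray):
        if np.any(dt <= 0):
            raise ValueError("ModelBlocks expects follow-up rows only (dt > 0)")
        self.n = dt.size
        patients, p_idx = np.unique(patient_ids, return_inverse=True)
        keys = np.array([f"{p}\x00{e}" for p, e in zip(patient_ids, eyes)])
        eye_u, e_idx = np.unique(keys, return_inverse=True)
        self.patients = [str(p) for p in patients]
        self.eye_labels = [tuple(s.split("\x00")) for s in eye_u]
        self.blocks = []
        for i in range(len(patients)):
            idx = np.flatnonzero(p_idx == i)
            ti = dt[idx]
            eyes_here = np.unique(e_idx[idx])
            zs = [(int(e), np.where(e_idx[idx] == e, ti, 0.0)) for e in eyes_here]
            TT = np.outer(ti, ti)
            ZZ = np.zeros_like(TT)
            for _, z in zs:
                ZZ += np.outer(z, z)
            eye_n = np.eye(ti.size)
            self.blocks.append((idx, ti, TT, ZZ, zs, eye_n))

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_eyes(self) -> int:
        return len(self.eye_labels)


def _neg2loglik(
    log_gamma: np.ndarray, blocks: ModelBlocks, y: np.ndarray, reml: bool
) -> tuple[float, float, float, float]:
    """Profiled −2·log-likelihood and GLS pieces at given variance ratios.

    Returns ``(neg2ll, slope, sigma2, xtWx)``.
    """
    lg = np.clip(log_gamma, _LOG_GAMMA_MIN, _LOG_GAMMA_MAX)
    gp, ge = np.exp(lg)
    n = y.size
    logdet = 0.0
    xtWx = xtWy = ytWy = 0.0
    for idx, ti, TT, ZZ, _, eye_n in blocks.blocks:
        W = eye_n + gp * TT + ge * ZZ
        L = np.linalg.cholesky(W)
        logdet += 2.0 * np.log(np.diag(L)).sum()
        sol = np.linalg.solve(L, np.column_stack([ti, y[idx]]))
        xtWx += sol[:, 0] @ sol[:, 0]
        xtWy += sol[:, 0] @ sol[:, 1]
        ytWy += sol[:, 1] @ sol[:, 1]
    slope = xtWy / xtWx
    rss = max(ytWy - xtWy * xtWy / xtWx, 1e-300)
    if reml:
        dof = n - 1
        sigma2 = rss / dof
        neg2 = dof * math.log(sigma2) + logdet + math.log(xtWx) + dof + dof * math.log(2 * math.pi)
    else:
        sigma2 = rss / n
        neg2 = n * math.log(sigma2) + logdet + n + n * math.log(2 * math.pi)
    return neg2, slope, sigma2, xtWx


def fit_prepared(
    blocks: ModelBlocks,
    y: np.ndarray,
    reml: bool = True,
    start: tuple[float, float] | None = None,
    tol: float = 1e-8,
) -> ProgressionFit:
    """Fit the model given precomputed blocks and the follow-up responses.

    The fast path used by the weight-grid search; :func:`fit_progression` is
    the DataFrame-facing wrapper.
    """
    if blocks.n_patients < 2:
        raise ValueError(f"need >= 2 patients with follow-up data, got {blocks.n_patients}")
    if y.size < 3:
        raise ValueError(f"need >= 3 usable records, got {y.size}")

    if start is not None and start[0] > 0 and start[1] > 0:
        x0 = np.log(np.clip(start, 1e-12, 1e6))
    else:
        x0 = np.array([0.0, 0.0])  # deterministic: both variance ratios start at 1

    res = minimize(
        lambda lg: _neg2loglik(lg, blocks, y, reml)[0],
        x0,
        method="Nelder-Mead",
        options={"fatol": tol, "xatol": 1e-6, "maxiter": 400, "maxfev": 800},
    )
    if not np.isfinite(res.fun):
        raise ConvergenceError(f"optimizer diverged: {res}")
    converged = bool(res.success)
    if not converged:
        warnings.warn(f"variance-ratio optimizer did not converge: {res.message}", stacklevel=2)

    lg = np.clip(res.x, _LOG_GAMMA_MIN, _LOG_GAMMA_MAX)
    neg2, slope, sigma2, xtWx = _neg2loglik(lg, blocks, y, reml)
    gp, ge = np.exp(lg)
    pinned = (gp < _PINNED_GAMMA, ge < _PINNED_GAMMA)
    if any(pinned):
        which = [name for name, p in zip(("patient", "eye"), pinned) if p]
        warnings.warn(f"variance estimate pinned at 0 for level(s): {which}", stacklevel=2)

    se = math.sqrt(sigma2 / xtWx)
    rmse = math.sqrt(sigma2)

    # BLUPs of the random slopes at the optimum
    cond: dict[tuple[str, str], float] = {}
    for idx, ti, TT, ZZ, zs, eye_n in blocks.blocks:
        ri = y[idx] - slope * ti
        W = eye_n + gp * TT + ge * ZZ
        Winv_r = np.linalg.solve(W, ri)
        u_p = gp * (ti @ Winv_r)
        for eye_code, z in zs:
            u_e = ge * (z @ Winv_r)
            cond[blocks.eye_labels[eye_code]] = float(slope + u_p + u_e)

    return ProgressionFit(
        slope=float(slope),
        ci_slope=(float(slope - _Z_95 * se), float(slope + _Z_95 * se)),
        se_slope=float(se),
        sd_patient=float(math.sqrt(gp * sigma2)) if not pinned[0] else 0.0,
        sd_eye=float(math.sqrt(ge * sigma2)) if not pinned[1] else 0.0,
        rmse=float(rmse),
        conditional_slopes=cond,
        n_obs=int(y.size),
        n_patients=blocks.n_patients,
        n_eyes=blocks.n_eyes,
        loglik=float(-0.5 * neg2),
        method="reml" if reml else "ml",
        converged=converged,
        gamma=(float(gp), float(ge)),
        pinned=pinned,
        n_iter=int(res.nit),
    )


def fit_progression(
    delta_frame: pd.DataFrame,
    response: str = "delta_c",
    reml: bool = True,
    start: tuple[float, float] | None = None,
    tol: float = 1e-8,
) -> ProgressionFit:
    """Fit the zero-intercept nested random-slope model to a delta table.

    Parameters
    ----------
    delta_frame
        Table with columns ``patient_id, eye, dt_years`` and the response
        (default ``delta_c``).  Rows with Δt = 0 or missing response are
        dropped before fitting.
    reml
        Restricted maximum likelihood (default); set False for ML, e.g. for
        likelihood comparisons across weightings.
    start
        Optional warm-start variance ratios ``(γ_p, γ_e)`` from a previous
        fit.
    """
    if response not in delta_frame.columns:
        raise ValueError(f"delta table has no {response!r} column")
    dt = delta_frame["dt_years"].to_numpy(dtype=float)
    y = delta_frame[response].to_numpy(dtype=float)
    keep = (dt > 0) & ~np.isnan(y)
    sub = delta_frame.loc[keep]
    blocks = ModelBlocks(
        sub["patient_id"].to_numpy(dtype=str), sub["eye"].to_numpy(dtype=str), dt[keep]
    )
    return fit_prepared(blocks, y[keep], reml=reml, start=start, tol=tol)


def msdr(fit: ProgressionFit) -> MsdrResult:
    """Responsiveness of the fitted endpoint: population slope over RMSE."""
    if fit.rmse <= 0 or not math.isfinite(fit.rmse):
        return MsdrResult(msdr=math.inf, slope=fit.slope, rmse=fit.rmse, infinite=True)
    return MsdrResult(msdr=fit.slope / fit.rmse, slope=fit.slope, rmse=fit.rmse)


def predict_change(
    fit: ProgressionFit, patient_id: str, eye: str, dt_years: float
) -> float:
    """Conditional predicted composite change (degrees) after ``dt_years``.

    Uses the BLUP slope ``s + ŝ_i + ŝ_ij`` for fitted eyes; unseen eyes fall
    back to the population slope with a warning.
    """
    if dt_years < 0:
        raise ValueError(f"dt_years must be >= 0, got {dt_years}")
    key = (str(patient_id), str(eye))
    if key in fit.conditional_slopes:
        return fit.conditional_slopes[key] * dt_years
    warnings.warn(f"eye {key} not in fit; using population slope", stacklevel=2)
    return fit.slope * dt_years


def adjusted_rmse(fit: ProgressionFit, delta_frame: pd.DataFrame, response: str = "delta_c") -> float:
    """Root-mean-square conditional residual over follow-up records only.

    Baseline records (Δt = 0) have zero residual by construction and are
    excluded; the result is the noise scale used by the trial simulator.
    """
    dt = delta_frame["dt_years"].to_numpy(dtype=float)
    y = delta_frame[response].to_numpy(dtype=float)
    keep = (dt > 0) & ~np.isnan(y)
    if not keep.any():
        raise ValueError("no follow-up (dt > 0) records with a response")
    sub = delta_frame.loc[keep]
    preds = np.array(
        [
            fit.conditional_slopes.get((str(p), str(e)), fit.slope) * d
            for p, e, d in zip(sub["patient_id"], sub["eye"], sub["dt_years"])
        ]
    )
    resid = y[keep] - preds
    return float(np.sqrt(np.mean(resid**2)))
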