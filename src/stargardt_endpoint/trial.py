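"""Monte-Carlo power analysis of a simulated interventional trial.

The fitted progression model supplies each eye's conditional predicted
composite change over the trial's follow-up window; the adjusted RMSE (the
residual scale over follow-up visits) supplies the measurement noise.  Per
replicate, each analysed eye's observed x-year increment is

    predicted increment + noise − δ,          δ = effect × predicted increment

with δ applied to treated eyes only.  In the paired design one eye of each
patient is treated (fellow eye as within-patient control) and the
per-patient between-eye differences go into a two-sided paired t-test; in
the non-paired design patients are randomized 1:1 and one eye per patient is
analysed with a two-sample t-test.  Power at each effect size is the
fraction of replicates rejecting at level α.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mixedmodel import ProgressionFit

__all__ = ["TrialDesign", "PowerCurve", "simulate_trial", "power_scenarios"]


def _default_effects() -> tuple[float, ...]:
    return tuple(np.round(np.arange(0.0, 1.0001, 0.05), 10))


@dataclass(frozen=True)
class TrialDesign:
    """Design of the simulated trial.

    ``noise`` selects how the residual enters the simulated measurement:
    ``"normal"`` draws Normal(0, adjusted_rmse²) (default, matching the
    model's residual term); ``"pm"`` is the literal ±adjusted_rmse with equal
    probability, kept for sensitivity analysis.
    """

    follow_up_years: float = 2.0
    paired: bool = True
    assignment: Literal["random_bernoulli", "worse_eye_treated"] = "random_bernoulli"
    endpoint: str = "optimal_weighted"
    alpha: float = 0.05
    effect_sizes: tuple[float, ...] = field(default_factory=_default_effects)
    n_sims: int = 10_000
    seed: int = 0
    noise: Literal["normal", "pm"] = "normal"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if any(e < 0 or e > 1 for e in self.effect_sizes):
            raise ValueError("effect sizes must lie in [0, 1]")
        if self.follow_up_years <= 0:
            raise ValueError("follow_up_years must be > 0")


@dataclass
class PowerCurve:
    """Estimated power per effect size, with Monte-Carlo standard errors."""

    frame: pd.DataFrame  # effect_size, power, mc_se, rejections, n_sims, degenerate
    design: TrialDesign

    def power_at(self, effect: float) -> float:
        row = self.frame[np.isclose(self.frame["effect_size"], effect)]
        if row.empty:
            raise KeyError(f"effect size {effect} not in the sweep")
        return float(row["power"].iloc[0])


def _eye_slopes(fit: ProgressionFit) -> tuple[list[str], np.ndarray]:
    """Per-patient (n, 2) conditional slopes; single-eye patients reuse the
    population slope for the missing fellow eye."""
    by_patient: dict[str, dict[str, float]] = {}
    for (pid, eye), sl in fit.conditional_slopes.items():
        by_patient.setdefault(pid, {})[eye] = sl
    patients = sorted(by_patient)
    slopes = np.array(
        [
            [
                by_patient[p].get("OD", fit.slope),
                by_patient[p].get("OS", fit.slope),
            ]
            for p in patients
        ]
    )
    return patients, slopes


def simulate_trial(
    fit: ProgressionFit,
    adjusted_rmse: float,
    design: TrialDesign,
    baseline_ecc: Mapping[tuple[str, str], float] | None = None,
) -> PowerCurve:
    """Monte-Carlo power curve for one endpoint and design.

    Parameters
    ----------
    fit
        Progression fit providing conditional slopes for the trial patients.
    adjusted_rmse
        Residual noise scale (degrees) for simulated follow-up measurements.
    baseline_ecc
        Baseline composite eccentricity per (patient, eye); required only for
        ``assignment="worse_eye_treated"`` (the eye with the larger baseline
        value is treated).

    Replicates whose test statistic is undefined (zero variance) count as
    non-rejections and are tallied in the ``degenerate`` column.
    """
    if adjusted_rmse < 0:
        raise ValueError("adjusted_rmse must be >= 0")
    patients, slopes = _eye_slopes(fit)
    n_pat = len(patients)
    if n_pat < 2:
        raise ValueError(f"need >= 2 patients, got {n_pat}")
    x = design.follow_up_years
    inc = slopes * x  # (n_pat, 2) predicted x-year increments per eye

    if design.assignment == "worse_eye_treated":
        if baseline_ecc is None:
            raise ValueError("worse_eye_treated assignment needs baseline_ecc")
        worse = np.array(
            [
                0
                if baseline_ecc.get((p, "OD"), -np.inf) >= baseline_ecc.get((p, "OS"), -np.inf)
                else 1
                for p in patients
            ]
        )
    else:
        worse = None

    ss = np.random.SeedSequence(design.seed)
    children = ss.spawn(len(design.effect_sizes))
    rows = []
    for effect, child in zip(design.effect_sizes, children):
        rng = np.random.default_rng(child)
        if design.assignment == "random_bernoulli":
            treated = rng.integers(0, 2, size=(design.n_sims, n_pat))
        else:
            treated = np.broadcast_to(worse, (design.n_sims, n_pat)).copy()

        if design.noise == "normal":
            noise = rng.normal(0.0, adjusted_rmse, size=(design.n_sims, n_pat, 2))
        else:
            noise = adjusted_rmse * rng.choice([-1.0, 1.0], size=(design.n_sims, n_pat, 2))

        inc_b = np.broadcast_to(inc, (design.n_sims, n_pat, 2))
        rowsel = np.arange(n_pat)
        simsel = np.arange(design.n_sims)[:, None]
        inc_t = inc_b[simsel, rowsel, treated]
        inc_c = inc_b[simsel, rowsel, 1 - treated]
        noise_t = noise[simsel, rowsel, treated]
        noise_c = noise[simsel, rowsel, 1 - treated]
        delta = effect * inc_t
        change_t = inc_t - delta + noise_t
        change_c = inc_c + noise_c

        if design.paired:
            d = change_t - change_c  # (n_sims, n_pat)
            mean = d.mean(axis=1)
            sd = d.std(axis=1, ddof=1)
            ok = sd > 0
            tstat = np.zeros(design.n_sims)
            tstat[ok] = mean[ok] / (sd[ok] / np.sqrt(n_pat))
            pvals = np.ones(design.n_sims)
            pvals[ok] = 2 * stats.t.sf(np.abs(tstat[ok]), df=n_pat - 1)
            degenerate = int((~ok).sum())
        else:
            # 1:1 patient randomization; one eye per patient enters analysis
            arm = rng.integers(0, 2, size=(design.n_sims, n_pat))  # 1 = treated arm
            obs = np.where(arm == 1, change_t, change_c)
            n1 = arm.sum(axis=1)
            n0 = n_pat - n1
            ok = (n1 >= 2) & (n0 >= 2)
            with np.errstate(invalid="ignore", divide="ignore"):
                mean1 = (obs * arm).sum(axis=1) / n1
                mean0 = (obs * (1 - arm)).sum(axis=1) / n0
                ss1 = (((obs - mean1[:, None]) ** 2) * arm).sum(axis=1)
                ss0 = (((obs - mean0[:, None]) ** 2) * (1 - arm)).sum(axis=1)
                sp2 = (ss1 + ss0) / (n1 + n0 - 2)
                tstat = (mean1 - mean0) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
            ok &= np.isfinite(tstat) & (sp2 > 0)
            pvals = np.ones(design.n_sims)
            pvals[ok] = 2 * stats.t.sf(np.abs(tstat[ok]), df=n_pat - 2)
            degenerate = int((~ok).sum())

        rej = int((pvals < design.alpha).sum())
        p_hat = rej / design.n_sims
        rows.append(
            {
                "effect_size": effect,
                "power": p_hat,
                "mc_se": float(np.sqrt(p_hat * (1 - p_hat) / design.n_sims)),
                "rejections": rej,
                "n_sims": design.n_sims,
                "degenerate": degenerate,
            }
        )
    return PowerCurve(frame=pd.DataFrame(rows), design=design)


def power_scenarios(
    scenarios: Sequence[
        tuple[str, ProgressionFit, float, TrialDesign, Mapping[tuple[str, str], float] | None]
    ]
) -> pd.DataFrame:
    """Power curves for a set of named scenario variants.

    Each scenario is ``(name, fit, adjusted_rmse, design, baseline_ecc)``.
    Scenarios sharing a seed share the same stream structure, so their curves
    are directly comparable.  Returns a long table with a ``scenario``
    column.
    """
    if not scenarios:
        raise ValueError("no scenarios given")
    parts = []
    for name, fit, adj, design, baseline in scenarios:
        curve = simulate_trial(fit, adj, design, baseline_ecc=baseline)
        frame = curve.frame.copy()
        frame.insert(0, "scenario", name)
        frame["seed"] = design.seed
        parts.append(frame)
    return pd.concat(parts, ignore_index=True)
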