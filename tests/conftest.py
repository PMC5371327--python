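import numpy as np
import pytest

import stargardt_endpoint as se


@pytest.fixture(scope="session")
def dev_cohort():
    """One synthetic development-preset cohort (fixed seed)."""
    return se.generate_cohort(se.paper_preset("development"))


@pytest.fixture(scope="session")
def dev_ecc(dev_cohort):
    """The same cohort standardized to eccentricity degrees."""
    return se.standardize_cohort(dev_cohort.to_frame())


@pytest.fixture(scope="session")
def dev_deltas(dev_ecc):
    """Per-biomarker deltas with the optimal-weight composite column."""
    deltas = se.deltas_from_baseline(dev_ecc)
    deltas["delta_c"] = se.composite_column(deltas, se.OPTIMAL_WEIGHTS)
    return deltas


@pytest.fixture(scope="session")
def dev_fit(dev_deltas):
    """Progression fit of the optimal-weight composite on the dev preset."""
    return se.fit_progression(dev_deltas)


def homogeneous_fit(slope: float, n_patients: int, rmse: float = 0.13) -> se.ProgressionFit:
    """A fit whose conditional slopes all equal the population slope —
    the closed-form-comparable case for the trial simulator."""
    cond = {}
    for i in range(n_patients):
        pid = f"H{i + 1:02d}"
        cond[(pid, "OD")] = slope
        cond[(pid, "OS")] = slope
    return se.ProgressionFit(
        slope=slope,
        ci_slope=(slope, slope),
        se_slope=0.0,
        sd_patient=0.0,
        sd_eye=0.0,
        rmse=rmse,
        conditional_slopes=cond,
        n_obs=4 * n_patients,
        n_patients=n_patients,
        n_eyes=2 * n_patients,
        loglik=0.0,
    )
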