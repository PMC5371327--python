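"""Hold-out validation of the composite endpoint, then external replication.

For eyes with three or more visits, the last visit is withheld; the model is
trained on the rest and the withheld composite change is predicted from each
eye's conditional slope.  The same frozen weighting is then applied to the
validation cohort (its own model fit, no re-optimization).  Reports
predicted-vs-measured calibration (R², slope, intercept) for both cohorts.
"""

import argparse
import json
import warnings
from pathlib import Path

import pandas as pd

import stargardt_endpoint as se


def _run(label: str, ecc_path: Path, weights: se.WeightVector) -> dict:
    ecc = pd.read_csv(ecc_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cal, fit, adj = se.holdout_validation(ecc, weights)
    out = {
        "cohort": label,
        "n_heldout_pairs": cal.n_pairs,
        "r_squared": round(cal.r_squared, 3),
        "calibration_slope": round(cal.ols_slope, 3),
        "calibration_slope_ci": [round(v, 3) for v in cal.ols_slope_ci],
        "calibration_intercept": round(cal.ols_intercept, 3),
        "calibration_intercept_ci": [round(v, 3) for v in cal.ols_intercept_ci],
        "training_slope_deg_per_year": round(fit.slope, 3),
        "training_slope_ci": [round(v, 3) for v in fit.ci_slope],
        "adjusted_rmse_deg": round(adj, 4),
    }
    print(
        f"{label}: R2 {out['r_squared']}, calibration slope {out['calibration_slope']} "
        f"{out['calibration_slope_ci']}, intercept {out['calibration_intercept']} "
        f"{out['calibration_intercept_ci']}, training slope "
        f"{out['training_slope_deg_per_year']} deg/yr {out['training_slope_ci']}"
    )
    return out


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dev-ecc", type=Path, default=Path("results/ecc_development.csv"))
    ap.add_argument("--val-ecc", type=Path, default=Path("results/ecc_validation.csv"))
    ap.add_argument(
        "--weights",
        type=str,
        default="0,25,5,55,15",
        help="frozen weighting percentages bcva,qdaf,ddaf,ez,elm",
    )
    ap.add_argument("--out", type=Path, default=Path("results/calibration.json"))
    args = ap.parse_args()

    weights = se.WeightVector.from_percents([float(x) for x in args.weights.split(",")])
    results = [
        _run("development", args.dev_ecc, weights),
        _run("validation", args.val_ecc, weights),
    ]
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(results, indent=2) + "\n")
    print(f"calibration report -> {args.out}")


if __name__ == "__main__":
    main()
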