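"""Univariable progression rates and responsiveness per biomarker.

Fits the zero-intercept random-slope model to each biomarker's eccentricity
change separately (weight 100% on that biomarker) and tabulates slope,
residual SD, and MSDR — the per-biomarker baseline that the weighted
composite has to beat.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

import stargardt_endpoint as se


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--ecc", type=Path, default=Path("results/ecc_development.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/univariable_msdr.csv"))
    args = ap.parse_args()

    ecc = pd.read_csv(args.ecc)
    deltas = se.deltas_from_baseline(ecc)
    rows = []
    for i, marker in enumerate(se.BIOMARKERS):
        pct = [0] * 5
        pct[i] = 100
        wv = se.WeightVector.from_percents(pct)
        work = deltas.copy()
        work["delta_c"] = se.composite_column(work, wv)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = se.fit_progression(work)
            m = se.msdr(fit)
            rows.append(
                {
                    "biomarker": marker,
                    "slope_deg_per_year": round(fit.slope, 3),
                    "ci_low": round(fit.ci_slope[0], 3),
                    "ci_high": round(fit.ci_slope[1], 3),
                    "residual_sd_deg": round(fit.rmse, 3),
                    "msdr": round(m.msdr, 3),
                    "n_obs": fit.n_obs,
                }
            )
        except ValueError as exc:
            rows.append({"biomarker": marker, "note": f"not fittable: {exc}"})
    out = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(args.out, index=False)
    print(f"univariable fits on {args.ecc.name} -> {args.out}")
    print(out.to_string(index=False))


if __name__ == "__main__":
    main()
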