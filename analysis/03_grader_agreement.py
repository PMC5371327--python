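"""Inter-grader reconciliation and agreement statistics on simulated gradings.

Emulates two blinded graders measuring the same lesions: true eccentricities
are taken from the development cohort's standardized table and each grader
reads them with independent zero-mean error (SD chosen so the absolute
inter-grader differences match the reported 0.2-0.3° scale).  Pairs
differing by more than 1° are flagged for consensus; the mean absolute
difference and the absolute-agreement ICC(2,1) are tabulated per biomarker.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import stargardt_endpoint as se

GRADER_ERROR_SD = 0.20  # deg; reproduces ~0.23 deg mean absolute difference
MARKERS = {"QDAF": "eps_qdaf", "DDAF": "eps_ddaf", "EZ": "eps_ez", "ELM": "eps_elm"}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--ecc", type=Path, default=Path("results/ecc_development.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/agreement.csv"))
    args = ap.parse_args()

    ecc = pd.read_csv(args.ecc)
    rng = np.random.default_rng(args.seed)
    rows = []
    for label, col in MARKERS.items():
        truth = ecc[col].dropna().to_numpy()
        pairs = [
            se.GraderPair(
                label,
                max(t + rng.normal(0, GRADER_ERROR_SD), 0.0),
                max(t + rng.normal(0, GRADER_ERROR_SD), 0.0),
            )
            for t in truth
        ]
        means, flags = se.reconcile_graders(pairs, threshold_deg=1.0)
        res = se.agreement_stats(pairs)
        rows.append(
            {
                "biomarker": label,
                "n_pairs": res.n_pairs,
                "mean_abs_diff_deg": round(res.mean_abs_diff, 3),
                "sd_abs_diff_deg": round(res.sd_abs_diff, 3),
                "icc": round(res.icc, 4),
                "icc_ci_low": round(res.icc_ci[0], 4),
                "icc_ci_high": round(res.icc_ci[1], 4),
                "n_consensus_flags": int(flags.sum()),
                "mean_of_means_deg": round(float(np.mean(means)), 3),
            }
        )
    out = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(args.out, index=False)
    print(f"grader agreement on {args.ecc.name} -> {args.out}")
    print(out.to_string(index=False))


if __name__ == "__main__":
    main()
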