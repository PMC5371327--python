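"""Standardize cohort measurements to retinal eccentricity (degrees).

Appends the five ε columns to each cohort table and writes a small table of
reference unit conversions (the worked examples of the conversion formulas:
acuity 20/205 ↔ 12.76°, atrophy areas, transverse band loss).
"""

import argparse
from pathlib import Path

import pandas as pd

import stargardt_endpoint as se


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in-dir", type=Path, default=Path("results/cohorts"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    for label in ("development", "validation"):
        path = args.in_dir / f"{label}.csv"
        table = se.read_cohort(path)
        ecc = se.standardize_cohort(table.to_frame())
        out = args.out_dir / f"ecc_{label}.csv"
        ecc.to_csv(out, index=False, float_format="%.6f")
        print(f"{label}: wrote {len(ecc)} standardized eye-visits -> {out}")

    conversions = pd.DataFrame(
        [
            {"input": "BCVA 20/205", "output": "eccentricity deg",
             "value": round(se.ecc_from_bcva(20 / 205), 2)},
            {"input": "eccentricity 12.76 deg", "output": "equivalent diameter mm",
             "value": round(se.transverse_from_ecc(12.76), 1)},
            {"input": "eccentricity 4.22 deg", "output": "atrophy area mm2",
             "value": round(se.area_from_ecc(4.22), 2)},
            {"input": "eccentricity 1.80 deg", "output": "atrophy area mm2",
             "value": round(se.area_from_ecc(1.80), 2)},
            {"input": "eccentricity 5.09 deg", "output": "transverse loss mm",
             "value": round(se.transverse_from_ecc(5.09), 2)},
            {"input": "eccentricity 3.54 deg", "output": "transverse loss mm",
             "value": round(se.transverse_from_ecc(3.54), 2)},
        ]
    )
    out = args.out_dir / "conversions.csv"
    conversions.to_csv(out, index=False)
    print(f"reference conversions -> {out}")
    print(conversions.to_string(index=False))


if __name__ == "__main__":
    main()
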