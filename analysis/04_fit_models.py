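"""Fit the five spiked OPLS calibrations.

For each analyte: restrict the matrix to the analyte's spectral regions,
choose the orthogonal component count by leave-vessel-out cross-validation
under the R2-Q2 <= 0.3 overfit guard, and store the refitted model as JSON.
"""

import argparse
from pathlib import Path

import pandas as pd

from ramcal import ANALYTES, calibrate, make_cv_groups
from ramcal.pipeline_io import read_matrix


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    X, meta, axis = read_matrix(args.out / "preprocessed.csv")
    flags = pd.read_csv(args.out / "outliers.csv")
    plan = make_cv_groups(meta["vessel_id"], k=4)

    for analyte in ANALYTES:
        result = calibrate(X, meta, axis, analyte, plan,
                           exclude=flags["flagged"].to_numpy(dtype=bool))
        (args.out / f"model_{analyte}.json").write_text(result["model"].to_json())
        rep = result["report"]
        print(f"{analyte:10s} 1+{rep.n_ortho}  n={rep.n:3d}  "
              f"R2={rep.r2:.3f}  Q2={rep.q2:.3f}  RMSEcv={rep.rmsecv:.3f}")


if __name__ == "__main__":
    main()
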