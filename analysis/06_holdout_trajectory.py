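"""Holdout-vessel trajectory prediction.

Excludes one vessel entirely from model building and predicts its daily
analyte trajectories, the realistic monitoring scenario: a model trained on
past batches applied to a new one. Writes trajectory.csv with one
(vessel, analyte, day, observed, predicted) row per point.
"""

import argparse
from pathlib import Path

import pandas as pd

from ramcal import ANALYTES, holdout_trajectory
from ramcal.pipeline_io import read_matrix


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--vessel", type=int, default=24,
                    help="held-out vessel (default: a control vessel)")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    X, meta, axis = read_matrix(args.out / "preprocessed.csv")
    parts = []
    for analyte in ANALYTES:
        series, rmse = holdout_trajectory(X, meta, axis, args.vessel, analyte)
        series.insert(0, "analyte", analyte)
        series.insert(0, "vessel_id", args.vessel)
        parts.append(series)
        print(f"{analyte:10s} trajectory RMSE: {rmse:.4f}")
    pd.concat(parts, ignore_index=True).to_csv(args.out / "trajectory.csv",
                                               index=False)
    print(f"-> {args.out/'trajectory.csv'}")


if __name__ == "__main__":
    main()
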