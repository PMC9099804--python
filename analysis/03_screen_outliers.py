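"""PCA outlier screening of the preprocessed spectra.

Fits a PCA to the preprocessed matrix and flags confirmed outliers:
Hotelling-T2 candidates verified by their distance to the model (DmodX),
plus strong DmodX or extreme-T2 rows on their own. Writes outliers.csv; a
healthy run stays well below 5% flagged.
"""

import argparse
from pathlib import Path

from ramcal import screen_outliers
from ramcal.pipeline_io import read_matrix


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    X, meta, _axis = read_matrix(args.out / "preprocessed.csv")
    flags, summary = screen_outliers(X, meta)
    flags.to_csv(args.out / "outliers.csv", index=False)

    print(f"PCA components: {summary['n_components']}, "
          f"T2 limit: {summary['t2_limit']:.2f}")
    print(f"flagged {summary['n_flagged']}/{summary['n']} "
          f"({summary['fraction']:.1%}) -> {args.out/'outliers.csv'}")
    if summary["n_flagged"]:
        print(flags.loc[flags.flagged, "reason"].value_counts().to_string())


if __name__ == "__main__":
    main()
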