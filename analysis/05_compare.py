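"""Cross-method comparison with compact significance letters.

Loads the cached result tables written by 02-04 (rerunning any missing grid
cheaply via the fingerprint cache), picks each method family's best row,
runs pairwise Welch tests with Holm correction on the per-run accuracies,
and writes the comparison table plus the letter-annotated box plot.
"""

import argparse
from pathlib import Path

import pandas as pd

from seroblot.experiments import compare_report


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    for task in ("three_class", "two_class"):
        tables = {}
        for method in ("knn_dtw", "ecnn", "deepga_cnn"):
            path = args.out / f"{method}_{task}.csv"
            if path.exists():
                tables[method] = pd.read_csv(path)
        if len(tables) < 2:
            print(f"{task}: need at least two method tables under {args.out} "
                  "(run analysis/02..04 first)")
            continue
        report = compare_report(
            tables, plot_path=args.out / f"compare_{task}.png")
        report.to_csv(args.out / f"compare_{task}.csv", index=False)
        print(f"\n=== method comparison, {task} ===")
        print(report.to_string(index=False))
        print(f"plot -> {args.out}/compare_{task}.png")


if __name__ == "__main__":
    main()
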