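"""Generate the synthetic strip cohort and inspect its class structure.

Writes the per-strip PNGs + manifest, a multi-lane montage, the extracted
lane profiles as CSV, and prints a within/between-class DTW distance summary
showing that cancer and healthy band patterns are homogeneous and mutually
distinct while benign overlaps both.
"""

import argparse
import itertools
from pathlib import Path

import imageio.v3 as iio
import numpy as np

import seroblot as sb
from seroblot.profiles import profiles_to_csv
from seroblot.synth import montage, save_cohort


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = parser.parse_args()

    cohort = sb.generate_cohort(sb.CohortConfig(seed=args.seed))
    manifest = save_cohort(cohort, args.out)
    print(f"cohort: {len(cohort)} strips -> {manifest}")

    sample = cohort[:8] + cohort[50:58] + cohort[100:108]
    iio.imwrite(args.out / "montage.png",
                np.round(montage(sample)).astype(np.uint8))

    profiles = sb.extract_cohort_profiles(cohort, seed=args.seed)
    # small illustrative sample; the full set is regenerated on demand
    profiles_to_csv(profiles[:3] + profiles[50:53] + profiles[100:103],
                    args.out / "profiles_sample.csv")
    lengths = sorted({len(p) for p in profiles})
    print(f"profiles: lengths span {lengths[0]}..{lengths[-1]} "
          f"({len(lengths)} distinct) — manual-selection jitter emulated")

    by = {}
    for p in profiles:
        by.setdefault(p.label, []).append(p)
    rng = np.random.default_rng(args.seed)

    def mean_dtw(pairs, cap=120):
        pairs = list(pairs)
        if len(pairs) > cap:
            pairs = [pairs[i] for i in rng.choice(len(pairs), cap, replace=False)]
        return float(np.mean([sb.dtw_distance(a, b) for a, b in pairs]))

    print("mean DTW distances (subsampled):")
    for lab in sb.CLASS_ORDER:
        print(f"  within {lab:8s}: "
              f"{mean_dtw(itertools.combinations(by[lab], 2)):9.1f}")
    for la, lb in itertools.combinations(sb.CLASS_ORDER, 2):
        print(f"  {la} vs {lb:8s}: "
              f"{mean_dtw(itertools.product(by[la], by[lb])):9.1f}")


if __name__ == "__main__":
    main()
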