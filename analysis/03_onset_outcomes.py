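#!/usr/bin/env python
"""Summarize time-to-onset and outcome severity for the simulated ICI cohort.

Reads the tables written by 02_signals.py and reports the onset medians,
quartiles and landmark cumulative proportions per respiratory class, and
the per-class death proportions, against the generator's configured onset
and mortality models.
"""

import argparse
from pathlib import Path

from faerspv import pipeline as pl


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--out-dir", type=Path, default=Path("results/analysis"))
    args = parser.parse_args()

    onset = pl.read_output_csv(args.out_dir / "onset_by_class.csv")
    print("time to onset (ICI respiratory pairs, day-precision dates only):")
    for _, row in onset.iterrows():
        if row["n_dated"] == 0:
            continue
        print(f"  {row['event_class']:40s} n={int(row['n_dated']):5d}  "
              f"median {row['median_days']:5.1f} d "
              f"(Q1-Q3 {row['q1_days']:.0f}-{row['q3_days']:.0f})  "
              f"<=90 d: {100 * row['cum_90d']:.1f}%")

    deaths = pl.read_output_csv(args.out_dir / "death_by_class.csv")
    print("\nfatal-outcome proportions per class:")
    for _, row in deaths.iterrows():
        if row["n"] == 0:
            continue
        print(f"  {row['event_class']:40s} n={int(row['n']):5d}  "
              f"deaths {int(row['deaths']):4d} ({row['death_pct']:.2f}%)")

    chars = pl.read_output_csv(args.out_dir / "characteristics.csv")
    sex = chars[chars["dimension"] == "sex"].set_index("level")
    print("\nsex distribution of ICI respiratory pairs: "
          + ", ".join(f"{lvl} {row['pct_ici']:.1f}%" for lvl, row in sex.iterrows()))


if __name__ == "__main__":
    main()
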