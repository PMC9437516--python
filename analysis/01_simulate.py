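#!/usr/bin/env python
"""Simulate a FAERS-shaped corpus with known injected respiratory signals.

Writes quarterly '$'-delimited DEMO/DRUG/REAC/OUTC/THER files plus ground
truth under scratch/corpus (large, regenerable; excluded from version
control).  The corpus carries three injected drug-PT disproportionalities
spanning the interesting range: a strong signal, a moderate one, and a
null (target shrunk ROR 4, 2 and 1).
"""

import argparse
from pathlib import Path

from faerspv.synthetic import SimConfig, generate

INJECTED = [
    ("durvalumab", "PNEUMONITIS", 4.0),
    ("nivolumab", "INTERSTITIAL LUNG DISEASE", 2.0),
    ("avelumab", "DYSPNOEA", 1.0),
]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--n-cases", type=int, default=20_000)
    parser.add_argument("--out-dir", type=Path, default=Path("scratch/corpus"))
    args = parser.parse_args()

    config = SimConfig(seed=args.seed, n_cases=args.n_cases,
                       injected_signals=INJECTED, n_orphan_reac=10)
    manifest = generate(config, args.out_dir)

    counts = manifest["counts"]
    print(f"wrote {len(manifest['quarters'])} quarters under {args.out_dir}")
    print(f"cases retained: {counts['n_cases']} "
          f"(+{counts['n_duplicate_versions']} duplicate versions, "
          f"{counts['n_cases_no_event']} event-free cases dropped)")
    print(f"ground-truth drug-event pairs: {counts['n_pairs']}")
    print("injected signals (drug, PT, target shrunk ROR -> solved P(pt|drug)):")
    for (drug, pt, target) in INJECTED:
        q = manifest["boosts"][f"{drug}|{pt}"]
        print(f"  {drug:12s} {pt:28s} {target:.1f} -> {q:.4f}")


if __name__ == "__main__":
    main()
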