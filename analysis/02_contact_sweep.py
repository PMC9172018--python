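#!/usr/bin/env python
"""Static oil-retina contact over the full study grid.

Runs the capillary equilibrium solver for every (geometry, posture, fill)
combination — fills 80-100 % in 5 % steps, standing / 45-degree upward tilt /
supine — and writes the long-format contact table to
results/contact_sweep.csv.  Use --resolution to trade accuracy for speed
(default 96, the reporting resolution; 48 for a quick look).
"""

import argparse

from tamponade import SweepConfig, run_sweep


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--resolution", type=int, default=96)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    cfg = SweepConfig(resolution=args.resolution, output_dir=args.out)
    df = run_sweep(cfg)
    overall = df[df.region == "overall"]
    print(f"\n{len(overall)} cases at {args.resolution}^3 voxels "
          f"-> {args.out}/contact_sweep.csv")
    lo = overall.loc[overall.contact_pct.idxmin()]
    hi = overall.loc[overall[overall.fill_pct < 100].contact_pct.idxmax()]
    print(f"lowest contact:  {lo.contact_pct:.1f}%  "
          f"({lo.variant}, {lo.posture}, {lo.fill_pct:.0f}% fill)")
    print(f"highest contact below complete fill: {hi.contact_pct:.1f}%  "
          f"({hi.variant}, {hi.posture}, {hi.fill_pct:.0f}% fill)")
    at90 = overall[overall.fill_pct == 90.0]
    print(f"untouched retina at the representative 90% fill: "
          f"{(100 - at90.contact_pct).min():.1f}-"
          f"{(100 - at90.contact_pct).max():.1f}%")


if __name__ == "__main__":
    main()
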