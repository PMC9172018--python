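#!/usr/bin/env python
"""Reduce the contact sweep to the figure-panel tables (and optional plots).

Reads results/contact_sweep.csv (from 02_contact_sweep.py) and writes the
three panel summaries: overall contact vs fill per posture, the
pre-/post-equatorial quadrant curves, and the per-region bars at 90 % fill.
With --plot, renders the overall-contact panels to results/overall_vs_fill.png.
"""

import argparse
from pathlib import Path

import pandas as pd

from tamponade import summarize_figures


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", default="results/contact_sweep.csv")
    ap.add_argument("--out", default="results")
    ap.add_argument("--plot", action="store_true")
    args = ap.parse_args()

    df = pd.read_csv(args.results)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    tables = summarize_figures(df)
    for name, table in tables.items():
        path = out / f"summary_{name}.csv"
        table.to_csv(path, float_format="%.6f")
        print(f"wrote {path}")

    overall = tables["overall_vs_fill"]
    print("\noverall contact (%) vs fill:")
    print(overall.round(1).to_string())

    if args.plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        postures = overall.columns.get_level_values("posture").unique()
        fig, axes = plt.subplots(1, len(postures), figsize=(4 * len(postures), 3.2),
                                 sharey=True)
        for ax, posture in zip(axes, postures):
            sub = overall[posture]
            for variant in sub.columns:
                ax.plot(sub.index, sub[variant], marker="o", label=variant)
            ax.set_title(posture)
            ax.set_xlabel("fill (%)")
        axes[0].set_ylabel("retinal contact (%)")
        axes[-1].legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "overall_vs_fill.png", dpi=150)
        print(f"wrote {out / 'overall_vs_fill.png'}")


if __name__ == "__main__":
    main()
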