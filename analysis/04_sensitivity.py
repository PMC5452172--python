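#!/usr/bin/env python
"""Sensitivity envelopes: energy compensation and reformulation bounds.

Runs each family's primary + lower/upper parameter sets on all discretionary
choices (aggregate mode on the reference table) and writes the envelope
tables that back error-bar style figures.  Pass --plot to also draw the
percent-change chart for the primary outcomes.
"""

import argparse
from pathlib import Path

from dietsim import load_reference, run_sensitivity_suite
from dietsim.reporting import sensitivity_report

ROOT = Path(__file__).resolve().parents[1]
PRIMARY = ("energy", "sfa", "added_sugars", "sodium", "alcohol")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--plot", action="store_true")
    args = parser.parse_args()

    table = load_reference()
    results_dir = ROOT / "results"
    results_dir.mkdir(exist_ok=True)
    envelopes = {}
    for family in ("moderation", "substitution", "reformulation"):
        results = run_sensitivity_suite(table, family)
        df = sensitivity_report(results)
        out = results_dir / f"sensitivity_{family}.tsv"
        df.to_csv(out, sep="\t", index=False)
        envelopes[family] = results
        pct_cols = [c for c in df.columns if c.startswith("pct_change_")]
        for nutrient in PRIMARY:
            row = df[df.nutrient == nutrient].iloc[0]
            span = ", ".join(f"{c.removeprefix('pct_change_')} {row[c]}"
                             for c in pct_cols if row[c] != "")
            print(f"{family:14s} {nutrient:12s} {span}")
        print(f"wrote {out}")

    if args.plot:
        _plot(envelopes, results_dir / "sensitivity_primary_outcomes.png")


def _plot(envelopes, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    fig, ax = plt.subplots(figsize=(8, 4))
    width = 0.25
    x = np.arange(len(PRIMARY))
    for i, (family, results) in enumerate(envelopes.items()):
        keys = list(results)
        centre = "primary" if "primary" in results else keys[0]
        values = [results[centre].pct_change.get(n) or 0.0 for n in PRIMARY]
        lows = [min((results[k].pct_change.get(n) or 0.0) for k in keys)
                for n in PRIMARY]
        highs = [max((results[k].pct_change.get(n) or 0.0) for k in keys)
                 for n in PRIMARY]
        err = [[v - lo for v, lo in zip(values, lows)],
               [hi - v for v, hi in zip(values, highs)]]
        ax.bar(x + (i - 1) * width, values, width, yerr=err, capsize=3,
               label=family)
    ax.set_xticks(x, PRIMARY)
    ax.set_ylabel("% change from base case")
    ax.axhline(0, color="k", lw=0.5)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
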