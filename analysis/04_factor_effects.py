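"""Summarize how SNP density (and sample size, when present) moves accuracy.

Reads ``results/accuracy.csv``, computes the across-version mean accuracy by
(density, sample size, method) and the pairwise contrasts, and writes
``results/factor_effects.csv``.  With only the scaled benchmark run the
sample-size contrast is reported as not estimable (both cells use 100
trios); the density contrast (10k - 5k) is the headline effect.

Run:  python analysis/04_factor_effects.py
"""

import argparse
from pathlib import Path

import pandas as pd

from trioboost.evaluate import AccuracyReport, factor_effects


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()
    path = args.results / "accuracy.csv"
    if not path.exists():
        raise SystemExit(f"{path} not found - run analysis/02_impute_benchmark.py first")

    report = AccuracyReport(pd.read_csv(path))
    fx = factor_effects(report)
    out = args.results / "factor_effects.csv"
    fx.to_csv(out, index=False)

    print(fx.to_string(index=False))
    gains = fx[(fx["effect"] == "density_10k_minus_5k") & (fx["note"] == "")]
    if len(gains):
        print(
            "\nDensity effect: moving from the 5k to the 10k panel changes the "
            "dataset-level accuracy by "
            + ", ".join(f"{r['method']} {r['value']:+.4f}" for _, r in gains.iterrows())
        )
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
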