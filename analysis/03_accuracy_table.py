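"""Tabulate the benchmark accuracies in the version x method layout.

Reads ``results/accuracy.csv`` (written by 02_impute_benchmark.py),
rebuilds the per-version means and the across-version dataset means, and
writes ``results/table_accuracy.csv``.

Run:  python analysis/03_accuracy_table.py
"""

import argparse
from pathlib import Path

import pandas as pd

from trioboost.evaluate import AccuracyReport


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()
    path = args.results / "accuracy.csv"
    if not path.exists():
        raise SystemExit(f"{path} not found - run analysis/02_impute_benchmark.py first")

    report = AccuracyReport(pd.read_csv(path))
    table = report.version_table()
    means = report.dataset_means()
    out = args.results / "table_accuracy.csv"
    table.to_csv(out, index=False)

    print("Mean imputation accuracy per version (replicate means):")
    print(table.to_string(index=False))
    print("\nAcross-version dataset means:")
    print(means.to_string(index=False))
    ordered = means.pivot_table(index="dataset", columns="method", values="accuracy")
    for ds, row in ordered.iterrows():
        verdict = "LB >= AB >= TB" if row["LB"] >= row["AB"] >= row["TB"] else "NOT in the expected order"
        print(f"{ds}: method ordering {verdict}")
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
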