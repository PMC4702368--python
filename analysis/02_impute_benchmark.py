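"""Run the scaled imputation benchmark: three boosting methods on 5k and 10k panels.

Simulates the scaled 5k (G1-like, 5 replicates) and 10k (G2-like, 2
replicates) single-chromosome designs, imputes every masked version
(NA10...NA90) with AdaBoost, LogitBoost and TotalBoost (L = 10, M = 100),
scores per-SNP correlations against the truth, and writes the long-format
accuracy table plus its means under ``results/``.

Run:  python analysis/02_impute_benchmark.py [--seed 1] [--quick]
(takes on the order of ten minutes; --quick runs 1 replicate of NA10/NA90 only)
"""

import argparse
import logging
import sys
from pathlib import Path

from trioboost.benchmark import run_scaled_benchmark


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    parser.add_argument("--quick", action="store_true")
    args = parser.parse_args()
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(asctime)s %(message)s")

    kwargs = dict(seed=args.seed, outdir=str(args.outdir))
    if args.quick:
        kwargs.update(g1_replicates=1, g2_replicates=1, versions=("NA10", "NA90"))
    report = run_scaled_benchmark(**kwargs)

    print("\nDataset-level mean accuracy (across versions and replicates):")
    print(report.dataset_means().to_string(index=False))
    print(f"\nwrote {args.outdir}/accuracy.csv (+ _means, _dataset_means, factor_effects)")


if __name__ == "__main__":
    main()
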