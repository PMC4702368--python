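"""Simulate an example trio dataset and write it as VCF + pedigree.

Generates one replicate of the scaled 5k-panel design (one 1-Morgan
chromosome, 1000 SNPs, 100 trios), masks it at the NA50 level, and writes
the masked VCF, the truth VCF, the pedigree, and a summary of allele
frequencies and mask structure under ``results/data/``.

Run:  python analysis/01_simulate_datasets.py [--seed 1]
"""

import argparse
from pathlib import Path

import numpy as np

from trioboost.io import write_pedigree, write_vcf
from trioboost.simulate import SimulationConfig, apply_missingness, simulate_base_dataset


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(density="5k", n_trios=100, n_chrom=1, seed=args.seed)
    base = simulate_base_dataset(cfg, replicate=0)
    masked = apply_missingness(base, 0.5, "shared_panel", seed=args.seed)
    masked.version = "NA50"

    write_vcf(base, args.outdir / "G1_rep0_truth.vcf")
    write_vcf(masked, args.outdir / "G1_rep0_NA50.vcf")
    write_pedigree(base.trios, args.outdir / "G1_rep0.ped")

    maf = np.minimum(base.truth.mean(axis=(0, 1)), 1 - base.truth.mean(axis=(0, 1)))
    print(f"simulated {base.n_trios} trios x {base.n_loci} SNPs (seed {args.seed})")
    print(f"minor-allele frequency: mean {maf.mean():.3f}, min {maf.min():.3f}")
    print(
        f"NA50 mask: {masked.mask.masked.mean():.1%} of offspring entries hidden, "
        f"panel identical across offspring: "
        f"{bool(np.all(masked.mask.masked == masked.mask.masked[:1]))}"
    )
    print(f"wrote truth/masked VCFs and pedigree under {args.outdir}/")


if __name__ == "__main__":
    main()
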