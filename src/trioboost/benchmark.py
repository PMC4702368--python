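"""The scaled benchmark study: configurations and a one-call driver.

The full four-dataset design (five 1-Morgan chromosomes, up to 500 trios,
30 replicates) is desk-scale only in aggregate; the scaled benchmark keeps
the quantities that drive the statistical behaviour — per-chromosome SNP
density (1000/Morgan for the "5k" panel, 2000/Morgan for "10k"), 100 trios,
all five missing-data versions, window L = 10, M = 100 trees — and runs a
single chromosome with 5 replicates for the 5k panel and 2 for the 10k
density contrast.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .evaluate import AccuracyReport, ExperimentConfig, run_experiment
from .simulate import SimulationConfig

__all__ = ["scaled_configs", "run_scaled_benchmark"]


def scaled_configs(
    seed: int,
    g1_replicates: int = 5,
    g2_replicates: int = 2,
    versions: Sequence[str] = ("NA10", "NA30", "NA50", "NA70", "NA90"),
):
    """Scaled G1-like (5k) and G2-like (10k) simulation configurations."""
    g1 = SimulationConfig(
        density="5k",
        n_trios=100,
        versions=tuple(versions),
        replicates=g1_replicates,
        n_chrom=1,
        seed=seed,
        label="G1",
    )
    g2 = SimulationConfig(
        density="10k",
        n_trios=100,
        versions=tuple(versions),
        replicates=g2_replicates,
        n_chrom=1,
        seed=seed,
        label="G2",
    )
    return g1, g2


def run_scaled_benchmark(
    seed: int,
    g1_replicates: int = 5,
    g2_replicates: int = 2,
    methods: Sequence[str] = ("AB", "LB", "TB"),
    versions: Sequence[str] = ("NA10", "NA30", "NA50", "NA70", "NA90"),
    outdir: Optional[str] = None,
) -> AccuracyReport:
    """Run the scaled benchmark end to end and return its report."""
    g1, g2 = scaled_configs(seed, g1_replicates, g2_replicates, versions)
    return run_experiment(
        ExperimentConfig(simulations=[g1, g2], methods=tuple(methods), outdir=outdir)
    )
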