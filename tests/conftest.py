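"""Shared fixtures: small simulated datasets and the scaled benchmark study."""

import numpy as np
import pytest

from trioboost.evaluate import ExperimentConfig, run_experiment
from trioboost.simulate import (
    SimulationConfig,
    apply_missingness,
    generate_dataset,
    simulate_base_dataset,
)


def tiny_sim_config(**overrides) -> SimulationConfig:
    """A fast, structurally complete simulation configuration for unit tests."""
    kw = dict(
        density="1k",
        n_trios=20,
        versions=("NA50",),
        replicates=1,
        seed=7,
        n_chrom=2,
        historic_size=60,
        historic_generations=3,
        reference_generations=3,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


def make_toy_dataset(haps) -> "TrioDataset":
    """TrioDataset from a raw (3n x 2 x loci) 0/1 array (n sires, n dams, n offspring)."""
    from trioboost.simulate import GeneticMap, TrioDataset

    haps = np.asarray(haps, dtype=np.uint8)
    n_loci = haps.shape[2]
    gmap = GeneticMap([("chr1", 1.0)], [np.linspace(0.01, 0.99, n_loci)])
    n = haps.shape[0] // 3
    ids = (
        [f"S{i}" for i in range(n)]
        + [f"D{i}" for i in range(n)]
        + [f"O{i}" for i in range(n)]
    )
    trios = [(f"S{i}", f"D{i}", f"O{i}") for i in range(n)]
    return TrioDataset(ids, trios, haps.astype(np.float32), haps.copy(), gmap)


@pytest.fixture(scope="session")
def tiny_base_dataset():
    """One unmasked, recoded 20-trio dataset (2 chromosomes x 200 loci)."""
    return simulate_base_dataset(tiny_sim_config(), replicate=0)


@pytest.fixture()
def tiny_masked_dataset(tiny_base_dataset):
    return apply_missingness(tiny_base_dataset, 0.5, "shared_panel", seed=1)


@pytest.fixture(scope="session")
def scaled_study():
    """The scaled benchmark: G1-like (5 reps) and G2-like (2 reps) runs.

    One chromosome at the study's per-chromosome densities (1000 and 2000
    SNPs/Morgan), 100 trios, all five missing-data versions, all three
    methods, window L=10 and M=100 trees.  Shared by the acceptance tests.
    """
    from trioboost.benchmark import run_scaled_benchmark

    return run_scaled_benchmark(seed=20260929)
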