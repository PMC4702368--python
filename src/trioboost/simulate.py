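"""Forward-in-time simulation of parent-offspring trio genotype datasets.

The generator emulates a livestock-style breeding design: a historic
population of constant size is random-mated for 50 generations (Haldane
recombination, recurrent bi-allelic mutation), a reference population is then
bred for 50 further generations with 50% of each sex selected as parents, and
parent-offspring trios are sampled from the final generation.  Offspring
genotypes are masked at a chosen rate to create the low-density-panel versions
(NA10 ... NA90) on which imputation is benchmarked; parents are always fully
genotyped.

Alleles are coded 0 = major, 1 = minor after per-locus recoding; unknown
entries are NaN.  All randomness flows through :class:`numpy.random.Generator`
streams derived from a single master seed, so every dataset is reproducible
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GeneticMap",
    "HaplotypePopulation",
    "PanelMask",
    "TrioDataset",
    "SimulationConfig",
    "VERSION_FRACTIONS",
    "make_genetic_map",
    "make_founders",
    "simulate_historic_population",
    "breed_reference_population",
    "sample_trios",
    "recode_major_minor",
    "apply_missingness",
    "generate_dataset",
]

#: Missing-data versions: fraction of each offspring's loci that is masked.
VERSION_FRACTIONS = {
    "NA10": 0.1,
    "NA30": 0.3,
    "NA50": 0.5,
    "NA70": 0.7,
    "NA90": 0.9,
}

#: Study dataset labels keyed by (density label, number of trios).
DATASET_LABELS = {
    ("5k", 100): "G1",
    ("10k", 100): "G2",
    ("5k", 500): "G3",
    ("10k", 500): "G4",
}

SNPS_PER_CHROM = {"1k": 200, "5k": 1000, "10k": 2000}


class SimulationError(ValueError):
    """Invalid parameter or breeding-structure error in the simulator."""


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticMap:
    """Genetic positions (Morgans) of loci on a set of chromosomes.

    ``chromosomes`` is a list of ``(id, length_in_morgans)``; ``positions``
    holds one sorted array of locus positions per chromosome.
    """

    chromosomes: list
    positions: list

    @property
    def n_loci(self) -> int:
        return int(sum(len(p) for p in self.positions))

    @property
    def n_chrom(self) -> int:
        return len(self.chromosomes)

    @property
    def chrom_offsets(self) -> np.ndarray:
        """Global index of the first locus of each chromosome (plus a sentinel)."""
        return np.concatenate([[0], np.cumsum([len(p) for p in self.positions])])

    def chrom_of_locus(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_chrom), [len(p) for p in self.positions])

    def subset(self, keep: np.ndarray) -> "GeneticMap":
        """New map retaining the loci at sorted global indices ``keep``."""
        keep = np.asarray(keep)
        off = self.chrom_offsets
        positions = []
        for c in range(self.n_chrom):
            local = keep[(keep >= off[c]) & (keep < off[c + 1])] - off[c]
            positions.append(self.positions[c][local])
        return GeneticMap(list(self.chromosomes), positions)


def make_genetic_map(
    n_chrom: int, length_morgans: float, snps_per_chrom: int, seed
) -> GeneticMap:
    """Place ``snps_per_chrom`` loci uniformly at random on each chromosome.

    Positions are sorted and strictly increasing within a chromosome.
    """
    if n_chrom < 1 or snps_per_chrom < 2 or length_morgans <= 0:
        raise SimulationError(
            "need n_chrom >= 1, snps_per_chrom >= 2 and a positive length"
        )
    rng = np.random.default_rng(seed)
    positions = []
    for _ in range(n_chrom):
        pos = np.sort(rng.random(snps_per_chrom) * length_morgans)
        # uniform draws collide with probability 0 in theory; nudge in practice
        while np.any(np.diff(pos) <= 0):  # pragma: no cover
            pos = np.sort(rng.random(snps_per_chrom) * length_morgans)
        positions.append(pos)
    chromosomes = [(f"chr{i + 1}", float(length_morgans)) for i in range(n_chrom)]
    return GeneticMap(chromosomes, positions)


# ---------------------------------------------------------------------------
# Populations and meiosis
# ---------------------------------------------------------------------------


@dataclass
class HaplotypePopulation:
    """Phased binary haplotypes of one generation of individuals.

    ``haplotypes`` has shape ``(n, 2, n_loci)`` with entries in {0, 1}.
    ``parents`` (if set) maps each individual to the indices of its sire and
    dam in ``parent_pop``, the previous generation.
    """

    haplotypes: np.ndarray
    is_female: np.ndarray
    gmap: GeneticMap
    generation: int = 0
    parents: Optional[np.ndarray] = None  # (n, 2) -> [sire, dam] in parent_pop
    parent_pop: Optional["HaplotypePopulation"] = None

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    def males(self) -> np.ndarray:
        return np.flatnonzero(~self.is_female)

    def females(self) -> np.ndarray:
        return np.flatnonzero(self.is_female)

    def subset_loci(self, keep: np.ndarray) -> "HaplotypePopulation":
        parent = self.parent_pop.subset_loci(keep) if self.parent_pop is not None else None
        return HaplotypePopulation(
            self.haplotypes[:, :, keep],
            self.is_female.copy(),
            self.gmap.subset(keep),
            self.generation,
            None if self.parents is None else self.parents.copy(),
            parent,
        )


def make_founders(
    n_individuals: int,
    gmap: GeneticMap,
    seed,
    freq_low: float = 0.1,
    freq_high: float = 0.9,
) -> HaplotypePopulation:
    """Founder generation with independent per-site allele frequencies.

    Each locus gets an allele-1 frequency drawn from Uniform(freq_low,
    freq_high); founder alleles are then independent Bernoulli draws, so the
    founders start with segregating variation but no linkage disequilibrium
    (LD builds up over the breeding generations through drift).
    """
    if n_individuals % 2:
        raise SimulationError("n_individuals must be even (half female, half male)")
    rng = np.random.default_rng(seed)
    p = rng.uniform(freq_low, freq_high, gmap.n_loci)
    haps = (rng.random((n_individuals, 2, gmap.n_loci)) < p).astype(np.uint8)
    is_female = np.arange(n_individuals) < n_individuals // 2
    return HaplotypePopulation(haps, is_female, gmap, generation=0)


def _meiosis(rng, diplos, gmap, return_counts=False):
    """Transmit one gamete from each diplotype in ``diplos``.

    Crossovers per chromosome are Poisson with mean equal to the chromosome's
    Morgan length, placed uniformly (Haldane model, no interference).  Returns
    ``(gametes, counts)`` where ``counts`` (``n x n_chrom``) is the realized
    crossover tally when requested.
    """
    n = diplos.shape[0]
    off = gmap.chrom_offsets
    gametes = np.empty((n, gmap.n_loci), dtype=np.uint8)
    counts = np.zeros((n, gmap.n_chrom), dtype=np.int64) if return_counts else None
    for c, (_, length) in enumerate(gmap.chromosomes):
        pos = gmap.positions[c]
        m = len(pos)
        k = rng.poisson(length, n)
        total = int(k.sum())
        xpos = rng.random(total) * length
        gidx = np.repeat(np.arange(n), k)
        # crossovers falling before each locus, tallied per inter-locus gap
        gap = np.searchsorted(pos, xpos)
        per_gap = np.zeros((n, m + 1), dtype=np.int32)
        np.add.at(per_gap, (gidx, gap), 1)
        before = np.cumsum(per_gap, axis=1)[:, :m]
        start = rng.integers(0, 2, n)
        source = (start[:, None] + before) % 2
        block = diplos[:, :, off[c] : off[c + 1]]
        gametes[:, off[c] : off[c + 1]] = np.where(
            source == 0, block[:, 0, :], block[:, 1, :]
        )
        if return_counts:
            counts[:, c] = k
    return gametes, counts


def _mutate(rng, gametes, mutation_rate):
    """Flip alleles with per-site probability ``mutation_rate`` (recurrent)."""
    if mutation_rate <= 0:
        return
    total = gametes.size
    n_mut = rng.binomial(total, mutation_rate)
    if n_mut:
        flat = rng.integers(0, total, size=n_mut)
        gametes.reshape(-1)[flat] ^= 1


def _breed(rng, pop, sires, dams, pairing, mutation_rate):
    """Produce the next generation from per-offspring (sire, dam) pairs."""
    sire_idx = sires[pairing[:, 0]]
    dam_idx = dams[pairing[:, 1]]
    pat, _ = _meiosis(rng, pop.haplotypes[sire_idx], pop.gmap)
    mat, _ = _meiosis(rng, pop.haplotypes[dam_idx], pop.gmap)
    _mutate(rng, pat, mutation_rate)
    _mutate(rng, mat, mutation_rate)
    haps = np.stack([pat, mat], axis=1)
    n = haps.shape[0]
    is_female = np.arange(n) < n // 2
    parents = np.column_stack([sire_idx, dam_idx])
    return HaplotypePopulation(
        haps, is_female, pop.gmap, pop.generation + 1, parents, pop
    )


def simulate_historic_population(
    n_individuals: int,
    n_generations: int,
    mutation_rate: float,
    gmap: GeneticMap,
    seed,
) -> HaplotypePopulation:
    """Random-mating historic population of constant size.

    Each offspring draws its sire and dam uniformly at random from the males
    and females of the previous generation.  ``n_generations == 0`` returns
    the founders unchanged.
    """
    if mutation_rate < 0:
        raise SimulationError("mutation_rate must be >= 0")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_found, s_breed = ss.spawn(2)
    pop = make_founders(n_individuals, gmap, s_found)
    rng = np.random.default_rng(s_breed)
    for _ in range(n_generations):
        males, females = pop.males(), pop.females()
        if len(males) == 0 or len(females) == 0:
            raise SimulationError("both sexes required for breeding")
        pairing = np.column_stack(
            [
                rng.integers(0, len(males), n_individuals),
                rng.integers(0, len(females), n_individuals),
            ]
        )
        pop = _breed(rng, pop, males, females, pairing, mutation_rate)
        pop.parent_pop.parent_pop = None  # keep memory bounded
    return pop


def breed_reference_population(
    hp: HaplotypePopulation,
    n_generations: int = 50,
    selection_fraction: float = 0.5,
    seed=None,
    mutation_rate: float = 0.0,
) -> HaplotypePopulation:
    """Breed the reference population from the historic one.

    Per generation, ``selection_fraction`` of the males and of the females are
    selected at random as parents; matings are distinct random sire x dam
    pairs and each mating contributes two offspring (one male, one female),
    keeping the population size constant.  The returned population retains
    its pedigree link to the parental generation so trios can be sampled.
    """
    if not (0 < selection_fraction <= 1):
        raise SimulationError("selection_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    pop = hp
    n = pop.n
    n_matings = n // 2
    for _ in range(n_generations):
        males, females = pop.males(), pop.females()
        n_s = max(1, int(round(selection_fraction * len(males))))
        n_d = max(1, int(round(selection_fraction * len(females))))
        if len(males) == 0 or len(females) == 0:
            raise SimulationError("selected parent set is empty")
        sires = rng.choice(males, n_s, replace=False)
        dams = rng.choice(females, n_d, replace=False)
        # distinct (sire, dam) pairs whenever enough exist
        n_pairs = n_s * n_d
        if n_matings <= n_pairs:
            pair_ids = rng.choice(n_pairs, n_matings, replace=False)
        else:  # pragma: no cover - only for tiny toy populations
            pair_ids = rng.integers(0, n_pairs, n_matings)
        pairing = np.column_stack([pair_ids // n_d, pair_ids % n_d])
        pairing = np.repeat(pairing, 2, axis=0)  # two offspring per mating
        pop = _breed(rng, pop, sires, dams, pairing, mutation_rate)
        pop.parent_pop.parent_pop = None
    return pop


# ---------------------------------------------------------------------------
# Trio datasets
# ---------------------------------------------------------------------------


@dataclass
class PanelMask:
    """Which (offspring, locus) entries are unknown in a masked dataset."""

    mode: str  # "shared_panel" | "per_offspring_random"
    fraction: float
    masked: np.ndarray  # (n_offspring, n_loci) bool

    def masked_loci(self, offspring: int) -> np.ndarray:
        return np.flatnonzero(self.masked[offspring])


@dataclass
class TrioDataset:
    """Coded genotypes for a set of parent-offspring trios.

    Individuals are ordered sires, dams, offspring (``n = 3 * n_trios``).
    ``haplos`` is the working copy (float, NaN = unknown); ``truth`` is the
    pre-masking copy.  Alleles are 0 = major / 1 = minor after recoding.
    """

    ids: list
    trios: list  # (sire_id, dam_id, offspring_id)
    haplos: np.ndarray  # (n_ind, 2, n_loci) float32, NaN = unknown
    truth: np.ndarray  # (n_ind, 2, n_loci) uint8
    gmap: GeneticMap
    mask: Optional[PanelMask] = None
    density: Optional[str] = None
    sample_size: Optional[int] = None
    replicate: int = 0
    seed: Optional[int] = None
    label: Optional[str] = None
    version: Optional[str] = None

    @property
    def n_trios(self) -> int:
        return len(self.trios)

    @property
    def n_loci(self) -> int:
        return self.haplos.shape[2]

    @property
    def parent_slice(self) -> slice:
        return slice(0, 2 * self.n_trios)

    @property
    def offspring_slice(self) -> slice:
        return slice(2 * self.n_trios, 3 * self.n_trios)

    def genotypes(self, which: str = "coded") -> np.ndarray:
        """Genotype dosages (n_ind x n_loci); NaN where either allele unknown."""
        arr = self.haplos if which == "coded" else self.truth.astype(np.float32)
        return arr.sum(axis=1)

    def copy(self) -> "TrioDataset":
        return replace(
            self,
            ids=list(self.ids),
            trios=list(self.trios),
            haplos=self.haplos.copy(),
            truth=self.truth.copy(),
            mask=None
            if self.mask is None
            else PanelMask(self.mask.mode, self.mask.fraction, self.mask.masked.copy()),
        )


def sample_trios(pop: HaplotypePopulation, n_trios: int, seed) -> TrioDataset:
    """Sample ``n_trios`` distinct mated pairs and one offspring of each.

    Requires the population to carry pedigree links (``parents`` /
    ``parent_pop``).
    """
    if pop.parents is None or pop.parent_pop is None:
        raise SimulationError("population carries no pedigree links")
    rng = np.random.default_rng(seed)
    pairs, inverse = np.unique(pop.parents, axis=0, return_inverse=True)
    if len(pairs) < n_trios:
        raise SimulationError(
            f"only {len(pairs)} distinct mated pairs available, need {n_trios}"
        )
    chosen = rng.choice(len(pairs), n_trios, replace=False)
    offspring_idx = np.empty(n_trios, dtype=np.int64)
    for k, pair_id in enumerate(chosen):
        kids = np.flatnonzero(inverse == pair_id)
        offspring_idx[k] = rng.choice(kids)
    sire_idx = pairs[chosen, 0]
    dam_idx = pairs[chosen, 1]

    par = pop.parent_pop
    truth = np.concatenate(
        [
            par.haplotypes[sire_idx],
            par.haplotypes[dam_idx],
            pop.haplotypes[offspring_idx],
        ]
    ).astype(np.uint8)
    ids = (
        [f"S{k + 1}" for k in range(n_trios)]
        + [f"D{k + 1}" for k in range(n_trios)]
        + [f"O{k + 1}" for k in range(n_trios)]
    )
    trios = [(f"S{k + 1}", f"D{k + 1}", f"O{k + 1}") for k in range(n_trios)]
    return TrioDataset(
        ids=ids,
        trios=trios,
        haplos=truth.astype(np.float32),
        truth=truth,
        gmap=pop.gmap,
        sample_size=n_trios,
    )


def recode_major_minor(dataset: TrioDataset) -> TrioDataset:
    """Relabel alleles per locus so the more frequent allele is coded 0.

    Frequencies are computed over all sampled individuals.  An exact 0.5/0.5
    tie keeps the original labels; a monomorphic locus ends up all-0.
    """
    if np.isnan(dataset.haplos).any():
        raise SimulationError("recoding requires a dataset with no unknowns")
    ds = dataset.copy()
    freq1 = ds.truth.mean(axis=(0, 1))
    flip = freq1 > 0.5
    ds.truth[:, :, flip] = 1 - ds.truth[:, :, flip]
    ds.haplos = ds.truth.astype(np.float32)
    return ds


def apply_missingness(
    dataset: TrioDataset, fraction: float, mode: str = "shared_panel", seed=None
) -> TrioDataset:
    """Mask a fraction of each offspring's loci; parents are never masked.

    ``shared_panel`` keeps an evenly index-spaced subset of loci, identical
    across offspring (a true low-density panel); ``per_offspring_random``
    masks loci independently per offspring.
    """
    if not (0 < fraction < 1):
        raise SimulationError("fraction must be in (0, 1)")
    if mode not in ("shared_panel", "per_offspring_random"):
        raise SimulationError(f"unknown masking mode {mode!r}")
    ds = dataset.copy()
    n_off = ds.n_trios
    n = ds.n_loci
    n_masked = int(round(fraction * n))
    masked = np.zeros((n_off, n), dtype=bool)
    if mode == "shared_panel":
        n_keep = n - n_masked
        keep = np.floor(np.arange(n_keep) * n / n_keep).astype(np.int64)
        cols = np.ones(n, dtype=bool)
        cols[keep] = False
        masked[:, :] = cols
    else:
        rng = np.random.default_rng(seed)
        for i in range(n_off):
            masked[i, rng.choice(n, n_masked, replace=False)] = True
    off0 = 2 * ds.n_trios
    for i in range(n_off):
        ds.haplos[off0 + i, :, masked[i]] = np.nan
    ds.mask = PanelMask(mode, fraction, masked)
    return ds


# ---------------------------------------------------------------------------
# End-to-end dataset generation
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Study-design knobs for :func:`generate_dataset`.

    Defaults are the study conditions: five 1-Morgan chromosomes, 50 + 50
    breeding generations, mutation rate 2.5e-8 per site, 50% parental
    selection, a 400-animal historic population, evenly spaced shared panels,
    and 5 replicates.
    """

    density: str = "5k"  # "1k" | "5k" | "10k"
    n_trios: int = 100
    versions: Sequence[str] = ("NA10", "NA30", "NA50", "NA70", "NA90")
    replicates: int = 5
    seed: int = 0
    n_chrom: int = 5
    chrom_length: float = 1.0
    historic_size: int = 400
    historic_generations: int = 50
    reference_generations: int = 50
    selection_fraction: float = 0.5
    mutation_rate: float = 2.5e-8
    mask_mode: str = "shared_panel"
    maf_min: float = 0.05
    oversample: float = 1.3
    label: Optional[str] = None

    def snps_per_chrom(self) -> int:
        try:
            return SNPS_PER_CHROM[self.density]
        except KeyError:
            raise SimulationError(f"unknown density label {self.density!r}") from None

    def dataset_label(self) -> str:
        if self.label:
            return self.label
        return DATASET_LABELS.get((self.density, self.n_trios), "Gx")


def _select_panel_loci(pop, per_chrom: int, maf_min: float, rng) -> np.ndarray:
    """Pick ``per_chrom`` segregating loci per chromosome.

    Loci with minor-allele frequency >= ``maf_min`` in the final generation
    are eligible; the threshold halves iteratively if too few qualify.
    Selected loci are evenly spaced (by index) among the eligible ones.
    """
    freq = pop.haplotypes.mean(axis=(0, 1))
    maf = np.minimum(freq, 1 - freq)
    off = pop.gmap.chrom_offsets
    keep = []
    for c in range(pop.gmap.n_chrom):
        cmaf = maf[off[c] : off[c + 1]]
        thr = maf_min
        eligible = np.flatnonzero(cmaf >= thr)
        while len(eligible) < per_chrom and thr > 1e-9:
            thr /= 2
            eligible = np.flatnonzero(cmaf >= thr)
        if len(eligible) < per_chrom:
            eligible = np.flatnonzero(cmaf > 0)
        if len(eligible) < per_chrom:
            raise SimulationError(
                f"chromosome {c}: only {len(eligible)} segregating loci, "
                f"need {per_chrom}; increase oversample"
            )
        pick = np.floor(np.arange(per_chrom) * len(eligible) / per_chrom).astype(int)
        keep.append(eligible[pick] + off[c])
    return np.concatenate(keep)


def simulate_base_dataset(config: SimulationConfig, replicate: int = 0) -> TrioDataset:
    """One unmasked, recoded trio dataset for a given replicate index."""
    ss = np.random.SeedSequence(entropy=(config.seed, replicate))
    s_map, s_hist, s_ref, s_panel, s_trio, _ = ss.spawn(6)
    per_chrom = config.snps_per_chrom()
    n_sim = int(np.ceil(per_chrom * config.oversample))
    gmap = make_genetic_map(config.n_chrom, config.chrom_length, n_sim, s_map)
    pop_size = max(config.historic_size, 2 * config.n_trios)
    if pop_size % 2:
        pop_size += 1
    hist = simulate_historic_population(
        pop_size, config.historic_generations, config.mutation_rate, gmap, s_hist
    )
    ref = breed_reference_population(
        hist,
        config.reference_generations,
        config.selection_fraction,
        s_ref,
        config.mutation_rate,
    )
    keep = _select_panel_loci(
        ref, per_chrom, config.maf_min, np.random.default_rng(s_panel)
    )
    ref = ref.subset_loci(keep)
    ds = sample_trios(ref, config.n_trios, s_trio)
    ds = recode_major_minor(ds)
    ds.density = config.density
    ds.replicate = replicate
    ds.seed = config.seed
    ds.label = config.dataset_label()
    return ds


def generate_dataset(config: SimulationConfig) -> list:
    """All (version, replicate) masked datasets for one study cell.

    Returns a list of :class:`TrioDataset`, one per requested version and
    replicate, each carrying its label (G1-G4), version tag and replicate
    index.  Fully deterministic given ``config.seed``.
    """
    for v in config.versions:
        if v not in VERSION_FRACTIONS:
            raise SimulationError(f"unknown version {v!r}")
    out = []
    for rep in range(config.replicates):
        base = simulate_base_dataset(config, rep)
        for v in config.versions:
            mask_seed = np.random.SeedSequence(
                entropy=(config.seed, rep, int(100 * VERSION_FRACTIONS[v]))
            )
            masked = apply_missingness(
                base, VERSION_FRACTIONS[v], config.mask_mode, mask_seed
            )
            masked.version = v
            out.append(masked)
    return out
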