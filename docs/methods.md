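# Methods

## Problem and design

The package studies genotype imputation in parent-offspring trios: both
parents are genotyped on a dense SNP panel, the offspring on a low-density
(evenly spaced) subset, and the un-typed offspring genotypes are predicted
from nearby typed markers.  Everything is benchmarked on simulated data, so
the truth of every masked entry is known and the imputation accuracy — the
per-SNP Pearson correlation between imputed and true values over the masked
entries — can be measured exactly.

The three imputers are binary boosting classifiers (AdaBoost, LogitBoost,
TotalBoost) over decision-stump weak learners, trained *per un-typed locus*
on the parents only and applied to the offspring.  No pedigree transmission
logic, phasing HMM or haplotype-cluster model is involved: the methods learn
the local LD structure from the parental haplotypes and nothing else, which
is exactly what makes them an interesting baseline.

## Simulation model

`trioboost.simulate` is a forward-in-time locus-based simulator:

* **Genome.** Five chromosomes of 1 Morgan by default; SNP positions
  uniform on the genetic map.  The "5k" panel carries 1000 SNPs per
  chromosome, "10k" 2000, "1k" 200.  VCF emission maps 1 Morgan to 1e8 bp.
* **Founders.** A historic population (default 400 animals, half female)
  starts from independent per-site allele frequencies drawn Uniform(0.1,
  0.9).  Founders therefore segregate at every site but carry *no* linkage
  disequilibrium; all LD in the final data is built up by drift during the
  breeding phases.
* **Breeding.** 50 generations of random mating (historic phase), then 50
  generations in which 50% of each sex is selected at random as parents and
  matings are distinct random sire x dam pairs with two offspring each
  (reference phase), keeping population size constant.
* **Meiosis.** Crossover counts per chromosome are Poisson with mean equal
  to the Morgan length, positions uniform (Haldane, no interference);
  mutation is a recurrent allele flip at rate 2.5e-8 per site per
  transmission.  Transmission is implemented by tallying crossovers into
  inter-locus gaps, which is exact at the locus level and fully vectorized;
  the realized crossover counts are retained so the Poisson(1)-per-Morgan
  calibration can be tested directly.
* **Trios and coding.** Trios are distinct mated pairs of the final
  generation plus one of their offspring.  Alleles are recoded per locus so
  the major allele is 0 (exact 0.5 ties keep their labels); panel loci are
  chosen per chromosome among loci with MAF >= 0.05 (threshold halves if
  too few qualify), evenly spaced among the eligible.
* **Masking.** Versions NA10...NA90 hide 10-90% of each offspring's loci.
  Default mode `shared_panel` retains an evenly index-spaced locus subset
  identical across offspring (a true low-density panel); mode
  `per_offspring_random` masks independently per offspring.  Parents are
  never masked.  The realized fraction is within one locus of the nominal.

**What the generator does not emulate:** founder haplotype structure (real
livestock founders share long haplotypes, giving far more long-range LD
than drift alone builds in 100 generations at N = 400), genotyping error,
selection on phenotype, sex chromosomes, and mutation-drift equilibrium.
Consequently the *absolute* accuracies here are conservative: at NA90 the
typed-marker spacing (~0.01 Morgan on the 5k panel) carries equilibrium
r^2 of roughly 1/(1 + 4Nc) ~ 0.06 between neighbours, so no method can
approach the 0.92+ accuracies reported for simulations seeded with strongly
linked founder haplotypes.  Passing trend tests therefore show the methods'
*relative* behaviour (method ordering, density and missingness effects),
not field-realistic absolute accuracy.

## Window imputation

For an un-typed locus *i*, the window takes the nearest L/2 typed loci on
each side (locus-index distance, same chromosome); near a chromosome end the
deficit is compensated on the long side up to L features total.  Window
sizes default to the validation-selected values L = 10 for the 5k/10k panels
and L = 22 for 1k; `select_window_size` re-runs that selection by masking an
extra 5% of known offspring entries as a validation set.

Training rows are the parents' phased haplotypes (two rows per parent):
features are the window alleles, the label is the allele at the target
locus mapped minor -> +1, major -> -1.  Rows with an unknown target are
excluded from training but imputed like any other.  Offspring never enter a
training set.  One model is fit per target locus; offspring feature
unknowns at prediction time are filled with the parent-training major
value, keeping one model per locus in the per-offspring-random mode.
Monomorphic targets short-circuit to a constant prediction.  A genotype
(dosage) mode for unphased input classifies minor-allele carriage and minor
homozygosity separately and combines them to a 0/1/2 dosage.

## Boosting algorithms

All three fitters are deterministic (exhaustive stump search, no internal
randomness), use M = 100 stages by default, and share depth-1 weighted
decision trees (depth is configurable).  With 0/1 allele features the
exhaustive stump search reduces exactly to a handful of matrix-vector
products; this fast path is verified against brute-force enumeration.

* **AdaBoost** (discrete): stage coefficient a_m = 0.5 ln((1-e_m)/e_m) with
  weighted error e_m; weights w_i <- w_i exp(-a_m y_i h_m(x_i)),
  renormalized.  Error 0 gets a large capped coefficient (e = 1e-10) and
  stops; error >= 0.5 stops without adding the stage.  A `literal`
  weight-update variant (the sample weight inside the exponent) is kept
  behind a flag for comparison; it does not reduce to any standard scheme
  and is not used by the pipeline.
* **LogitBoost** (two-class): Newton steps on the binomial log-likelihood;
  working response z = (y* - P)/(P(1-P)) with y* in {0,1}, weights P(1-P),
  half of the fitted regression stump added to the additive score H, and
  P = exp(H)/(exp(H)+exp(-H)).  Numerical guards: P clamped to
  [1e-5, 1-1e-5], z to [-4, 4].  Stops when the fitted stump is identically
  zero.
* **TotalBoost** (totally corrective): after each stage the sample
  distribution is re-solved as the minimum-relative-entropy distribution
  (against uniform) whose edge on every past hypothesis is at most
  gamma_hat - nu, where gamma_hat is the running minimum of observed edges
  and nu = 0.05 by default.  Stage coefficients are the final projection's
  dual multipliers, renormalized.

### The entropy projection

The projection min KL(w || uniform) s.t. Uw <= cap is solved in the dual:
the optimum is w_i proportional to exp(-(lam U)_i) with lam >= 0 minimizing
the smooth convex function log mean exp(-(lam U)_i) + cap sum(lam).  We
minimize it with L-BFGS-B and polish any residual constraint violation with
exact one-dimensional exponential tilts (Brent root-finds), to a feasibility
tolerance of 1e-8.  A cyclic-projection (Hildreth/Bregman) solver was tried
first and failed to converge on near-degenerate constraint systems arising
at high missingness; the dual solve is both faster and verifiably correct
(it matches an SLSQP primal solve and a simplex grid search in the tests).
Infeasibility — the normal totally-corrective stopping signal — is detected
as a single unsatisfiable constraint or as diverging multipliers.

### TotalBoost termination in practice

With binary stump features the hypothesis pool is finite (at most a few
dozen distinct prediction vectors per window).  When the best response under
the re-solved weights duplicates an earlier hypothesis, the constraint set
— and hence the weight vector — can never change again, so training stops.
A near-perfect first hypothesis likewise collapses the edge polytope
immediately.  TB ensembles are therefore typically far smaller than M = 100
and TB tracks single-stump accuracy; this reproduces, and under weak-LD
simulation conditions exaggerates, the benchmark's finding that TB is the
least accurate of the three methods.

## Scoring and aggregation

Per-SNP accuracy is the Pearson correlation between imputed and true values
across the masked offspring entries of that locus, computed at the level the
imputation ran (allele level by default: two entries per masked offspring
genotype).  Loci where either vector is constant are skipped and counted
(Pearson r is undefined); a concordance rate is reported alongside.  Means
are taken per (dataset, version, method) across replicates, then across the
NA10...NA90 versions for the dataset-level accuracy.  Factor summaries
contrast these dataset means by panel density and trio count.  Wall-clock
per cell is logged for information only and excluded from the written CSVs
so identical seeds give byte-identical reports.

## Scaled benchmark

The acceptance benchmark (`trioboost.benchmark`) runs one chromosome at the
full per-chromosome densities (1000 and 2000 SNPs/Morgan), 100 trios, all
five versions and all three methods, with 5 replicates for the 5k run and 2
for the 10k density contrast — the quantities that drive LD (marker spacing)
and training-set size (trio count) are unscaled; only total genome length
and replicate count for the contrast arm are reduced.  Replicates use 5 as
the averaging count, with more available via configuration.

## Numerical choices and tie-breaks

* Stump search ties: lowest feature index, then lowest threshold; leaf
  labels are weighted majorities with ties to +1; a split must strictly
  improve on the constant learner.
* Ensemble score exactly zero: predicted label is the majority training
  label.
* Major/minor recoding ties (frequency exactly 0.5): original labels kept.
* Seeds: one master seed per study cell; per-replicate and per-stage
  substreams derived through `numpy.random.SeedSequence`.

## Known limitations

* Absolute accuracies depend strongly on founder LD, which is deliberately
  minimal here (see above); relative comparisons are the robust output.
* The per-offspring-random masking mode trades fidelity for compute by
  reusing one model per locus with major-value feature filling.
* The genotype-dosage mode does not infer phase; filled haplotype entries
  of heterozygous imputations carry an arbitrary phase.
* Runtime comparisons between methods are logged but hardware-dependent and
  not part of any assertion.
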