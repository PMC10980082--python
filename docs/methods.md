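# Methods

This note records the scientific model implemented by `mapnn`, the
parameter choices that matter, and the places where the design was
genuinely open. Nothing here reports an empirical number that the test
suite or `scripts/acceptance.py` does not itself compute.

## The demographic model

Individuals are hermaphroditic and live in continuous space on a square
habitat of side `w` map units, discretized for bookkeeping into `w x w`
unit pixels. Two rasters parameterize the landscape: carrying capacity `K`
(individuals per unit area) and effective dispersal `sigma` (map units per
generation). Values at an individual's location are bilinearly
interpolated from pixel centers; the coordinate convention everywhere is
origin at the lower-left, `grid[row, col]` with row indexing y, centers at
half-integer offsets.

Each non-overlapping cycle is reproduction → dispersal → mortality:

* **Mating.** A prospective mother chooses a mate among neighbors within
  `3 sigma_m` with probability proportional to `exp(-d^2 / (2 sigma_m^2))`.
  No neighbor in range means no offspring that cycle (and, because deaths
  are competition-driven, an isolated individual also never dies — sparse
  populations freeze rather than vanish; see *Viability*, below).
* **Fecundity.** Offspring counts per individual per cycle are
  Poisson(1/L) with `L = 4`, the rough mean lifetime at stationarity.
  Offspring are displaced from the mother by independent Gaussian(0,
  `sigma_f`) draws per axis; offspring landing off the habitat or on a
  masked pixel are discarded, not re-drawn.
* **Mortality.** Everyone (newborns included) survives with probability
  `p = 1 / (1 + eta / (K (1 + L)))`, where `eta` sums the competition
  kernel over neighbors within `3 sigma_c`.

**Competition-kernel normalization.** The kernel is the normalized 2-D
Gaussian density, peak `1/(2 pi sigma_c^2)`, times a configurable
`competition_scale` (default 1). The constant matters: with it, the
expected load at uniform density `rho` is approximately `rho`
(`1 - e^{-4.5}` of the mass survives the truncation), and the mean-field
equilibrium density tracks the `K` map — birth/death balance forces the
mean survival to `L/(1+L)`, hence `eta ≈ (1+L)K/L` and a census density
within a percent of `K`. An unnormalized kernel (peak 1) would
equilibrate near `0.16 K` and decouple the map from its intended
meaning. Around that baseline, two opposing spatial effects structure
the realized maps: low-dispersal habitats *accumulate* density near
borders (border individuals have truncated competition neighborhoods),
while high-dispersal habitats *lose* density there (offspring dispersing
off-habitat are discarded). `evaluate.realized_vs_input_bias` quantifies
the resulting input-vs-realized differences; at the package's desk scale
the dispersal channel agrees with its realized counterpart to within a
few percent, and realized density stays within a few percent of `K` —
closer than the roughly one-seventh overstatement reported for the
original large-scale implementation, whose source evidently lies in
simulator details beyond the published model description (the
acceptance suite reports this discrepancy rather than hiding it).

**Effective dispersal.** The estimand is effective sigma: the RMS
single-axis displacement from an offspring to a *random* parent. The
father sits a mating-kernel displacement away from the mother, so

    sigma^2 = 1/2 sigma_f^2 + 1/2 (sigma_f^2 + sigma_m^2).

The simulator holds `sigma_m = sigma_c = 1` fixed (benchmark setting) and
inverts this per mother location for `sigma_f`. With the benchmark
`sigma_f` range (0.2, 3.0) the implied prior endpoints are 0.73 and 3.08
to two decimals. Near a habitat mask, interpolated sigma can fall below
the invertibility bound `sigma_m / sqrt(2)`; the simulator clamps
`sigma_f` at a tiny positive value there, while the public
`sigma_f_from_target` raises instead.

**Realized-map recording.** After a spatial burn-in (250 generations in
benchmark settings) the recorder accumulates, per pixel: the
post-mortality head count each generation (time-averaged into realized
density), and for every birth the squared x- and y-displacements to both
parents, binned by the offspring's natal pixel (four single-axis events
per birth, RMS-ed into realized dispersal). Pixels with no events are
NaN-flagged and excluded from error metrics. Dispersal events are logged
at birth, before that cycle's mortality; density is the surviving
population.

**Genetic ancestry.** The forward simulation records every transmission
directly into tskit tables: two genome nodes per individual, gamete edges
with Poisson(`rate x length`) crossovers at uniform positions per genome
segment, and a uniformly chosen starting haplotype per segment (free
recombination between segments). For a sample, the tables are simplified
to the sampled genomes and the founder lineages are completed by an
msprime coalescent — constant `Ne` equal to the final spatial census by
default, or an explicit epoch list `(Ne, duration)` for multi-epoch
histories. Genotype matrices with a fixed SNP count `m` follow the
rate-doubling recipe: mutations at `mu = 1e-15`, doubling until at least
`m` infinite-sites binary mutations segregate, then a uniform
without-replacement subsample of exactly `m` sites, position-ordered, and
minor-allele (0/1/2) coding with ties at frequency 0.5 keeping the
derived allele.

**Neighbor search.** Both interaction kernels use unit cell lists
(expected linear cost); the competition kernel visits each pair once and
adds to both members. Results are contract-tested against brute-force
all-pairs references. The weighted mate draw uses single-pass weighted
reservoir sampling, chi-square-tested against the explicit Gaussian
weights.

## Map generation

Each channel independently: a polynomial boundary of degree uniform on
{0..3} (degree 0 → flat map with one log-uniform prior draw); anchor
points uniform on the landscape; the curve cuts the square into up to
degree+1 connected regions (4-connected labelling of the below/above
sets). Segmented maps draw a value range `r` uniform on the prior
interval — rejected until `p_max - r > p_min`, since the subsequent
log-uniform draw of the map minimum from `(p_min, p_max - r)` would
otherwise be empty — then assign the two extreme values to two random
regions and uniform intermediates to the rest, followed by a uniformly
chosen dihedral symmetry of the square. All values are therefore inside
the prior by construction.

**Viability correction.** For habitats where low `sigma` or `K` cannot
sustain a population, a pilot-simulation calibration fits
`log sigma_min = m log K + b` and maps are corrected by boosting a
randomly chosen channel to 1.25x the threshold. The calibration scans
dispersal with the natal, mating and interaction scales tied
(`sigma_f = sigma_m = sigma_c`), because with a fixed mating radius small
sigma never extinguishes anything. "Stable" requires both a minimum head
count and ongoing reproduction over the final quarter of the horizon
(at least 0.5 births per survivor), since frozen populations of isolated
immortal singles would otherwise count as alive.

## The network

Implemented in NumPy with hand-derived backpropagation (layers, Adam, and
the pair-gradient mask); gradients are verified against central finite
differences in the test suite, away from ReLU kinks where the derivative
is undefined. Weights are Glorot-uniform, biases zero.

Architecture defaults (the exact published layer sizes are not specified
in the available text; these are this package's choices, all exposed in
`NetworkConfig`): a conv stack of (Conv1D `k=7` → ReLU → average-pool)
blocks with filters growing 16→64 until the SNP axis is ≤16; a linear
dense layer to `F = 128` pair summaries; spatial branch `7 → F → F` dense
with ReLU output (scores are non-negative by construction); combine
`W: F x F` with ReLU and pair-wise pooling; head `F → 2F → 2` shared
across pixels. Several deliberate design choices, all empirically
motivated at desk scale:

* Pair rows are pooled by their *mean* rather than raw sum. This is the
  same function family (the 1/k factor is absorbable into the head's
  first layer) but keeps the head's input scale independent of `k_init`,
  so pair-subset sizes can differ between training and inference.
* Optional `global_pool` finishes the conv stack with a global average
  pool over the SNP axis, making pair summaries genome-wide means of
  local sharing detections — the form classical summary statistics
  take. This removes most of the extractor's memorization capacity,
  which is decisive when training sets are small (hundreds rather than
  tens of thousands of simulations): without it, desk-scale training
  memorizes example identities through the wide flatten layer and
  generalizes at chance.
* Weights are Glorot-uniform with zero biases, followed by a one-pass
  data-dependent scale calibration (in the spirit of layer-sequential
  unit-variance initialization): the G-producing layer, the spatial
  output layer, the combine layer and the head input layer are rescaled
  so each stage's activations have unit SD on a real example. Without
  this, the elementwise product `G ⊙ S` starts with SD ~1e-2, the
  combine units operate in a noise-dominated near-linear regime, and
  optimization stalls at predicting the target mean.

* The pair-summary layer is *linear*. With a ReLU there, `G ⊙ S` is
  non-negative everywhere and combine units whose weights turn negative
  can never re-activate — they die permanently. Signed summaries keep the
  combine stage trainable.
* Inputs are centered by default (`center_inputs`): genotypes to
  {-1, 0, 1} and coordinates rescaled by the map width. With raw
  non-negative inputs and zero biases, a large fraction of ReLU units is
  dead at initialization and desk-scale optimization stalls.
* The head is applied per pixel with shared weights, which is what keeps
  the parameter count independent of map width (a structural invariant
  asserted in the tests, along with independence from the pair count).

Pairs: `k_init` unordered pairs are drawn uniformly without replacement,
ordered within a pair by sample index; fresh subsets are drawn per example
per epoch (augmentation; a fixed-subset mode exists). During training the
extractor's gradients flow only through a random `k_extract`-subset per
step; the forward pass always uses all `k_init` pairs, and the excluded
pairs' extractor gradients are exactly zero (tested).

Training targets are log-transformed and per-channel standardized using
statistics of the *training* split only; the split is made at the
simulation level so augmented sample sets of one simulation never straddle
it. Loss is MSE over unmasked pixels, both channels weighted equally.
Schedule: Adam, batch 10 (gradient averaging), default lr 1e-4; lr halves
after 10 consecutive epochs without a strict validation improvement,
training stops after 100, and the best-validation weights are returned.
Halving and stopping counters are independent and both reset on
improvement.

## Evaluation and uncertainty

* MRAE: per channel, mean over included pixels of |pred - true| / true,
  computed on raw maps (any cosmetic smoothing happens after, in plotting
  only). Pixels without recorded events are excluded.
* Ensembles: the point estimate averages replicate predictions made with
  independently drawn pair subsets, pixel-wise in natural units.
* Parametric bootstrap: `parametric_bootstrap` is generic machinery over a
  `simulate_fn` / `estimate_fn` pair — B replicates, per-pixel empirical
  2.5%/97.5% quantiles, relative width `(q_hi - q_lo) / point` — and
  `bootstrap_pipeline` wires it to the package's simulator, sampler and a
  trained model. Failed replicates (extinctions) are skipped and counted,
  with a warning above 10%. Coverage is verified on a toy generative
  model with independent per-pixel multiplicative noise, where the
  binomial error band for nominal 95% coverage is actually valid; the
  full pipeline wrapper is exercised end-to-end at small scale.
* Helpers reproduce the worked planar arithmetic (total area = land area /
  land fraction; width = sqrt(total)) and epoch conversion
  (round-half-up of years / generation time).

## What the synthetic data does and does not emulate

The generator reproduces the benchmark study conditions: segmented maps
from log-uniform priors `K in (4, 40)`, `sigma in (0.73, 3.08)`,
`sigma_m = sigma_c = 1`, initial size = mean K x habitat area, genome of
1e8 bp at recombination rate 1e-8, uniform/grid/fixed sampling, and
fixed-SNP genotyping. It does not emulate: real geographies or GIS
projections, overlapping generations with age structure, selection,
sex-specific or biased dispersal, temporally varying demography during
the spatial phase, genotyping error or missing data. Passing tests
therefore demonstrate method correctness and recoverability *under the
model*, not robustness to the many ways real data deviate from it.

## Desk-scale problem sizes

All test-suite and acceptance computations run on one CPU in NumPy, so
the published full-scale experiment (50,000 training simulations, 5,000
SNPs, n = 100, 50 x 50 maps, GPU training) is out of reach by design.
The package's chosen desk-scale conditions are:

* **Simulator fidelity:** 20 heterogeneous maps at `w = 20`, benchmark
  priors, 400 generations with 250 burn-in. At this scale edge effects
  are stronger than at `w = 50`, which is why the fidelity checks carry a
  +-5 percentage-point band around the full-scale reference values.
* **Parameter recovery (toy benchmark):** flat maps at two well-separated
  levels per channel — `sigma in {0.8, 2.4}`, `K in {5, 25}` — on `w = 8`,
  60 spatial generations over a 1e7 bp genome, `n = 20` sampled
  uniformly, 500 SNPs; ~200 underlying simulations providing 240
  training examples via two sample sets each; a small network (`F = 16`,
  conv filters (8, 16, 32), pool 2, global average pooling,
  `k_init = 120`) trained with Adam at lr 3e-3 and the halving schedule.
  Held-out datasets are scored by whether the predicted map mean falls
  on the correct side of the log-midpoint between levels, and by MRAE.
* **Bootstrap calibration:** 40 repetitions of a B = 50 bootstrap on a
  10 x 10 toy generative model with 15% lognormal pixel noise.

## Known limitations

* Competition-driven mortality means isolated individuals are immortal;
  "extinction" is flagged when the population can no longer reproduce
  (fewer than two individuals), and viability calibration additionally
  requires ongoing reproduction.
* Multi-segment genomes recombine freely between segments in the forward
  recorder, but the coalescent completion uses a piecewise rate map
  without free assortment between segments; with the default
  single-segment genome the distinction is moot.
* Training with symmetrized pair ordering (`pair_symmetrize`) is
  inference-only; the backward pass supports the default index-ordered
  convention.
* The NumPy implementation is practical up to roughly the desk scales
  above; the architecture itself is framework-agnostic and scales on
  accelerators, but this package does not provide that path.
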