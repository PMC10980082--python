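"""End-to-end synthetic dataset generation for benchmarks and tests.

Two entry points:

* :func:`generate_benchmark_simulations` reproduces the benchmark study
  conditions - segmented maps drawn from the log-uniform priors K in
  (4, 40) and sigma in (0.73, 3.08), simulated forward in continuous space
  with realized-map recording - at a configurable scale.

* :func:`make_toy_flat_datasets` builds the desk-scale parameter-recovery
  benchmark: flat maps at one of two well-separated (sigma, K) levels on a
  small habitat, with genotypes for a uniform sample.  This is the
  stand-in used to verify that the network can recover dispersal and
  density levels end-to-end at laptop scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import sample_uniform, simulate_genotypes
from .maps import DemographicMap, K_PRIOR, SIGMA_PRIOR, generate_map
from .sim import SimParams, simulate
from .training import TrainingDataset


# toy parameter-recovery conditions: two well-separated levels per channel,
# both inside the benchmark priors
TOY_SIGMA_LEVELS = (0.8, 2.4)
TOY_K_LEVELS = (5.0, 25.0)
TOY_WIDTH = 8
TOY_N_SAMPLES = 20
TOY_N_SNPS = 500
TOY_GENERATIONS = 100  # spatial generations; deep ancestry is coalescent


def generate_benchmark_simulations(
    n_maps: int,
    width: int = 50,
    n_generations: int = 400,
    burn_in: int = 250,
    seed: int = 0,
    record_genealogy: bool = False,
    k_prior=K_PRIOR,
    sigma_prior=SIGMA_PRIOR,
):
    """Simulate ``n_maps`` random segmented maps under benchmark conditions.

    Returns the list of non-extinct :class:`~mapnn.sim.SimResult` objects
    (extinctions are skipped and replaced so the requested count is met,
    up to 3x attempts).
    """
    rng = np.random.default_rng(seed)
    params = SimParams(n_generations=n_generations, burn_in=burn_in)
    sims = []
    attempts = 0
    while len(sims) < n_maps and attempts < 3 * n_maps:
        attempts += 1
        dmap = generate_map(k_prior, sigma_prior, width, rng)
        sim = simulate(
            dmap, params, seed=int(rng.integers(2**31)),
            record_realized=True, record_genealogy=record_genealogy,
        )
        if not sim.extinct:
            sims.append(sim)
    if len(sims) < n_maps:
        raise RuntimeError("too many extinct simulations under the priors")
    return sims


def flat_map(width: int, K: float, sigma: float) -> DemographicMap:
    return DemographicMap(
        np.full((width, width), float(K)),
        np.full((width, width), float(sigma)),
        np.ones((width, width), dtype=bool),
    )


@dataclass
class ToyDataset:
    dataset: TrainingDataset
    sigma_level: float
    k_level: float


def make_toy_flat_datasets(
    n_datasets: int,
    seed: int = 0,
    width: int = TOY_WIDTH,
    n_samples: int = TOY_N_SAMPLES,
    n_snps: int = TOY_N_SNPS,
    n_generations: int = TOY_GENERATIONS,
    sigma_levels=TOY_SIGMA_LEVELS,
    k_levels=TOY_K_LEVELS,
    n_sample_sets: int = 1,
):
    """Flat-map datasets at two (sigma, K) levels for parameter recovery.

    Each underlying simulation draws one of the four level combinations
    uniformly, runs the spatial model with genealogy recording, and yields
    ``n_sample_sets`` datasets of ``n_samples`` uniformly sampled
    individuals with ``n_snps`` SNPs each (sample-set augmentation: the
    expensive forward simulation is reused; datasets from one simulation
    share a ``group`` id so validation splits stay leakage-free).
    Returns a list of :class:`ToyDataset` of length ``n_datasets``.
    """
    rng = np.random.default_rng(seed)
    # a 10 Mb genome keeps tree counts (and recapitation cost) modest while
    # still averaging over many quasi-independent marginal genealogies
    params = SimParams(
        n_generations=n_generations, burn_in=0, genome=((1e7, 1e-8),)
    )
    out = []
    group = 0
    guard = 0
    while len(out) < n_datasets:
        guard += 1
        if guard > 3 * n_datasets:
            raise RuntimeError("too many failed toy simulations")
        sig = float(sigma_levels[rng.integers(2)])
        K = float(k_levels[rng.integers(2)])
        dmap = flat_map(width, K, sig)
        sim = simulate(
            dmap, params, seed=int(rng.integers(2**31)),
            record_realized=False, record_genealogy=True,
        )
        if sim.extinct or sim.final_size < n_samples:
            continue
        for _ in range(n_sample_sets):
            if len(out) >= n_datasets:
                break
            ss = sample_uniform(sim, n_samples, rng)
            gm = simulate_genotypes(sim, ss, n_snps, int(rng.integers(2**31)))
            ds = TrainingDataset(
                genotypes=gm.values,
                locations=ss.locations,
                target=dmap.channels(),
                group=group,
            )
            out.append(ToyDataset(dataset=ds, sigma_level=sig, k_level=K))
        group += 1
    return out
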