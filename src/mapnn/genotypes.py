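"""Sampling individuals and producing fixed-size SNP genotype matrices.

Three sampling schemes are supported: uniform over living individuals, a
fixed number per cell of a regular spatial grid, and nearest-individual
matching to arbitrary target coordinates (with radius doubling), which
mirrors an empirical sampling design.

Genotypes are produced by completing the recorded forward-time pedigree
with a neutral coalescent on the founders (constant Ne or a multi-epoch
history), then dropping neutral mutations along the genealogy of the
sampled individuals.  Rather than fixing a mutation rate, a fixed number of
polymorphic sites m is targeted: mutations are first added at the tiny rate
mu = 1e-15, and mu is iteratively doubled until at least m segregating
sites are found, at which point exactly m sites are uniformly subsampled
(without replacement, order preserved by genomic position).  Matrices are
coded as minor-allele counts in {0, 1, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass

import msprime
import numpy as np

from .sim import SimResult


__all__ = [
    "SampleSet",
    "GenotypeMatrix",
    "sample_uniform",
    "sample_grid",
    "sample_fixed",
    "recapitate",
    "place_mutations",
    "minor_allele_code",
]

MU_INITIAL = 1e-15
MAX_DOUBLINGS = 64


@dataclass
class SampleSet:
    """Indices (into a simulation's final population) plus locations."""

    indices: np.ndarray
    locations: np.ndarray  # (n, 2) planar coordinates
    scheme: str

    @property
    def n(self) -> int:
        return int(self.indices.size)


@dataclass
class GenotypeMatrix:
    """n x m minor-allele counts with site positions.

    Every column is polymorphic with minor-allele frequency <= 0.5.  In
    phased mode ``haplotypes`` holds the (2n, m) 0/1 matrix the counts were
    summed from.
    """

    values: np.ndarray
    positions: np.ndarray
    haplotypes: np.ndarray | None = None

    @property
    def n_snps(self) -> int:
        return int(self.values.shape[1])


# ---------------------------------------------------------------------------
# sampling schemes


def sample_uniform(sim: SimResult, n: int, rng) -> SampleSet:
    """n distinct individuals uniformly at random from the final population."""
    rng = np.random.default_rng(rng)
    if sim.final_size < n:
        raise ValueError(f"population of {sim.final_size} cannot supply {n} samples")
    idx = rng.choice(sim.final_size, size=n, replace=False)
    return SampleSet(idx, sim.locations[idx], "uniform")


def sample_grid(sim: SimResult, per_cell: int, grid_dim: int, rng) -> SampleSet:
    """per_cell individuals uniformly from each cell of a grid over the map.

    Raises (naming the cell) when any cell holds fewer than ``per_cell``
    individuals, as near-uniform spatial sampling is then impossible.
    """
    rng = np.random.default_rng(rng)
    W = float(sim.dmap.width)
    cell = W / grid_dim
    cx = np.clip((sim.x / cell).astype(int), 0, grid_dim - 1)
    cy = np.clip((sim.y / cell).astype(int), 0, grid_dim - 1)
    chosen = []
    for gy in range(grid_dim):
        for gx in range(grid_dim):
            pool = np.flatnonzero((cx == gx) & (cy == gy))
            if pool.size < per_cell:
                raise ValueError(
                    f"grid cell ({gx}, {gy}) holds {pool.size} < {per_cell} individuals"
                )
            chosen.append(rng.choice(pool, size=per_cell, replace=False))
    idx = np.concatenate(chosen)
    return SampleSet(idx, sim.locations[idx], "grid")


def sample_fixed(sim: SimResult, coords, rng, initial_radius_frac: float = 0.02) -> SampleSet:
    """One individual near each target coordinate, radius doubling on misses.

    For each target, a random not-yet-sampled individual within radius
    ``initial_radius_frac * map width`` is taken; an empty radius is doubled
    until an individual is found.  No individual serves two targets.
    """
    rng = np.random.default_rng(rng)
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] > sim.final_size:
        raise ValueError(
            f"{coords.shape[0]} targets exceed population of {sim.final_size}"
        )
    available = np.ones(sim.final_size, dtype=bool)
    pos = sim.locations
    chosen = []
    for tx, ty in coords:
        radius = initial_radius_frac * sim.dmap.width
        d2 = (pos[:, 0] - tx) ** 2 + (pos[:, 1] - ty) ** 2
        while True:
            pool = np.flatnonzero(available & (d2 <= radius**2))
            if pool.size:
                pick = int(rng.choice(pool))
                chosen.append(pick)
                available[pick] = False
                break
            radius *= 2.0
    idx = np.asarray(chosen)
    return SampleSet(idx, pos[idx], "fixed")


# ---------------------------------------------------------------------------
# genealogy completion and mutation placement


def _demography(params, fallback_ne: float) -> msprime.Demography:
    demog = msprime.Demography()
    epochs = params.epochs
    if not epochs:
        epochs = ((fallback_ne, None),)
    # the name must match the (metadata-free) population of the forward tables
    demog.add_population(name="pop_0", initial_size=max(float(epochs[0][0]), 1.0))
    # epoch boundaries are measured backwards from the founder generation,
    # which sits at tskit time = generations simulated spatially
    t = 0.0
    for (ne, duration), (next_ne, _) in zip(epochs[:-1], epochs[1:]):
        t += float(duration)
        demog.add_population_parameters_change(
            time=t, initial_size=max(float(next_ne), 1.0), population="pop_0"
        )
    return demog


def recapitate(sim: SimResult, sample_set: SampleSet, seed: int):
    """Genealogy of a sample, completed with the pre-spatial coalescent.

    Simplifies the recorded forward tables down to the sampled individuals'
    genomes and extends the founder lineages backwards under the configured
    demographic epochs (default: constant Ne equal to the final census).
    Returns a tree sequence whose samples are the 2n sampled genomes, in
    sample order.
    """
    if sim.tables is None:
        raise ValueError("simulation was run without genealogy recording")
    sample_nodes = sim.nodes[sample_set.indices].reshape(-1).astype(np.int32)
    tables = sim.tables.copy()
    tables.simplify(samples=sample_nodes, keep_input_roots=True)
    ts = tables.tree_sequence()
    demog = _demography(sim.params, fallback_ne=sim.final_size)
    # shift epoch-change times so they are measured from the founders
    founder_time = float(sim.n_generations_run)
    for event in demog.events:
        event.time += founder_time
    rates = [seg[1] for seg in sim.params.genome]
    breaks = np.cumsum([0.0] + [seg[0] for seg in sim.params.genome])
    rate_map = msprime.RateMap(position=breaks, rate=rates)
    return msprime.sim_ancestry(
        initial_state=ts,
        demography=demog,
        recombination_rate=rate_map,
        random_seed=max(1, seed % (2**31)),
    )


def place_mutations(
    ts,
    n_snps: int,
    rng,
    phased: bool = False,
) -> GenotypeMatrix:
    """Drop neutral mutations until >= m segregating sites, keep exactly m.

    Implements the fixed-SNP procedure: start at mu = 1e-15 and double until
    the target is crossed, then subsample m sites uniformly without
    replacement.  Infinite-sites binary mutations guarantee biallelic sites.
    """
    rng = np.random.default_rng(rng)
    if ts.num_samples == 0:
        raise ValueError("tree sequence has no samples")
    total_length = sum(t.total_branch_length * t.span for t in ts.trees())
    if total_length <= 0:
        raise ValueError("total tree length is zero; no branches to mutate")
    mu = MU_INITIAL
    mts = None
    for _ in range(MAX_DOUBLINGS):
        mts = msprime.sim_mutations(
            ts,
            rate=mu,
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
            random_seed=int(rng.integers(1, 2**31)),
        )
        if mts.num_sites >= n_snps:
            break
        mu *= 2.0
    else:
        raise RuntimeError(
            f"could not reach {n_snps} segregating sites after "
            f"{MAX_DOUBLINGS} rate doublings"
        )
    sites = np.sort(rng.choice(mts.num_sites, size=n_snps, replace=False))
    H = mts.genotype_matrix()[sites, :]  # (m, 2n) haplotypes
    positions = mts.tables.sites.position[sites]
    haplotypes = H.T.astype(np.int8)  # (2n, m)
    diploid = haplotypes.reshape(-1, 2, n_snps).sum(axis=1)
    coded = minor_allele_code(diploid)
    return GenotypeMatrix(
        values=coded.values,
        positions=positions,
        haplotypes=haplotypes if phased else None,
    )


def minor_allele_code(raw: np.ndarray, positions=None) -> GenotypeMatrix:
    """Recode a 0/1/2 genotype matrix so each column counts the minor allele.

    Columns with alternate-allele frequency above 0.5 are flipped
    (g -> 2 - g); an exact tie keeps the derived (alternate) allele.
    Monomorphic or non-biallelic columns are rejected.
    """
    raw = np.asarray(raw)
    if raw.ndim != 2:
        raise ValueError("genotype matrix must be 2-D")
    if np.any((raw < 0) | (raw > 2)):
        raise ValueError("genotypes must be biallelic counts in {0, 1, 2}")
    n = raw.shape[0]
    freq = raw.sum(axis=0) / (2.0 * n)
    if np.any(freq == 0) or np.any(freq == 1):
        bad = np.flatnonzero((freq == 0) | (freq == 1))
        raise ValueError(f"monomorphic column(s): {bad.tolist()[:10]}")
    flip = freq > 0.5  # tie (0.5) keeps the derived allele
    values = np.where(flip[None, :], 2 - raw, raw).astype(np.int8)
    if positions is None:
        positions = np.arange(raw.shape[1], dtype=float)
    return GenotypeMatrix(values=values, positions=np.asarray(positions, dtype=float))


def simulate_genotypes(
    sim: SimResult, sample_set: SampleSet, n_snps: int, seed: int, phased: bool = False
) -> GenotypeMatrix:
    """Convenience: recapitate a sample's genealogy and place mutations."""
    rng = np.random.default_rng(seed)
    ts = recapitate(sim, sample_set, seed=int(rng.integers(1, 2**31)))
    return place_mutations(ts, n_snps, rng, phased=phased)
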