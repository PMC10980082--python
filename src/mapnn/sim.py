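"""Forward-time, continuous-space, individual-based simulator.

Each life cycle consists of reproduction, dispersal, and mortality.
Individuals are hermaphroditic and live on a square habitat of side ``w``
(map units, one pixel per unit).  Mates are chosen with probability
proportional to a Gaussian density of SD ``sigma_m`` about the focal
individual, truncated at ``3 sigma_m``.  Each individual with a mate
produces a Poisson(1/L) number of offspring, where L is the rough average
lifetime at stationarity; offspring are displaced from the mother by
independent Gaussian(0, sigma_f) draws in x and y and are discarded (not
re-drawn) if they land outside the habitat or on a masked pixel.  Mortality
is competition-based: individual i survives with probability

    p_i = 1 / (1 + eta_i / (K_i (1 + L)))

where K_i is the carrying-capacity map bilinearly interpolated at the
individual's location and eta_i is the summed Gaussian competition kernel
(SD ``sigma_c``, truncated at 3 sigma_c) over neighbors.  The kernel is the
normalized 2-D Gaussian density (peak ``1/(2 pi sigma_c^2)``), so that at
uniform density rho the expected load is approximately rho and equilibrium
density tracks the K map; the multiplicative constant is exposed as
``competition_scale`` because it directly shifts equilibrium density
relative to K.

The per-pixel dispersal map encodes *effective* sigma: the root-mean-square
single-axis displacement from an offspring to a random parent.  Because the
father is displaced from the mother by the mating kernel, effective sigma
decomposes as ``sigma^2 = sigma_f^2/2 + (sigma_f^2 + sigma_m^2)/2``; the
simulator inverts this per mother location to find the sigma_f that yields
the intended local sigma.

Genetic ancestry is recorded (optionally) directly into tskit tables:
every offspring gets two genome nodes and the maternal/paternal gametes are
laid down as edges with Poisson-recombination breakpoints.  The pre-spatial
phase (deep ancestry of the founders) is completed later by a neutral
coalescent with the configured epochs; see :mod:`mapnn.genotypes`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tskit

from ._neighbors import competition, mate_choice
from .maps import DemographicMap


__all__ = [
    "SimParams",
    "RealizedMaps",
    "SimResult",
    "simulate",
    "effective_sigma",
    "sigma_f_from_target",
    "choose_mate",
    "competition_load",
    "survival_probability",
    "interpolate_map",
    "initial_population_size",
]


@dataclass(frozen=True)
class SimParams:
    """Life-cycle and genome parameters of the spatial simulation."""

    sigma_m: float = 1.0  # mate-choice kernel SD, map units
    sigma_c: float = 1.0  # competition kernel SD, map units
    L: float = 4.0  # rough mean lifetime at stationarity, generations
    n_generations: int = 400
    burn_in: int = 250  # generations excluded from realized-map recording
    competition_scale: float = 1.0  # multiplies the normalized kernel peak
    # genome: tuple of (segment length in bp, recombination rate /bp/gen)
    genome: tuple = ((1e8, 1e-8),)
    # pre-spatial demography: tuple of (Ne, duration) going backwards from
    # the founders; duration None = final epoch.  None -> constant Ne equal
    # to the final spatial census size.
    epochs: tuple | None = None

    def __post_init__(self):
        if self.sigma_m <= 0 or self.sigma_c <= 0 or self.L <= 0:
            raise ValueError("sigma_m, sigma_c and L must be positive")
        if not (0 <= self.burn_in < self.n_generations):
            raise ValueError("need 0 <= burn_in < n_generations")

    @property
    def sequence_length(self) -> float:
        return float(sum(seg[0] for seg in self.genome))


@dataclass
class RealizedMaps:
    """Per-pixel density and dispersal realized during the simulation.

    ``density`` is the post-burn-in time average of per-pixel head counts
    divided by pixel area (=1 map unit^2).  ``dispersal`` is the RMS
    single-axis offspring-to-random-parent displacement, with both parents'
    displacements contributing, binned by the offspring's natal pixel; NaN
    where no event was recorded.
    """

    density: np.ndarray
    dispersal: np.ndarray
    n_events: np.ndarray


@dataclass
class SimResult:
    """Final state of a simulation plus optional recordings."""

    x: np.ndarray
    y: np.ndarray
    extinct: bool
    n_generations_run: int
    census: np.ndarray  # post-mortality population size per generation
    births: np.ndarray  # retained offspring per generation
    params: SimParams
    dmap: DemographicMap
    seed: int
    realized: RealizedMaps | None = None
    tables: tskit.TableCollection | None = None
    # genome node ids (2 per individual) of the final population, aligned
    # with x/y; only present when genealogy was recorded
    nodes: np.ndarray | None = None

    @property
    def final_size(self) -> int:
        return int(self.x.size)

    @property
    def locations(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


# ---------------------------------------------------------------------------
# small closed-form operations


def effective_sigma(sigma_f: float, sigma_m: float) -> float:
    """Effective dispersal from its components:
    sigma^2 = sigma_f^2/2 + (sigma_f^2 + sigma_m^2)/2."""
    return float(np.sqrt(0.5 * sigma_f**2 + 0.5 * (sigma_f**2 + sigma_m**2)))


def sigma_f_from_target(sigma_target, sigma_m):
    """Invert the effective-sigma composition for the natal kernel SD.

    Solves sigma_target^2 = sigma_f^2 + sigma_m^2/2 for sigma_f; raises if
    the target is too small relative to the mating kernel (no real root).
    """
    sigma_target = np.asarray(sigma_target, dtype=float)
    val = sigma_target**2 - 0.5 * sigma_m**2
    if np.any(val <= 0):
        raise ValueError(
            f"sigma_target={sigma_target} unreachable with sigma_m={sigma_m}: "
            "requires sigma_target^2 > sigma_m^2 / 2"
        )
    return np.sqrt(val) if sigma_target.ndim else float(np.sqrt(val))


def survival_probability(eta, K_local, L: float = 4.0):
    """p = 1 / (1 + eta / (K_local (1 + L)))."""
    eta = np.asarray(eta, dtype=float)
    K_local = np.asarray(K_local, dtype=float)
    if np.any(K_local <= 0):
        raise ValueError("K_local must be positive")
    p = 1.0 / (1.0 + eta / (K_local * (1.0 + L)))
    return p if p.ndim else float(p)


def competition_load(
    focal_xy, neighbors_xy, sigma_c: float = 1.0, competition_scale: float = 1.0
) -> float:
    """Summed Gaussian competition kernel over neighbors within 3 sigma_c.

    Kernel peak is ``competition_scale / (2 pi sigma_c^2)``; the focal
    individual itself is not among ``neighbors_xy``.
    """
    neighbors_xy = np.atleast_2d(np.asarray(neighbors_xy, dtype=float))
    if neighbors_xy.size == 0:
        return 0.0
    d2 = np.sum((neighbors_xy - np.asarray(focal_xy, dtype=float)) ** 2, axis=1)
    peak = competition_scale / (2 * np.pi * sigma_c**2)
    w = peak * np.exp(-d2 / (2 * sigma_c**2))
    w[d2 > 9 * sigma_c**2] = 0.0
    return float(w.sum())


def choose_mate(focal_xy, neighbors_xy, sigma_m, rng, size=None):
    """Sample a mate index with Gaussian-density weights, cutoff 3 sigma_m.

    Returns None (or an array of -1) when no neighbor is within range.
    With ``size`` set, returns that many independent draws (for Monte-Carlo
    checks of the weighting).
    """
    rng = np.random.default_rng(rng)
    neighbors_xy = np.atleast_2d(np.asarray(neighbors_xy, dtype=float))
    d2 = np.sum((neighbors_xy - np.asarray(focal_xy, dtype=float)) ** 2, axis=1)
    in_range = d2 <= 9 * sigma_m**2
    if not in_range.any():
        return None if size is None else np.full(size, -1)
    w = np.where(in_range, np.exp(-d2 / (2 * sigma_m**2)), 0.0)
    p = w / w.sum()
    idx = rng.choice(neighbors_xy.shape[0], size=size, p=p)
    return idx


def interpolate_map(grid: np.ndarray, x, y, width: float | None = None):
    """Bilinear interpolation of a pixel-center grid at map coordinates.

    Grid values sit at pixel centers (col + 0.5, row + 0.5); queries beyond
    the outermost centers clamp to the edge value.  Raises if a location is
    outside the map square.
    """
    grid = np.asarray(grid, dtype=float)
    w = grid.shape[0] if width is None else width
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < 0) or np.any(x > w) or np.any(y < 0) or np.any(y > w):
        raise ValueError("location outside the map")
    return _bilinear(grid, x, y)


def _bilinear(grid: np.ndarray, x, y):
    n = grid.shape[0]
    gx = np.clip(np.asarray(x, dtype=float) - 0.5, 0.0, n - 1.0)
    gy = np.clip(np.asarray(y, dtype=float) - 0.5, 0.0, n - 1.0)
    x0 = np.clip(np.floor(gx).astype(np.int64), 0, n - 2) if n > 1 else np.zeros_like(gx, int)
    y0 = np.clip(np.floor(gy).astype(np.int64), 0, n - 2) if n > 1 else np.zeros_like(gy, int)
    if n == 1:
        return np.broadcast_to(grid[0, 0], gx.shape).copy()
    fx = gx - x0
    fy = gy - y0
    g00 = grid[y0, x0]
    g01 = grid[y0, x0 + 1]
    g10 = grid[y0 + 1, x0]
    g11 = grid[y0 + 1, x0 + 1]
    return (
        g00 * (1 - fx) * (1 - fy)
        + g01 * fx * (1 - fy)
        + g10 * (1 - fx) * fy
        + g11 * fx * fy
    )


def initial_population_size(dmap: DemographicMap) -> int:
    """Mean carrying capacity over the habitat times the habitat area."""
    return int(round(float(dmap.K[dmap.mask].mean()) * int(dmap.mask.sum())))


# ---------------------------------------------------------------------------
# forward simulation


class _GenealogyRecorder:
    """Accumulates nodes/edges in forward time, finalized as tskit tables."""

    def __init__(self, sequence_length: float, genome: tuple):
        self.sequence_length = sequence_length
        starts = np.cumsum([0.0] + [seg[0] for seg in genome])
        self.seg_start = starts[:-1]
        self.seg_end = starts[1:]
        self.seg_lambda = np.array([seg[0] * seg[1] for seg in genome])
        self.birth_gen: list[np.ndarray] = []
        self.edges_l: list[np.ndarray] = []
        self.edges_r: list[np.ndarray] = []
        self.edges_p: list[np.ndarray] = []
        self.edges_c: list[np.ndarray] = []
        self.n_nodes = 0

    def add_nodes(self, count: int, gen: int) -> np.ndarray:
        """Register ``count`` new genome nodes born at forward time ``gen``."""
        ids = np.arange(self.n_nodes, self.n_nodes + count, dtype=np.int64)
        self.n_nodes += count
        self.birth_gen.append(np.full(count, gen, dtype=np.int64))
        return ids

    def add_gametes(self, parent_nodes: np.ndarray, child_nodes: np.ndarray, rng):
        """Record transmissions: one gamete per row of ``parent_nodes``.

        ``parent_nodes`` is (G, 2): the parent's two genome node ids.
        Breakpoint counts are Poisson(rate * length) per genome segment with
        uniform positions; the starting haplotype of each segment is chosen
        uniformly (free recombination between segments).
        """
        G = parent_nodes.shape[0]
        if G == 0:
            return
        S = self.seg_lambda.size
        counts = rng.poisson(self.seg_lambda, size=(G, S))  # runs = G*S
        counts_flat = counts.reshape(-1)
        run_gamete = np.repeat(np.arange(G), S)
        run_seg = np.tile(np.arange(S), G)
        n_bp = int(counts_flat.sum())
        seg_len = self.seg_end - self.seg_start
        bp = rng.uniform(0, 1, size=n_bp)
        run_of_bp = np.repeat(np.arange(G * S), counts_flat)
        bp = self.seg_start[run_seg[run_of_bp]] + bp * seg_len[run_seg[run_of_bp]]
        # sort breakpoints within runs: stable sort on (run, position)
        order = np.lexsort((bp, run_of_bp))
        bp = bp[order]
        bp_offset = np.concatenate([[0], np.cumsum(counts_flat)])

        n_edges_per_run = counts_flat + 1
        starts = np.concatenate([[0], np.cumsum(n_edges_per_run)])
        total = int(starts[-1])
        edge_run = np.repeat(np.arange(G * S), n_edges_per_run)
        within = np.arange(total) - starts[edge_run]
        bp_pad = np.concatenate([bp, [0.0]])  # dummy slot for unused lookups
        left = np.where(
            within == 0,
            self.seg_start[run_seg[edge_run]],
            bp_pad[np.clip(bp_offset[edge_run] + within - 1, 0, n_bp)],
        )
        right = np.where(
            within == counts_flat[edge_run],
            self.seg_end[run_seg[edge_run]],
            bp_pad[np.clip(bp_offset[edge_run] + within, 0, n_bp)],
        )
        start_hap = rng.integers(0, 2, size=G * S)
        hap = (start_hap[edge_run] + within) % 2
        parent = parent_nodes[run_gamete[edge_run], hap]
        child = child_nodes[run_gamete[edge_run]]
        keep = right > left  # zero-length pieces from coincident breakpoints
        self.edges_l.append(left[keep])
        self.edges_r.append(right[keep])
        self.edges_p.append(parent[keep])
        self.edges_c.append(child[keep])

    def finalize(self, final_gen: int, sample_nodes: np.ndarray) -> tskit.TableCollection:
        tables = tskit.TableCollection(sequence_length=self.sequence_length)
        tables.time_units = "generations"
        tables.populations.add_row(metadata=b"")
        birth = np.concatenate(self.birth_gen) if self.birth_gen else np.empty(0, int)
        times = (final_gen - birth).astype(np.float64)
        flags = np.zeros(self.n_nodes, dtype=np.uint32)
        flags[sample_nodes] = tskit.NODE_IS_SAMPLE
        tables.nodes.set_columns(
            flags=flags,
            time=times,
            population=np.zeros(self.n_nodes, dtype=np.int32),
        )
        if self.edges_l:
            left = np.concatenate(self.edges_l)
            right = np.concatenate(self.edges_r)
            parent = np.concatenate(self.edges_p).astype(np.int32)
            child = np.concatenate(self.edges_c).astype(np.int32)
            tables.edges.set_columns(left=left, right=right, parent=parent, child=child)
        tables.sort()
        return tables


def _pixels(x, y, w):
    px = np.clip(np.floor(x).astype(np.int64), 0, w - 1)
    py = np.clip(np.floor(y).astype(np.int64), 0, w - 1)
    return px, py


def simulate(
    dmap: DemographicMap,
    params: SimParams,
    seed: int,
    record_realized: bool = True,
    record_genealogy: bool = False,
    init_size: int | None = None,
) -> SimResult:
    """Run the forward spatial simulation on a demographic map.

    Pure function of (dmap, params, seed).  Extinction (population below 2)
    halts the run gracefully with ``extinct=True`` so that batch dataset
    generation can skip failed draws.
    """
    rng = np.random.default_rng(seed)
    w = dmap.width
    W = float(w)
    mask = dmap.mask
    if record_realized and params.n_generations <= params.burn_in:
        raise ValueError("no generations after burn-in to record")

    # initial placement: uniform over unmasked pixels
    n0 = init_size if init_size is not None else initial_population_size(dmap)
    xs, ys = [], []
    need = n0
    while need > 0:
        cx = rng.uniform(0, W, size=2 * need + 16)
        cy = rng.uniform(0, W, size=cx.size)
        px, py = _pixels(cx, cy, w)
        ok = mask[py, px]
        xs.append(cx[ok][:need])
        ys.append(cy[ok][:need])
        need = n0 - sum(a.size for a in xs)
    x = np.concatenate(xs)
    y = np.concatenate(ys)

    recorder = None
    nodes = None
    if record_genealogy:
        recorder = _GenealogyRecorder(params.sequence_length, params.genome)
        founder_nodes = recorder.add_nodes(2 * n0, 0)
        nodes = founder_nodes.reshape(n0, 2)

    half_sm2 = 0.5 * params.sigma_m**2
    eta_peak = params.competition_scale / (2 * np.pi * params.sigma_c**2)
    fecundity = 1.0 / params.L

    density_acc = np.zeros((w, w))
    disp_sq = np.zeros((w, w))
    disp_n = np.zeros((w, w), dtype=np.int64)
    census = np.zeros(params.n_generations, dtype=np.int64)
    births = np.zeros(params.n_generations, dtype=np.int64)
    extinct = False
    gens_run = 0

    for gen in range(1, params.n_generations + 1):
        n = x.size
        if n < 2:
            extinct = True
            break
        gens_run = gen
        recording = record_realized and gen > params.burn_in

        # --- reproduction -------------------------------------------------
        # offspring counts are drawn first so the mate search runs only for
        # prospective mothers; the joint law (counts, mates) is unchanged
        n_off_all = rng.poisson(fecundity, size=n)
        prospective = np.flatnonzero(n_off_all > 0)
        mate_of = mate_choice(
            x, y, prospective, W, params.sigma_m, int(rng.integers(2**31))
        )
        found = mate_of >= 0  # no neighbor within 3 sigma_m -> no offspring
        mothers = prospective[found]
        mom = np.repeat(mothers, n_off_all[mothers])
        dad = np.repeat(mate_of[found], n_off_all[mothers])

        sigma_loc = _bilinear(dmap.sigma, x[mom], y[mom])
        sigma_f = np.sqrt(np.maximum(sigma_loc**2 - half_sm2, 1e-12))
        ox = x[mom] + rng.normal(0.0, 1.0, size=mom.size) * sigma_f
        oy = y[mom] + rng.normal(0.0, 1.0, size=mom.size) * sigma_f
        inside = (ox >= 0) & (ox <= W) & (oy >= 0) & (oy <= W)
        opx, opy = _pixels(ox, oy, w)
        keep = inside & mask[opy, opx]
        mom, dad = mom[keep], dad[keep]
        ox, oy, opx, opy = ox[keep], oy[keep], opx[keep], opy[keep]

        if recording and mom.size:
            sq = (ox - x[mom]) ** 2 + (oy - y[mom]) ** 2
            sq += (ox - x[dad]) ** 2 + (oy - y[dad]) ** 2
            np.add.at(disp_sq, (opy, opx), sq)
            np.add.at(disp_n, (opy, opx), 4)  # 4 single-axis events each

        if recorder is not None:
            child = recorder.add_nodes(2 * mom.size, gen).reshape(mom.size, 2)
            recorder.add_gametes(nodes[mom], child[:, 0], rng)
            recorder.add_gametes(nodes[dad], child[:, 1], rng)
            nodes = np.concatenate([nodes, child], axis=0)

        births[gen - 1] = mom.size
        x = np.concatenate([x, ox])
        y = np.concatenate([y, oy])

        # --- mortality ----------------------------------------------------
        eta = competition(x, y, W, params.sigma_c, eta_peak)
        K_loc = _bilinear(dmap.K, x, y)
        denom = K_loc * (1.0 + params.L)
        p = np.where(denom > 0, denom / (denom + eta), 0.0)
        alive = rng.random(x.size) < p
        x, y = x[alive], y[alive]
        if recorder is not None:
            nodes = nodes[alive]

        census[gen - 1] = x.size
        if recording:
            px, py = _pixels(x, y, w)
            np.add.at(density_acc, (py, px), 1)

    realized = None
    if record_realized and not extinct:
        n_rec = params.n_generations - params.burn_in
        with np.errstate(invalid="ignore", divide="ignore"):
            dispersal = np.sqrt(disp_sq / disp_n)
        dispersal[disp_n == 0] = np.nan
        realized = RealizedMaps(
            density=density_acc / n_rec, dispersal=dispersal, n_events=disp_n
        )

    tables = None
    sample_nodes = None
    if recorder is not None:
        flat = nodes.reshape(-1) if nodes is not None and nodes.size else np.empty(0, np.int64)
        tables = recorder.finalize(gens_run if not extinct else gens_run, flat)

    return SimResult(
        x=x,
        y=y,
        extinct=extinct,
        n_generations_run=gens_run,
        census=census[:gens_run],
        births=births[:gens_run],
        params=params,
        dmap=dmap,
        seed=seed,
        realized=realized,
        tables=tables,
        nodes=nodes,
    )
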