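"""Random segmented training maps of carrying capacity and dispersal.

A training map is a pair of ``w x w`` rasters: per-pixel carrying capacity
``K`` (individuals per unit area) and per-pixel effective dispersal rate
``sigma`` (distance per generation), plus a boolean habitat mask.  Each
channel is generated independently by cutting the unit landscape with a
random polynomial curve and assigning log-uniform / uniform values to the
resulting regions, so that a downstream network sees coarse spatial
heterogeneity in both parameters.

Coordinate convention (used consistently by the simulator, the recorder and
the network): planar map units with the origin at the lower-left corner,
pixels addressed as ``grid[row, col]`` with ``row`` indexing y and ``col``
indexing x, and pixel centers at half-integer offsets
``(col + 0.5, row + 0.5)``.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
import pathlib

import numpy as np
from scipy import ndimage


__all__ = [
    "MapPrior",
    "BoundaryCurve",
    "DemographicMap",
    "ViabilityFit",
    "sample_boundary",
    "generate_channel",
    "generate_map",
    "apply_habitat_mask",
    "calibrate_viability",
    "apply_viability_correction",
    "save_map",
    "load_map",
    "map_to_rgb",
]


@dataclass(frozen=True)
class MapPrior:
    """Range of a map channel; values are drawn log-uniformly from it."""

    p_min: float
    p_max: float

    def __post_init__(self) -> None:
        if not (0 < self.p_min < self.p_max):
            raise ValueError(
                f"prior requires 0 < p_min < p_max, got ({self.p_min}, {self.p_max})"
            )


# benchmark priors: K log-uniform on (4, 40) individuals per unit area,
# sigma log-uniform on (0.73, 3.08) map units per generation
K_PRIOR = MapPrior(4.0, 40.0)
SIGMA_PRIOR = MapPrior(0.73, 3.08)


@dataclass(frozen=True)
class BoundaryCurve:
    """Polynomial boundary y(x) separating map segments.

    ``degree`` is in {1, 2, 3}; ``coefficients`` are in descending powers
    (``numpy.polyval`` order).  A drawn degree of zero produces no curve
    (flat map) and is represented by ``None`` rather than by this type.
    """

    degree: int
    coefficients: np.ndarray

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients, x)


@dataclass
class DemographicMap:
    """Stacked carrying-capacity and dispersal rasters with a habitat mask."""

    K: np.ndarray
    sigma: np.ndarray
    mask: np.ndarray  # True = habitable

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mask is None:
            self.mask = np.ones_like(self.K, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.K.shape == self.sigma.shape == self.mask.shape):
            raise ValueError("K, sigma and mask must share one shape")
        if self.K.ndim != 2 or self.K.shape[0] != self.K.shape[1]:
            raise ValueError("maps must be square 2-D grids")

    @property
    def width(self) -> int:
        return self.K.shape[0]

    def channels(self) -> np.ndarray:
        """Return the (w, w, 2) stack, channel 0 = sigma, channel 1 = K."""
        return np.stack([self.sigma, self.K], axis=-1)

    def copy(self) -> "DemographicMap":
        return DemographicMap(self.K.copy(), self.sigma.copy(), self.mask.copy())


@dataclass(frozen=True)
class ViabilityFit:
    """Least-squares fit of log(sigma_min) on log(K).

    ``sigma_min(K) = exp(slope_m * log(K) + intercept_b)`` is the smallest
    dispersal rate that sustains a stable population at carrying capacity K.
    """

    slope_m: float
    intercept_b: float

    def sigma_min(self, K: np.ndarray) -> np.ndarray:
        return np.exp(self.slope_m * np.log(K) + self.intercept_b)

    def k_min(self, sigma: np.ndarray) -> np.ndarray:
        return np.exp((np.log(sigma) - self.intercept_b) / self.slope_m)


def sample_boundary(width: int, rng: np.random.Generator) -> BoundaryCurve | None:
    """Draw a random polynomial boundary over a ``width x width`` landscape.

    The polynomial degree is uniform on {0, 1, 2, 3}; degree zero returns
    ``None`` (a flat map).  Otherwise ``degree + 1`` anchor points are drawn
    uniformly from the landscape and the unique interpolating polynomial is
    solved for.  Anchor sets with (near-)duplicate x are resampled.
    """
    if width < 2:
        raise ValueError("width must be >= 2")
    degree = int(rng.integers(0, 4))
    return _sample_boundary_of_degree(degree, width, rng)


def fit_boundary(xs, ys) -> BoundaryCurve:
    """Interpolating polynomial through ``len(xs)`` anchor points."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    degree = xs.size - 1
    return BoundaryCurve(degree, np.polyfit(xs, ys, degree))


def _sample_boundary_of_degree(
    degree: int, width: int, rng: np.random.Generator
) -> BoundaryCurve | None:
    if degree == 0:
        return None
    while True:
        xs = rng.uniform(0, width, size=degree + 1)
        # resample degenerate anchors: Vandermonde solve needs distinct x
        if np.min(np.diff(np.sort(xs))) < 1e-6 * width:
            continue
        ys = rng.uniform(0, width, size=degree + 1)
        return fit_boundary(xs, ys)


def _segment_labels(curve: BoundaryCurve, width: int) -> np.ndarray:
    """Label pixels by connected region of the square cut by the curve.

    A pixel belongs to the 'below' set when its center lies below y(x) at
    the center's x.  Where the curve leaves the square the below/above sets
    can each split into several connected components (a degree-d curve cuts
    the square into at most d + 1 regions); components are identified with
    4-connected labelling so that regions are never merged across the curve.
    Labels are contiguous integers starting at 0.
    """
    centers = np.arange(width) + 0.5
    y_curve = curve(centers)  # y at each pixel-column center
    below = centers[:, None] < y_curve[None, :]  # [row, col]: center_y < y(x)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    lab_below, n_below = ndimage.label(below, structure=structure)
    lab_above, n_above = ndimage.label(~below, structure=structure)
    labels = np.where(below, lab_below - 1, n_below + lab_above - 1)
    return labels


def _log_uniform(low: float, high: float, rng: np.random.Generator) -> float:
    return float(np.exp(rng.uniform(np.log(low), np.log(high))))


def _dihedral(grid: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply a uniformly drawn element of the square's symmetry group."""
    k = int(rng.integers(0, 4))
    out = np.rot90(grid, k)
    if rng.integers(0, 2):
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def generate_channel(
    prior: MapPrior,
    width: int,
    rng: np.random.Generator,
    max_degree: int = 3,
) -> np.ndarray:
    """Generate one ``width x width`` channel of a segmented training map.

    Flat maps (degree 0) take a single log-uniform value from the prior.
    Segmented maps draw a value range ``r``, a log-uniform minimum ``m``
    (so that all values stay inside the prior), assign ``m`` and ``m + r``
    to two randomly chosen regions and uniform values in ``(m, m + r)`` to
    any remaining regions, then apply a random flip/rotation.
    """
    degree = int(rng.integers(0, max_degree + 1))
    curve = _sample_boundary_of_degree(degree, width, rng)
    if curve is None:
        return np.full((width, width), _log_uniform(prior.p_min, prior.p_max, rng))

    # range of values on the map; rejected while (p_min, p_max - r) would be
    # an empty interval for the log-uniform minimum draw
    while True:
        r = rng.uniform(prior.p_min, prior.p_max)
        if prior.p_max - r > prior.p_min:
            break
    m_val = _log_uniform(prior.p_min, prior.p_max - r, rng)

    labels = _segment_labels(curve, width)
    n_seg = int(labels.max()) + 1
    values = np.empty(n_seg)
    if n_seg == 1:  # curve misses the square entirely
        values[0] = m_val
    else:
        order = rng.permutation(n_seg)
        values[order[0]] = m_val
        values[order[1]] = m_val + r
        for s in order[2:]:
            values[s] = rng.uniform(m_val, m_val + r)
    grid = values[labels]
    return _dihedral(grid, rng)


def generate_map(
    k_prior: MapPrior = K_PRIOR,
    sigma_prior: MapPrior = SIGMA_PRIOR,
    width: int = 50,
    rng: np.random.Generator | None = None,
    max_degree: int = 3,
) -> DemographicMap:
    """Generate a demographic map: two independent channels, stacked."""
    rng = np.random.default_rng(rng)
    K = generate_channel(k_prior, width, rng, max_degree=max_degree)
    sigma = generate_channel(sigma_prior, width, rng, max_degree=max_degree)
    return DemographicMap(K, sigma, np.ones((width, width), dtype=bool))


def apply_habitat_mask(dmap: DemographicMap, mask: np.ndarray) -> DemographicMap:
    """Zero both channels outside the habitat; unmasked pixels unchanged."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dmap.K.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match map shape {dmap.K.shape}"
        )
    return DemographicMap(
        np.where(mask, dmap.K, 0.0), np.where(mask, dmap.sigma, 0.0), mask
    )


def calibrate_viability(
    K_values,
    sigma_scan=None,
    width: int = 10,
    horizon: int = 500,
    extinction_threshold: int = 10,
    sim_params=None,
    seed: int = 0,
) -> ViabilityFit:
    """Fit the extinction threshold sigma_min(K) from pilot simulations.

    For each carrying capacity a flat ``width x width`` habitat is simulated
    over ``horizon`` generations at each dispersal rate of an ascending scan
    grid; sigma_min is the smallest rate whose final population stays at or
    above ``extinction_threshold``.  The scan follows the wolf-style
    parameterization in which natal, mating and interaction distances share
    one scale (sigma_f = sigma_m = sigma_c), so a small dispersal rate also
    shrinks the mating radius - the mechanism that extinguishes sparse
    populations.  Returns the least-squares line of log(sigma_min) on
    log(K).

    With exactly two (K, sigma_min) points the fit passes through both, and
    refitting on predicted points reproduces the line; both properties are
    exercised in the test-suite via :func:`fit_viability_line`.
    """
    from .sim import SimParams, simulate  # local import: avoid cycle

    K_values = np.asarray(K_values, dtype=float)
    if K_values.size < 2 or np.unique(K_values).size < 2:
        raise ValueError("need at least two distinct K values")
    if sigma_scan is None:
        sigma_scan = np.geomspace(0.1, 3.2, 10)
    base = sim_params or SimParams(n_generations=horizon, burn_in=0)
    rng = np.random.default_rng(seed)
    sigma_min = []
    for K in K_values:
        found = None
        for sig in np.sort(np.asarray(sigma_scan, dtype=float)):
            # effective sigma^2 = 1.5 sigma_f^2 when sigma_f = sigma_m
            component = sig / np.sqrt(1.5)
            params = SimParams(
                sigma_m=component, sigma_c=component, L=base.L,
                n_generations=base.n_generations, burn_in=0,
                competition_scale=base.competition_scale, genome=base.genome,
            )
            dmap = DemographicMap(
                np.full((width, width), K),
                np.full((width, width), sig),
                np.ones((width, width), dtype=bool),
            )
            result = simulate(
                dmap, params, seed=int(rng.integers(2**31)), record_realized=False
            )
            # "stable" means the population is both large enough and still
            # reproducing: isolated individuals experience no competition
            # and linger indefinitely, so head count alone is not viability
            tail = max(10, base.n_generations // 4)
            reproducing = (
                result.births.size >= tail
                and result.births[-tail:].sum() >= 0.5 * result.final_size
            )
            if result.final_size >= extinction_threshold and reproducing:
                found = sig
                break
        if found is None:
            raise RuntimeError(
                f"no dispersal rate in the scan range sustains K={K:g}"
            )
        sigma_min.append(found)
    return fit_viability_line(K_values, np.asarray(sigma_min))


def fit_viability_line(K_values, sigma_min_values) -> ViabilityFit:
    """Least-squares line of log(sigma_min) on log(K)."""
    logK = np.log(np.asarray(K_values, dtype=float))
    logS = np.log(np.asarray(sigma_min_values, dtype=float))
    slope, intercept = np.polyfit(logK, logS, 1)
    return ViabilityFit(float(slope), float(intercept))


def apply_viability_correction(
    dmap: DemographicMap, fit: ViabilityFit, rng: np.random.Generator
) -> DemographicMap:
    """Boost sigma or K (randomly chosen per map) above the viability line.

    Pixels whose (K, sigma) combination falls below the fitted threshold get
    the boosted channel set to 1.25x the threshold value, allowing for random
    noise; all other pixels are unchanged.  Masked pixels stay zero.
    """
    rng = np.random.default_rng(rng)
    out = dmap.copy()
    boost_sigma = bool(rng.integers(0, 2))
    live = dmap.mask
    if boost_sigma:
        thresh = fit.sigma_min(np.where(live, dmap.K, 1.0))
        low = live & (dmap.sigma < thresh)
        out.sigma[low] = 1.25 * thresh[low]
    else:
        thresh = fit.k_min(np.where(live, dmap.sigma, 1.0))
        low = live & (dmap.K < thresh)
        out.K[low] = 1.25 * thresh[low]
    return out


# ---------------------------------------------------------------------------
# raster I/O: one CSV grid per channel, row-major; optional RGB export where
# red scales with K and blue with sigma (green is zero), with the scaling
# ranges stored in a JSON sidecar


def save_map(dmap: DemographicMap, out_dir) -> None:
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "map_K.csv", dmap.K, delimiter=",")
    np.savetxt(out / "map_sigma.csv", dmap.sigma, delimiter=",")
    np.savetxt(out / "habitat_mask.csv", dmap.mask.astype(int), delimiter=",", fmt="%d")


def load_map(in_dir) -> DemographicMap:
    src = pathlib.Path(in_dir)
    K = np.loadtxt(src / "map_K.csv", delimiter=",", ndmin=2)
    sigma = np.loadtxt(src / "map_sigma.csv", delimiter=",", ndmin=2)
    mask_path = src / "habitat_mask.csv"
    if mask_path.exists():
        mask = np.loadtxt(mask_path, delimiter=",", ndmin=2).astype(bool)
    else:
        mask = np.ones_like(K, dtype=bool)
    return DemographicMap(K, sigma, mask)


def map_to_rgb(dmap: DemographicMap, out_png=None):
    """Render the map as an RGB raster (red = K, green = 0, blue = sigma).

    Channel scaling ranges are written to a sidecar ``<out>.json`` so the
    raster can be decoded back to natural units.
    """
    from PIL import Image

    def _scale(channel):
        lo, hi = float(channel.min()), float(channel.max())
        span = hi - lo if hi > lo else 1.0
        return ((channel - lo) / span * 255).astype(np.uint8), lo, hi

    red, k_lo, k_hi = _scale(dmap.K)
    blue, s_lo, s_hi = _scale(dmap.sigma)
    rgb = np.stack([red, np.zeros_like(red), blue], axis=-1)
    rgb = rgb[::-1, :, :]  # image row 0 is the top; map row 0 is min-y
    if out_png is not None:
        out_png = pathlib.Path(out_png)
        Image.fromarray(rgb).save(out_png)
        sidecar = {"K_range": [k_lo, k_hi], "sigma_range": [s_lo, s_hi]}
        out_png.with_suffix(out_png.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1)
        )
    return rgb
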