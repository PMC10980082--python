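"""Accuracy metrics, ensembles, bootstrap uncertainty, and fidelity checks.

The headline accuracy metric is the mean relative absolute error (MRAE):
the mean over unmasked pixels of |predicted - true| / true, computed per
channel.  Point estimates may be stabilized by averaging an ensemble of
predictions made with independently drawn pair subsets, and pixel-wise 95%
confidence maps are produced by a parametric bootstrap: simulate new
datasets under the inferred map, re-estimate each, and take empirical
2.5%/97.5% quantiles per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


__all__ = [
    "ErrorReport",
    "UncertaintyMaps",
    "mrae",
    "pixelwise_r2",
    "ensemble_predict",
    "parametric_bootstrap",
    "bootstrap_pipeline",
    "realized_vs_input_bias",
    "window_ci_comparison",
    "planar_extent",
    "years_to_generations",
]


@dataclass
class ErrorReport:
    mrae_sigma: float
    mrae_density: float
    rae_sigma: np.ndarray
    rae_density: np.ndarray
    r2_sigma: float | None = None
    r2_density: float | None = None


@dataclass
class UncertaintyMaps:
    """Pixel-wise bootstrap quantile maps, per channel (sigma, density)."""

    lower: np.ndarray  # (w, w, 2) 2.5% quantiles
    upper: np.ndarray  # (w, w, 2) 97.5% quantiles
    relative_width: np.ndarray  # (upper - lower) / point estimate
    n_replicates: int
    n_skipped: int = 0


def mrae(pred, true, mask=None, valid=None) -> ErrorReport:
    """Mean relative absolute error per channel over unmasked pixels.

    ``pred`` and ``true`` are (w, w, 2) stacks (channel 0 sigma, channel 1
    density); ``valid`` optionally excludes pixels with no recorded events
    (NaN in a realized map).  Error is computed on the raw maps - any
    cosmetic smoothing for figures happens after, never before.
    """
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if mask is None:
        mask = np.ones(pred.shape[:2], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if valid is not None:
        mask = mask & np.asarray(valid, dtype=bool)
    if np.any(true[mask, :] <= 0) or np.any(~np.isfinite(true[mask, :])):
        raise ValueError("true map must be strictly positive on included pixels")
    rae = np.full(pred.shape, np.nan)
    rae[mask, :] = np.abs(pred[mask, :] - true[mask, :]) / true[mask, :]
    return ErrorReport(
        mrae_sigma=float(np.nanmean(rae[mask, 0])),
        mrae_density=float(np.nanmean(rae[mask, 1])),
        rae_sigma=rae[:, :, 0],
        rae_density=rae[:, :, 1],
    )


def pixelwise_r2(pred, true) -> float:
    """Squared Pearson correlation between predicted and true pixel values."""
    pred = np.asarray(pred, dtype=float).ravel()
    true = np.asarray(true, dtype=float).ravel()
    if pred.size < 2:
        raise ValueError("need at least two pixels")
    if np.std(pred) == 0 or np.std(true) == 0:
        return float("nan")  # undefined: zero variance
    r = np.corrcoef(pred, true)[0, 1]
    return float(r * r)


def ensemble_predict(model, genotypes, locations, n_replicates, rng, stats=None):
    """Average prediction over replicates with independent pair subsets.

    Returns (mean_map, sd_map) in natural units (when stats is given);
    with a single replicate this equals a plain prediction.
    """
    from .network import predict_map

    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(rng)
    preds = np.stack(
        [
            predict_map(model, genotypes, locations, rng, stats=stats)
            for _ in range(n_replicates)
        ]
    )
    return preds.mean(axis=0), preds.std(axis=0)


def parametric_bootstrap(point_estimate, simulate_fn, estimate_fn, B, rng):
    """Generic parametric-bootstrap machinery over pluggable callables.

    ``simulate_fn(point_estimate, seed)`` produces a replicate dataset under
    the inferred parameters (or None for a failed replicate, e.g.
    extinction, which is skipped and counted); ``estimate_fn(dataset,
    seed)`` re-estimates a map from it.  Returns pixel-wise 2.5% / 97.5%
    quantile maps per channel and the relative interval width
    (upper - lower) / point estimate.
    """
    rng = np.random.default_rng(rng)
    point = np.asarray(point_estimate, dtype=float)
    replicates = []
    skipped = 0
    for _ in range(B):
        seed = int(rng.integers(2**31))
        data = simulate_fn(point, seed)
        if data is None:
            skipped += 1
            continue
        replicates.append(np.asarray(estimate_fn(data, seed), dtype=float))
    if not replicates:
        raise RuntimeError("all bootstrap replicates failed")
    if skipped > 0.1 * B:
        import warnings

        warnings.warn(f"{skipped}/{B} bootstrap replicates skipped")
    stack = np.stack(replicates)
    lower = np.quantile(stack, 0.025, axis=0)
    upper = np.quantile(stack, 0.975, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (upper - lower) / point
    return UncertaintyMaps(
        lower=lower,
        upper=upper,
        relative_width=rel,
        n_replicates=len(replicates),
        n_skipped=skipped,
    )


def bootstrap_pipeline(
    model,
    stats,
    inferred_map,
    sim_params,
    n_samples,
    n_snps,
    B,
    rng,
    n_pairs_ensemble: int = 1,
):
    """Full-pipeline bootstrap: simulate under the inferred demographic map,
    sample, and re-estimate with the trained model for each replicate."""
    from .genotypes import sample_uniform, simulate_genotypes
    from .maps import DemographicMap
    from .sim import simulate

    rng = np.random.default_rng(rng)
    dmap = DemographicMap(
        inferred_map[:, :, 1], inferred_map[:, :, 0],
        np.ones(inferred_map.shape[:2], dtype=bool),
    )

    def simulate_fn(point, seed):
        srng = np.random.default_rng(seed)
        sim = simulate(dmap, sim_params, seed=seed, record_realized=False,
                       record_genealogy=True)
        if sim.extinct or sim.final_size < n_samples:
            return None
        ss = sample_uniform(sim, n_samples, srng)
        gm = simulate_genotypes(sim, ss, n_snps, int(srng.integers(2**31)))
        return gm.values, ss.locations

    def estimate_fn(data, seed):
        genotypes, locations = data
        mean_map, _ = ensemble_predict(
            model, genotypes, locations, n_pairs_ensemble,
            np.random.default_rng(seed), stats=stats,
        )
        return mean_map

    return parametric_bootstrap(inferred_map, simulate_fn, estimate_fn, B, rng)


def realized_vs_input_bias(realized_list, input_list, mask=None):
    """Input-vs-realized relative differences across simulated datasets.

    Per dataset, the mean over valid pixels of (input - realized)/realized
    is computed per channel (sigma, density); returned as per-channel
    (mean, SD) across datasets, in percent.  Sign follows the convention
    that a positive value means the input map overstates the realized
    quantity.  Pixels with no recorded dispersal events are excluded.
    """
    sig, den = [], []
    for realized, dmap in zip(realized_list, input_list):
        live = dmap.mask if mask is None else (dmap.mask & mask)
        valid_d = live & (realized.density > 0)
        valid_s = live & np.isfinite(realized.dispersal) & (realized.dispersal > 0)
        if not valid_d.any() or not valid_s.any():
            raise ValueError("a dataset has no valid pixels")
        sig.append(
            np.mean(
                (dmap.sigma[valid_s] - realized.dispersal[valid_s])
                / realized.dispersal[valid_s]
            )
        )
        den.append(
            np.mean(
                (dmap.K[valid_d] - realized.density[valid_d])
                / realized.density[valid_d]
            )
        )
    sig = 100 * np.asarray(sig)
    den = 100 * np.asarray(den)
    return {
        "sigma_bias_pct": float(sig.mean()),
        "sigma_bias_sd_pct": float(sig.std(ddof=1)) if sig.size > 1 else 0.0,
        "density_bias_pct": float(den.mean()),
        "density_bias_sd_pct": float(den.std(ddof=1)) if den.size > 1 else 0.0,
    }


def window_ci_comparison(
    relative_width: np.ndarray, sample_locations: np.ndarray, window: int = 5,
    mask=None,
):
    """Mean relative CI width in sampled vs unsampled map windows.

    Tiles the map with non-overlapping ``window x window`` pixel blocks,
    marks a block sampled when at least one sampling location falls inside
    it, and returns the ratio of mean relative widths
    (unsampled / sampled) together with the two means.
    """
    w = relative_width.shape[0]
    nb = w // window
    if nb == 0:
        raise ValueError("window larger than the map")
    px = np.clip((sample_locations[:, 0] // window).astype(int), 0, nb - 1)
    py = np.clip((sample_locations[:, 1] // window).astype(int), 0, nb - 1)
    sampled = np.zeros((nb, nb), dtype=bool)
    sampled[py, px] = True
    means = np.full((nb, nb), np.nan)
    for by in range(nb):
        for bx in range(nb):
            block = relative_width[
                by * window : (by + 1) * window, bx * window : (bx + 1) * window
            ]
            if mask is not None:
                sub = np.asarray(mask, dtype=bool)[
                    by * window : (by + 1) * window, bx * window : (bx + 1) * window
                ]
                block = block[sub]
            means[by, bx] = np.nanmean(block) if np.size(block) else np.nan
    m_sampled = float(np.nanmean(means[sampled]))
    m_unsampled = float(np.nanmean(means[~sampled])) if (~sampled).any() else np.nan
    return {
        "sampled_mean": m_sampled,
        "unsampled_mean": m_unsampled,
        "ratio_unsampled_over_sampled": m_unsampled / m_sampled,
    }


def planar_extent(land_area: float, land_fraction: float):
    """Total square-map area and width from a land area and its fraction.

    E.g. a projected land area of 11,083,509.65 km^2 covering 21.93% of the
    square map gives a total of 50,540,399.68 km^2 and width 7109.18 km.
    """
    if not (0 < land_fraction <= 1):
        raise ValueError("land fraction must be in (0, 1]")
    total = land_area / land_fraction
    return total, float(np.sqrt(total))


def years_to_generations(years: float, generation_time: float) -> int:
    """Convert years to generations, rounding half-up to the nearest integer."""
    if years <= 0 or generation_time <= 0:
        raise ValueError("years and generation time must be positive")
    import math

    return int(math.floor(years / generation_time + 0.5))
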