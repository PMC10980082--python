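"""Shared fixtures.

Heavy session-scoped fixtures (benchmark-scale simulations, the toy
parameter-recovery run) live here so the end-to-end checks can share one
computation; everything is generated programmatically at test time.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", message=".*time_units.*")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_sim():
    """Small heterogeneous simulation with genealogy, reused across tests."""
    from mapnn.maps import DemographicMap
    from mapnn.sim import SimParams, simulate

    w = 6
    K = np.full((w, w), 10.0)
    K[:, : w // 2] = 20.0
    sigma = np.full((w, w), 1.2)
    dmap = DemographicMap(K, sigma, np.ones((w, w), dtype=bool))
    params = SimParams(n_generations=40, burn_in=20)
    sim = simulate(dmap, params, seed=77, record_realized=True, record_genealogy=True)
    assert not sim.extinct
    return sim


@pytest.fixture(scope="session")
def benchmark_sims():
    """Reduced-scale benchmark simulations: 20 heterogeneous maps, w=20,
    400 generations with 250 burn-in, benchmark priors."""
    from mapnn.datasets import generate_benchmark_simulations

    return generate_benchmark_simulations(
        20, width=20, n_generations=400, burn_in=250, seed=17
    )


@pytest.fixture(scope="session")
def toy_recovery_run():
    """Desk-scale parameter recovery: train on ~200 flat-map toy datasets,
    evaluate level assignment and MRAE on held-out datasets."""
    from mapnn.datasets import (
        TOY_K_LEVELS,
        TOY_SIGMA_LEVELS,
        make_toy_flat_datasets,
    )
    from mapnn.estimator import MapNNRegressor
    from mapnn.evaluate import mrae

    n_train, n_test = 240, 30  # 120 simulations x 2 sample sets
    train = make_toy_flat_datasets(
        n_train, seed=101, n_generations=60, n_sample_sets=2
    )
    test = make_toy_flat_datasets(n_test, seed=2020, n_generations=60)

    X = [(t.dataset.genotypes, t.dataset.locations) for t in train]
    y = np.stack([t.dataset.target for t in train])
    groups = [t.dataset.group for t in train]
    est = MapNNRegressor(
        width=8, n_snps=500, k_init=120, k_extract=120, feature_width=16,
        conv_filters=(8, 16, 32), pool_size=2, global_pool=True,
        batch_size=10, learning_rate=3e-3, halve_patience=10,
        stop_patience=30, max_epochs=30, seed=3,
    )
    est.fit(X, y, groups=groups)

    # point estimates are ensemble means over independent pair subsets,
    # the package's canonical prediction
    from mapnn.evaluate import ensemble_predict

    preds = np.stack(
        [
            ensemble_predict(
                est.model_, t.dataset.genotypes, t.dataset.locations,
                n_replicates=10, rng=np.random.default_rng(9 + i),
                stats=est.stats_,
            )[0]
            for i, t in enumerate(test)
        ]
    )
    log_means = np.log(preds.reshape(n_test, -1, 2).mean(axis=1))
    mid_sigma = float(np.mean(np.log(TOY_SIGMA_LEVELS)))
    mid_k = float(np.mean(np.log(TOY_K_LEVELS)))
    true_sigma_high = np.array([t.sigma_level for t in test]) > np.exp(mid_sigma)
    true_k_high = np.array([t.k_level for t in test]) > np.exp(mid_k)
    acc_sigma = float(np.mean((log_means[:, 0] > mid_sigma) == true_sigma_high))
    acc_k = float(np.mean((log_means[:, 1] > mid_k) == true_k_high))
    reports = [
        mrae(preds[i], test[i].dataset.target) for i in range(n_test)
    ]
    return {
        "estimator": est,
        "test": test,
        "preds": preds,
        "acc_sigma": acc_sigma,
        "acc_k": acc_k,
        "mrae_sigma": float(np.mean([r.mrae_sigma for r in reports])),
        "mrae_density": float(np.mean([r.mrae_density for r in reports])),
    }
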