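"""scikit-learn-style estimator wrapping the two-branch map network.

``MapNNRegressor`` follows the sklearn estimator contract (``get_params``/
``set_params`` from ``BaseEstimator``, ``fit``/``predict``, fitted
attributes with a trailing underscore), so it composes with sklearn
pipelines and model selection.  X is a sequence of (genotypes, locations)
tuples - one geo-referenced SNP dataset per example - and y is an
(n, w, w, 2) array of demographic target maps in natural units.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .network import MapNN, NetworkConfig, predict_map
from .training import TrainConfig, TrainingDataset, train


class MapNNRegressor(BaseEstimator):
    """Estimate dispersal/density maps from genotypes + sampling locations.

    Parameters mirror :class:`~mapnn.network.NetworkConfig` and
    :class:`~mapnn.training.TrainConfig`; see those classes for semantics.

    Attributes (after fit)
    ----------------------
    model_ : MapNN
        Trained network (best validation weights).
    stats_ : PreprocessStats
        Log-space normalization statistics from the training split.
    history_ : list of dict
        Per-epoch train/validation losses and learning rate.
    mask_ : ndarray of bool
        Habitat mask used in the loss.
    """

    def __init__(
        self,
        width=50,
        n_snps=5000,
        k_init=450,
        k_extract=100,
        feature_width=128,
        conv_filters=None,
        conv_kernel=7,
        pool_size=2,
        global_pool=False,
        batch_size=10,
        learning_rate=1e-4,
        val_frac=0.2,
        halve_patience=10,
        stop_patience=100,
        max_epochs=1000,
        redraw_pairs=True,
        augment_symmetry=False,
        seed=0,
    ):
        self.width = width
        self.n_snps = n_snps
        self.k_init = k_init
        self.k_extract = k_extract
        self.feature_width = feature_width
        self.conv_filters = conv_filters
        self.conv_kernel = conv_kernel
        self.pool_size = pool_size
        self.global_pool = global_pool
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.val_frac = val_frac
        self.halve_patience = halve_patience
        self.stop_patience = stop_patience
        self.max_epochs = max_epochs
        self.redraw_pairs = redraw_pairs
        self.augment_symmetry = augment_symmetry
        self.seed = seed

    def _net_config(self):
        return NetworkConfig(
            n_snps=self.n_snps,
            width=self.width,
            k_init=self.k_init,
            k_extract=self.k_extract,
            feature_width=self.feature_width,
            conv_filters=self.conv_filters,
            conv_kernel=self.conv_kernel,
            pool_size=self.pool_size,
            global_pool=self.global_pool,
        )

    def fit(self, X, y, groups=None, mask=None, verbose=False):
        y = np.asarray(y, dtype=float)
        if y.ndim != 4 or y.shape[1:] != (self.width, self.width, 2):
            raise ValueError(
                f"y must be (n, {self.width}, {self.width}, 2), got {y.shape}"
            )
        if len(X) != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if groups is None:
            groups = np.arange(len(X))
        datasets = [
            TrainingDataset(
                genotypes=np.asarray(g), locations=np.asarray(l, dtype=float),
                target=y[i], group=int(groups[i]),
            )
            for i, (g, l) in enumerate(X)
        ]
        tc = TrainConfig(
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            val_frac=self.val_frac,
            halve_patience=self.halve_patience,
            stop_patience=self.stop_patience,
            max_epochs=self.max_epochs,
            seed=self.seed,
            redraw_pairs=self.redraw_pairs,
            augment_symmetry=self.augment_symmetry,
        )
        self.model_, self.stats_, self.history_ = train(
            datasets, self._net_config(), tc, mask=mask, verbose=verbose
        )
        self.mask_ = (
            np.ones((self.width, self.width), dtype=bool) if mask is None
            else np.asarray(mask, dtype=bool)
        )
        return self

    def predict(self, X, seed=None):
        """Predict (n, w, w, 2) maps in natural units.

        Pair subsets are drawn from ``seed`` (defaults to the estimator
        seed), so repeated calls are reproducible.
        """
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        rng = np.random.default_rng(self.seed if seed is None else seed)
        out = [
            predict_map(
                self.model_, np.asarray(g), np.asarray(l, dtype=float), rng,
                stats=self.stats_,
            )
            for g, l in X
        ]
        return np.stack(out)

    def score(self, X, y, seed=None):
        """Negative masked MSE in normalized space (higher is better)."""
        from .training import masked_mse, preprocess_targets

        preds = self.predict(X, seed=seed)
        total = 0.0
        for p, t in zip(preds, np.asarray(y, dtype=float)):
            pz = preprocess_targets(p, self.mask_, self.stats_)
            tz = preprocess_targets(t, self.mask_, self.stats_)
            total += masked_mse(pz, tz, self.mask_)
        return -total / len(X)
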