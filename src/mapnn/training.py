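"""Target preprocessing, masked MSE loss, and the optimization schedule.

Training targets are log transformed and each channel is independently
centered and scaled using statistics computed on the training split only
(the 80% side of the validation split), so validation stays honest.  The
loss is mean squared error in the normalized space, with every unmasked
pixel of both channels contributing equally; masked (non-habitat) pixels
contribute to neither numerator nor denominator.

The schedule follows the Adam optimizer with batch size 10 and learning
rate 1e-4 by default; the learning rate is halved after 10 consecutive
epochs without improvement of the validation loss, training stops after
100 such epochs, and the weights from the best validation epoch are
returned.  "Improvement" means any strict decrease below the best value
seen so far; the halving and stopping counters are tracked independently
and both reset on improvement.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
import pathlib

import numpy as np

from .layers import Adam
from .network import (
    MapNN,
    NetworkConfig,
    build_coord_table,
    build_pairs,
    pair_tensor,
)


__all__ = [
    "PreprocessStats",
    "TrainConfig",
    "TrainingDataset",
    "preprocess_targets",
    "inverse_preprocess",
    "masked_mse",
    "train",
    "package_training_set",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class PreprocessStats:
    """Per-channel mean/SD of log map values over unmasked training pixels."""

    mean: np.ndarray  # (2,) channel order: sigma, density
    sd: np.ndarray


def preprocess_targets(targets, mask=None, stats: PreprocessStats | None = None):
    """Normalize (n, w, w, 2) targets: z = (log v - mean_c) / sd_c.

    With ``stats=None`` the statistics are computed from the given maps
    (training split) and returned alongside; otherwise the provided
    statistics are reused (validation / inference).  Masked pixels are not
    transformed and are returned as zeros; callers carry the mask.
    """
    targets = np.asarray(targets, dtype=float)
    single = targets.ndim == 3
    if single:
        targets = targets[None]
    if mask is None:
        mask = np.ones(targets.shape[1:3], dtype=bool)
    live = np.asarray(mask, dtype=bool)
    vals = targets[:, live, :]  # (n, n_live, 2)
    if np.any(vals <= 0):
        raise ValueError("unmasked map values must be positive for the log transform")
    logs = np.log(vals)
    computed = stats is None
    if computed:
        mean = logs.mean(axis=(0, 1))
        sd = logs.std(axis=(0, 1))
        if np.any(sd <= 0):
            raise ValueError("a target channel is constant (zero SD)")
        stats = PreprocessStats(mean=mean, sd=sd)
    z = np.zeros_like(targets)
    z[:, live, :] = (logs - stats.mean) / stats.sd
    z = z[0] if single else z
    return (z, stats) if computed else z


def inverse_preprocess(z, stats: PreprocessStats):
    """Map normalized values back to natural units: v = exp(z * sd + mean)."""
    return np.exp(np.asarray(z, dtype=float) * stats.sd + stats.mean)


def masked_mse(pred, target, mask=None):
    """MSE over unmasked pixels of both channels.

    loss = [sum_p (sig_hat - sig)^2 + sum_p (K_hat - K)^2] / (pixels * 2)
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if mask is None:
        mask = np.ones(pred.shape[:2], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    n_pix = int(mask.sum())
    if n_pix == 0:
        raise ValueError("empty habitat mask")
    diff = (pred - target)[mask, :]
    return float((diff**2).sum() / (n_pix * 2))


def _masked_mse_grad(pred, target, mask):
    n_pix = int(mask.sum())
    g = np.zeros_like(pred)
    g[mask, :] = (pred - target)[mask, :] / n_pix
    return g


@dataclass
class TrainConfig:
    batch_size: int = 10
    learning_rate: float = 1e-4
    val_frac: float = 0.20
    halve_patience: int = 10
    stop_patience: int = 100
    max_epochs: int = 1000
    seed: int = 0
    redraw_pairs: bool = True  # fresh pair subset per example per epoch
    # randomly apply one of the square's 8 symmetries to each training
    # example per epoch (locations, target and mask together); a cheap
    # augmentation that enforces the model's physical symmetry
    augment_symmetry: bool = False

    def __post_init__(self):
        if not (0 < self.val_frac < 1):
            raise ValueError("validation fraction must be in (0, 1)")


class PatienceSchedule:
    """Learning-rate halving and early stopping on validation loss.

    An epoch "improves" when its validation loss is strictly below the best
    seen so far; both counters reset on improvement and are otherwise
    tracked independently.  After ``halve_patience`` non-improving epochs
    the learning rate is halved (and that counter resets); after
    ``stop_patience`` the schedule asks to stop.
    """

    def __init__(self, halve_patience: int, stop_patience: int):
        self.halve_patience = halve_patience
        self.stop_patience = stop_patience
        self.best = np.inf
        self._halve = 0
        self._stop = 0

    def update(self, val_loss: float):
        """Returns (improved, halve_now, stop_now)."""
        if val_loss < self.best:
            self.best = val_loss
            self._halve = 0
            self._stop = 0
            return True, False, False
        self._halve += 1
        self._stop += 1
        halve_now = self._halve >= self.halve_patience
        if halve_now:
            self._halve = 0
        return False, halve_now, self._stop >= self.stop_patience


@dataclass
class TrainingDataset:
    """One training example: genotypes, locations, target map, and the
    simulation it came from (for leakage-free validation splits)."""

    genotypes: np.ndarray
    locations: np.ndarray
    target: np.ndarray  # (w, w, 2) natural units, channel 0 sigma
    group: int = 0


def _dihedral_points(locations, w, k_rot, flip):
    """Apply the square symmetry matching :func:`_dihedral_grid` to points."""
    x = locations[:, 0].copy()
    y = locations[:, 1].copy()
    for _ in range(k_rot):
        x, y = y.copy(), w - x
    if flip:
        y = w - y
    return np.column_stack([x, y])


def _dihedral_grid(grid, k_rot, flip):
    out = np.rot90(grid, k_rot, axes=(0, 1))
    if flip:
        out = out[::-1]
    return np.ascontiguousarray(out)


def _split_by_group(datasets, val_frac, rng):
    """80/20 split at the simulation level so augmented sample sets of one
    simulation never straddle the split."""
    groups = np.array([d.group for d in datasets])
    uniq = np.unique(groups)
    uniq = uniq[rng.permutation(uniq.size)]
    n_val = max(1, int(round(val_frac * uniq.size)))
    val_groups = set(uniq[:n_val].tolist())
    train_idx = [i for i, g in enumerate(groups) if g not in val_groups]
    val_idx = [i for i, g in enumerate(groups) if g in val_groups]
    return train_idx, val_idx


def train(
    datasets,
    net_config: NetworkConfig,
    train_config: TrainConfig | None = None,
    mask: np.ndarray | None = None,
    verbose: bool = False,
):
    """Fit the network on (genotypes, locations, target-map) triples.

    Returns ``(model, stats, history)`` where history is a list of per-epoch
    records (train loss, validation loss, learning rate).  The returned
    model carries the weights of the best validation epoch.  Fully
    deterministic given ``train_config.seed``.
    """
    train_config = train_config or TrainConfig()
    rng = np.random.default_rng(train_config.seed)
    if mask is None:
        mask = np.ones(datasets[0].target.shape[:2], dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    train_idx, val_idx = _split_by_group(datasets, train_config.val_frac, rng)
    if not train_idx or not val_idx:
        raise ValueError("need at least one training and one validation example")
    train_targets = np.stack([datasets[i].target for i in train_idx])
    _, stats = preprocess_targets(train_targets, mask)
    norm_targets = [
        preprocess_targets(d.target, mask, stats) for d in datasets
    ]

    model = MapNN(net_config, seed=int(rng.integers(2**31)))
    # data-dependent scale calibration on one example (see MapNN docs)
    d0 = datasets[0]
    cal_pairs = build_pairs(
        d0.locations.shape[0], net_config.k_init, np.random.default_rng(0)
    )
    model.calibrate_scales(
        pair_tensor(d0.genotypes, cal_pairs, net_config.phased),
        build_coord_table(d0.locations, cal_pairs, net_config.width),
    )
    optimizer = Adam(model.parameters(), lr=train_config.learning_rate)
    n = datasets[0].locations.shape[0]
    cfg = net_config

    # fixed per-example pair draws for validation (and for training when
    # redraw_pairs is off), so the validation loss is comparable across epochs
    fixed_pairs = {
        i: build_pairs(n, cfg.k_init, np.random.default_rng(train_config.seed + 7 * i))
        for i in range(len(datasets))
    }

    def example_forward(i, pairs, locations=None):
        d = datasets[i]
        locs = d.locations if locations is None else locations
        coords = build_coord_table(locs, pairs, cfg.width)
        pred = model.forward(pair_tensor(d.genotypes, pairs, cfg.phased), coords)
        return pred

    schedule = PatienceSchedule(train_config.halve_patience, train_config.stop_patience)
    best_weights = model.get_weights()
    history = []

    for epoch in range(train_config.max_epochs):
        order = rng.permutation(len(train_idx))
        train_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), train_config.batch_size):
            batch = [train_idx[o] for o in order[start : start + train_config.batch_size]]
            model.zero_grad()
            for i in batch:
                if train_config.redraw_pairs:
                    pairs = build_pairs(n, cfg.k_init, rng)
                else:
                    pairs = fixed_pairs[i]
                if cfg.k_extract < cfg.k_init:
                    sel = rng.choice(cfg.k_init, size=cfg.k_extract, replace=False)
                    extract_mask = np.zeros(cfg.k_init, dtype=bool)
                    extract_mask[sel] = True
                else:
                    extract_mask = None
                target_i = norm_targets[i]
                mask_i = mask
                locs_i = None
                if train_config.augment_symmetry:
                    k_rot = int(rng.integers(4))
                    flip = bool(rng.integers(2))
                    locs_i = _dihedral_points(
                        datasets[i].locations, cfg.width, k_rot, flip
                    )
                    target_i = _dihedral_grid(target_i, k_rot, flip)
                    mask_i = _dihedral_grid(mask, k_rot, flip)
                pred = example_forward(i, pairs, locations=locs_i)
                loss = masked_mse(pred, target_i, mask_i)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, example {i}"
                    )
                train_loss += loss
                model.backward(_masked_mse_grad(pred, target_i, mask_i), extract_mask)
            optimizer.step(scale=1.0 / len(batch))
            n_batches += 1
        train_loss /= len(order)

        val_loss = 0.0
        for i in val_idx:
            pred = example_forward(i, fixed_pairs[i])
            val_loss += masked_mse(pred, norm_targets[i], mask)
        val_loss /= len(val_idx)
        history.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss,
             "lr": optimizer.lr}
        )
        if verbose:
            print(
                f"epoch {epoch:4d}  train {train_loss:.5f}  val {val_loss:.5f}  "
                f"lr {optimizer.lr:.2e}"
            )

        improved, halve_now, stop_now = schedule.update(val_loss)
        if improved:
            best_weights = model.get_weights()
        if halve_now:
            optimizer.lr /= 2.0
        if stop_now:
            break

    model.set_weights(best_weights)
    return model, stats, history


def package_training_set(
    bundles,
    target_source: str = "input",
    n_snps: int = 500,
    sample_scheme: str = "uniform",
    n_samples: int = 20,
    n_sample_sets: int = 1,
    seed: int = 0,
    grid_dim: int = 5,
    per_cell: int = 4,
):
    """Turn simulation results into training triples, with augmentation.

    ``target_source`` selects between the simulation-input maps ("input")
    and the recorded realized maps ("realized"); ``n_sample_sets`` draws
    that many (possibly overlapping) sample sets per simulation, each
    becoming its own training example, all tagged with the simulation's
    group id.  Extinct simulations are skipped.
    """
    from .genotypes import sample_grid, sample_uniform, simulate_genotypes

    if target_source not in ("input", "realized"):
        raise ValueError("target_source must be 'input' or 'realized'")
    rng = np.random.default_rng(seed)
    datasets = []
    for group, sim in enumerate(bundles):
        if sim.extinct:
            continue
        if target_source == "realized":
            if sim.realized is None:
                raise ValueError(f"simulation {group} has no realized maps")
            target = np.stack(
                [sim.realized.dispersal, sim.realized.density], axis=-1
            )
        else:
            target = sim.dmap.channels()
        for _ in range(n_sample_sets):
            if sample_scheme == "grid":
                ss = sample_grid(sim, per_cell, grid_dim, rng)
            else:
                ss = sample_uniform(sim, n_samples, rng)
            gm = simulate_genotypes(sim, ss, n_snps, int(rng.integers(2**31)))
            datasets.append(
                TrainingDataset(
                    genotypes=gm.values,
                    locations=ss.locations,
                    target=target,
                    group=group,
                )
            )
    return datasets


# ---------------------------------------------------------------------------
# checkpoints: weights + architecture + preprocessing statistics together


def save_checkpoint(path, model: MapNN, stats: PreprocessStats) -> None:
    path = pathlib.Path(path)
    arrays = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    np.savez(
        path,
        config=model.config.to_json(),
        mean=stats.mean,
        sd=stats.sd,
        **arrays,
    )


def load_checkpoint(path):
    """Restore (model, stats); predictions are bit-identical to the saved model."""
    data = np.load(path, allow_pickle=False)
    config = NetworkConfig.from_json(str(data["config"]))
    model = MapNN(config, seed=0)
    weights = [data[f"w{i}"] for i in range(len(model.get_weights()))]
    model.set_weights(weights)
    stats = PreprocessStats(mean=data["mean"], sd=data["sd"])
    return model, stats
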