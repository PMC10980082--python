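"""Two-branch network estimating demographic maps from genotype pairs.

Branch 1 (feature extraction) stacks the two genotype rows of each sample
pair as channels and applies a shared 1-D convolution/pooling stack along
the SNP axis, followed by a dense layer, yielding F machine-learned
summaries per pair; concatenated over pairs this is the matrix G (k x F).

Branch 2 (spatial scores) takes, for every (pixel, pair) combination, the
row (x_pix, y_pix, x_ind1, y_ind1, x_ind2, y_ind2, w) and passes it through
two dense layers with ReLU output, producing a non-negative score matrix
S_i (k x F) for every pixel i.

The combine stage computes, for each pixel,

    y_i = f( sum_j ReLU( (G * S_i) W + b )_j )

with the sum over pair rows and f a shared per-pixel stack of dense layers;
the per-pixel outputs are reshaped to a (w, w, 2) map (channel 0 =
dispersal, channel 1 = density).  Because every stage is shared across
pairs and pixels, the parameter count is independent of both the number of
pairs and the map width.

Memory is kept in check by analyzing only ``k_init`` random pairs and,
during training, restricting gradients into the extractor to a random
``k_extract``-subset of them; the forward pass always uses all k_init
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np

from .layers import AvgPool1D, Conv1D, Dense, Flatten, ReLU, Sequential


__all__ = ["NetworkConfig", "MapNN", "build_pairs", "build_coord_table", "predict_map"]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``conv_filters`` gives the output channels of successive
    (conv -> ReLU -> average-pool) blocks; by default blocks are added,
    with filter counts growing from 16 to 64, until the SNP axis is at most
    ``min_conv_len``.  ``k_extract <= k_init`` controls the pair-gradient
    mask; ``feature_width`` (F) is the number of genotype summaries per
    pair and equals the number of spatial scores.
    """

    n_snps: int
    width: int
    k_init: int
    k_extract: int | None = None
    feature_width: int = 128
    conv_kernel: int = 7
    pool_size: int = 2
    min_conv_len: int = 16
    conv_filters: tuple | None = None
    combine_hidden: int | None = None  # defaults to feature_width
    head_hidden: int | None = None  # defaults to 2 * feature_width
    phased: bool = False
    pair_symmetrize: bool = False
    # finish the conv stack with a global average pool over the SNP axis,
    # so pair summaries are genome-wide means of local detections (the
    # form classical summary statistics take); this removes most of the
    # extractor's memorization capacity, which matters when the training
    # set is small
    global_pool: bool = False
    # center genotype values (to -1..1) and rescale coordinates by the map
    # width (to roughly -0.5..0.5) before the branches; with raw
    # non-negative inputs and zero biases many ReLU units are dead at
    # initialization, which stalls optimization at desk scale
    center_inputs: bool = True

    def __post_init__(self):
        if self.k_extract is None:
            self.k_extract = self.k_init
        if self.k_extract > self.k_init:
            raise ValueError("k_extract must be <= k_init")
        if self.feature_width < 1:
            raise ValueError("feature_width must be >= 1")
        if self.conv_filters is None:
            filters = []
            length = self.n_snps
            f = 16
            while length - self.conv_kernel + 1 >= self.pool_size and (
                length > self.min_conv_len
            ):
                filters.append(f)
                f = min(f * 2, 64)
                length = (length - self.conv_kernel + 1) // self.pool_size
            if not filters:
                filters = [16]
            self.conv_filters = tuple(filters)
        else:
            self.conv_filters = tuple(self.conv_filters)
        if self.combine_hidden is None:
            self.combine_hidden = self.feature_width
        if self.head_hidden is None:
            self.head_hidden = 2 * self.feature_width

    def to_json(self) -> str:
        return json.dumps(
            {k: getattr(self, k) for k in self.__dataclass_fields__}, default=list
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkConfig":
        return cls(**json.loads(text))


def build_pairs(n: int, k_init: int, rng) -> np.ndarray:
    """Uniform sample of k_init distinct unordered pairs, as a (k, 2) array.

    Individuals within a pair are ordered by sample index (the documented
    channel-ordering convention).
    """
    rng = np.random.default_rng(rng)
    total = n * (n - 1) // 2
    if k_init > total:
        raise ValueError(f"k_init={k_init} exceeds {total} available pairs")
    i, j = np.triu_indices(n, k=1)
    chosen = rng.choice(total, size=k_init, replace=False)
    return np.column_stack([i[chosen], j[chosen]])


def build_coord_table(locations: np.ndarray, pairs: np.ndarray, width: int) -> np.ndarray:
    """(w^2, k, 7) coordinate features: pixel center, both individuals, w.

    Pixels are enumerated row-major with centers at (col + 0.5, row + 0.5),
    matching the output reshape to (w, w, 2).
    """
    w = width
    rows, cols = np.divmod(np.arange(w * w), w)
    px = cols + 0.5
    py = rows + 0.5
    k = pairs.shape[0]
    table = np.empty((w * w, k, 7))
    table[:, :, 0] = px[:, None]
    table[:, :, 1] = py[:, None]
    table[:, :, 2] = locations[pairs[:, 0], 0][None, :]
    table[:, :, 3] = locations[pairs[:, 0], 1][None, :]
    table[:, :, 4] = locations[pairs[:, 1], 0][None, :]
    table[:, :, 5] = locations[pairs[:, 1], 1][None, :]
    table[:, :, 6] = float(w)
    return table


class MapNN:
    """The assembled two-branch model with explicit forward/backward."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        layers = []
        c_in = 4 if config.phased else 2  # haplotype mode: 2 rows per individual
        length = config.n_snps
        for idx, f in enumerate(config.conv_filters):
            layers += [
                Conv1D(c_in, f, config.conv_kernel, rng, first_layer=idx == 0),
                ReLU(),
            ]
            length = length - config.conv_kernel + 1
            if length // config.pool_size >= 1:
                layers.append(AvgPool1D(config.pool_size))
                length //= config.pool_size
            c_in = f
        if config.global_pool and length > 1:
            layers.append(AvgPool1D(length))
            length = 1
        layers.append(Flatten())
        # the pair-summary layer is linear: signed features keep the
        # combine stage's ReLU units trainable (G * S would otherwise be
        # non-negative everywhere and dead units could never recover)
        layers.append(Dense(c_in * length, config.feature_width, rng))
        self.extractor = Sequential(layers)

        F = config.feature_width
        self.spatial = Sequential(
            [Dense(7, F, rng), ReLU(), Dense(F, F, rng), ReLU()]
        )
        self.combine_dense = Dense(F, config.combine_hidden, rng)
        self.combine_relu = ReLU()
        self.head = Sequential(
            [
                Dense(config.combine_hidden, config.head_hidden, rng),
                ReLU(),
                Dense(config.head_hidden, 2, rng),
            ]
        )

    # -- parameter plumbing -------------------------------------------------

    def parameters(self):
        return (
            self.extractor.parameters()
            + self.spatial.parameters()
            + self.combine_dense.parameters()
            + self.head.parameters()
        )

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.parameters()))

    def zero_grad(self):
        self.extractor.zero_grad()
        self.spatial.zero_grad()
        self.combine_dense.zero_grad()
        self.head.zero_grad()

    def get_weights(self):
        return [p.copy() for p, _ in self.parameters()]

    def set_weights(self, weights):
        for (p, _), w in zip(self.parameters(), weights):
            p[...] = w

    # -- forward / backward -------------------------------------------------

    def extract_pair_features(self, pair_genotypes: np.ndarray) -> np.ndarray:
        """G matrix from a (k, channels, n_snps) stack of genotype rows."""
        if pair_genotypes.shape[-1] != self.config.n_snps:
            raise ValueError(
                f"expected {self.config.n_snps} SNPs, got {pair_genotypes.shape[-1]}"
            )
        pair_genotypes = pair_genotypes.astype(float)
        if self.config.center_inputs:
            pair_genotypes = pair_genotypes - 1.0
        G = self.extractor.forward(pair_genotypes)
        if self.config.pair_symmetrize:
            swapped = pair_genotypes[:, ::-1, :].astype(float)
            G = 0.5 * (G + self.extractor.forward(swapped))
        return G

    def spatial_scores(self, coord_table: np.ndarray) -> np.ndarray:
        """Non-negative (w^2, k, F) score tensor from the coordinate table."""
        if self.config.center_inputs:
            w = float(self.config.width)
            coord_table = coord_table / w
            coord_table = coord_table - np.array([0.5] * 6 + [0.0])
        return self.spatial.forward(coord_table)

    def forward(self, pair_genotypes: np.ndarray, coord_table: np.ndarray):
        """Full forward pass; returns the (w, w, 2) output in normalized units."""
        w = self.config.width
        G = self.extract_pair_features(pair_genotypes)
        S = self.spatial_scores(coord_table)
        self._G, self._S = G, S
        M = G[None, :, :] * S  # (P, k, F)
        z = self.combine_relu.forward(self.combine_dense.forward(M))
        # combine pair rows by their mean: the same function family as a
        # row-wise sum (the 1/k factor is absorbable into the head), but
        # numerically well-scaled and invariant to the choice of k_init
        pooled = z.mean(axis=1)  # (P, H)
        out = self.head.forward(pooled)
        return out.reshape(w, w, 2)

    def calibrate_scales(self, pair_genotypes, coord_table, target_sd=1.0):
        """Rescale layer weights so intermediate activations have unit SD.

        With standard fan-based initialization the elementwise product
        G * S has SD around 1e-2, the combine units then operate in a
        near-linear noise regime, and optimization stalls at the target
        mean.  This data-dependent calibration (in the spirit of
        layer-sequential unit-variance init) runs one forward pass and
        scales the G-producing dense layer, the spatial output layer, the
        combine layer and the head input layer so each stage's output SD
        is ``target_sd``.  Biases are zero at this point, so pure weight
        scaling preserves the architecture's constraints (spatial scores
        stay non-negative).
        """

        def _scale(layer, factor):
            layer.W *= factor
            layer.b *= factor

        G = self.extract_pair_features(pair_genotypes)
        sd = G.std()
        if sd > 0:
            _scale(self.extractor.layers[-1], target_sd / sd)
            G = G * (target_sd / sd)
        S = self.spatial_scores(coord_table)
        sd = S.std()
        if sd > 0:
            _scale(self.spatial.layers[-2], target_sd / sd)
            S = S * (target_sd / sd)
        z = self.combine_dense.forward(G[None] * S)
        sd = z.std()
        if sd > 0:
            _scale(self.combine_dense, target_sd / sd)
            z = z * (target_sd / sd)
        pooled = np.maximum(z, 0.0).mean(axis=1)
        sd = pooled.std()
        if sd > 0:
            _scale(self.head.layers[0], target_sd / sd)

    def backward(self, dY: np.ndarray, extract_mask: np.ndarray | None = None):
        """Backpropagate d(loss)/d(output); accumulate parameter gradients.

        ``extract_mask`` (length k_init, boolean) limits which pair rows
        propagate gradients into the extractor branch; all other weights
        always receive full gradients.
        """
        P = self._S.shape[0]
        k = self._S.shape[1]
        dpooled = self.head.backward(dY.reshape(P, 2))
        dz = np.broadcast_to(dpooled[:, None, :] / k, (P, k, dpooled.shape[1]))
        dM = self.combine_dense.backward(self.combine_relu.backward(dz))
        dS = dM * self._G[None, :, :]
        dG = (dM * self._S).sum(axis=0)
        self.spatial.backward(dS)
        if extract_mask is not None:
            dG = dG * extract_mask[:, None]
        if self.config.pair_symmetrize:
            # layer caches hold only the last (swapped) pass, so training
            # with symmetrized pairs is not supported; it is an
            # inference-time option
            raise NotImplementedError(
                "backward with pair_symmetrize=True is not supported"
            )
        self.extractor.backward(dG)


def pair_tensor(genotypes: np.ndarray, pairs: np.ndarray, phased: bool = False):
    """Stack genotype rows of each pair into the (k, channels, S) input."""
    if phased:
        # two haplotype rows per individual -> 4 channels per pair
        a = genotypes[2 * pairs[:, 0]], genotypes[2 * pairs[:, 0] + 1]
        b = genotypes[2 * pairs[:, 1]], genotypes[2 * pairs[:, 1] + 1]
        return np.stack([a[0], a[1], b[0], b[1]], axis=1).astype(float)
    return np.stack(
        [genotypes[pairs[:, 0]], genotypes[pairs[:, 1]]], axis=1
    ).astype(float)


def predict_map(
    model: MapNN,
    genotypes: np.ndarray,
    locations: np.ndarray,
    rng,
    stats=None,
) -> np.ndarray:
    """Predict a (w, w, 2) map; natural units when ``stats`` is provided.

    Pairs are drawn with ``rng`` (deterministic given a seed); genotype
    channel 0/1 order within a pair follows sample index.
    """
    n = locations.shape[0]
    if n < 2:
        raise ValueError("need at least two sampled individuals")
    cfg = model.config
    rng = np.random.default_rng(rng)
    pairs = build_pairs(n, cfg.k_init, rng)
    coords = build_coord_table(locations, pairs, cfg.width)
    out = model.forward(pair_tensor(genotypes, pairs, cfg.phased), coords)
    if stats is not None:
        from .training import inverse_preprocess

        out = inverse_preprocess(out, stats)
    return out
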