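"""Network contracts: pair handling, branches, combine, gradients."""

import numpy as np
import pytest

from mapnn.network import (
    MapNN,
    NetworkConfig,
    build_coord_table,
    build_pairs,
    pair_tensor,
    predict_map,
)


def tiny_config(**kw):
    base = dict(
        n_snps=16, width=3, k_init=4, k_extract=4, feature_width=3,
        conv_filters=(2,), conv_kernel=3, pool_size=2,
    )
    if "k_init" in kw and "k_extract" not in kw:
        kw["k_extract"] = min(kw["k_init"], base["k_extract"])
    base.update(kw)
    return NetworkConfig(**base)


@pytest.fixture
def tiny_inputs(rng):
    cfg = tiny_config()
    n = 5
    genotypes = rng.integers(0, 3, size=(n, cfg.n_snps))
    locations = rng.uniform(0, cfg.width, size=(n, 2))
    pairs = build_pairs(n, cfg.k_init, rng)
    coords = build_coord_table(locations, pairs, cfg.width)
    return cfg, genotypes, locations, pairs, coords


class TestBuildPairs:
    def test_all_pairs_when_k_is_total(self):
        pairs = build_pairs(5, 10, np.random.default_rng(0))
        assert pairs.shape == (10, 2)
        assert len({tuple(p) for p in pairs}) == 10

    def test_benchmark_subset_distinct(self):
        # the benchmark setting: 450 pairs from n=100 (of 4950 possible)
        pairs = build_pairs(100, 450, np.random.default_rng(1))
        assert pairs.shape == (450, 2)
        assert len({tuple(p) for p in pairs}) == 450
        assert np.all(pairs[:, 0] < pairs[:, 1])  # index-ordered channels

    def test_too_many_pairs_raises(self):
        with pytest.raises(ValueError):
            build_pairs(5, 11, np.random.default_rng(0))


class TestExtractor:
    def test_deterministic(self, tiny_inputs, rng):
        cfg, genotypes, _, pairs, _ = tiny_inputs
        model = MapNN(cfg, seed=0)
        x = pair_tensor(genotypes, pairs)
        np.testing.assert_array_equal(
            model.extract_pair_features(x), model.extract_pair_features(x)
        )

    def test_zero_weights_give_zero_features(self, tiny_inputs):
        cfg, genotypes, _, pairs, _ = tiny_inputs
        model = MapNN(cfg, seed=0)
        model.set_weights([np.zeros_like(w) for w in model.get_weights()])
        G = model.extract_pair_features(pair_tensor(genotypes, pairs))
        assert np.all(G == 0)

    def test_row_depends_only_on_its_pair(self, tiny_inputs, rng):
        cfg, genotypes, _, pairs, _ = tiny_inputs
        model = MapNN(cfg, seed=1)
        G1 = model.extract_pair_features(pair_tensor(genotypes, pairs))
        other = genotypes.copy()
        # perturb an individual not in pair 0
        used = set(pairs[0])
        victim = next(i for i in range(len(genotypes)) if i not in used)
        other[victim] = (other[victim] + 1) % 3
        G2 = model.extract_pair_features(pair_tensor(other, pairs))
        np.testing.assert_array_equal(G1[0], G2[0])

    def test_snp_length_mismatch_raises(self, tiny_inputs):
        cfg, *_ = tiny_inputs
        model = MapNN(cfg, seed=0)
        with pytest.raises(ValueError):
            model.extract_pair_features(np.zeros((2, 2, cfg.n_snps + 1)))


class TestSpatialScores:
    def test_non_negative_for_any_input(self, rng):
        cfg = tiny_config()
        model = MapNN(cfg, seed=3)
        coords = rng.normal(size=(cfg.width**2, cfg.k_init, 7)) * 50
        assert np.all(model.spatial_scores(coords) >= 0)

    def test_identical_coordinates_identical_scores(self, tiny_inputs):
        cfg, _, locations, pairs, _ = tiny_inputs
        model = MapNN(cfg, seed=4)
        dup = pairs.copy()
        dup[1] = dup[0]
        coords = build_coord_table(locations, dup, cfg.width)
        S = model.spatial_scores(coords)
        np.testing.assert_array_equal(S[:, 0, :], S[:, 1, :])

    def test_translation_is_not_an_invariance(self, tiny_inputs):
        cfg, _, locations, pairs, _ = tiny_inputs
        model = MapNN(cfg, seed=5)
        coords = build_coord_table(locations, pairs, cfg.width)
        shifted = coords.copy()
        shifted[:, :, :6] += 2.0  # translate pixels and individuals together
        assert not np.allclose(
            model.spatial_scores(coords), model.spatial_scores(shifted)
        )


class TestCombine:
    def test_hand_computed_combine(self, rng):
        # arithmetic oracle on tiny tensors: explicit per-pixel loops
        cfg = tiny_config(width=2, k_init=2, feature_width=2)
        model = MapNN(cfg, seed=6)
        n = 4
        genotypes = rng.integers(0, 3, size=(n, cfg.n_snps))
        locations = rng.uniform(0, 2, size=(n, 2))
        pairs = np.array([[0, 1], [2, 3]])
        coords = build_coord_table(locations, pairs, cfg.width)
        x = pair_tensor(genotypes, pairs)
        # put activations in a healthy regime so the check is not vacuous
        model.calibrate_scales(x, coords)
        model.combine_dense.b += 0.1  # ensure some combine units fire
        out = model.forward(x, coords)

        G = model.extract_pair_features(x)
        S = model.spatial_scores(coords)
        Wc, bc = model.combine_dense.W, model.combine_dense.b
        k = pairs.shape[0]
        expected = np.empty((cfg.width**2, 2))
        nonzero = False
        for i in range(cfg.width**2):
            pooled = np.zeros(Wc.shape[1])
            for j in range(k):
                z = np.maximum((G[j] * S[i, j]) @ Wc + bc, 0.0)
                pooled += z
            pooled /= k  # pair rows combine by their mean
            nonzero = nonzero or np.any(pooled != 0)
            h = pooled
            for layer in model.head.layers:
                h = layer.forward(h[None])[0] if hasattr(layer, "W") else np.maximum(h, 0)
            expected[i] = h
        assert nonzero
        np.testing.assert_allclose(out.reshape(-1, 2), expected, rtol=1e-10)

    def test_pair_permutation_invariance(self, tiny_inputs, rng):
        cfg, genotypes, locations, pairs, coords = tiny_inputs
        model = MapNN(cfg, seed=7)
        out1 = model.forward(pair_tensor(genotypes, pairs), coords)
        perm = rng.permutation(pairs.shape[0])
        out2 = model.forward(
            pair_tensor(genotypes, pairs[perm]),
            build_coord_table(locations, pairs[perm], cfg.width),
        )
        np.testing.assert_allclose(out1, out2, rtol=1e-12)

    def test_duplicated_pair_doubles_its_contribution(self, tiny_inputs):
        cfg, genotypes, locations, pairs, coords = tiny_inputs
        model = MapNN(cfg, seed=8)
        model.calibrate_scales(pair_tensor(genotypes, pairs), coords)
        model.combine_dense.b += 0.1  # ensure some combine units fire

        def pooled_sum_for(pair_subset):
            c = build_coord_table(locations, pair_subset, cfg.width)
            model.forward(pair_tensor(genotypes, pair_subset), c)
            G, S = model._G, model._S
            z = np.maximum(
                (G[None] * S) @ model.combine_dense.W + model.combine_dense.b, 0.0
            )
            return z.sum(axis=1)

        single = pooled_sum_for(pairs[:1])
        double = pooled_sum_for(np.vstack([pairs[:1], pairs[:1]]))
        assert np.any(single != 0)
        np.testing.assert_allclose(double, 2 * single, rtol=1e-12)


class TestModelContracts:
    def test_parameter_count_independent_of_pairs_and_width(self):
        base = MapNN(tiny_config(), seed=0).n_parameters()
        more_pairs = MapNN(tiny_config(k_init=10, k_extract=2), seed=0).n_parameters()
        wider_map = MapNN(tiny_config(width=12), seed=0).n_parameters()
        assert base == more_pairs == wider_map
        # but it does (and should) depend on the genotype input length
        more_snps = MapNN(tiny_config(n_snps=64), seed=0).n_parameters()
        assert more_snps != base

    def test_masked_pairs_get_exactly_zero_extractor_gradient(self, tiny_inputs):
        cfg, genotypes, locations, pairs, coords = tiny_inputs
        model = MapNN(cfg, seed=9)
        out = model.forward(pair_tensor(genotypes, pairs), coords)
        dY = np.ones_like(out)
        model.zero_grad()
        model.backward(dY, extract_mask=np.zeros(cfg.k_init, dtype=bool))
        for p, g in model.extractor.parameters():
            assert np.all(g == 0)
        # every other branch still receives gradient
        assert any(np.any(g != 0) for _, g in model.spatial.parameters())
        assert any(np.any(g != 0) for _, g in model.head.parameters())

    def test_full_mask_equals_standard_backprop(self, tiny_inputs):
        cfg, genotypes, locations, pairs, coords = tiny_inputs
        x = pair_tensor(genotypes, pairs)
        model = MapNN(cfg, seed=10)
        out = model.forward(x, coords)
        dY = np.ones_like(out)
        model.zero_grad()
        model.backward(dY, extract_mask=np.ones(cfg.k_init, dtype=bool))
        masked = [g.copy() for _, g in model.parameters()]
        model.forward(x, coords)
        model.zero_grad()
        model.backward(dY, extract_mask=None)
        for gm, (_, g) in zip(masked, model.parameters()):
            np.testing.assert_allclose(gm, g, rtol=1e-12)

    def test_gradients_match_finite_differences(self, tiny_inputs):
        from mapnn.training import masked_mse, _masked_mse_grad

        cfg, genotypes, locations, pairs, coords = tiny_inputs
        x = pair_tensor(genotypes, pairs)
        model = MapNN(cfg, seed=11)
        # move off exact-zero pre-activations: ReLU is not differentiable at
        # its kink, so finite differences are only valid away from it
        jitter = np.random.default_rng(7)
        for p, _ in model.parameters():
            p += jitter.normal(0, 0.05, size=p.shape)
        mask = np.ones((cfg.width, cfg.width), dtype=bool)
        target = np.random.default_rng(0).normal(size=(cfg.width, cfg.width, 2))

        def loss():
            return masked_mse(model.forward(x, coords), target, mask)

        model.zero_grad()
        pred = model.forward(x, coords)
        model.backward(_masked_mse_grad(pred, target, mask))
        rng = np.random.default_rng(42)
        checked = 0
        for p, g in model.parameters():
            flat = p.reshape(-1)
            gflat = g.reshape(-1)
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                eps = 1e-6
                old = flat[idx]
                flat[idx] = old + eps
                lp = loss()
                flat[idx] = old - eps
                lm = loss()
                flat[idx] = old
                numeric = (lp - lm) / (2 * eps)
                assert numeric == pytest.approx(gflat[idx], rel=1e-4, abs=1e-8)
                checked += 1
        assert checked >= 20


class TestPredictMap:
    def test_shape_and_determinism(self, tiny_inputs):
        cfg, genotypes, locations, *_ = tiny_inputs
        model = MapNN(cfg, seed=12)
        out1 = predict_map(model, genotypes, locations, np.random.default_rng(5))
        out2 = predict_map(model, genotypes, locations, np.random.default_rng(5))
        assert out1.shape == (cfg.width, cfg.width, 2)
        np.testing.assert_array_equal(out1, out2)

    def test_single_individual_raises(self, tiny_inputs):
        cfg, genotypes, locations, *_ = tiny_inputs
        model = MapNN(cfg, seed=0)
        with pytest.raises(ValueError):
            predict_map(model, genotypes[:1], locations[:1], np.random.default_rng(0))

    def test_zeroed_final_layer_predicts_training_mean(self, tiny_inputs):
        from mapnn.training import PreprocessStats

        cfg, genotypes, locations, *_ = tiny_inputs
        model = MapNN(cfg, seed=13)
        last = model.head.layers[-1]
        last.W[...] = 0.0
        last.b[...] = 0.0
        stats = PreprocessStats(mean=np.array([0.3, 1.1]), sd=np.array([0.5, 0.2]))
        out = predict_map(
            model, genotypes, locations, np.random.default_rng(0), stats=stats
        )
        np.testing.assert_allclose(out[:, :, 0], np.exp(0.3), rtol=1e-12)
        np.testing.assert_allclose(out[:, :, 1], np.exp(1.1), rtol=1e-12)
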