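import numpy as np
import pytest
from hypothesis import given, strategies as st

import ssrbm.rbm as R
from ssrbm.ingest import encode_sequences, split_train_valid
from ssrbm.rbm import (RBMParams, TrainConfig, TrainingDivergedError,
                       all_block_probs, block_probs, cd_gradient, energy,
                       enumerate_hidden_states, exact_likelihood_gradient,
                       exact_log_likelihood, exact_log_partition, free_energy,
                       generate_sequences, hidden_conditional, local_fields,
                       model_from_dict, model_to_dict, pseudo_log_likelihood,
                       sample_hidden, sample_visible, train)

from oracles import EnumeratedRBM


def random_params(gamma, n_hidden, seed, scale=0.4):
    gen = np.random.default_rng(seed)
    return RBMParams(gen.normal(0, scale, (20 * gamma, n_hidden)),
                     gen.normal(0, scale / 2, 20 * gamma),
                     gen.normal(0, scale / 2, n_hidden))


# ---------------------------------------------------------------------------
# Energy and conditionals
# ---------------------------------------------------------------------------

class TestEnergy:
    def test_zero_parameters_zero_energy(self, rng):
        p = RBMParams(np.zeros((20, 2)), np.zeros(20), np.zeros(2))
        v = encode_sequences(["A"])[0]
        assert energy(v, np.array([1.0, -1.0]), p) == 0.0

    def test_gauge_symmetry(self, tiny_params, rng):
        v = encode_sequences(["W"])[0].astype(float)
        h = np.array([1.0, -1.0])
        flipped = tiny_params.gauge_flip([0])
        h_flipped = h * np.array([-1.0, 1.0])
        assert np.isclose(energy(v, h, tiny_params),
                          energy(v, h_flipped, flipped))

    def test_hand_value(self):
        # 2 visible sites, 1 hidden unit, evaluated term by term
        p = RBMParams(np.array([[1.0], [-1.0]]), np.array([0.5, 0.0]),
                      np.array([0.2]))
        assert np.isclose(energy(np.array([1.0, -1.0]), np.array([1.0]), p),
                          -2.7)

    def test_shape_mismatch(self, tiny_params):
        with pytest.raises(ValueError):
            energy(np.ones(19), np.ones(2), tiny_params)


class TestConditionals:
    def test_zero_parameters_half(self):
        p = RBMParams(np.zeros((20, 3)), np.zeros(20), np.zeros(3))
        v = encode_sequences(["C"])[0]
        assert np.allclose(hidden_conditional(v, p), 0.5)

    def test_monotone_in_hidden_bias(self, tiny_params):
        v = encode_sequences(["D"])[0]
        base = hidden_conditional(v, tiny_params)
        shifted = RBMParams(tiny_params.weights, tiny_params.visible_bias,
                            tiny_params.hidden_bias + 0.5)
        assert np.all(hidden_conditional(v, shifted) > base)

    def test_matches_enumeration(self, tiny_params):
        oracle = EnumeratedRBM(tiny_params.weights, tiny_params.visible_bias,
                               tiny_params.hidden_bias)
        v = encode_sequences(["Q"])[0].astype(float)
        assert np.allclose(hidden_conditional(v, tiny_params),
                           oracle.p_h_given_v(v), atol=1e-12)

    def test_extreme_inputs_stable(self):
        p = RBMParams(np.full((20, 1), 50.0), np.zeros(20), np.zeros(1))
        v = encode_sequences(["A"])[0]
        q = hidden_conditional(v, p)
        assert np.all(np.isfinite(q)) and 0.0 <= q[0] <= 1.0


class TestFieldsAndBlocks:
    def test_zero_weights_fields_equal_bias(self, rng):
        a = rng.normal(size=20)
        p = RBMParams(np.zeros((20, 2)), a, np.zeros(2))
        assert np.allclose(local_fields(np.array([1.0, -1.0]), p), a)

    def test_fields_mirror_about_bias(self, tiny_params):
        h = np.array([1.0, -1.0])
        up = local_fields(h, tiny_params)
        down = local_fields(-h, tiny_params)
        assert np.allclose((up + down) / 2, tiny_params.visible_bias)

    def test_uniform_blocks_at_zero(self):
        p = RBMParams(np.zeros((40, 1)), np.zeros(40), np.zeros(1))
        assert np.allclose(block_probs(np.array([1.0]), p, 1), 1 / 20)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_block_normalization(self, seed):
        p = random_params(2, 2, seed)
        h = np.where(np.random.default_rng(seed).random(2) < 0.5, 1.0, -1.0)
        probs = all_block_probs(h, p)
        assert np.all(np.abs(probs.sum(axis=-1) - 1.0) < 1e-12)

    def test_matches_block_enumeration(self, tiny_params):
        oracle = EnumeratedRBM(tiny_params.weights, tiny_params.visible_bias,
                               tiny_params.hidden_bias)
        h = np.array([1.0, -1.0])
        assert np.allclose(block_probs(h, tiny_params, 0),
                           oracle.p_block_given_h(h, 0), atol=1e-12)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

class TestSampling:
    def test_zero_model_hidden_frequency(self, rng):
        p = RBMParams(np.zeros((20, 2)), np.zeros(20), np.zeros(2))
        v = np.tile(encode_sequences(["A"])[0], (100000, 1))
        draws = sample_hidden(v, p, rng)
        freq = (draws > 0).mean(axis=0)
        assert np.all(np.abs(freq - 0.5) < 3 * 0.5 / np.sqrt(1e5))

    def test_zero_model_block_frequency(self, rng):
        p = RBMParams(np.zeros((20, 1)), np.zeros(20), np.zeros(1))
        h = np.ones((100000, 1))
        v = sample_visible(h, p, rng)
        freq = (v.reshape(-1, 20) > 0).mean(axis=0)
        se = np.sqrt(0.05 * 0.95 / 1e5)
        assert np.all(np.abs(freq - 0.05) < 4 * se)

    def test_hidden_frequency_matches_conditional(self, tiny_params, rng):
        v0 = encode_sequences(["M"])[0]
        p_plus = hidden_conditional(v0, tiny_params)
        draws = sample_hidden(np.tile(v0, (100000, 1)), tiny_params, rng)
        freq = (draws > 0).mean(axis=0)
        se = np.sqrt(p_plus * (1 - p_plus) / 1e5)
        assert np.all(np.abs(freq - p_plus) < 4 * se)

    def test_visible_frequency_matches_block_probs(self, tiny_params, rng):
        h = np.array([1.0, -1.0])
        target = block_probs(h, tiny_params, 0)
        v = sample_visible(np.tile(h, (100000, 1)), tiny_params, rng)
        freq = (v.reshape(-1, 20) > 0).mean(axis=0)
        se = np.sqrt(target * (1 - target) / 1e5) + 1e-9
        assert np.all(np.abs(freq - target) < 5 * se)


# ---------------------------------------------------------------------------
# Free energy, PLL, partition function (exact-oracle equivalence)
# ---------------------------------------------------------------------------

class TestExactness:
    def test_zero_model_pll_uniform(self):
        p = RBMParams(np.zeros((100, 3)), np.zeros(100), np.zeros(3))
        samples = encode_sequences(["ACDEF", "WYWYW"])
        assert np.isclose(pseudo_log_likelihood(p, samples), 5 * np.log(1 / 20))

    def test_pll_gauge_invariant(self, two_block_params):
        samples = encode_sequences(["AC", "WY", "DD"])
        flipped = two_block_params.gauge_flip([1])
        assert np.isclose(pseudo_log_likelihood(two_block_params, samples),
                          pseudo_log_likelihood(flipped, samples))

    def test_free_energy_matches_enumeration(self, two_block_params):
        oracle = EnumeratedRBM(two_block_params.weights,
                               two_block_params.visible_bias,
                               two_block_params.hidden_bias)
        v = encode_sequences(["WY"])[0].astype(float)
        assert np.isclose(free_energy(v, two_block_params),
                          oracle.free_energy(v), atol=1e-10)

    def test_pll_matches_full_enumeration(self, two_block_params):
        oracle = EnumeratedRBM(two_block_params.weights,
                               two_block_params.visible_bias,
                               two_block_params.hidden_bias)
        seqs = ["AC", "WY", "DD", "KL"]
        combos = [tuple("ACDEFGHIKLMNPQRSTVWY".index(c) for c in s)
                  for s in seqs]
        assert np.isclose(pseudo_log_likelihood(two_block_params,
                                                encode_sequences(seqs)),
                          oracle.pll(combos), atol=1e-10)

    def test_log_partition_matches_enumeration(self, two_block_params):
        oracle = EnumeratedRBM(two_block_params.weights,
                               two_block_params.visible_bias,
                               two_block_params.hidden_bias)
        assert np.isclose(exact_log_partition(two_block_params),
                          oracle.log_partition(), atol=1e-10)

    def test_enumeration_bound_enforced(self):
        with pytest.raises(ValueError):
            enumerate_hidden_states(13)


# ---------------------------------------------------------------------------
# Gradients
# ---------------------------------------------------------------------------

def numerical_gradient(params, samples, eps=1e-5):
    """Central finite differences of the exact log-likelihood."""
    grads = []
    for arr in (params.weights, params.visible_bias, params.hidden_bias):
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + eps
            up = exact_log_likelihood(params, samples)
            arr[idx] = orig - eps
            down = exact_log_likelihood(params, samples)
            arr[idx] = orig
            g[idx] = (up - down) / (2 * eps)
        grads.append(g)
    return grads


class TestGradients:
    def test_analytic_matches_finite_differences(self):
        samples = encode_sequences(["A", "W", "D", "K"]).astype(float)
        p = random_params(1, 2, seed=3)
        analytic = exact_likelihood_gradient(p, samples)
        numeric = numerical_gradient(p, samples)
        for a, n in zip(analytic, numeric):
            assert np.max(np.abs(a - n)) / (np.max(np.abs(n)) + 1e-12) < 1e-5

    def test_cd_stationary_on_model_data(self, rng):
        # data drawn from the model itself: gradient should average to ~0
        p = random_params(1, 2, seed=5, scale=0.3)
        v = generate_sequences(p, 20000, rng, as_spins=True).astype(float)
        (gw, ga, gb), _ = cd_gradient(v, p, n_steps=20, chains=None, rng=rng)
        assert np.max(np.abs(gw)) < 0.05
        assert np.max(np.abs(ga)) < 0.05
        assert np.max(np.abs(gb)) < 0.05

    def test_cd_infinity_matches_exact_gradient(self, rng):
        # long chains approximate the model expectation of the exact gradient
        p = random_params(1, 2, seed=9, scale=0.3)
        data = generate_sequences(p, 5000, rng, as_spins=True).astype(float)
        exact = exact_likelihood_gradient(p, data)
        (gw, _, _), _ = cd_gradient(data, p, n_steps=50,
                                    chains=generate_sequences(p, 100000, rng,
                                                              as_spins=True).astype(float),
                                    rng=rng)
        assert np.max(np.abs(gw - exact[0])) < 0.05

    def test_empty_batch_errors(self, tiny_params, rng):
        with pytest.raises(ValueError):
            cd_gradient(np.empty((0, 20)), tiny_params, 1, None, rng)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class TestTraining:
    def make_split(self, n=400, seed=0):
        gen = np.random.default_rng(seed)
        p = random_params(1, 1, seed=2, scale=0.8)
        v = generate_sequences(p, n, gen, as_spins=True)
        return split_train_valid(v, seed=seed)

    def test_zero_learning_rate_leaves_parameters(self):
        split = self.make_split()
        config = TrainConfig(epochs=2, learning_rate=0.0, seed=4)
        trained = train(split, 2, config)
        expected = R.initial_params(20, 2, config, np.random.default_rng(4),
                                    split.train.astype(float))
        assert np.array_equal(trained.params.weights, expected.weights)
        assert np.array_equal(trained.params.visible_bias, expected.visible_bias)

    def test_identical_seeds_identical_trajectories(self):
        split = self.make_split()
        cfg = TrainConfig(epochs=3, seed=8)
        a = train(split, 2, cfg)
        b = train(split, 2, cfg)
        assert np.array_equal(a.params.weights, b.params.weights)
        assert np.array_equal(a.pll_valid, b.pll_valid)

    def test_pll_series_lengths(self):
        split = self.make_split()
        trained = train(split, 2, TrainConfig(epochs=4, seed=0))
        assert len(trained.pll_train) == len(trained.pll_valid) == 4

    def test_training_improves_pll_on_planted_data(self):
        from ssrbm.synthetic import default_planted_spec, make_planted_rbm, sample_planted
        params = make_planted_rbm(default_planted_spec(2, gamma=4))
        data = sample_planted(params, 12000, seed=0, as_spins=True)
        split = split_train_valid(data, seed=0)
        finals = []
        for seed in range(5):
            tr = train(split, 2, TrainConfig(epochs=25, seed=seed))
            assert tr.pll_valid[-1] > tr.pll_valid[0]
            finals.append(tr.pll_valid[-1])
        planted_pll = pseudo_log_likelihood(params, split.valid)
        # median final PLL within 0.05 nats/position of the generator's own
        gap = abs(np.median(finals) - planted_pll) / params.gamma
        assert gap < 0.05

    def test_divergence_detected(self):
        split = self.make_split()
        cfg = TrainConfig(epochs=3, learning_rate=np.inf,
                          final_learning_rate=None, weight_decay=0.0, seed=0)
        with pytest.raises((TrainingDivergedError, FloatingPointError)):
            with np.errstate(over="ignore", invalid="ignore"):
                train(split, 2, cfg)

    def test_serialization_round_trip(self):
        split = self.make_split()
        trained = train(split, 2, TrainConfig(epochs=2, seed=1))
        doc = model_to_dict(trained)
        back = model_from_dict(doc)
        assert np.allclose(back.params.weights, trained.params.weights)
        assert back.config == trained.config


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

class TestGeneration:
    def test_zero_model_uniform_frequencies(self, rng):
        p = RBMParams(np.zeros((40, 2)), np.zeros(40), np.zeros(2))
        seqs = generate_sequences(p, 100000, rng)
        counts = np.zeros(20)
        for s in seqs:
            counts["ACDEFGHIKLMNPQRSTVWY".index(s[0])] += 1
        freq = counts / len(seqs)
        se = np.sqrt(0.05 * 0.95 / 1e5)
        assert np.all(np.abs(freq - 0.05) < 4 * se)

    def test_marginals_match_enumeration(self, rng):
        p = random_params(2, 2, seed=21, scale=0.5)
        oracle = EnumeratedRBM(p.weights, p.visible_bias, p.hidden_bias)
        target = oracle.marginal_table()
        v = generate_sequences(p, 100000, rng, as_spins=True)
        freq = (v.reshape(len(v), 2, 20) > 0).mean(axis=0).T
        assert np.max(np.abs(freq - target)) < 0.01

    def test_gauge_flip_generates_same_distribution(self, rng):
        p = random_params(2, 2, seed=23, scale=0.5)
        flipped = p.gauge_flip([0, 1])
        a = generate_sequences(p, 50000, np.random.default_rng(1), as_spins=True)
        b = generate_sequences(flipped, 50000, np.random.default_rng(2),
                               as_spins=True)
        fa = (a.reshape(len(a), 2, 20) > 0).mean(axis=0)
        fb = (b.reshape(len(b), 2, 20) > 0).mean(axis=0)
        assert np.max(np.abs(fa - fb)) < 0.01
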