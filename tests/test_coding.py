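import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmricode import (
    EncoderSpec,
    LayerWeights,
    build_factorial_design,
    encode_factorial,
    encode_gain_control,
    encode_hash,
    encode_matrix_multiplication,
    encode_multilayer,
    encode_perceptron,
    encode_vector_space,
    generate_distortions,
    generate_prototype,
    init_network,
    model_table,
    pearson_similarity,
)
from fmricode.coding import binarize_factors

# The 2^3 full factorial design, columns I A B C AB AC BC ABC, rows in
# Yates order (first factor fastest): intercept, main effects and all
# interaction products of a two-level three-factor design.
TABLE_2POW3 = np.array(
    [
        [1, -1, -1, -1, 1, 1, 1, -1],
        [1, 1, -1, -1, -1, -1, 1, 1],
        [1, -1, 1, -1, -1, 1, -1, 1],
        [1, 1, 1, -1, 1, -1, -1, -1],
        [1, -1, -1, 1, 1, -1, -1, 1],
        [1, 1, -1, 1, -1, 1, -1, -1],
        [1, -1, 1, 1, -1, -1, 1, -1],
        [1, 1, 1, 1, 1, 1, 1, 1],
    ]
)


class TestInitNetwork:
    def test_weight_count_and_determinism(self):
        net = init_network(dim=100, depth=8, seed=0)
        assert sum(w.matrix.size for w in net.weights) == 80_000
        net2 = init_network(dim=100, depth=8, seed=0)
        for a, b in zip(net.weights, net2.weights):
            np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_standard_normal_entries(self):
        net = init_network(dim=100, depth=8, seed=1)
        entries = np.concatenate([w.matrix.ravel() for w in net.weights])
        se = 1.0 / np.sqrt(entries.size)
        assert abs(entries.mean()) < 4 * se
        assert abs(entries.std() - 1.0) < 4 * se

    def test_depth_outside_study_range_warns(self):
        with pytest.warns(UserWarning):
            init_network(dim=10, depth=9, seed=0)

    def test_truncated_shares_layers(self):
        net = init_network(dim=10, depth=8, seed=2)
        sub = net.truncated(3)
        assert sub.depth == 3
        for a, b in zip(sub.weights, net.weights[:3]):
            assert a is b


class TestEncoders:
    def test_vector_space_is_identity(self, rng):
        x = rng.standard_normal(30)
        np.testing.assert_array_equal(encode_vector_space(x), x)

    def test_gain_control_values(self):
        np.testing.assert_array_equal(encode_gain_control(np.zeros(5)), np.zeros(5))
        out = encode_gain_control(np.array([1.0, -1.0]))
        np.testing.assert_allclose(out, [0.7615941559557649, -0.7615941559557649], atol=1e-15)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=20))
    def test_tanh_outputs_bounded(self, values):
        out = encode_gain_control(np.array(values))
        assert np.all(np.abs(out) <= 1.0)

    def test_matrix_multiplication_identity_and_linearity(self, rng):
        w = LayerWeights(matrix=np.eye(6))
        x = rng.standard_normal(6)
        np.testing.assert_array_equal(encode_matrix_multiplication(x, w), x)
        wr = LayerWeights(matrix=rng.standard_normal((6, 6)))
        x1, x2 = rng.standard_normal(6), rng.standard_normal(6)
        lhs = encode_matrix_multiplication(2.0 * x1 + 3.0 * x2, wr)
        rhs = 2.0 * encode_matrix_multiplication(x1, wr) + 3.0 * encode_matrix_multiplication(x2, wr)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_shape_mismatch(self, rng):
        w = LayerWeights(matrix=rng.standard_normal((5, 5)))
        with pytest.raises(ValueError):
            encode_matrix_multiplication(rng.standard_normal(6), w)

    def test_perceptron_is_gain_of_matmul(self, rng):
        w = LayerWeights(matrix=rng.standard_normal((8, 8)))
        x = rng.standard_normal(8)
        np.testing.assert_array_equal(
            encode_perceptron(x, w), encode_gain_control(encode_matrix_multiplication(x, w))
        )
        np.testing.assert_array_equal(
            encode_perceptron(np.ones(8), LayerWeights(matrix=np.zeros((8, 8)))), np.zeros(8)
        )

    def test_multilayer_composition(self, small_network, rng):
        """Depth-d stack equals d-fold perceptron composition, to machine precision."""
        x = rng.standard_normal(20)
        y = x
        for d in range(1, 9):
            y = encode_perceptron(y, small_network.weights[d - 1])
            np.testing.assert_array_equal(encode_multilayer(x, small_network.truncated(d)), y)

    def test_multilayer_depth_one_equals_perceptron(self, small_network, rng):
        x = rng.standard_normal(20)
        np.testing.assert_array_equal(
            encode_multilayer(x, small_network.truncated(1)),
            encode_perceptron(x, small_network.weights[0]),
        )

    def test_return_layers_diagnostics(self, small_network, rng):
        x = rng.standard_normal(20)
        layers = encode_multilayer(x, small_network, return_layers=True)
        assert len(layers) == 8
        np.testing.assert_array_equal(layers[-1], encode_multilayer(x, small_network))

    def test_deep_layers_saturate(self):
        """At depth 8 with N(0,1) weights the tanh outputs hug +-1."""
        net = init_network(dim=100, depth=8, seed=3)
        proto = generate_prototype(100, seed=4)
        out = encode_multilayer(proto.values, net)
        assert np.mean(np.abs(out)) > 0.9
        assert np.mean(np.abs(out) > 0.99) > 0.5

    def test_model_table_numbering(self):
        net = init_network(dim=10, depth=8, seed=5)
        models = model_table(net)
        assert [m[0] for m in models] == list(range(1, 12))
        assert models[0][1] == "vector_space"
        assert models[-1][1] == "8-layer network"
        # models 3 and 4 share layer-1 weights with the stack
        assert models[2][2].weights[0] is net.weights[0]
        assert models[3][2].weights[0] is net.weights[0]


class TestFactorialDesign:
    def test_three_factor_design_matches_reference_table(self):
        design = build_factorial_design(3)
        assert design.column_labels == ("I", "A", "B", "C", "AB", "AC", "BC", "ABC")
        np.testing.assert_array_equal(design.matrix, TABLE_2POW3)

    @pytest.mark.parametrize("n", range(1, 9))
    def test_rows_and_columns_orthogonal_exact(self, n):
        design = build_factorial_design(n)
        m = design.matrix
        gram = m @ m.T
        np.testing.assert_array_equal(gram, (2**n) * np.eye(2**n, dtype=int))
        gram_c = m.T @ m
        np.testing.assert_array_equal(gram_c, (2**n) * np.eye(2**n, dtype=int))

    @pytest.mark.parametrize("n", [1, 3, 6])
    def test_normalized_design_is_orthogonal_matrix(self, n):
        q = build_factorial_design(n).normalized()
        eye = np.eye(2**n)
        assert np.abs(q @ q.T - eye).max() < 1e-12
        assert np.abs(q.T @ q - eye).max() < 1e-12

    def test_smallest_design(self):
        design = build_factorial_design(1)
        np.testing.assert_array_equal(design.matrix, [[1, -1], [1, 1]])

    def test_invalid_n_factors(self):
        for bad in (0, 13):
            with pytest.raises(ValueError):
                build_factorial_design(bad)

    def test_encode_factorial_first_row(self):
        rep = encode_factorial(np.array([-1, -1, -1]))
        np.testing.assert_array_equal(rep, [1, -1, -1, -1, 1, 1, 1, -1])

    def test_encode_factorial_matches_design_rows(self):
        design = build_factorial_design(3)
        for row in range(8):
            factors = design.matrix[row, 1:4]
            np.testing.assert_array_equal(encode_factorial(factors, design), design.matrix[row])

    def test_distinct_settings_orthogonal(self):
        design = build_factorial_design(3)
        reps = [encode_factorial(design.matrix[r, 1:4], design) for r in range(8)]
        for i in range(8):
            for j in range(i + 1, 8):
                assert int(reps[i] @ reps[j]) == 0

    def test_single_factor_flip_still_orthogonal(self):
        """Inputs differing in one factor give zero-similarity representations."""
        a = encode_factorial(np.array([-1, -1, -1]))
        b = encode_factorial(np.array([1, -1, -1]))
        assert int(a @ b) == 0

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError):
            encode_factorial(np.array([0.5, 1.0, -1.0]))

    def test_binarize_extension(self):
        np.testing.assert_array_equal(binarize_factors(np.array([0.3, -2.0, 0.0])), [1, -1, 1])


class TestHashCoding:
    def test_deterministic_and_shaped(self, rng):
        x = rng.standard_normal(10)
        a, b = encode_hash(x), encode_hash(x)
        np.testing.assert_array_equal(a, b)
        assert a.size == 200
        assert np.all(np.abs(a) <= 1.0)

    def test_similar_inputs_uncorrelated(self):
        """Prototype vs low-distortion member: |r| within the null band."""
        proto = generate_prototype(100, seed=6)
        sset = generate_distortions(proto, seed=7)
        r = pearson_similarity(encode_hash(proto.values), encode_hash(sset.distortions[0]))
        assert abs(r) < 4 / np.sqrt(2000)

    def test_avalanche(self):
        """A minimal perturbation of one element decorrelates the code."""
        rng = np.random.default_rng(8)
        x = rng.standard_normal(100)
        y = x.copy()
        y[0] = np.nextafter(y[0], np.inf)
        r = pearson_similarity(encode_hash(x), encode_hash(y))
        # all but one digest identical; the flipped digest is pseudo-random
        assert r < 1.0
        z = x + 1e-12  # perturb every element by one representable nudge
        rz = pearson_similarity(encode_hash(x), encode_hash(z))
        assert abs(rz) < 4 / np.sqrt(2000)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            encode_hash(np.array([1.0, np.nan]))


class TestEncoderSpecContract:
    def test_uniform_callable_contract(self, small_network, rng):
        x = rng.standard_normal(20)
        np.testing.assert_array_equal(EncoderSpec("vector_space")(x), x)
        np.testing.assert_array_equal(small_network(x), encode_multilayer(x, small_network))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            EncoderSpec("perceptron")  # missing weights
        with pytest.raises(ValueError):
            EncoderSpec("nonsense")

    def test_network_export_round_trip(self, tmp_path, rng):
        from fmricode.coding import load_network, save_network

        net = init_network(dim=6, depth=3, seed=13)
        save_network(net, tmp_path / "net")
        back = load_network(tmp_path / "net")
        assert back.scheme == "multilayer" and back.depth == 3
        x = rng.standard_normal(6)
        np.testing.assert_allclose(
            encode_multilayer(x, back), encode_multilayer(x, net), atol=1e-12
        )
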