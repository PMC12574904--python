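import numpy as np
import pytest

from dazzle.augmentation import sample_mask
from dazzle.model import (AdjacencyMatrix, LatentState, ModelConfig, ModelParams,
                          bce_loss, classify_dropout, compose_loss, decode,
                          encode, extract_edges, kl_divergence,
                          reconstruction_loss)


def identity_params(m, adj=None, seed=0):
    p = ModelParams(ModelConfig(n_genes=m, identity_nets=True),
                    np.random.default_rng(seed))
    if adj is not None:
        p.adj.data[:] = adj
        p.zero_adj_diagonal()
    return p


def random_stable_adjacency(m, rng, radius=0.5):
    a = rng.normal(size=(m, m))
    np.fill_diagonal(a, 0)
    a *= radius / np.abs(np.linalg.eigvals(a)).max()
    return a


class TestAdjacencyMatrix:
    def test_diagonal_zeroed_on_construction(self):
        adj = AdjacencyMatrix(np.ones((3, 3)), ["a", "b", "c"])
        assert np.diag(adj.weights).tolist() == [0, 0, 0]

    def test_rejects_nonsquare(self):
        with pytest.raises(ValueError):
            AdjacencyMatrix(np.ones((2, 3)), ["a", "b"])


class TestEncode:
    def test_zero_adjacency_identity_nets(self, rng):
        x = rng.uniform(0, 2, (4, 6))
        z = encode(x, identity_params(6, np.zeros((6, 6))))
        np.testing.assert_array_equal(z.mean[:, :, 0], x)

    def test_zero_input(self):
        z = encode(np.zeros((3, 5)), identity_params(5))
        np.testing.assert_allclose(z.mean, 0.0, atol=1e-10)

    def test_matches_dense_multiply_oracle(self, rng):
        a = random_stable_adjacency(5, rng)
        x = rng.uniform(0, 2, (7, 5))
        z = encode(x, identity_params(5, a))
        np.testing.assert_allclose(z.mean[:, :, 0], x @ (np.eye(5) - a),
                                   atol=1e-12)

    def test_deterministic_sample_equals_mean(self, rng):
        p = ModelParams(ModelConfig(n_genes=4), rng)
        z = encode(rng.uniform(0, 1, (3, 4)), p, stochastic=False)
        np.testing.assert_array_equal(z.sample, z.mean)

    def test_stochastic_sample_reparameterized(self, rng):
        p = ModelParams(ModelConfig(n_genes=4), rng)
        z = encode(rng.uniform(0, 1, (3, 4)), p, stochastic=True,
                   rng=np.random.default_rng(0))
        recomposed = z.mean + np.exp(z.log_var / 2) * z.epsilon
        np.testing.assert_allclose(z.sample, recomposed, atol=1e-12)


class TestDecode:
    def test_zero_adjacency_identity(self, rng):
        p = identity_params(5, np.zeros((5, 5)))
        z = encode(rng.uniform(0, 2, (3, 5)), p)
        np.testing.assert_allclose(decode(z, p)[:, :, None], z.sample, atol=1e-12)

    def test_round_trip_inverts_encoder(self, rng):
        # Z'(I-A)^{-1} undoes X'(I-A) for any stable A
        for _ in range(5):
            a = random_stable_adjacency(50, rng, radius=0.9)
            p = identity_params(50, a)
            x = rng.uniform(0, 3, (10, 50))
            z = encode(x, p)
            np.testing.assert_allclose(decode(z, p), x, atol=1e-5)

    def test_zero_latent_maps_to_zero(self):
        p = identity_params(4)
        z = LatentState(mean=np.zeros((2, 4, 1)), log_var=np.zeros((2, 4, 1)),
                        sample=np.zeros((2, 4, 1)))
        np.testing.assert_allclose(decode(z, p), 0.0, atol=1e-12)


class TestClassifier:
    def test_zero_final_layer_gives_half(self, rng):
        p = ModelParams(ModelConfig(n_genes=6), rng)
        z = encode(rng.uniform(0, 2, (4, 6)), p)
        np.testing.assert_array_equal(classify_dropout(z, p), 0.5)

    def test_probabilities_in_open_interval(self, rng):
        p = ModelParams(ModelConfig(n_genes=6), rng)
        p.W_c3.data[:] = rng.normal(size=p.W_c3.data.shape) * 10
        z = encode(rng.uniform(0, 2, (4, 6)), p)
        probs = classify_dropout(z, p)
        assert ((probs > 0) & (probs < 1)).all()
        assert probs.shape == (4, 6)


class TestLosses:
    def test_bce_uninformative_is_log2(self):
        mask = np.zeros((3, 3), dtype=bool)
        probs = np.full((3, 3), 0.5)
        assert bce_loss(mask, probs) == pytest.approx(np.log(2), abs=1e-12)

    def test_bce_perfect_classifier_near_zero(self, rng):
        mask = rng.random((4, 4)) < 0.3
        assert bce_loss(mask, mask.astype(float)) == pytest.approx(0.0, abs=1e-6)

    def test_bce_matches_scalar_loop(self, rng):
        mask = rng.random((4, 4)) < 0.5
        probs = rng.uniform(0.01, 0.99, (4, 4))
        acc = 0.0
        for i in range(4):
            for j in range(4):
                y, p = float(mask[i, j]), probs[i, j]
                acc += -(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert bce_loss(mask, probs) == pytest.approx(acc / 16, rel=1e-12)

    def test_kl_zero_at_prior(self):
        z = LatentState(mean=np.zeros((2, 3, 1)), log_var=np.zeros((2, 3, 1)),
                        sample=np.zeros((2, 3, 1)))
        assert kl_divergence(z) == 0.0

    def test_kl_single_unit_mean_one(self):
        z = LatentState(mean=np.ones((1, 1, 1)), log_var=np.zeros((1, 1, 1)),
                        sample=np.ones((1, 1, 1)))
        assert kl_divergence(z) == pytest.approx(0.5)

    def test_kl_matches_scalar_loop(self, rng):
        mean = rng.normal(size=(3, 4, 2))
        lv = rng.normal(size=(3, 4, 2))
        z = LatentState(mean=mean, log_var=lv, sample=mean)
        acc = sum(0.5 * (np.exp(lv[i, j, c]) + mean[i, j, c] ** 2 - 1 - lv[i, j, c])
                  for i in range(3) for j in range(4) for c in range(2))
        assert kl_divergence(z) == pytest.approx(acc / 3, rel=1e-12)

    def test_kl_nonnegative_property(self, rng):
        for _ in range(200):
            z = LatentState(mean=rng.normal(scale=3, size=(2, 3, 1)),
                            log_var=rng.normal(scale=3, size=(2, 3, 1)),
                            sample=np.zeros((2, 3, 1)))
            assert kl_divergence(z) >= 0.0

    def test_reconstruction_perfect_is_zero(self, rng):
        x = rng.uniform(0, 2, (3, 3))
        assert reconstruction_loss(x, x.copy()) == 0.0

    def test_reconstruction_single_entry(self):
        assert reconstruction_loss(np.array([[0.0]]), np.array([[2.0]])) == 4.0

    def test_reconstruction_matches_scalar_loop(self, rng):
        x, xh = rng.normal(size=(3, 3)), rng.normal(size=(3, 3))
        acc = sum((x[i, j] - xh[i, j]) ** 2 for i in range(3) for j in range(3))
        assert reconstruction_loss(x, xh) == pytest.approx(acc / 3, rel=1e-12)


class TestComposeLoss:
    def test_delay_zeroes_alpha(self):
        a = np.array([[0.0, 2.0], [-3.0, 0.0]])
        parts = compose_loss(1.0, 0.5, 0.2, a, alpha=1.0, beta=1.0, gamma=1.0,
                             epoch=0, sparse_delay=5)
        assert parts.alpha == 0.0
        assert parts.l1_sparse == 5.0
        assert parts.total == pytest.approx(1.0 + 0.5 + 0.2)

    def test_alpha_active_after_delay(self):
        a = np.array([[0.0, 2.0], [-3.0, 0.0]])
        parts = compose_loss(1.0, 0.5, 0.2, a, alpha=2.0, beta=1.0, gamma=1.0,
                             epoch=5, sparse_delay=5)
        assert parts.alpha == 2.0
        assert parts.total == pytest.approx(1.0 + 10.0 + 0.5 + 0.2)

    def test_zero_coefficients_leave_reconstruction(self):
        parts = compose_loss(3.3, 9.9, 9.9, np.zeros((2, 2)), alpha=0.0,
                             beta=0.0, gamma=0.0, epoch=10)
        assert parts.total == 3.3

    def test_exact_recomposition(self, rng):
        a = rng.normal(size=(4, 4))
        parts = compose_loss(rng.uniform(), rng.uniform(), rng.uniform(), a,
                             alpha=0.7, beta=1.3, gamma=0.2, epoch=9)
        manual = (parts.reconstruction + parts.alpha * parts.l1_sparse
                  + parts.beta * parts.kl + parts.gamma * parts.bce)
        assert abs(parts.total - manual) <= 1e-10 * max(1.0, abs(manual))

    def test_negative_coefficients_rejected(self):
        with pytest.raises(ValueError):
            compose_loss(1.0, 1.0, 1.0, np.zeros((2, 2)), alpha=-1.0,
                         beta=1.0, gamma=1.0, epoch=0)


class TestExtractEdges:
    def test_below_threshold_excluded(self):
        a = np.zeros((2, 2))
        a[0, 1] = 0.0005
        adj = AdjacencyMatrix(a, ["a", "b"])
        assert extract_edges(adj, 0.001).empty

    def test_zero_matrix_empty(self):
        assert extract_edges(AdjacencyMatrix(np.zeros((3, 3)), list("abc"))).empty

    def test_sorted_by_magnitude(self):
        a = np.zeros((3, 3))
        a[0, 1], a[1, 2], a[2, 0] = 0.5, -0.7, 0.0005
        df = extract_edges(AdjacencyMatrix(a, list("abc")), 0.001)
        assert df["weight"].tolist() == [-0.7, 0.5]
        assert df["regulator"].tolist() == ["b", "a"]

    def test_tie_break_lexicographic(self):
        a = np.zeros((3, 3))
        a[2, 0] = a[0, 1] = a[1, 2] = 0.5
        df = extract_edges(AdjacencyMatrix(a, list("abc")), 0.1)
        assert list(zip(df["regulator"], df["target"])) == \
            [("a", "b"), ("b", "c"), ("c", "a")]


def test_classifier_learns_dropout_on_synthetic_data(reference_world):
    """After training, masked entries score higher dropout probability."""
    from dazzle.training import TrainConfig, train

    world = reference_world
    params, _ = train(world.expression_observed, TrainConfig(seed=3))
    # mask on the log scale, then standardize — the order training uses
    obs = world.expression_observed.values
    mask = sample_mask(*obs.shape, 0.1, np.random.default_rng(11))
    masked = obs * ~mask.mask
    vals = (masked - params.input_mean) / params.input_std
    z = encode(vals, params)
    probs = classify_dropout(z, params, use_mean=True)
    assert probs[mask.mask].mean() > probs[~mask.mask].mean()


def test_checkpoint_round_trip(tmp_path, rng):
    """Save -> load reproduces parameters, config and outputs exactly."""
    from dazzle.training import TrainConfig, train
    from dazzle import make_world

    world = make_world(n_genes=8, n_cells=40, density=0.2, seed=1)
    params, _ = train(world.expression_observed,
                      TrainConfig(n_iterations=2, sparse_delay=1, hidden_dim=8,
                                  seed=2))
    path = tmp_path / "model.npz"
    params.save(path)
    back = ModelParams.load(path)
    for key, val in params.state_dict().items():
        np.testing.assert_array_equal(back.state_dict()[key], val)
    np.testing.assert_array_equal(back.input_mean, params.input_mean)
    x = rng.uniform(0, 2, (5, 8))
    np.testing.assert_array_equal(encode(x, back).mean, encode(x, params).mean)
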