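import numpy as np
import pytest

from aucurve.au_graph import (
    AdjacencyMatrix,
    AUGraphNet,
    CooccurrenceCounts,
    GraphLossConfig,
    adjacency_conditional,
    adjacency_symmetric,
    au_gcn_forward,
    count_cooccurrence,
    gcn_layer,
    graph_loss,
    read_adjacency_csv,
    renorm_propagation,
    sag_pool,
    write_adjacency_csv,
)
from aucurve.fixtures import analytic_adjacencies, sample_au_corpus
from aucurve.inventory import AU_INVENTORY

from oracles import cooccurrence_oracle, gcn_dense_oracle


class TestCounts:
    def test_brute_force_example(self):
        counts = count_cooccurrence([{"AU1", "AU2"}, {"AU1"}, {"AU2"}], ("AU1", "AU2"))
        np.testing.assert_array_equal(counts.N, [2, 2])
        assert counts.N_pair[0, 1] == 1

    def test_empty_corpus_all_zero(self):
        counts = count_cooccurrence([], ("AU1", "AU2"))
        assert counts.N.sum() == 0 and counts.N_pair.sum() == 0

    def test_duplication_doubles_counts(self):
        corpus = [{"AU1", "AU4"}, {"AU4"}, {"AU1", "AU2", "AU4"}]
        ids = ("AU1", "AU2", "AU4")
        a = count_cooccurrence(corpus, ids)
        b = count_cooccurrence(corpus * 2, ids)
        np.testing.assert_array_equal(b.N, 2 * a.N)
        np.testing.assert_array_equal(b.N_pair, 2 * a.N_pair)

    def test_matches_loop_oracle_on_random_corpora(self):
        rng = np.random.default_rng(0)
        ids = AU_INVENTORY[:6]
        corpus = [frozenset(au for au in ids if rng.random() < 0.4) for _ in range(200)]
        corpus = [s for s in corpus if s]
        counts = count_cooccurrence(corpus, ids)
        N, N_pair = cooccurrence_oracle(corpus, ids)
        np.testing.assert_array_equal(counts.N, N)
        np.testing.assert_array_equal(counts.N_pair, N_pair)

    def test_unknown_au_rejected(self):
        with pytest.raises(ValueError, match="AU99"):
            count_cooccurrence([{"AU99"}], ("AU1",))


class TestAdjacency:
    def test_conditional_brute_force_example(self):
        counts = count_cooccurrence([{"AU1", "AU2"}, {"AU1", "AU2"}, {"AU1"}], ("AU1", "AU2"))
        adj = adjacency_conditional(counts)
        assert adj.values[1, 0] == pytest.approx(2 / 3)   # P(U2 | U1)
        assert adj.values[0, 1] == pytest.approx(1.0)     # P(U1 | U2)
        assert not adj.symmetric

    def test_never_cooccurring_gives_zero(self):
        counts = count_cooccurrence([{"AU1"}, {"AU2"}], ("AU1", "AU2"))
        assert adjacency_conditional(counts).values[0, 1] == 0.0
        assert adjacency_symmetric(counts).values[0, 1] == 0.0

    def test_always_together_gives_one(self):
        counts = count_cooccurrence([{"AU1", "AU2"}] * 3, ("AU1", "AU2"))
        assert adjacency_conditional(counts).values[0, 1] == 1.0
        assert adjacency_symmetric(counts).values[0, 1] == 1.0

    def test_symmetric_worked_example(self):
        counts = count_cooccurrence([{"AU1", "AU2"}, {"AU1"}, {"AU2"}], ("AU1", "AU2"))
        adj = adjacency_symmetric(counts)
        assert adj.values[0, 1] == pytest.approx(0.5)  # 2*1 / (2+2)
        assert adj.symmetric
        np.testing.assert_array_equal(adj.values, adj.values.T)

    def test_zero_count_au_row_is_zero(self):
        counts = count_cooccurrence([{"AU1"}], ("AU1", "AU2"))
        cond = adjacency_conditional(counts)
        assert cond.values[0, 1] == 0.0  # P(U1|U2) undefined -> 0
        assert cond.values[1, 1] == 0.0

    def test_estimators_recover_generative_joint(self):
        """Empirical adjacencies from 5000 sampled sets match the analytic
        conditional/symmetric values of the generator within +-0.03 (the
        densely active recovery fixture keeps the conditional estimators'
        standard error near 0.01)."""
        from aucurve.fixtures import recovery_spec

        spec = recovery_spec()
        corpus = sample_au_corpus(spec, 5000, seed=17)
        counts = count_cooccurrence(corpus, spec.au_ids)
        cond_true, sym_true = analytic_adjacencies(spec)
        cond_emp = adjacency_conditional(counts).values
        sym_emp = adjacency_symmetric(counts).values
        assert np.abs(cond_emp - cond_true).max() < 0.03
        assert np.abs(sym_emp - sym_true).max() < 0.03

    def test_csv_round_trip(self, tmp_path):
        counts = count_cooccurrence([{"AU1", "AU2"}, {"AU1"}, {"AU2"}], ("AU1", "AU2"))
        adj = adjacency_symmetric(counts)
        path = tmp_path / "adj.csv"
        write_adjacency_csv(adj, path)
        back = read_adjacency_csv(path)
        np.testing.assert_array_equal(back.values, adj.values)
        assert back.au_ids == adj.au_ids


class TestGcnLayer:
    def test_no_edges_reduces_to_dense_relu(self):
        rng = np.random.default_rng(1)
        H = rng.normal(size=(4, 3))
        W = rng.normal(size=(3, 2))
        out = gcn_layer(H, np.zeros((4, 4)), W, renormalize=True)
        np.testing.assert_allclose(out, np.maximum(H @ W, 0.0), atol=1e-12)

    def test_two_node_hand_computation(self):
        out = gcn_layer(np.eye(2), np.array([[0.0, 1.0], [1.0, 0.0]]), np.eye(2))
        np.testing.assert_allclose(out, 0.5 * np.ones((2, 2)), atol=1e-12)

    def test_plain_variant(self):
        H = np.eye(2)
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = gcn_layer(H, A, np.eye(2), renormalize=False)
        np.testing.assert_allclose(out, A, atol=1e-12)

    def test_matches_dense_loop_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            H = rng.normal(size=(5, 4))
            A = rng.random((5, 5))
            A = (A + A.T) / 2
            W = rng.normal(size=(4, 3))
            np.testing.assert_allclose(
                gcn_layer(H, A, W), gcn_dense_oracle(H, A, W), atol=1e-10)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            H = rng.normal(size=(6, 4))
            A = rng.random((6, 6))
            A = (A + A.T) / 2
            W = rng.normal(size=(4, 3))
            perm = rng.permutation(6)
            out = gcn_layer(H, A, W)
            out_p = gcn_layer(H[perm], A[np.ix_(perm, perm)], W)
            np.testing.assert_allclose(out_p, out[perm], atol=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            gcn_layer(np.ones((3, 2)), np.eye(4), np.ones((2, 2)))


class TestSagPool:
    def test_ratio_one_keeps_everything(self):
        rng = np.random.default_rng(4)
        H = rng.normal(size=(5, 3))
        A = rng.random((5, 5))
        H2, A2, kept = sag_pool(H, A, rng.normal(size=3), p=1.0)
        np.testing.assert_array_equal(kept, np.arange(5))
        np.testing.assert_array_equal(A2, A)

    def test_half_ratio_on_twelve_nodes_keeps_six(self):
        rng = np.random.default_rng(5)
        H = rng.normal(size=(12, 4))
        A = rng.random((12, 12))
        _, _, kept = sag_pool(H, A, rng.normal(size=4), p=0.5)
        assert len(kept) == 6

    def test_top_k_by_score_with_identity_propagation(self):
        # no edges + unit feature: score is the feature itself
        H = np.array([[0.9], [0.1], [0.5]])
        _, _, kept = sag_pool(H, np.zeros((3, 3)), np.array([1.0]), p=0.5)
        np.testing.assert_array_equal(kept, [0, 2])

    def test_gating_applies_tanh_of_score(self):
        H = np.array([[2.0], [1.0]])
        H2, _, kept = sag_pool(H, np.zeros((2, 2)), np.array([1.0]), p=1.0)
        np.testing.assert_allclose(H2, H * np.tanh(H), atol=1e-12)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            sag_pool(np.zeros((0, 2)), np.zeros((0, 0)), np.ones(2), p=0.5)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            sag_pool(np.ones((2, 2)), np.eye(2), np.ones(2), p=0.0)


class TestGraphLoss:
    def test_perfect_prediction_zero(self):
        loss, _ = graph_loss(np.array([1 - 1e-12, 1e-12]), np.array([1.0, 0.0]),
                             np.array([100.0, -100.0]), 0)
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_alpha_weighting_worked_example(self):
        """L_AU = 1.0 and L_emotion = 0 under alpha = 0.7 gives loss 0.7."""
        p = np.exp(-1.0)  # -ln p = 1 for every AU term
        au_pred = np.array([p, p])
        au_truth = np.array([1.0, 1.0])
        loss, br = graph_loss(au_pred, au_truth, np.array([100.0, -100.0]), 0)
        assert br["au"] == pytest.approx(1.0, abs=1e-9)
        assert br["emotion"] == pytest.approx(0.0, abs=1e-6)
        assert loss == pytest.approx(0.7, abs=1e-4)

    def test_alpha_zero_leaves_only_emotion_term(self):
        loss, br = graph_loss(np.array([0.5]), np.array([1.0]),
                              np.array([0.0, 0.0]), 1, GraphLossConfig(alpha=0.0))
        assert loss == pytest.approx(br["emotion"], abs=1e-12)
        assert loss == pytest.approx(np.log(2.0), abs=1e-9)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            graph_loss(np.array([0.5, 0.5]), np.array([1.0]), np.array([0.0]), 0)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            GraphLossConfig(alpha=1.5)


@pytest.fixture(scope="module")
def default_net():
    rng = np.random.default_rng(6)
    A = rng.random((12, 12))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 1.0)
    adj = AdjacencyMatrix(A, symmetric=True, au_ids=AU_INVENTORY)
    return AUGraphNet(adj, feature_dim=512, seed=0), adj


class TestAUGraphNet:

    def test_default_widths_are_1024_and_512(self, default_net):
        net, _ = default_net
        assert net.W1.shape[1] == 1024
        assert net.W2.shape == (1024, 512)

    def test_output_covers_full_inventory(self, default_net):
        net, adj = default_net
        feat = np.random.default_rng(7).normal(size=512)
        au_values, emo_logits = au_gcn_forward(feat, adj, net)
        assert au_values.shape == (12,)
        assert np.all((au_values >= 0.0) & (au_values <= 1.0))
        # pooling at ratio 0.5 zeroes exactly half the nodes
        assert (au_values == 0.0).sum() == 6

    def test_forward_deterministic(self, default_net):
        net, adj = default_net
        feat = np.random.default_rng(8).normal(size=512)
        a1, e1 = au_gcn_forward(feat, adj, net)
        a2, e2 = au_gcn_forward(feat, adj, net)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(e1, e2)

    def test_node_count_mismatch_rejected(self, default_net):
        net, _ = default_net
        small = AdjacencyMatrix(np.eye(3), symmetric=True, au_ids=("AU1", "AU2", "AU4"))
        with pytest.raises(ValueError, match="nodes"):
            au_gcn_forward(np.zeros(512), small, net)


class TestCountsValidation:
    def test_asymmetric_pair_matrix_rejected(self):
        with pytest.raises(ValueError):
            CooccurrenceCounts(("AU1", "AU2"), np.array([1, 1]),
                               np.array([[1, 1], [0, 1]]))

    def test_joint_exceeding_marginal_rejected(self):
        with pytest.raises(ValueError):
            CooccurrenceCounts(("AU1", "AU2"), np.array([1, 1]),
                               np.array([[1, 2], [2, 1]]))
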