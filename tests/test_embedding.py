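"""Adversarial bidirectional embedding: shapes, losses, training behaviour."""

import numpy as np
import pytest

from fgrnet import data_io
from fgrnet.embedding import (DiscriminatorNet, EmbedConfig, GeneratorNet,
                              discriminate, discriminator_loss, edge_scores,
                              generate_fake_neighbor, generator_loss,
                              get_node_features, read_tables, train_embedding,
                              write_tables)


def chain_net(*names):
    edges = [(names[i], names[i + 1], "activation") for i in range(len(names) - 1)]
    return data_io.SignedNetwork(edges, node_ids=list(names))


@pytest.fixture
def tiny_cfg():
    return EmbedConfig(d=8, noise_dim=4, condition_dim=4, epochs=5,
                       batch_size=8, seed=0)


class TestGenerator:
    def test_pipeline_shapes_for_d64(self, rng):
        # dense output (1,512) reshaped to 16 x 32, upsampled to 16 x 64,
        # convolved down to the (64,) fake neighbor
        cfg = EmbedConfig(d=64, noise_dim=32, condition_dim=32)
        gen = GeneratorNet("source", 5, cfg, rng)
        assert gen.dense.w.value.shape[1] == 512
        out = generate_fake_neighbor(gen, [0, 1], rng.standard_normal((2, 32)))
        assert out.shape == (2, 64)

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError, match="even"):
            EmbedConfig(d=7).validate()

    def test_zero_weights_eval_output_is_conv_bias(self, rng, tiny_cfg):
        gen = GeneratorNet("source", 3, tiny_cfg, rng)
        for p in gen.params():
            p.value[...] = 0.0
        gen.conv.b.value[...] = 0.7
        gen.bn.gamma.value[...] = 1.0
        gen.conv_bn.gamma.value[...] = 1.0
        out = gen.forward(np.array([0]), np.zeros((1, 4)), training=False)
        assert np.allclose(out, 0.7, atol=1e-4)

    def test_noise_changes_output(self, rng, tiny_cfg):
        gen = GeneratorNet("source", 3, tiny_cfg, rng)
        a = generate_fake_neighbor(gen, [1], rng.standard_normal((1, 4)))
        b = generate_fake_neighbor(gen, [1], rng.standard_normal((1, 4)))
        assert not np.allclose(a, b)

    def test_deterministic_given_noise(self, rng, tiny_cfg):
        gen = GeneratorNet("source", 3, tiny_cfg, rng)
        noise = rng.standard_normal((1, 4))
        assert np.array_equal(generate_fake_neighbor(gen, [2], noise),
                              generate_fake_neighbor(gen, [2], noise))


class TestDiscriminator:
    def test_output_in_unit_interval(self, rng, tiny_cfg):
        disc = DiscriminatorNet(tiny_cfg, rng)
        s = discriminate(disc, rng.standard_normal((5, 8)), rng.standard_normal((5, 8)))
        assert ((s > 0) & (s < 1)).all()

    def test_zero_weights_give_half(self, rng, tiny_cfg):
        disc = DiscriminatorNet(tiny_cfg, rng)
        for p in disc.params():
            if not p.name.endswith("gamma"):
                p.value[...] = 0.0
        s = discriminate(disc, np.ones((2, 8)), np.ones((2, 8)))
        assert np.allclose(s, 0.5)

    def test_length_mismatch_rejected(self, rng, tiny_cfg):
        disc = DiscriminatorNet(tiny_cfg, rng)
        with pytest.raises(ValueError):
            disc.forward(np.zeros((1, 8)), np.zeros((1, 6)))


class TestLosses:
    def test_generator_loss_closed_forms(self):
        assert generator_loss([1.0] * 5, [1.0] * 5) == -10.0
        assert generator_loss([0.5] * 2, [0.5] * 2) == -2.0

    def test_generator_loss_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            generator_loss([], [])

    def test_discriminator_loss_ideal(self):
        assert discriminator_loss([1.0] * 8, [[0.0]] * 4) == -8.0

    def test_discriminator_loss_hand_sum(self):
        # real scores 0.5 on 4 edges, fake 0.5 per term on 2 nodes:
        # -4*0.5 + 4 * (2*0.5) = 2
        assert discriminator_loss([0.5] * 4, [[0.5, 0.5]] * 4) == pytest.approx(2.0)

    def test_losses_match_bruteforce_on_random_batches(self, rng):
        for _ in range(100):
            a = rng.random(rng.integers(1, 20))
            b = rng.random(rng.integers(1, 20))
            assert abs(generator_loss(a, b) - (-(sum(a) + sum(b)))) < 1e-9
            real = rng.random(rng.integers(1, 20))
            fakes = [rng.random(rng.integers(1, 20)) for _ in range(4)]
            expected = -sum(real) + sum(sum(f) for f in fakes)
            assert abs(discriminator_loss(real, fakes) - expected) < 1e-9

    def test_fake_terms_bound_loss_below(self, rng):
        real = rng.random(10)
        fakes = [rng.random(10) for _ in range(4)]
        assert discriminator_loss(real, fakes) >= -real.sum()


class TestTrainEmbedding:
    def test_chain_real_edges_outscore_non_edges(self):
        net = chain_net("a", "b", "c")
        cfg = EmbedConfig(d=8, noise_dim=4, condition_dim=4, epochs=200,
                          batch_size=4, seed=3)
        tables = train_embedding(net, cfg)
        real = edge_scores(tables, [("a", "b"), ("b", "c")])
        non = edge_scores(tables, [("b", "a"), ("c", "b"), ("c", "a"), ("a", "c")])
        assert real.mean() > non.mean()

    def test_single_edge_graph_trains_finite(self, tiny_cfg):
        net = data_io.SignedNetwork([("a", "b", "repression")])
        tables = train_embedding(net, tiny_cfg)
        assert np.isfinite(tables.s).all() and np.isfinite(tables.t).all()

    def test_isolated_node_gets_finite_rows(self, tiny_cfg):
        net = data_io.SignedNetwork([("a", "b", "activation")],
                                    node_ids=["a", "b", "loner"])
        tables = train_embedding(net, tiny_cfg)
        fs, ft = get_node_features(tables, "loner")
        assert np.isfinite(fs).all() and np.isfinite(ft).all()

    def test_zero_edge_graph_rejected(self, tiny_cfg):
        net = data_io.SignedNetwork([], node_ids=["a", "b"])
        with pytest.raises(ValueError, match="zero edges"):
            train_embedding(net, tiny_cfg)

    def test_deterministic_per_seed(self, tiny_cfg):
        net = chain_net("a", "b", "c", "d")
        t1 = train_embedding(net, tiny_cfg)
        t2 = train_embedding(net, tiny_cfg)
        assert np.array_equal(t1.s, t2.s) and np.array_equal(t1.t, t2.t)


class TestNodeFeatures:
    def test_lookup_shapes_and_purity(self, tiny_cfg):
        net = chain_net("a", "b", "c")
        tables = train_embedding(net, tiny_cfg)
        fs1, ft1 = get_node_features(tables, "b")
        fs2, ft2 = get_node_features(tables, "b")
        assert fs1.shape == (8,) and ft1.shape == (8,)
        assert np.array_equal(fs1, fs2) and np.array_equal(ft1, ft2)

    def test_distinct_genes_distinct_vectors(self, tiny_cfg):
        net = chain_net("a", "b", "c")
        tables = train_embedding(net, tiny_cfg)
        assert not np.allclose(get_node_features(tables, "a")[0],
                               get_node_features(tables, "c")[0])

    def test_unknown_gene_suggests_nearest(self, tiny_cfg):
        net = chain_net("alpha", "beta", "gamma")
        tables = train_embedding(net, tiny_cfg)
        with pytest.raises(KeyError, match="alpha"):
            get_node_features(tables, "alpa")

    def test_tables_roundtrip_tsv(self, tmp_path, tiny_cfg):
        net = chain_net("a", "b", "c")
        tables = train_embedding(net, tiny_cfg)
        write_tables(tables, tmp_path / "emb.tsv")
        back = read_tables(tmp_path / "emb.tsv")
        assert back.gene_ids == tables.gene_ids
        assert np.allclose(back.s, tables.s) and np.allclose(back.t, tables.t)


class TestLinkPrediction:
    def test_held_out_edges_outrank_random_non_edges(self):
        """On a simulated 200-node prior, D(S[u], T[v]) ranks held-out true
        edges above uniform random non-edges with AUC > 0.7."""
        from fgrnet.evaluation import auc_ovr
        from fgrnet.synthetic import SimulationConfig, simulate_network

        net = simulate_network(SimulationConfig(seed=11))
        rng = np.random.default_rng(0)
        edges = list(net.edges)
        idx = rng.permutation(len(edges))
        held = [(edges[i][0], edges[i][1]) for i in idx[:80]]
        train_net = data_io.SignedNetwork([edges[i] for i in idx[80:]],
                                          node_ids=list(net.node_ids))
        cfg = EmbedConfig(d=16, epochs=100, batch_size=64, seed=5)
        tables = train_embedding(train_net, cfg)
        edge_set = net.edge_set()
        genes = list(net.node_ids)
        neg = []
        while len(neg) < 300:
            u = genes[rng.integers(200)]
            v = genes[rng.integers(200)]
            if u != v and (u.lower(), v.lower()) not in edge_set:
                neg.append((u, v))
        pos_scores = edge_scores(tables, held)
        neg_scores = edge_scores(tables, neg)
        y = np.r_[np.ones(len(pos_scores)), np.zeros(len(neg_scores))].astype(int)
        assert auc_ovr(y, np.r_[pos_scores, neg_scores]) > 0.7


class TestDirectionSensitivity:
    def test_true_direction_scores_higher_in_majority_of_seeds(self):
        # asymmetric star digraph: hub regulates three leaves
        edges = [("hub", leaf, "activation") for leaf in ("x", "y", "z")]
        net = data_io.SignedNetwork(edges)
        wins = 0
        for seed in range(10):
            cfg = EmbedConfig(d=8, noise_dim=4, condition_dim=4, epochs=120,
                              batch_size=4, seed=seed)
            tables = train_embedding(net, cfg)
            fwd = edge_scores(tables, [("hub", leaf) for leaf in "xyz"]).mean()
            rev = edge_scores(tables, [(leaf, "hub") for leaf in "xyz"]).mean()
            wins += fwd > rev
        assert wins > 5
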