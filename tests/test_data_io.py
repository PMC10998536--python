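"""Expression/network parsing, normalization, pairing and class weights."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fgrnet import data_io
from fgrnet.data_io import (ExpressionMatrix, SignedNetwork, build_pair_samples,
                            class_weights, intersect, normalize, one_hot,
                            read_expression, read_signed_network,
                            write_expression, write_signed_network)


def make_expr(gene_ids, values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(gene_ids, values,
                            [f"s{i}" for i in range(values.shape[1])])


class TestReadExpression:
    def test_log_then_minmax(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene\ts0\ts1\ts2\ng1\t0\t1\t3\n")
        expr = read_expression(p, log_transform=True)
        # log2([0,1,3]+1) = [0,1,2] -> min-max [0, 0.5, 1]
        assert np.allclose(expr.row("g1"), [0, 0.5, 1.0])

    def test_constant_gene_maps_to_zeros(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene\ts0\ts1\ts2\ng1\t5\t5\t5\ng2\t0\t1\t2\n")
        expr = read_expression(p)
        assert np.array_equal(expr.row("g1"), np.zeros(3))

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        expr = normalize(make_expr([f"g{i}" for i in range(10)],
                                   rng.random((10, 4))))
        write_expression(expr, tmp_path / "w.tsv")
        back = read_expression(tmp_path / "w.tsv")
        assert np.abs(back.values - expr.values).max() < 1e-12
        assert back.gene_ids == expr.gene_ids

    def test_non_numeric_cell_names_location(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene\ts0\ts1\ng1\t1\tabc\n")
        with pytest.raises(ValueError, match="g1.*s1"):
            read_expression(p)

    def test_duplicate_gene_ids_rejected(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene\ts0\ng1\t1\nG1\t2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_expression(p)

    def test_negative_with_log_rejected(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene\ts0\ts1\ng1\t-1\t2\n")
        with pytest.raises(ValueError, match="negative"):
            read_expression(p, log_transform=True)

    def test_normalize_idempotent(self):
        rng = np.random.default_rng(12)
        expr = normalize(make_expr(["a", "b"], rng.random((2, 6)) * 9))
        again = normalize(expr)
        assert np.abs(again.values - expr.values).max() < 1e-12

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(13)
        expr = normalize(make_expr(["a", "b", "c"], rng.standard_normal((3, 5)) * 10))
        assert expr.values.min() >= 0.0 and expr.values.max() <= 1.0


class TestReadSignedNetwork:
    def test_dedup(self, tmp_path):
        p = tmp_path / "n.tsv"
        p.write_text("A\tB\t+\nA\tC\t-\nA\tB\t+\n")
        net = read_signed_network(p)
        assert net.n_edges == 2
        assert net.parse_stats["n_duplicates"] == 1

    def test_conflicting_signs_dropped_entirely(self, tmp_path):
        p = tmp_path / "n.tsv"
        p.write_text("A\tB\t+\nA\tB\t-\n")
        net = read_signed_network(p)
        assert net.n_edges == 0
        assert net.parse_stats["n_conflicts"] == 1

    def test_planted_conflicts_in_generated_file(self, tmp_path):
        # 100 rows, 5 pairs planted with both signs -> 90 edges survive
        rows = [f"R{i}\tT{i}\t{'+' if i % 2 else '-'}" for i in range(90)]
        for i in range(5):
            rows += [f"C{i}\tX{i}\t+", f"C{i}\tX{i}\t-"]
        p = tmp_path / "n.tsv"
        p.write_text("\n".join(rows) + "\n")
        net = read_signed_network(p)
        assert net.n_edges == 90
        assert net.parse_stats["n_conflicts"] == 5

    def test_unknown_sign_reports_line(self, tmp_path):
        p = tmp_path / "n.tsv"
        p.write_text("A\tB\t+\nA\tC\tmaybe\n")
        with pytest.raises(ValueError, match=":2"):
            read_signed_network(p)

    def test_sign_words_accepted(self, tmp_path):
        p = tmp_path / "n.tsv"
        p.write_text("A\tB\tActivation\nA\tC\tREPRESSION\n")
        net = read_signed_network(p)
        assert [e[2] for e in net.edges] == ["activation", "repression"]

    def test_self_loop_kept_and_counted(self, tmp_path):
        p = tmp_path / "n.tsv"
        p.write_text("A\tA\t+\n")
        net = read_signed_network(p)
        assert net.n_edges == 1
        assert net.parse_stats["n_self_loops"] == 1

    def test_round_trip(self, tmp_path, toy_net):
        write_signed_network(toy_net, tmp_path / "n.tsv")
        back = read_signed_network(tmp_path / "n.tsv")
        assert back.edges == toy_net.edges


class TestIntersect:
    def test_basic_set_algebra(self):
        expr = normalize(make_expr(["a", "b", "c"], np.arange(12).reshape(3, 4)))
        net = SignedNetwork([("a", "b", "activation"), ("a", "d", "repression")])
        expr2, net2 = intersect(expr, net)
        assert expr2.gene_ids == ["a", "b"]
        assert net2.n_edges == 1

    def test_identity_when_universes_match(self, toy_expr, toy_net):
        expr2, net2 = intersect(toy_expr, toy_net)
        assert expr2.gene_ids == toy_expr.gene_ids
        assert net2.edges == toy_net.edges

    def test_known_overlap_count(self):
        rng = np.random.default_rng(21)
        expr_genes = [f"g{i}" for i in range(300)]
        expr = normalize(make_expr(expr_genes, rng.random((300, 3))))
        # network over g100..g349: overlap with expression = g100..g299 -> 200
        edges = [(f"g{100 + i}", f"g{100 + (i + 1) % 250}", "activation")
                 for i in range(250)]
        net = SignedNetwork(edges)
        expr2, _ = intersect(expr, net)
        assert expr2.n_genes == 200

    def test_projection_idempotent(self, toy_expr):
        net = SignedNetwork([("TF1", "G1", "activation"), ("TF1", "zz", "repression")])
        once = intersect(toy_expr, net)
        twice = intersect(*once)
        assert twice[0].gene_ids == once[0].gene_ids
        assert twice[1].edges == once[1].edges

    def test_empty_intersection_error(self, toy_expr):
        net = SignedNetwork([("x1", "x2", "activation")])
        with pytest.raises(ValueError, match="empty"):
            intersect(toy_expr, net)


class TestOneHot:
    @pytest.mark.parametrize("label,n,expected", [
        ("activation", 3, [1, 0, 0]),
        ("repression", 3, [0, 1, 0]),
        ("non-regulation", 3, [0, 0, 1]),
        ("regulation", 2, [1, 0]),
        ("non-regulation", 2, [0, 1]),
    ])
    def test_basis_vectors(self, label, n, expected):
        assert np.array_equal(one_hot(label, n), expected)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            one_hot("activation", 2)


class TestBuildPairSamples:
    def test_counts_and_histogram(self, toy_expr, toy_net):
        net = SignedNetwork(toy_net.edges[:3])  # 2 activation + 1 repression
        samples = build_pair_samples(toy_expr, net, negative_ratio=1.0, seed=0)
        assert len(samples) == 6
        hist = {c: sum(s.label == c for s in samples) for c in data_io.CLASSES_3}
        assert hist == {"activation": 2, "repression": 1, "non-regulation": 3}

    def test_zero_ratio_only_positives(self, toy_expr, toy_net):
        samples = build_pair_samples(toy_expr, toy_net, negative_ratio=0.0, seed=0)
        assert len(samples) == toy_net.n_edges
        assert all(s.label != "non-regulation" for s in samples)

    def test_deterministic_for_seed(self, toy_expr, toy_net):
        a = build_pair_samples(toy_expr, toy_net, 1.0, seed=5)
        b = build_pair_samples(toy_expr, toy_net, 1.0, seed=5)
        assert [(s.regulator_id, s.target_id, s.label) for s in a] == \
               [(s.regulator_id, s.target_id, s.label) for s in b]

    def test_negatives_disjoint_from_positives(self, toy_expr, toy_net):
        samples = build_pair_samples(toy_expr, toy_net, 2.0, seed=3)
        pos = {(s.regulator_id, s.target_id) for s in samples
               if s.label != "non-regulation"}
        neg = {(s.regulator_id, s.target_id) for s in samples
               if s.label == "non-regulation"}
        assert not pos & neg
        assert all(r != t for r, t in neg)

    def test_pool_exhaustion_error(self, toy_expr, toy_net):
        with pytest.raises(ValueError, match="pool"):
            build_pair_samples(toy_expr, toy_net, negative_ratio=100.0, seed=0)

    def test_binary_mode_labels(self, toy_expr, toy_net):
        samples = build_pair_samples(toy_expr, toy_net, 1.0, seed=0, n_classes=2)
        assert all(len(s.y) == 2 for s in samples)
        assert {s.label for s in samples} == {"regulation", "non-regulation"}


class TestClassWeights:
    def test_balanced_counts_give_unit_weights(self, toy_expr):
        net = SignedNetwork([("a", "b", "activation"), ("a", "c", "repression")],
                            node_ids=["a", "b", "c", "d", "e"])
        expr = normalize(make_expr(["a", "b", "c", "d", "e"],
                                   np.random.default_rng(0).random((5, 5))))
        samples = build_pair_samples(expr, net, 1.0, seed=0)
        w = class_weights(samples)
        # counts (1, 1, 2) out of 4 -> weights 4/(3*1), 4/(3*1), 4/(3*2)
        assert w["activation"] == pytest.approx(4 / 3)
        assert w["non-regulation"] == pytest.approx(2 / 3)

    @given(counts=st.tuples(st.integers(1, 40), st.integers(1, 40), st.integers(1, 40)))
    @settings(max_examples=25, deadline=None)
    def test_weighted_counts_sum_to_n(self, counts):
        samples = []
        x = np.zeros(4)
        for c, k in zip(data_io.CLASSES_3, counts):
            samples += [data_io.PairSample("r", "t", x, x, c, one_hot(c, 3))] * k
        w = class_weights(samples)
        total = sum(w[c] * k for c, k in zip(data_io.CLASSES_3, counts))
        assert total == pytest.approx(sum(counts))

    def test_missing_class_error(self, toy_expr, toy_net):
        samples = build_pair_samples(toy_expr, toy_net, 0.0, seed=0)
        with pytest.raises(ValueError, match="no samples"):
            class_weights(samples)
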