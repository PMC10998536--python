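"""Bidirectional node embeddings of the prior digraph via adversarial training.

Every gene gets two trainable vectors: a source-role row in table ``S``
(how the gene looks as a regulator) and a target-role row in table ``T``
(how it looks as a target).  The tables are owned by the discriminator: a
real directed edge (u, v) is scored as ``D(S[u], T[v])``.  Two conditional
generators produce fake neighbor vectors — ``G_s(u)`` imitates the
source-role vector of a regulator of ``u`` and ``G_t(u)`` imitates the
target-role vector of a gene regulated by ``u``.  The discriminator is
pushed to score real edges high and the four fake pairings
(G_s(u), T[u]), (S[u], G_t(u)), (G_s(v), T[v]), (S[v], G_t(v)) low; the
generators are pushed the opposite way.  Sign labels are ignored here —
only edge presence and direction are embedded.

The reported objectives (:func:`generator_loss`, :func:`discriminator_loss`)
are plain sums of discriminator outputs.  Taken literally as *training*
objectives, those sums admit a degenerate optimum: since the fake terms
outnumber the real term four to one, a discriminator that scores every
pair as fake reaches loss 3mc, minimized by a constant output c -> 0,
where sigmoid saturation then kills all gradients — observed reliably on
benchmark-sized graphs.  Training therefore defaults to the standard
logarithmic GAN objective (log-loss for the discriminator, non-saturating
generator), whose optimum coincides with the intended real/fake
separation and which penalizes the constant collapse unboundedly.
``loss_form="literal"`` restores the sum-form training signal, and a
``wgan_strict`` flag removes the sigmoid and clips discriminator weights
instead, for experimentation.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from .data_io import SignedNetwork, _canon

logger = logging.getLogger(__name__)


@dataclass
class EmbedConfig:
    d: int = 64                 # embedding dimension (even)
    noise_dim: int = 32
    condition_dim: int = 32
    epochs: int = 50
    batch_size: int = 64
    lr: float = 2e-4
    k_d: int = 1                # discriminator steps per generator step
    #: "log": saturating-log discriminator loss with non-saturating
    #: generator loss (default; see module docstring).  "literal": plain
    #: sum-form objectives, matching generator_loss / discriminator_loss.
    loss_form: str = "log"
    wgan_strict: bool = False
    clip_value: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.d % 2 != 0 or self.d < 2:
            raise ValueError(
                f"embedding dimension must be even (reshape to ({self.d // 2},16) "
                "is impossible otherwise)")
        if min(self.noise_dim, self.condition_dim, self.epochs, self.batch_size,
               self.k_d) < 1:
            raise ValueError("noise_dim, condition_dim, epochs, batch_size, k_d must be >= 1")


class EmbeddingTables:
    """Per-gene source-role (S) and target-role (T) embedding tables."""

    def __init__(self, gene_ids: list[str], s: np.ndarray, t: np.ndarray) -> None:
        if s.shape != t.shape or s.shape[0] != len(gene_ids):
            raise ValueError("table shapes must be (|V|, d) for both roles")
        self.gene_ids = list(gene_ids)
        self.s = np.asarray(s, dtype=np.float64)
        self.t = np.asarray(t, dtype=np.float64)
        self._index = {_canon(g): i for i, g in enumerate(gene_ids)}

    @property
    def d(self) -> int:
        return self.s.shape[1]

    def index(self, gene: str) -> int:
        key = _canon(gene)
        if key not in self._index:
            close = difflib.get_close_matches(key, self._index, n=1)
            hint = f"; did you mean {close[0]!r}?" if close else ""
            raise KeyError(f"unknown gene {gene!r}{hint}")
        return self._index[key]

    def __contains__(self, gene: str) -> bool:
        return _canon(gene) in self._index


def get_node_features(tables: EmbeddingTables, gene: str) -> tuple[np.ndarray, np.ndarray]:
    """Source-role and target-role embedding rows of a gene."""
    i = tables.index(gene)
    return tables.s[i].copy(), tables.t[i].copy()


def write_tables(tables: EmbeddingTables, path) -> None:
    with open(path, "w") as fh:
        cols = "\t".join(f"e{j}" for j in range(tables.d))
        fh.write(f"gene\trole\t{cols}\n")
        for role, mat in (("source", tables.s), ("target", tables.t)):
            for g, row in zip(tables.gene_ids, mat):
                vals = "\t".join(f"{v:.17g}" for v in row)
                fh.write(f"{g}\t{role}\t{vals}\n")


def read_tables(path) -> EmbeddingTables:
    import pandas as pd
    df = pd.read_csv(path, sep="\t")
    src = df[df["role"] == "source"]
    tgt = df[df["role"] == "target"]
    genes = list(src["gene"].astype(str))
    vals = df.columns[2:]
    return EmbeddingTables(genes, src[vals].to_numpy(float), tgt[vals].to_numpy(float))


class GeneratorNet:
    """Conditional fake-neighbor generator (one per role).

    concat(condition[gene], noise) -> dense(8d) -> BN -> LeakyReLU ->
    reshape (16, d/2) -> nearest upsample x2 -> conv block -> (1, d) ->
    flatten.  The learned per-node condition vector is what lets a single
    generator produce node-specific neighbors.
    """

    def __init__(self, role: str, n_nodes: int, cfg: EmbedConfig,
                 rng: np.random.Generator) -> None:
        cfg.validate()
        self.role = role
        self.cfg = cfg
        d = cfg.d
        self.condition = nn.Param(
            rng.normal(0.0, 0.1, size=(n_nodes, cfg.condition_dim)), f"gen.{role}.cond")
        self.dense = nn.Dense(cfg.condition_dim + cfg.noise_dim, 8 * d, rng)
        self.bn = nn.BatchNorm1d(8 * d)
        self.act = nn.LeakyReLU()
        self.up = nn.Upsample1d(2)
        self.conv = nn.Conv1d(16, 1, 3, rng)
        self.conv_bn = nn.BatchNorm1d(1)
        self.conv_act = nn.LeakyReLU()

    def params(self):
        return ([self.condition] + self.dense.params() + self.bn.params()
                + self.conv.params() + self.conv_bn.params())

    def forward(self, node_idx: np.ndarray, noise: np.ndarray,
                training: bool = False) -> np.ndarray:
        d = self.cfg.d
        self._node_idx = node_idx
        h = np.concatenate([self.condition.value[node_idx], noise], axis=1)
        h = self.dense.forward(h, training=training)
        h = self.bn.forward(h, training=training)
        h = self.act.forward(h, training=training)
        h = h.reshape(h.shape[0], 16, d // 2)
        h = self.up.forward(h, training=training)
        h = self.conv.forward(h, training=training)
        h = self.conv_bn.forward(h, training=training)
        h = self.conv_act.forward(h, training=training)
        return h[:, 0, :]

    def backward(self, dy: np.ndarray) -> None:
        d = self.cfg.d
        dh = self.conv_act.backward(dy[:, None, :])
        dh = self.conv_bn.backward(dh)
        dh = self.conv.backward(dh)
        dh = self.up.backward(dh)
        dh = dh.reshape(dh.shape[0], 8 * d)
        dh = self.act.backward(dh)
        dh = self.bn.backward(dh)
        dh = self.dense.backward(dh)
        np.add.at(self.condition.grad, self._node_idx,
                  dh[:, : self.cfg.condition_dim])


def generate_fake_neighbor(gen: GeneratorNet, node_idx, noise: np.ndarray,
                           training: bool = False) -> np.ndarray:
    """Fake neighbor embeddings for the given node indices."""
    node_idx = np.atleast_1d(np.asarray(node_idx, dtype=int))
    noise = np.atleast_2d(np.asarray(noise, dtype=np.float64))
    if noise.shape != (len(node_idx), gen.cfg.noise_dim):
        raise ValueError(f"noise must have shape ({len(node_idx)}, {gen.cfg.noise_dim})")
    return gen.forward(node_idx, noise, training=training)


class DiscriminatorNet:
    """Scores a (source-role, target-role) vector pair as real or fake.

    concat -> two conv blocks (conv -> BN -> LeakyReLU) -> two dense
    layers -> sigmoid (omitted under ``wgan_strict``).
    """

    def __init__(self, cfg: EmbedConfig, rng: np.random.Generator) -> None:
        self.cfg = cfg
        self.conv1 = nn.Conv1d(1, 8, 3, rng)
        self.bn1 = nn.BatchNorm1d(8)
        self.act1 = nn.LeakyReLU()
        self.conv2 = nn.Conv1d(8, 16, 3, rng)
        self.bn2 = nn.BatchNorm1d(16)
        self.act2 = nn.LeakyReLU()
        self.flat = nn.Flatten()
        self.dense1 = nn.Dense(16 * 2 * cfg.d, 32, rng)
        self.act3 = nn.LeakyReLU()
        self.dense2 = nn.Dense(32, 1, rng)
        self.sigmoid = nn.Sigmoid()

    def params(self):
        return (self.conv1.params() + self.bn1.params() + self.conv2.params()
                + self.bn2.params() + self.dense1.params() + self.dense2.params())

    def forward(self, left: np.ndarray, right: np.ndarray,
                training: bool = False) -> np.ndarray:
        left = np.atleast_2d(left)
        right = np.atleast_2d(right)
        if left.shape != right.shape or left.shape[1] != self.cfg.d:
            raise ValueError(
                f"discriminator inputs must both be (N, {self.cfg.d}); "
                f"got {left.shape} and {right.shape}")
        x = np.concatenate([left, right], axis=1)[:, None, :]
        h = self.act1.forward(self.bn1.forward(self.conv1.forward(x, training), training))
        h = self.act2.forward(self.bn2.forward(self.conv2.forward(h, training), training))
        h = self.flat.forward(h)
        h = self.act3.forward(self.dense1.forward(h, training))
        logits = self.dense2.forward(h, training)
        if self.cfg.wgan_strict:
            return logits[:, 0]
        return self.sigmoid.forward(logits)[:, 0]

    def backward(self, dscore: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dy = np.asarray(dscore, dtype=np.float64)[:, None]
        if not self.cfg.wgan_strict:
            dy = self.sigmoid.backward(dy)
        dh = self.dense1.backward(self.act3.backward(self.dense2.backward(dy)))
        dh = self.flat.backward(dh)
        dh = self.conv2.backward(self.bn2.backward(self.act2.backward(dh)))
        dx = self.conv1.backward(self.bn1.backward(self.act1.backward(dh)))
        dx = dx[:, 0, :]
        d = self.cfg.d
        return dx[:, :d], dx[:, d:]


def discriminate(disc: DiscriminatorNet, left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Probability (or raw critic score under ``wgan_strict``) that a pair is real."""
    return disc.forward(left, right, training=False)


def generator_loss(disc_scores_source, disc_scores_target) -> float:
    """Sum-form generator objective: minus the summed fooled-discriminator scores."""
    a = np.asarray(disc_scores_source, dtype=np.float64)
    b = np.asarray(disc_scores_target, dtype=np.float64)
    if a.size == 0 and b.size == 0:
        raise ValueError("empty score batch")
    return float(-(a.sum() + b.sum()))


def discriminator_loss(real_scores, fake_scores_by_term) -> float:
    """Sum-form discriminator objective: -sum(real) + sum of the four fake terms."""
    real = np.asarray(real_scores, dtype=np.float64)
    if real.size == 0:
        raise ValueError("empty real-score batch")
    if len(fake_scores_by_term) != 4:
        raise ValueError("expected four fake-score lists")
    total = -real.sum()
    for term in fake_scores_by_term:
        total += np.asarray(term, dtype=np.float64).sum()
    return float(total)


def _clip(params, value):
    for p in params:
        np.clip(p.value, -value, value, out=p.value)


def train_embedding(net: SignedNetwork, cfg: EmbedConfig) -> EmbeddingTables:
    """Alternating adversarial training of tables, generators and discriminator.

    The node universe is ``net.node_ids``; genes without training edges keep
    their (finite) initialization plus whatever the fake terms teach about
    them.  Deterministic for a fixed seed.
    """
    cfg.validate()
    if net.n_edges == 0:
        raise ValueError("cannot train an embedding on a graph with zero edges")
    rng = np.random.default_rng(cfg.seed)
    genes = list(net.node_ids)
    index = {_canon(g): i for i, g in enumerate(genes)}
    n = len(genes)
    edges = np.array([[index[_canon(r)], index[_canon(t)]] for r, t, _ in net.edges])

    s_tab = nn.Param(rng.normal(0.0, 0.1, size=(n, cfg.d)), "tables.S")
    t_tab = nn.Param(rng.normal(0.0, 0.1, size=(n, cfg.d)), "tables.T")
    gen_s = GeneratorNet("source", n, cfg, rng)
    gen_t = GeneratorNet("target", n, cfg, rng)
    disc = DiscriminatorNet(cfg, rng)

    opt_d = nn.Adam(disc.params() + [s_tab, t_tab], lr=cfg.lr)
    opt_g = nn.Adam(gen_s.params() + gen_t.params(), lr=cfg.lr)

    def noise(m):
        return rng.standard_normal((m, cfg.noise_dim))

    eps = 1e-6
    use_log = cfg.loss_form == "log" and not cfg.wgan_strict

    def d_real(score):   # dL/dscore for a real-pair term
        return -1.0 / np.maximum(score, eps) if use_log else -np.ones_like(score)

    def d_fake(score):   # dL/dscore for a fake-pair term
        return 1.0 / np.maximum(1.0 - score, eps) if use_log else np.ones_like(score)

    def d_gen(score):    # dL/dscore for the (non-saturating) generator
        return -1.0 / np.maximum(score, eps) if use_log else -np.ones_like(score)

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(edges))
        d_losses, g_losses = [], []
        for start in range(0, len(edges), cfg.batch_size):
            batch = edges[order[start:start + cfg.batch_size]]
            u, v = batch[:, 0], batch[:, 1]
            m = len(u)

            for _ in range(cfg.k_d):
                opt_d.zero_grad()
                real = disc.forward(s_tab.value[u], t_tab.value[v], training=True)
                dl, dr = disc.backward(d_real(real))
                np.add.at(s_tab.grad, u, dl)
                np.add.at(t_tab.grad, v, dr)
                fake_terms = []
                for node, fake_role in ((u, "s"), (u, "t"), (v, "s"), (v, "t")):
                    if fake_role == "s":
                        fake = gen_s.forward(node, noise(m), training=True)
                        score = disc.forward(fake, t_tab.value[node], training=True)
                        _, dr = disc.backward(d_fake(score))
                        np.add.at(t_tab.grad, node, dr)
                    else:
                        fake = gen_t.forward(node, noise(m), training=True)
                        score = disc.forward(s_tab.value[node], fake, training=True)
                        dl, _ = disc.backward(d_fake(score))
                        np.add.at(s_tab.grad, node, dl)
                    fake_terms.append(score)
                d_losses.append(discriminator_loss(real, fake_terms))
                opt_d.step()
                if cfg.wgan_strict:
                    _clip(disc.params() + [s_tab, t_tab], cfg.clip_value)

            opt_g.zero_grad()
            fake_s = gen_s.forward(u, noise(m), training=True)
            score_s = disc.forward(fake_s, t_tab.value[u], training=True)
            dl, _ = disc.backward(d_gen(score_s))
            gen_s.backward(dl)
            fake_t = gen_t.forward(v, noise(m), training=True)
            score_t = disc.forward(s_tab.value[v], fake_t, training=True)
            _, dr = disc.backward(d_gen(score_t))
            gen_t.backward(dr)
            g_losses.append(generator_loss(score_s, score_t))
            opt_g.step()
        logger.debug("embedding epoch %d: L_D=%.4f L_G=%.4f",
                     epoch, float(np.mean(d_losses)), float(np.mean(g_losses)))

    tables = EmbeddingTables(genes, s_tab.value, t_tab.value)
    tables.discriminator = disc  # kept for link scoring / diagnostics
    return tables


def edge_scores(tables: EmbeddingTables, pairs: list[tuple[str, str]]) -> np.ndarray:
    """D(S[u], T[v]) for (u, v) pairs, using the discriminator trained alongside."""
    disc = getattr(tables, "discriminator", None)
    if disc is None:
        raise ValueError("these tables carry no trained discriminator")
    left = np.stack([tables.s[tables.index(u)] for u, _ in pairs])
    right = np.stack([tables.t[tables.index(v)] for _, v in pairs])
    return disc.forward(left, right, training=False)
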