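"""Synthetic signed GRNs and matching expression profiles.

The generator emulates the two structural facts the inference method leans
on: (1) real regulatory networks are sparse directed graphs whose
out-degree mass sits on a small regulator subset, and (2) expression of an
activator-target pair co-varies positively while a repressor-target pair
co-varies negatively.

The expression model is linear-Gaussian: each regulator has an exogenous
standard-normal activity per sample; a regulated gene is the signed,
weighted sum of its regulators' activities plus independent Gaussian noise.
For a single edge with weight w and noise s.d. sigma this gives the
closed-form |Pearson correlation| = w / sqrt(w^2 + sigma^2), which the test
suite uses as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import (ACTIVATION, REPRESSION, ExpressionMatrix, SignedNetwork,
                      normalize)


@dataclass
class SimulationConfig:
    n_genes: int = 200
    n_regulators: int = 20
    n_edges: int = 400
    frac_activation: float = 0.5
    n_samples: int = 100
    noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_regulators < 1 or self.n_edges < 1:
            raise ValueError("n_genes, n_regulators and n_edges must be positive")
        if self.n_regulators > self.n_genes:
            raise ValueError("n_regulators cannot exceed n_genes")
        if self.n_edges > self.n_regulators * (self.n_genes - self.n_regulators):
            raise ValueError("n_edges exceeds the number of possible regulator->target pairs")
        if not 0.0 <= self.frac_activation <= 1.0:
            raise ValueError("frac_activation must be in [0, 1]")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{i:0{width}d}" for i in range(n)]


def simulate_network(cfg: SimulationConfig) -> SignedNetwork:
    """Sparse signed digraph with preferential-attachment regulator out-degrees.

    The first ``n_regulators`` genes are the only edge sources; regulators
    are exogenous, so targets are drawn from the non-regulator genes only
    (no regulator-on-regulator edges), keeping expression generation
    single-pass.  Each edge picks its regulator proportionally to
    (current out-degree + 1), giving a heavy-tailed out-degree profile
    over the regulator subset, and a uniform target.  No duplicates.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)
    regulators = genes[: cfg.n_regulators]
    out_deg = np.zeros(cfg.n_regulators)
    taken: set[tuple[int, int]] = set()
    edges: list[tuple[str, str, str]] = []
    while len(edges) < cfg.n_edges:
        weights = out_deg + 1.0
        r = int(rng.choice(cfg.n_regulators, p=weights / weights.sum()))
        t = int(rng.integers(cfg.n_regulators, cfg.n_genes))
        if (r, t) in taken:
            continue
        taken.add((r, t))
        out_deg[r] += 1
        sign = ACTIVATION if rng.random() < cfg.frac_activation else REPRESSION
        edges.append((regulators[r], genes[t], sign))
    return SignedNetwork(edges, node_ids=genes)


def simulate_expression(net: SignedNetwork, cfg: SimulationConfig) -> ExpressionMatrix:
    """Linear-Gaussian expression for a simulated network, min-max normalized.

    Regulators carry exogenous standard-normal activity; a regulated gene
    is the signed weighted sum of its regulators' activities plus noise.
    Edge weights are Uniform(0.5, 1.5).  Min-max scaling is a positive
    affine map per gene, so Pearson correlations are unchanged by it.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    genes = list(net.node_ids)
    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    activity = rng.standard_normal((n, cfg.n_samples))  # exogenous activity per gene
    values = np.zeros((n, cfg.n_samples))
    incoming: dict[int, list[tuple[int, float]]] = {}
    for r, t, s in net.edges:
        w = rng.uniform(0.5, 1.5) * (1.0 if s == ACTIVATION else -1.0)
        incoming.setdefault(index[t], []).append((index[r], w))
    for i in range(n):
        if i in incoming:
            for j, w in incoming[i]:
                values[i] += w * activity[j]
            values[i] += rng.normal(0.0, cfg.noise_sd, size=cfg.n_samples)
        else:
            values[i] = activity[i]
    expr = ExpressionMatrix(genes, values, [f"s{k}" for k in range(cfg.n_samples)])
    return normalize(expr)


def simulate(cfg: SimulationConfig) -> tuple[SignedNetwork, ExpressionMatrix]:
    net = simulate_network(cfg)
    return net, simulate_expression(net, cfg)
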