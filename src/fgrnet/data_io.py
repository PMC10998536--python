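"""Reading, normalizing and pairing expression profiles with prior signed networks.

Expression files are tab-separated with a header row of sample names and
gene identifiers in the first column.  Prior networks are 3-column TSV
``regulator<TAB>target<TAB>sign``.  Gene identifiers are matched
case-insensitively with surrounding whitespace stripped, because symbol
casing is inconsistent across the curation databases these files come from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ACTIVATION = "activation"
REPRESSION = "repression"
NON_REGULATION = "non-regulation"
REGULATION = "regulation"

#: Fixed class orders for one-hot labels.
CLASSES_3 = (ACTIVATION, REPRESSION, NON_REGULATION)
CLASSES_2 = (REGULATION, NON_REGULATION)

_SIGN_TOKENS = {
    "+": ACTIVATION,
    "-": REPRESSION,
    "activation": ACTIVATION,
    "repression": REPRESSION,
}


def _canon(gene: str) -> str:
    return gene.strip().casefold()


@dataclass
class ExpressionMatrix:
    """A genes x samples real matrix with a gene-ID index."""

    gene_ids: list[str]
    values: np.ndarray  # (numG, dimE)
    sample_ids: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D (genes x samples)")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length does not match row count")
        canon = [_canon(g) for g in self.gene_ids]
        if len(set(canon)) != len(canon):
            dupes = sorted({g for g in canon if canon.count(g) > 1})
            raise ValueError(f"duplicate gene IDs after case-folding: {dupes}")
        self._index = {c: i for i, c in enumerate(canon)}

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def row(self, gene: str) -> np.ndarray:
        key = _canon(gene)
        if key not in self._index:
            raise KeyError(f"unknown gene {gene!r}")
        return self.values[self._index[key]]

    def __contains__(self, gene: str) -> bool:
        return _canon(gene) in self._index


def normalize(expr: ExpressionMatrix, log_transform: bool = False) -> ExpressionMatrix:
    """log2(x+1) (optional) followed by per-gene min-max scaling to [0, 1].

    Constant genes map to the all-zero vector: a flat profile carries no
    information and zeroing it avoids a divide-by-zero deterministically.
    Idempotent on already-normalized data up to floating point.
    """
    x = expr.values.copy()
    if log_transform:
        if (x < 0).any():
            raise ValueError("negative expression values are incompatible with log2(x+1)")
        x = np.log2(x + 1.0)
    lo = x.min(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    span = hi - lo
    flat = span[:, 0] == 0
    span[flat] = 1.0
    x = (x - lo) / span
    x[flat] = 0.0
    return ExpressionMatrix(list(expr.gene_ids), x, list(expr.sample_ids), normalized=True)


def read_expression(path, log_transform: bool = False) -> ExpressionMatrix:
    """Read a TSV expression matrix and normalize it (see :func:`normalize`)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = np.argwhere(numeric.isna().values)[0]
        raise ValueError(
            f"non-numeric expression value at gene {df.index[bad[0]]!r}, "
            f"sample {df.columns[bad[1]]!r} in {path}")
    expr = ExpressionMatrix(
        [str(g) for g in df.index], numeric.values.astype(np.float64),
        [str(c) for c in df.columns])
    return normalize(expr, log_transform=log_transform)


def write_expression(expr: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.17g")


@dataclass
class SignedNetwork:
    """Directed signed edge list; regulators are the nodes with out-degree >= 1."""

    edges: list[tuple[str, str, str]]
    node_ids: list[str] = field(default_factory=list)
    parse_stats: dict | None = None

    def __post_init__(self) -> None:
        seen = set()
        for e in self.edges:
            key = (_canon(e[0]), _canon(e[1]), e[2])
            if key in seen:
                raise ValueError(f"duplicate edge triple {e}")
            if e[2] not in (ACTIVATION, REPRESSION):
                raise ValueError(f"invalid sign {e[2]!r}")
            seen.add(key)
        induced = []
        seen_nodes = set()
        for r, t, _ in self.edges:
            for g in (r, t):
                if _canon(g) not in seen_nodes:
                    seen_nodes.add(_canon(g))
                    induced.append(g)
        if not self.node_ids:
            self.node_ids = induced
        else:
            have = {_canon(g) for g in self.node_ids}
            missing = [g for g in induced if _canon(g) not in have]
            if missing:
                raise ValueError(f"edge endpoints outside node_ids: {missing}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def regulators(self) -> list[str]:
        seen, out = set(), []
        for r, _, _ in self.edges:
            if _canon(r) not in seen:
                seen.add(_canon(r))
                out.append(r)
        return out

    def edge_set(self) -> set[tuple[str, str]]:
        return {(_canon(r), _canon(t)) for r, t, _ in self.edges}

    def out_degrees(self) -> dict[str, int]:
        deg = {_canon(g): 0 for g in self.node_ids}
        for r, _, _ in self.edges:
            deg[_canon(r)] += 1
        return deg

    def in_degrees(self) -> dict[str, int]:
        deg = {_canon(g): 0 for g in self.node_ids}
        for _, t, _ in self.edges:
            deg[_canon(t)] += 1
        return deg


def read_signed_network(path) -> SignedNetwork:
    """Parse a signed edge list, deduplicating and dropping sign conflicts.

    A (regulator, target) pair recorded with *both* signs is removed
    entirely — a 3-class label cannot represent dual regulation, and
    silently keeping one sign would bias the classes.  Duplicate and
    conflicting rows are counted in ``parse_stats`` and logged.
    """
    rows: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            reg, tgt, sign_tok = (p.strip() for p in parts)
            sign = _SIGN_TOKENS.get(sign_tok.casefold())
            if sign is None:
                raise ValueError(f"{path}:{lineno}: unknown sign token {sign_tok!r}")
            rows.append((reg, tgt, sign))

    n_dupes = 0
    uniq: list[tuple[str, str, str]] = []
    seen = set()
    for r, t, s in rows:
        key = (_canon(r), _canon(t), s)
        if key in seen:
            n_dupes += 1
            continue
        seen.add(key)
        uniq.append((r, t, s))

    signs_by_pair: dict[tuple[str, str], set[str]] = {}
    for r, t, s in uniq:
        signs_by_pair.setdefault((_canon(r), _canon(t)), set()).add(s)
    conflicted = {p for p, ss in signs_by_pair.items() if len(ss) > 1}
    edges = [(r, t, s) for r, t, s in uniq if (_canon(r), _canon(t)) not in conflicted]

    n_self = sum(1 for r, t, _ in edges if _canon(r) == _canon(t))
    if n_dupes:
        logger.warning("%s: dropped %d duplicate edge rows", path, n_dupes)
    if conflicted:
        logger.warning("%s: dropped %d gene pairs recorded with both signs", path, len(conflicted))
    if n_self:
        logger.info("%s: %d self-loop edges kept", path, n_self)
    stats = {"n_rows": len(rows), "n_duplicates": n_dupes,
             "n_conflicts": len(conflicted), "n_self_loops": n_self}
    return SignedNetwork(edges, parse_stats=stats)


def write_signed_network(net: SignedNetwork, path) -> None:
    with open(path, "w") as fh:
        for r, t, s in net.edges:
            fh.write(f"{r}\t{t}\t{s}\n")


def intersect(expr: ExpressionMatrix, net: SignedNetwork) -> tuple[ExpressionMatrix, SignedNetwork]:
    """Restrict both inputs to the shared gene universe (case-folded match)."""
    expr_genes = {_canon(g) for g in expr.gene_ids}
    net_genes = {_canon(g) for g in net.node_ids}
    common = expr_genes & net_genes
    if not common:
        raise ValueError("empty intersection between expression genes and network nodes")
    keep_rows = [i for i, g in enumerate(expr.gene_ids) if _canon(g) in common]
    expr2 = ExpressionMatrix(
        [expr.gene_ids[i] for i in keep_rows], expr.values[keep_rows],
        list(expr.sample_ids), normalized=expr.normalized)
    edges = [e for e in net.edges if _canon(e[0]) in common and _canon(e[1]) in common]
    nodes = [g for g in net.node_ids if _canon(g) in common]
    net2 = SignedNetwork(edges, node_ids=nodes)
    n_act = sum(1 for e in edges if e[2] == ACTIVATION)
    logger.info("intersect: numG=%d, edges=%d (numA=%d, numR=%d)",
                len(keep_rows), len(edges), n_act, len(edges) - n_act)
    return expr2, net2


def one_hot(label: str, n_classes: int) -> np.ndarray:
    """Unit basis vector for a class label; class order is fixed."""
    classes = {2: CLASSES_2, 3: CLASSES_3}.get(n_classes)
    if classes is None:
        raise ValueError("n_classes must be 2 or 3")
    if label not in classes:
        raise ValueError(f"unknown label {label!r} for {n_classes}-class mode")
    v = np.zeros(n_classes)
    v[classes.index(label)] = 1.0
    return v


@dataclass
class PairSample:
    """One (regulator, target) instance with its expression vectors and label."""

    regulator_id: str
    target_id: str
    x_r: np.ndarray
    x_t: np.ndarray
    label: str
    y: np.ndarray  # one-hot

    def __post_init__(self) -> None:
        if len(self.x_r) != len(self.x_t):
            raise ValueError("x_r and x_t must have equal length")
        if self.y.sum() != 1.0 or ((self.y != 0) & (self.y != 1)).any():
            raise ValueError("label vector must be one-hot")


def build_pair_samples(expr: ExpressionMatrix, net: SignedNetwork,
                       negative_ratio: float = 1.0, seed: int = 0,
                       n_classes: int = 3) -> list[PairSample]:
    """Positive samples from signed edges plus sampled non-regulation pairs.

    Negatives are drawn uniformly without replacement from
    ``{(r, t): r a known regulator, t in V, (r, t) not an edge, r != t}``,
    anchoring the first element on known regulators to match the
    regulator->target framing of the task.  Deterministic for a fixed seed.
    """
    if negative_ratio < 0:
        raise ValueError("negative_ratio must be non-negative")
    samples: list[PairSample] = []
    for r, t, s in net.edges:
        label = s if n_classes == 3 else REGULATION
        samples.append(PairSample(r, t, expr.row(r), expr.row(t), label,
                                  one_hot(label, n_classes)))
    n_neg = round(negative_ratio * len(samples))
    if n_neg:
        edge_set = net.edge_set()
        regulators = sorted(net.regulators, key=_canon)
        nodes = sorted(net.node_ids, key=_canon)
        pool = [(r, t) for r in regulators for t in nodes
                if _canon(r) != _canon(t) and (_canon(r), _canon(t)) not in edge_set]
        if len(pool) < n_neg:
            raise ValueError(
                f"negative candidate pool has {len(pool)} pairs but {n_neg} were requested")
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pool), size=n_neg, replace=False)
        for i in sorted(idx):
            r, t = pool[i]
            samples.append(PairSample(r, t, expr.row(r), expr.row(t), NON_REGULATION,
                                      one_hot(NON_REGULATION, n_classes)))
    return samples


def class_weights(samples: list[PairSample]) -> dict[str, float]:
    """Inverse-frequency ("balanced") class weights: N / (n_classes * count_c)."""
    if not samples:
        raise ValueError("no samples")
    n_classes = len(samples[0].y)
    classes = {2: CLASSES_2, 3: CLASSES_3}[n_classes]
    counts = {c: 0 for c in classes}
    for s in samples:
        counts[s.label] += 1
    missing = [c for c, n in counts.items() if n == 0]
    if missing:
        raise ValueError(f"classes with no samples: {missing}")
    n = len(samples)
    return {c: n / (n_classes * counts[c]) for c in classes}


def write_pair_samples(samples: list[PairSample], path) -> None:
    with open(path, "w") as fh:
        for s in samples:
            fh.write(f"{s.regulator_id}\t{s.target_id}\t{s.label}\n")
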