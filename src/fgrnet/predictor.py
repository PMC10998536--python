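"""Pair classifier: feature assembly, conv+dense softmax head, and training.

A (regulator, target) pair is described by up to three feature families:

* ``corr`` — the Cnet correlation embedding of the pair's expression
  profiles (the default expression feature);
* ``expr`` — the per-gene residual-CNN features (global-average-pooled and
  densely projected), used by the expression-only ablation;
* ``blr`` — the four frozen bidirectional embedding rows
  (source/target role of regulator and of target).

The concatenated feature vector is treated as a one-channel sequence and
classified by conv -> ReLU -> BatchNorm -> MaxPool -> dense -> dense ->
softmax.  Embedding tables are pre-trained and stay frozen; the residual
extractor, Cnet and head train jointly with Adam under class-weighted
cross-entropy, with early stopping on a stratified validation split.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import train_test_split

from . import nn
from .correlation import Cnet, CnetConfig, ResidualExtractor, ResidualExtractorConfig
from .data_io import CLASSES_2, CLASSES_3, PairSample, class_weights
from .embedding import EmbedConfig, EmbeddingTables, train_embedding

logger = logging.getLogger(__name__)

VALID_FEATURES = ("corr", "expr", "blr")


@dataclass
class HeadConfig:
    channels: int = 64
    kernel_size: int = 3
    pool_size: int = 2
    hidden_dim: int = 64


@dataclass
class PredictorConfig:
    extractor: ResidualExtractorConfig = field(default_factory=ResidualExtractorConfig)
    cnet: CnetConfig = field(default_factory=CnetConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    features: tuple[str, ...] = ("corr", "blr")
    n_classes: int = 3
    embed_dim: int = 64        # must match the tables handed to the model
    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    val_fraction: float = 0.1
    #: Shuffle the sample axis (consistently for both genes of a pair) per
    #: training batch.  A shared permutation preserves a pair's correlation
    #: structure, but it also removes the position-specific cues the
    #: flatten-dense pair head relies on, so this is off by default.
    augment_sample_permutation: bool = False
    #: "constant" or "cosine" (anneal to lr/10 over max_epochs).
    lr_schedule: str = "cosine"
    #: Early-stopping monitor: "loss" (weighted val cross-entropy) or
    #: "auc" (val macro one-vs-rest AUC, the headline metric).
    early_stop_metric: str = "loss"
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")
        bad = [f for f in self.features if f not in VALID_FEATURES]
        if bad or not self.features:
            raise ValueError(f"features must be a non-empty subset of {VALID_FEATURES}")


def assemble_features(corr: np.ndarray | None,
                      f_r: tuple[np.ndarray, np.ndarray] | None,
                      f_t: tuple[np.ndarray, np.ndarray] | None) -> np.ndarray:
    """Concatenate (corr, F_source^R, F_target^R, F_source^T, F_target^T)."""
    named = {"correlation embedding": corr,
             "regulator embedding pair": f_r,
             "target embedding pair": f_t}
    for name, val in named.items():
        if val is None:
            raise ValueError(f"missing feature component: {name}")
    parts = [np.asarray(corr, dtype=np.float64).ravel()]
    for pair in (f_r, f_t):
        parts.append(np.asarray(pair[0], dtype=np.float64).ravel())
        parts.append(np.asarray(pair[1], dtype=np.float64).ravel())
    out = np.concatenate(parts)
    if not np.isfinite(out).all():
        raise ValueError("non-finite feature component")
    return out


class PredictionHead:
    """conv -> ReLU -> BatchNorm -> MaxPool -> dense -> dense -> softmax."""

    def __init__(self, in_dim: int, config: HeadConfig, n_classes: int,
                 rng: np.random.Generator) -> None:
        self.config = config
        self.in_dim = in_dim
        self.n_classes = n_classes
        pooled = -(-in_dim // config.pool_size)
        self.body = nn.Sequential(
            nn.Conv1d(1, config.channels, config.kernel_size, rng),
            nn.ReLU(),
            nn.BatchNorm1d(config.channels),
            nn.MaxPool1d(config.pool_size),
            nn.Flatten(),
            nn.Dense(config.channels * pooled, config.hidden_dim, rng),
            nn.ReLU(),
        )
        self.out = nn.Dense(config.hidden_dim, n_classes, rng)

    def params(self):
        return self.body.params() + self.out.params()

    def forward(self, features: np.ndarray, training: bool = False) -> np.ndarray:
        """Feature matrix (N, F) -> class probabilities (N, n_classes)."""
        features = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if not np.isfinite(features).all():
            raise ValueError("NaN or infinite value in pair features")
        h = self.body.forward(features[:, None, :], training=training)
        self._logits = self.out.forward(h, training=training)
        return nn.softmax(self._logits)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dh = self.out.backward(dlogits)
        return self.body.backward(dh)[:, 0, :]


def predict_proba(features: np.ndarray, head: PredictionHead) -> np.ndarray:
    """Class probabilities for assembled pair features."""
    return head.forward(features, training=False)


def cross_entropy(y_true: np.ndarray, y_pred: np.ndarray,
                  weights: np.ndarray | dict | None = None) -> float:
    """Class-weighted mean negative log-likelihood of one-hot labels.

    ``weights`` maps class index (or class name order position) to a factor
    multiplying that sample's term; all-ones recovers the plain mean NLL.
    Zero predicted probability at a true class is clipped to 1e-12.
    """
    y_true = np.atleast_2d(np.asarray(y_true, dtype=np.float64))
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=np.float64))
    if y_true.shape != y_pred.shape:
        raise ValueError("label and prediction batches must have equal shapes")
    p_true = (y_true * y_pred).sum(axis=1)
    if (p_true <= 0).any():
        warnings.warn("zero predicted probability for a true class; clipping at 1e-12",
                      stacklevel=2)
    p_true = np.clip(p_true, 1e-12, None)
    w = _sample_weights(y_true, weights)
    return float(np.mean(-w * np.log(p_true)))


def _sample_weights(y_true: np.ndarray, weights) -> np.ndarray:
    if weights is None:
        return np.ones(len(y_true))
    if isinstance(weights, dict):
        classes = CLASSES_3 if y_true.shape[1] == 3 else CLASSES_2
        weights = np.array([weights[c] for c in classes])
    weights = np.asarray(weights, dtype=np.float64)
    return y_true @ weights


class FGRNModel:
    """End-to-end pair classifier with frozen embedding tables."""

    def __init__(self, config: PredictorConfig, dim_e: int,
                 tables: EmbeddingTables | None = None,
                 rng: np.random.Generator | None = None) -> None:
        config.validate()
        if "blr" in config.features and tables is None:
            raise ValueError("feature set includes 'blr' but no embedding tables given")
        if tables is not None and tables.d != config.embed_dim:
            config = replace(config, embed_dim=tables.d)
        rng = rng or np.random.default_rng(config.seed)
        self.config = config
        self.dim_e = dim_e
        self.tables = tables
        self.extractor = None
        self.cnet = None
        feat_len = 0
        if {"corr", "expr"} & set(config.features):
            self.extractor = ResidualExtractor(config.extractor, rng)
        if "corr" in config.features:
            c3 = config.extractor.channels[-1]
            l3 = self.extractor.out_length(dim_e)
            self.cnet = Cnet(2 * c3 * l3, config.cnet, rng)
            feat_len += config.cnet.d_corr
        if "expr" in config.features:
            feat_len += 2 * config.extractor.output_dim
        if "blr" in config.features:
            feat_len += 4 * config.embed_dim
        self.feat_len = feat_len
        self.head = PredictionHead(feat_len, config.head, config.n_classes, rng)

    def params(self):
        out = []
        if self.extractor is not None:
            if "corr" in self.config.features:
                out.extend(self.extractor.block_params())
                out.extend(self.cnet.params())
            if "expr" in self.config.features:
                if "corr" not in self.config.features:
                    out.extend(self.extractor.block_params())
                out.extend(self.extractor.dense.params())
        return out + self.head.params()

    def embedding_features(self, samples: list[PairSample]) -> np.ndarray | None:
        if "blr" not in self.config.features:
            return None
        rows = []
        for s in samples:
            ir = self.tables.index(s.regulator_id)
            it = self.tables.index(s.target_id)
            rows.append(np.concatenate([self.tables.s[ir], self.tables.t[ir],
                                        self.tables.s[it], self.tables.t[it]]))
        return np.stack(rows)

    def forward(self, x_r: np.ndarray, x_t: np.ndarray,
                emb: np.ndarray | None, training: bool = False) -> np.ndarray:
        n = x_r.shape[0]
        feats = []
        parts = []
        if self.extractor is not None:
            stacked = self.extractor.forward_blocks(
                np.vstack([x_r, x_t]), training=training)
            y3_r, y3_t = stacked[:n], stacked[n:]
            self._n = n
        if "corr" in self.config.features:
            corr = self.cnet.forward(y3_r, y3_t, training=training)
            feats.append(corr)
            parts.append(("corr", corr.shape[1]))
        if "expr" in self.config.features:
            f = self.extractor.forward_head(stacked, training=training)
            feats.append(np.hstack([f[:n], f[n:]]))
            parts.append(("expr", 2 * f.shape[1]))
        if emb is not None:
            feats.append(emb)
            parts.append(("blr", emb.shape[1]))
        self._parts = parts
        return self.head.forward(np.hstack(feats), training=training)

    def backward(self, dlogits: np.ndarray) -> None:
        dfeat = self.head.backward(dlogits)
        offset = 0
        dy3 = None
        n = getattr(self, "_n", 0)
        for name, width in self._parts:
            chunk = dfeat[:, offset:offset + width]
            offset += width
            if name == "corr":
                dy_r, dy_t = self.cnet.backward(chunk)
                grad = np.vstack([dy_r, dy_t])
                dy3 = grad if dy3 is None else dy3 + grad
            elif name == "expr":
                half = width // 2
                dstack = np.vstack([chunk[:, :half], chunk[:, half:]])
                grad = self.extractor.backward_head(dstack)
                dy3 = grad if dy3 is None else dy3 + grad
            # "blr" chunk: tables are frozen, gradient discarded
        if dy3 is not None:
            self.extractor.backward_blocks(dy3)

    def predict_proba(self, samples: list[PairSample], batch_size: int = 512) -> np.ndarray:
        """Inference-mode class probabilities, one row per sample."""
        emb = self.embedding_features(samples)
        x_r = np.stack([s.x_r for s in samples])
        x_t = np.stack([s.x_t for s in samples])
        out = []
        for i in range(0, len(samples), batch_size):
            sl = slice(i, i + batch_size)
            out.append(self.forward(x_r[sl], x_t[sl],
                                    None if emb is None else emb[sl], training=False))
        return np.vstack(out)


def set_output_classes(model: FGRNModel, n: int) -> FGRNModel:
    """Rebuild only the final dense layer with ``n`` output units (2 or 3)."""
    if n not in (2, 3):
        raise ValueError("number of output classes must be 2 or 3")
    rng = np.random.default_rng(model.config.seed + 1)
    model.head.out = nn.Dense(model.config.head.hidden_dim, n, rng)
    model.head.n_classes = n
    model.config = replace(model.config, n_classes=n)
    return model


def fit(samples: list[PairSample], prior=None, cfg: PredictorConfig | None = None,
        tables: EmbeddingTables | None = None,
        embed_cfg: EmbedConfig | None = None) -> tuple[FGRNModel, dict]:
    """Train the correlation net and head; embedding tables stay frozen.

    If the feature set includes ``blr`` and no tables are given, the
    embedding is first trained on ``prior``.  Returns the model restored to
    its best validation epoch plus a training log (loss per epoch).
    """
    cfg = cfg or PredictorConfig()
    cfg.validate()
    labels = [s.label for s in samples]
    if len(set(labels)) < 2:
        raise ValueError("need samples from at least two classes")
    if "blr" in cfg.features and tables is None:
        if prior is None:
            raise ValueError("feature set includes 'blr': pass embedding tables or a prior network")
        embed_cfg = embed_cfg or EmbedConfig(d=cfg.embed_dim, seed=cfg.seed)
        tables = train_embedding(prior, embed_cfg)

    dim_e = len(samples[0].x_r)
    rng = np.random.default_rng(cfg.seed)
    model = FGRNModel(cfg, dim_e, tables=tables, rng=rng)

    idx = np.arange(len(samples))
    try:
        train_idx, val_idx = train_test_split(
            idx, test_size=cfg.val_fraction, stratify=labels,
            random_state=cfg.seed % (2 ** 32))
    except ValueError as err:
        raise ValueError(
            "stratified validation split failed (a class is too small): " + str(err)
        ) from err
    train = [samples[i] for i in train_idx]
    val = [samples[i] for i in val_idx]
    if len({s.label for s in val}) < len(set(labels)):
        raise ValueError("validation split left a class empty; use a stratified split")

    weights = class_weights(train)
    classes = CLASSES_3 if cfg.n_classes == 3 else CLASSES_2
    w_vec = np.array([weights[c] for c in classes])

    x_r = np.stack([s.x_r for s in train])
    x_t = np.stack([s.x_t for s in train])
    y = np.stack([s.y for s in train])
    emb = model.embedding_features(train)
    v_xr = np.stack([s.x_r for s in val])
    v_xt = np.stack([s.x_t for s in val])
    v_y = np.stack([s.y for s in val])
    v_emb = model.embedding_features(val)

    opt = nn.Adam(model.params(), lr=cfg.lr)
    history = {"train_loss": [], "val_loss": []}
    best_loss = np.inf
    best_val_loss = np.inf
    best_model = None
    bad_epochs = 0
    for epoch in range(cfg.max_epochs):
        if cfg.lr_schedule == "cosine":
            frac = epoch / max(cfg.max_epochs - 1, 1)
            opt.lr = cfg.lr * (0.1 + 0.9 * 0.5 * (1 + np.cos(np.pi * frac)))
        order = rng.permutation(len(train))
        epoch_losses = []
        for start in range(0, len(train), cfg.batch_size):
            b = order[start:start + cfg.batch_size]
            opt.zero_grad()
            if cfg.augment_sample_permutation:
                perm = rng.permutation(dim_e)
                xb_r, xb_t = x_r[b][:, perm], x_t[b][:, perm]
            else:
                xb_r, xb_t = x_r[b], x_t[b]
            probs = model.forward(xb_r, xb_t, None if emb is None else emb[b],
                                  training=True)
            yb = y[b]
            epoch_losses.append(cross_entropy(yb, probs, w_vec))
            wb = _sample_weights(yb, w_vec)
            dlogits = wb[:, None] * (probs - yb) / len(b)
            model.backward(dlogits)
            opt.step()
        v_probs = model.forward(v_xr, v_xt, v_emb, training=False)
        val_loss = cross_entropy(v_y, v_probs, w_vec)
        if cfg.early_stop_metric == "auc":
            from .evaluation import auc_ovr
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                monitored = -auc_ovr(v_y.argmax(axis=1), v_probs)
        else:
            monitored = val_loss
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(float(val_loss))
        logger.debug("epoch %d: train=%.4f val=%.4f", epoch,
                     history["train_loss"][-1], val_loss)
        if monitored < best_loss - 1e-9:
            best_loss = monitored
            best_val_loss = val_loss
            best_model = copy.deepcopy(model)
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > cfg.patience:
                logger.info("early stopping at epoch %d (best val %.4f)", epoch, best_loss)
                break
    final = best_model if best_model is not None else model
    final.tables = model.tables
    history["best_val_loss"] = float(best_val_loss)
    history["n_epochs"] = len(history["train_loss"])
    return final, history


def predict_network(model: FGRNModel, regulators: list[str], targets: list[str],
                    expr) -> "pd.DataFrame":
    """Score every requested (regulator, target) pair, skipping self-pairs."""
    import pandas as pd
    samples = []
    for r in regulators:
        for t in targets:
            if r.strip().casefold() == t.strip().casefold():
                continue
            y0 = np.zeros(model.config.n_classes)
            y0[0] = 1.0  # placeholder label, unused at inference
            samples.append(PairSample(r, t, expr.row(r), expr.row(t),
                                      (CLASSES_3 if model.config.n_classes == 3
                                       else CLASSES_2)[0], y0))
    classes = CLASSES_3 if model.config.n_classes == 3 else CLASSES_2
    cols = [f"p_{c}" for c in classes]
    if not samples:
        return pd.DataFrame(columns=["regulator", "target", *cols, "call"])
    probs = model.predict_proba(samples)
    df = pd.DataFrame(probs, columns=cols)
    df.insert(0, "regulator", [s.regulator_id for s in samples])
    df.insert(1, "target", [s.target_id for s in samples])
    df["call"] = [classes[i] for i in probs.argmax(axis=1)]
    return df
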