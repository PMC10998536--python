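"""Metric suite and repeated stratified k-fold cross-validation.

Metrics are implemented directly from their confusion-matrix / rank
definitions (multiclass MCC via the Gorodkin covariance form, one-vs-rest
ROC AUC via the Mann-Whitney statistic with tie mid-ranks) so they can be
cross-checked against an independent reference implementation in tests.

The cross-validation unit is the gene *pair*: the same gene may appear in
training and test pairs, mirroring how association-prediction benchmarks
are usually scored.  By default the bidirectional embedding is retrained
per fold on the training-fold positive edges only, so no test edge leaks
into the embedding; ``embed_on_full_prior=True`` trains it once on the
whole prior instead.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .data_io import PairSample, SignedNetwork, _canon, one_hot
from .embedding import EmbedConfig, train_embedding
from .predictor import PredictorConfig, fit

logger = logging.getLogger(__name__)

METRICS = ("auc", "mcc", "f1", "recall", "precision", "specificity", "accuracy")


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    for name, arr in (("true", y_true), ("predicted", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} label outside [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def mcc(cm: np.ndarray) -> float:
    """Matthews correlation coefficient, generalized (covariance) form."""
    cm = np.asarray(cm, dtype=np.float64)
    n = cm.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    t = cm.sum(axis=1)  # true-class totals
    p = cm.sum(axis=0)  # predicted-class totals
    num = np.trace(cm) * n - t @ p
    den = np.sqrt(n * n - p @ p) * np.sqrt(n * n - t @ t)
    if den == 0:
        warnings.warn("degenerate confusion matrix (single class); MCC set to 0",
                      stacklevel=2)
        return 0.0
    return float(num / den)


def prf(cm: np.ndarray) -> dict:
    """Per-class one-vs-rest precision/recall/F1 plus unweighted macro means."""
    cm = np.asarray(cm, dtype=np.float64)
    tp = np.diag(cm)
    pred_tot = cm.sum(axis=0)
    true_tot = cm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_tot > 0, tp / pred_tot, 0.0)
        recall = np.where(true_tot > 0, tp / true_tot, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    if (pred_tot == 0).any() or (true_tot == 0).any():
        warnings.warn("zero-division in precision/recall; affected classes score 0",
                      stacklevel=2)
    return {"precision": precision, "recall": recall, "f1": f1,
            "macro_precision": float(precision.mean()),
            "macro_recall": float(recall.mean()),
            "macro_f1": float(f1.mean())}


def specificity(cm: np.ndarray) -> float:
    """Macro one-vs-rest specificity TN / (TN + FP)."""
    cm = np.asarray(cm, dtype=np.float64)
    n = cm.sum()
    vals = []
    for k in range(cm.shape[0]):
        fp = cm[:, k].sum() - cm[k, k]
        tn = n - cm[k, :].sum() - fp
        vals.append(tn / (tn + fp) if tn + fp > 0 else 0.0)
    return float(np.mean(vals))


def _binary_auc(y: np.ndarray, scores: np.ndarray) -> float:
    ranks = rankdata(scores)  # average ranks handle ties as mid-ranks
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both positive and negative samples")
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc_ovr(y_true, y_scores) -> float:
    """Macro one-vs-rest ROC AUC from class-probability columns.

    ``y_scores`` may be 1-D (binary positive-class score, where class 0 is
    the positive class per the fixed label order) or (N, C).  Classes
    absent from ``y_true`` are skipped with a warning.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_scores = np.asarray(y_scores, dtype=np.float64)
    if y_scores.ndim == 1:
        # binary convenience path: y_true in {0, 1} with 1 = positive,
        # y_scores = positive-class score
        return _binary_auc((y_true == 1).astype(int), y_scores)
    aucs = []
    for c in range(y_scores.shape[1]):
        mask = (y_true == c).astype(int)
        if mask.sum() == 0:
            warnings.warn(f"class {c} absent from y_true; skipped in macro AUC",
                          stacklevel=2)
            continue
        aucs.append(_binary_auc(mask, y_scores[:, c]))
    return float(np.mean(aucs))


def fold_metrics(y_true_idx: np.ndarray, probs: np.ndarray) -> dict:
    preds = probs.argmax(axis=1)
    cm = confusion_matrix(y_true_idx, preds, probs.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = prf(cm)
        return {"auc": auc_ovr(y_true_idx, probs), "mcc": mcc(cm),
                "f1": p["macro_f1"], "recall": p["macro_recall"],
                "precision": p["macro_precision"], "specificity": specificity(cm),
                "accuracy": float(np.trace(cm) / cm.sum())}


@dataclass
class EvaluationReport:
    per_fold: pd.DataFrame
    n_folds: int
    n_repeats: int
    seeds: list[int]

    def aggregate(self) -> pd.DataFrame:
        return self.per_fold[list(METRICS)].agg(["mean", "std"])

    def to_json(self, path=None) -> str:
        agg = self.aggregate()
        payload = {
            "n_folds": self.n_folds, "n_repeats": self.n_repeats,
            "seeds": self.seeds,
            "aggregate": {m: {"mean": float(agg.loc["mean", m]),
                              "sd": float(agg.loc["std", m])} for m in METRICS},
            "per_fold": self.per_fold.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_text(self) -> str:
        agg = self.aggregate()
        lines = [f"{self.n_repeats} x {self.n_folds}-fold cross-validation",
                 f"{'metric':<12}{'mean':>10}{'sd':>10}"]
        for m in METRICS:
            lines.append(f"{m:<12}{agg.loc['mean', m]:>10.4f}{agg.loc['std', m]:>10.4f}")
        return "\n".join(lines)


def _label_indices(samples: list[PairSample]) -> np.ndarray:
    return np.array([int(np.argmax(s.y)) for s in samples])


def permute_labels(samples: list[PairSample], seed: int) -> list[PairSample]:
    """Negative control: reassign the label multiset randomly across pairs."""
    rng = np.random.default_rng(seed)
    labels = [s.label for s in samples]
    perm = rng.permutation(len(labels))
    n_classes = len(samples[0].y)
    return [PairSample(s.regulator_id, s.target_id, s.x_r, s.x_t,
                       labels[perm[i]], one_hot(labels[perm[i]], n_classes))
            for i, s in enumerate(samples)]


def _fold_prior(prior: SignedNetwork, train_samples: list[PairSample]) -> SignedNetwork:
    pos = {(_canon(s.regulator_id), _canon(s.target_id))
           for s in train_samples if s.label != "non-regulation"}
    edges = [e for e in prior.edges if (_canon(e[0]), _canon(e[1])) in pos]
    return SignedNetwork(edges, node_ids=list(prior.node_ids))


def cross_validate(samples: list[PairSample], prior: SignedNetwork,
                   cfg: PredictorConfig, n_folds: int = 5, n_repeats: int = 10,
                   embed_cfg: EmbedConfig | None = None,
                   embed_on_full_prior: bool = False,
                   seed: int = 0, predictions_path=None) -> EvaluationReport:
    """Repeated stratified k-fold CV of the full pipeline.

    Per repeat a fresh fold split seed is drawn; per fold the embedding is
    retrained on training-fold positives (unless ``embed_on_full_prior``)
    and the classifier is refit from scratch.  ``predictions_path``
    optionally dumps the per-fold raw test predictions as TSV.
    """
    labels = _label_indices(samples)
    counts = np.bincount(labels)
    if (counts < n_folds).any():
        raise ValueError(
            f"smallest class has {counts.min()} samples; cannot stratify into "
            f"{n_folds} folds")
    embed_cfg = embed_cfg or EmbedConfig(d=cfg.embed_dim)
    needs_embedding = "blr" in cfg.features
    full_tables = None
    if needs_embedding and embed_on_full_prior:
        full_tables = train_embedding(prior, replace(embed_cfg, seed=seed))

    rows = []
    pred_rows = []
    seeds = []
    for rep in range(n_repeats):
        rep_seed = seed + 1000 * rep
        seeds.append(rep_seed)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=rep_seed % (2 ** 32))
        for fold, (tr, te) in enumerate(skf.split(np.zeros(len(samples)), labels)):
            train = [samples[i] for i in tr]
            test = [samples[i] for i in te]
            fold_seed = rep_seed + fold
            tables = full_tables
            if needs_embedding and not embed_on_full_prior:
                tables = train_embedding(_fold_prior(prior, train),
                                         replace(embed_cfg, seed=fold_seed))
            model, _ = fit(train, cfg=replace(cfg, seed=fold_seed), tables=tables)
            probs = model.predict_proba(test)
            if predictions_path is not None:
                for s, p in zip(test, probs):
                    pred_rows.append({"repeat": rep, "fold": fold,
                                      "regulator": s.regulator_id,
                                      "target": s.target_id, "label": s.label,
                                      **{f"p{i}": v for i, v in enumerate(p)}})
            row = {"repeat": rep, "fold": fold,
                   **fold_metrics(_label_indices(test), probs)}
            rows.append(row)
            logger.info("repeat %d fold %d: AUC=%.3f MCC=%.3f", rep, fold,
                        row["auc"], row["mcc"])
    if predictions_path is not None:
        pd.DataFrame(pred_rows).to_csv(predictions_path, sep="\t", index=False,
                                       float_format="%.6g")
    report = EvaluationReport(pd.DataFrame(rows), n_folds, n_repeats, seeds)
    logger.info("CV aggregate:\n%s", report.to_text())
    return report
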