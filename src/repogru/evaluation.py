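"""Evaluation harness: negative sampling, classification metrics, ROC/AUC,
tenfold cross-validation, candidate ranking and top-N retrieval.

Known drug-disease pairs are the positive class; an equal number of
unobserved (zero) cells are drawn uniformly without replacement as presumed
negatives.  Cross-validation shuffles positives and negatives together into
ten near-equal folds; for each fold the features are re-derived from the
training interactions only (held-out positive cells masked out of the
interaction matrix), the classifier is retrained, and the held-out fold is
scored.  Reported metrics are mean +/- population standard deviation over
the folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .datasets import BenchmarkDataset, InteractionMatrix
from .pipeline import FittedPipeline, PipelineConfig, derive_seed, fit_pipeline

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "CVReport",
    "RankedList",
    "sample_negatives",
    "confusion_from_scores",
    "metrics_from_counts",
    "roc_auc",
    "tenfold_cv",
    "fit_predictor",
    "rank_candidates",
    "top_n_retrieval",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("acc", "tpr", "tnr", "ppv", "mcc", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Threshold metrics plus (optionally) ROC points and AUC.

    ``degenerate`` names the metrics whose denominator was zero and which
    were therefore reported as 0 rather than raising.
    """

    acc: float
    tpr: float
    tnr: float
    ppv: float
    mcc: float
    auc: Optional[float] = None
    roc: Optional[np.ndarray] = None
    degenerate: frozenset = frozenset()

    def as_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in ("acc", "tpr", "tnr", "ppv", "mcc")}
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def sample_negatives(
    I: InteractionMatrix, ratio: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Draw floor(ratio * #positives) distinct zero cells of I uniformly.

    Returns an (n, 2) array of (drug, disease) indices; reproducible by
    ``seed``; raises when the matrix does not contain enough zero cells.
    """
    n_pos = I.n_interactions
    k = int(ratio * n_pos)
    zeros = np.argwhere(I.values == 0)
    if k > zeros.shape[0]:
        raise ValueError(
            f"cannot sample {k} negatives from {zeros.shape[0]} zero cells"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(zeros.shape[0], size=k, replace=False)
    return zeros[np.sort(chosen)]


def confusion_from_scores(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Confusion counts at a probability threshold (predict 1 iff score >= t)."""
    pred = np.asarray(scores) >= threshold
    lab = np.asarray(labels).astype(bool)
    return ConfusionCounts(
        tp=int((pred & lab).sum()),
        tn=int((~pred & ~lab).sum()),
        fp=int((pred & ~lab).sum()),
        fn=int((~pred & lab).sum()),
    )


def metrics_from_counts(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, TPR, TNR, PPV and MCC from confusion counts.

    Acc = (TP+TN)/total, TPR = TP/(TP+FN), TNR = TN/(TN+FP),
    PPV = TP/(TP+FP), MCC = (TP*TN - FP*FN) /
    sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).  A zero denominator yields 0 and is
    recorded in ``degenerate``.
    """
    tp, tn, fp, fn = (float(c.tp), float(c.tn), float(c.fp), float(c.fn))
    degenerate: set[str] = set()

    def safe(num: float, den: float, name: str) -> float:
        if den == 0.0:
            degenerate.add(name)
            return 0.0
        return num / den

    acc = safe(tp + tn, tp + tn + fp + fn, "acc")
    tpr = safe(tp, tp + fn, "tpr")
    tnr = safe(tn, tn + fp, "tnr")
    ppv = safe(tp, tp + fp, "ppv")
    mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = safe(tp * tn - fp * fn, mcc_den, "mcc")
    return MetricsReport(acc, tpr, tnr, ppv, mcc, degenerate=frozenset(degenerate))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points and AUC.

    The AUC equals the Mann-Whitney statistic P(score+ > score-) plus half
    the tie probability; ROC points are taken at every distinct threshold.
    Raises when only one class is present.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if np.unique(labels).size < 2:
        raise ValueError("ROC/AUC require both classes to be present")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(roc_auc_score(labels, scores))
    return np.column_stack([fpr, tpr]), auc


@dataclass
class CVReport:
    """Per-fold metrics with mean and population standard deviation."""

    folds: list[MetricsReport]
    mean: dict[str, float]
    sd: dict[str, float]
    fold_assignment: np.ndarray
    pairs: np.ndarray
    labels: np.ndarray
    seed: int
    pooled_auc: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        """Per-fold rows plus mean/sd rows, metrics as percentages."""
        rows = []
        for i, m in enumerate(self.folds, start=1):
            rows.append({"fold": str(i), **{k: 100 * v for k, v in m.as_dict().items()}})
        rows.append({"fold": "mean", **{k: 100 * v for k, v in self.mean.items()}})
        rows.append({"fold": "sd", **{k: 100 * v for k, v in self.sd.items()}})
        return pd.DataFrame(rows)


def _cv_pairs(ds: BenchmarkDataset, cfg: PipelineConfig, seed: int):
    positives = np.argwhere(ds.interactions.values == 1)
    negatives = sample_negatives(
        ds.interactions, cfg.negative_ratio, derive_seed(seed, "negatives")
    )
    pairs = np.vstack([positives, negatives])
    labels = np.concatenate(
        [np.ones(len(positives), dtype=np.int8), np.zeros(len(negatives), dtype=np.int8)]
    )
    return pairs, labels


def tenfold_cv(ds: BenchmarkDataset, cfg: PipelineConfig, seed: int = 0) -> CVReport:
    """K-fold cross-validation of the full pipeline (default 10 folds).

    Positives and sampled negatives are shuffled together and split into
    near-equal folds (sizes differ by at most 1; test folds are disjoint and
    cover every sample).  Per fold, when ``cfg.refit_per_fold`` (default),
    the held-out positives are zeroed out of the interaction matrix before
    the GIP kernels and cluster boosting are computed, so no test label
    leaks into the features.
    """
    pairs, labels = _cv_pairs(ds, cfg, seed)
    n = len(labels)
    k = cfg.n_folds
    if int(labels.sum()) < k or int((1 - labels).sum()) < k:
        raise ValueError(f"need at least {k} samples per class for {k}-fold CV")

    rng = np.random.default_rng(derive_seed(seed, "folds"))
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=np.int64)
    fold_of[order] = np.arange(n) % k

    folds: list[MetricsReport] = []
    pooled_scores = np.empty(n)
    base_seed = derive_seed(seed, "train")
    for f in range(k):
        test_mask = fold_of == f
        tr_pairs, tr_labels = pairs[~test_mask], labels[~test_mask]
        te_pairs, te_labels = pairs[test_mask], labels[test_mask]

        I_train = ds.interactions.values.copy()
        if cfg.refit_per_fold:
            te_pos = te_pairs[te_labels == 1]
            I_train[te_pos[:, 0], te_pos[:, 1]] = 0

        fold_cfg = replace(
            cfg, train=replace(cfg.train, seed=(base_seed + f) % (2 ** 31))
        )
        fitted = fit_pipeline(ds, tr_pairs, tr_labels, fold_cfg, I_train)
        scores = fitted.score_pairs(te_pairs)
        pooled_scores[test_mask] = scores

        report = metrics_from_counts(
            confusion_from_scores(scores, te_labels, cfg.threshold)
        )
        report.roc, report.auc = roc_auc(scores, te_labels)
        folds.append(report)
        logger.info("fold %d/%d: auc=%.4f acc=%.4f", f + 1, k, report.auc, report.acc)

    mean = {m: float(np.mean([getattr(r, m) for r in folds])) for m in METRIC_NAMES}
    sd = {m: float(np.std([getattr(r, m) for r in folds])) for m in METRIC_NAMES}
    pooled = float(roc_auc(pooled_scores, labels)[1]) if cfg.pooled_auc else None
    return CVReport(folds, mean, sd, fold_of, pairs, labels, seed, pooled)


def fit_predictor(ds: BenchmarkDataset, cfg: PipelineConfig, seed: int = 0) -> FittedPipeline:
    """Train a scorer on all known interactions plus sampled negatives.

    This is the model used for case-study ranking of new candidates.
    """
    pairs, labels = _cv_pairs(ds, cfg, seed)
    run_cfg = replace(cfg, train=replace(cfg.train, seed=derive_seed(seed, "train")))
    return fit_pipeline(ds, pairs, labels, run_cfg)


@dataclass
class RankedList:
    """All candidates on the opposite axis of a query, ranked by score.

    Ranks are 1..n by descending score, ties broken by candidate id; known
    interactions are flagged, not removed, so confirmed indications can be
    checked against the top ranks.
    """

    query: str
    candidate_ids: list[str]
    scores: np.ndarray
    known: np.ndarray
    ranks: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        order = sorted(
            range(len(self.candidate_ids)),
            key=lambda i: (-self.scores[i], self.candidate_ids[i]),
        )
        self.candidate_ids = [self.candidate_ids[i] for i in order]
        self.scores = np.asarray(self.scores)[order]
        self.known = np.asarray(self.known)[order]
        self.ranks = np.arange(1, len(order) + 1)

    def __len__(self) -> int:
        return len(self.candidate_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": self.ranks,
            "candidate_id": self.candidate_ids,
            "score": self.scores,
            "known_flag": self.known.astype(int),
        })


def rank_candidates(ds: BenchmarkDataset, fitted: FittedPipeline, query: str) -> RankedList:
    """Score every entity on the other axis against ``query`` and rank them.

    ``query`` may be a drug id (ranks diseases) or a disease id (ranks
    drugs); an unknown id raises ``KeyError``.
    """
    if query in ds.drugs:
        qi = ds.drugs.position(query)
        pairs = [(qi, j) for j in range(ds.n_diseases)]
        candidate_ids = list(ds.diseases)
        known = ds.interactions.values[qi, :].astype(bool)
    elif query in ds.diseases:
        qj = ds.diseases.position(query)
        pairs = [(i, qj) for i in range(ds.n_drugs)]
        candidate_ids = list(ds.drugs)
        known = ds.interactions.values[:, qj].astype(bool)
    else:
        raise KeyError(f"query id not in the dataset: {query!r}")
    scores = fitted.score_pairs(pairs)
    return RankedList(query, candidate_ids, scores, known)


def top_n_retrieval(ranked: RankedList, n: int) -> int:
    """Number of known interactions among the top-n ranked candidates."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(ranked):
        logger.warning("top-N %d exceeds %d candidates; clamping", n, len(ranked))
        n = len(ranked)
    return int(ranked.known[:n].sum())
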