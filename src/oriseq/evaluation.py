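"""Metric suite, cross-validation, independent testing, cross-cell matrix.

Metrics follow the usual binary-classification conventions of the ORI
prediction literature: MCC, accuracy (Ac), sensitivity (Sn), specificity
(Sp), AUC, F1 and precision, reported in that column order.  Zero
denominators (degenerate confusion marginals) yield 0 rather than NaN;
AUC uses the rank statistic with midrank tie handling and is refused on
single-class label vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from .pipeline import OriPipeline, PipelineConfig
from .seq_data import (
    FoldAssignment,
    LabeledSequenceSet,
    split_folds,
    train_test_split_set,
)

METRIC_ORDER = ["MCC", "Ac", "Sn", "Sp", "AUC", "F1", "Precision"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    """One row of headline metrics, optionally with per-fold detail."""

    MCC: float
    Ac: float
    Sn: float
    Sp: float
    AUC: float
    F1: float
    Precision: float
    split: str = ""
    per_fold: list["MetricsReport"] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRIC_ORDER}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"split": f.split, **f.as_dict()} for f in self.per_fold]
        rows.append({"split": self.split or "mean", **self.as_dict()})
        return pd.DataFrame(rows, columns=["split"] + METRIC_ORDER)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def confusion(labels: np.ndarray, calls: np.ndarray) -> ConfusionCounts:
    labels = np.asarray(labels).astype(int)
    calls = np.asarray(calls).astype(int)
    return ConfusionCounts(
        TP=int(np.sum((labels == 1) & (calls == 1))),
        FP=int(np.sum((labels == 0) & (calls == 1))),
        TN=int(np.sum((labels == 0) & (calls == 0))),
        FN=int(np.sum((labels == 1) & (calls == 0))),
    )


def compute_metrics(labels, scores, threshold: float = 0.5, split: str = "") -> MetricsReport:
    """Headline metrics from binary labels and [0,1] scores."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined for single-class labels")
    calls = (scores >= threshold).astype(int)
    c = confusion(labels, calls)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns when MCC marginal is 0
        mcc = float(matthews_corrcoef(labels, calls))
    sn = _safe_div(c.TP, c.TP + c.FN)
    sp = _safe_div(c.TN, c.TN + c.FP)
    prec = _safe_div(c.TP, c.TP + c.FP)
    f1 = _safe_div(2 * prec * sn, prec + sn)
    return MetricsReport(
        MCC=mcc,
        Ac=_safe_div(c.TP + c.TN, c.n),
        Sn=sn,
        Sp=sp,
        AUC=float(roc_auc_score(labels, scores)),
        F1=f1,
        Precision=prec,
        split=split,
    )


def _mean_report(folds: list[MetricsReport], split: str) -> MetricsReport:
    mean = {m: float(np.mean([getattr(f, m) for f in folds])) for m in METRIC_ORDER}
    return MetricsReport(**mean, split=split, per_fold=folds)


def cross_validate(
    config: PipelineConfig,
    dataset: LabeledSequenceSet,
    folds: FoldAssignment | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> MetricsReport:
    """Stratified k-fold CV of the full pipeline.

    Everything that learns — the neural extractor, the Shapley selection
    and the classifier — is fitted on the training folds only; the
    held-out fold is scored once.  Per-fold reports plus their arithmetic
    mean are returned.
    """
    if folds is None:
        folds = split_folds(dataset, n_folds=n_folds, seed=seed)
    idx_by_fold = folds.fold_indices(dataset)
    y = dataset.labels()
    seqs = dataset.sequences()
    reports = []
    for k, test_idx in enumerate(idx_by_fold):
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        pipe = OriPipeline(config=replace(config, seed=config.seed + k))
        pipe.fit([seqs[i] for i in train_idx], y[train_idx])
        scores = pipe.predict_proba([seqs[i] for i in test_idx])[:, 1]
        reports.append(compute_metrics(y[test_idx], scores, split=f"fold{k}"))
    return _mean_report(reports, split="cv_mean")


def independent_test(
    config: PipelineConfig,
    dataset: LabeledSequenceSet,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> MetricsReport:
    """Fit on a stratified training split, score the held-out split."""
    train_set, test_set = train_test_split_set(dataset, test_fraction, seed=seed)
    pipe = OriPipeline(config=config)
    pipe.fit(train_set.sequences(), train_set.labels())
    scores = pipe.predict_proba(test_set.sequences())[:, 1]
    return compute_metrics(test_set.labels(), scores, split="independent")


@dataclass
class CrossCellMatrix:
    """Train-tag x test-tag grid of independent-test accuracies."""

    tags: list[str]
    accuracy: np.ndarray  # (n_tags, n_tags), rows = training cell

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.accuracy, index=self.tags, columns=self.tags)


def cross_cell_matrix(
    datasets: dict[str, LabeledSequenceSet],
    config: PipelineConfig,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> CrossCellMatrix:
    """Train one model per cell tag; evaluate accuracy on every cell's
    independent split (y-axis = training cell, x-axis = test cell)."""
    if len(datasets) < 2:
        raise ValueError("need at least two tagged datasets")
    lengths = {d.window_length for d in datasets.values()}
    if len(lengths) != 1:
        raise ValueError(f"window-length mismatch across cells: {sorted(lengths)}")
    tags = list(datasets)
    splits = {
        t: train_test_split_set(datasets[t], test_fraction, seed=seed) for t in tags
    }
    acc = np.zeros((len(tags), len(tags)))
    for i, t_train in enumerate(tags):
        pipe = OriPipeline(config=config)
        tr = splits[t_train][0]
        pipe.fit(tr.sequences(), tr.labels())
        for j, t_test in enumerate(tags):
            te = splits[t_test][1]
            calls = pipe.predict(te.sequences())
            acc[i, j] = float(np.mean(calls == te.labels()))
    return CrossCellMatrix(tags=tags, accuracy=acc)
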