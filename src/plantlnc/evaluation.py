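"""Classifier evaluation: confusion-matrix metrics, ROC/AUC, redundancy
analysis, category ablation and the cross-species harness.

All metrics use the standard confusion-matrix definitions:
precision = TP/(TP+FP), sensitivity/recall = TP/(TP+FN),
specificity = TN/(TN+FP), F1 = 2TP/(2TP+FP+FN),
MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
with rate-style metrics reported as percentages.  Any zero marginal
makes MCC 0 by convention; F1 is 0 when there are no true positives and
no positive predictions.  AUC integrates the ROC (thresholds at every
distinct probability) by the trapezoidal rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import train_test_split

from .dataset import LabeledDataset
from .features import SCHEMA
from .model import Hyperparameters, predict, train

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion counts plus derived metrics for one evaluation."""

    TP: int
    TN: int
    FP: int
    FN: int
    ACC: float  # percent
    SN: float  # percent (sensitivity / recall)
    SP: float  # percent (specificity)
    precision: float  # percent
    F1: float
    MCC: float
    AUC: Optional[float] = None
    roc_points: tuple[tuple[float, float], ...] = field(default=())

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def to_dict(self) -> dict:
        return {
            "TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN,
            "ACC": self.ACC, "SN": self.SN, "SP": self.SP,
            "precision": self.precision, "F1": self.F1, "MCC": self.MCC,
            "AUC": self.AUC,
        }


def metrics_from_counts(tp: int, tn: int, fp: int, fn: int) -> EvaluationReport:
    """Derive the metric set from raw confusion counts."""
    n = tp + tn + fp + fn
    if n == 0:
        raise ValueError("empty confusion matrix")
    acc = 100.0 * (tp + tn) / n
    sn = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    sp = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    prec = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    f1 = 2.0 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return EvaluationReport(
        TP=tp, TN=tn, FP=fp, FN=fn,
        ACC=acc, SN=sn, SP=sp, precision=prec, F1=f1, MCC=float(mcc),
    )


def compute_metrics(
    labels, predictions, probabilities=None
) -> EvaluationReport:
    """Evaluate binary predictions (and optionally scores) against labels.

    ``labels`` and ``predictions`` must be equal-length binary vectors;
    when ``probabilities`` is given, the ROC curve and trapezoidal AUC
    are included in the report.
    """
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape:
        raise ValueError("labels and predictions differ in length")
    if not np.isin(y, (0, 1)).all() or not np.isin(p, (0, 1)).all():
        raise ValueError("labels and predictions must be binary")
    tp = int(((y == 1) & (p == 1)).sum())
    tn = int(((y == 0) & (p == 0)).sum())
    fp = int(((y == 0) & (p == 1)).sum())
    fn = int(((y == 1) & (p == 0)).sum())
    report = metrics_from_counts(tp, tn, fp, fn)
    if probabilities is not None:
        prob = np.asarray(probabilities, dtype=np.float64)
        if prob.shape != y.shape:
            raise ValueError("probabilities differ in length")
        if len(np.unique(y)) < 2:
            logger.warning("single-class labels: AUC undefined, omitted")
            return report
        fpr, tpr, _ = roc_curve(y, prob)
        auc = float(np.trapezoid(tpr, fpr))
        report = replace(
            report, AUC=auc,
            roc_points=tuple(zip(fpr.tolist(), tpr.tolist())),
        )
    return report


def evaluate_model(bundle, test: LabeledDataset) -> EvaluationReport:
    """Predict on a labeled test set and score the result."""
    labels, proba = predict(bundle, test)
    return compute_metrics(test.y, labels, proba)


def pearson_matrix(X) -> np.ndarray:
    """Pairwise Pearson correlations between columns.

    Zero-variance columns correlate 0 with everything except themselves
    (diagonal 1), with a logged warning.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to correlate")
    sd = X.std(axis=0)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        logger.warning(
            "%d zero-variance columns; their correlations set to 0",
            degenerate.size,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(X, rowvar=False)
    rho = np.atleast_2d(rho)
    rho[degenerate, :] = 0.0
    rho[:, degenerate] = 0.0
    np.fill_diagonal(rho, 1.0)
    return rho


@dataclass
class CorrelationReport:
    """Result of redundancy filtering (and optional reintroduction)."""

    rho: np.ndarray
    retained: list[str]
    redundant: list[str]
    threshold: float
    reintroduction_table: Optional[pd.DataFrame] = None


def redundancy_filter(
    X, feature_names: Sequence[str], threshold: float = 0.8, seed: int = 0
) -> CorrelationReport:
    """Drop one member of every highly correlated feature pair.

    Pairs with |rho| > threshold are visited in schema order; when both
    members are still retained, the seeded generator picks which one
    moves to the redundant set.  After filtering, no retained pair
    exceeds the threshold.  Deterministic per seed.
    """
    names = list(feature_names)
    rho = pearson_matrix(X)
    rng = np.random.default_rng(seed)
    retained_mask = np.ones(len(names), dtype=bool)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if (
                retained_mask[i]
                and retained_mask[j]
                and abs(rho[i, j]) > threshold
            ):
                drop = (i, j)[int(rng.integers(0, 2))]
                retained_mask[drop] = False
    retained = [n for n, m in zip(names, retained_mask) if m]
    redundant = [n for n, m in zip(names, retained_mask) if not m]
    # post-condition: no retained pair above threshold
    idx = np.flatnonzero(retained_mask)
    sub = np.abs(rho[np.ix_(idx, idx)])
    np.fill_diagonal(sub, 0.0)
    assert (sub <= threshold).all()
    return CorrelationReport(
        rho=rho, retained=retained, redundant=redundant, threshold=threshold
    )


_METRIC_COLS = ("ACC", "precision", "SN", "SP", "F1", "MCC")


def _metrics_row(report: EvaluationReport) -> dict:
    return {m: getattr(report, m) for m in _METRIC_COLS}


def reintroduction_experiment(
    train_ds: LabeledDataset,
    test_ds: LabeledDataset,
    redundant_order: Sequence[str],
    hp: Optional[Hyperparameters] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Add filtered-out features back one at a time and re-score.

    Step 0 trains on the retained features only (all features minus
    ``redundant_order``); step t reintroduces the t-th redundant feature,
    retrains with the same hyperparameters and seed, and evaluates on the
    fixed test set.  Returns one metric row per step, with the added
    feature named.
    """
    unknown = set(redundant_order) - set(train_ds.feature_names)
    if unknown:
        raise KeyError(f"unknown feature names: {sorted(unknown)}")
    base = [n for n in train_ds.feature_names if n not in set(redundant_order)]
    rows = []
    current = list(base)
    for step, added in enumerate([None, *redundant_order]):
        if added is not None:
            current.append(added)
        bundle = train(train_ds.subset_features(current), hp, seed=seed)
        report = evaluate_model(bundle, test_ds.subset_features(current))
        rows.append(
            {"step": step, "added_feature": added or "(baseline)",
             "n_features": len(current), **_metrics_row(report)}
        )
    return pd.DataFrame(rows)


def ablation_by_category(
    train_ds: LabeledDataset,
    test_ds: Optional[LabeledDataset] = None,
    hp: Optional[Hyperparameters] = None,
    seed: int = 0,
    test_size: float = 0.3,
) -> pd.DataFrame:
    """Score the feature families separately and fused.

    Combinations: all 100 features fused, sequence-only (90),
    structure-only (7), biological-only (3).  When no test set is given,
    a stratified 70/30 split of ``train_ds`` is used.
    """
    if test_ds is None:
        idx = np.arange(len(train_ds))
        tr, te = train_test_split(
            idx, test_size=test_size, stratify=train_ds.y, random_state=seed
        )
        train_ds, test_ds = train_ds.subset_rows(tr), train_ds.subset_rows(te)
    combos = {
        "all": list(SCHEMA.names),
        "sequence": SCHEMA.names_in_category("sequence"),
        "structure": SCHEMA.names_in_category("structure"),
        "biological": SCHEMA.names_in_category("biological"),
    }
    rows = []
    for name, cols in combos.items():
        bundle = train(train_ds.subset_features(cols), hp, seed=seed)
        report = evaluate_model(bundle, test_ds.subset_features(cols))
        rows.append(
            {"combination": name, "n_features": len(cols),
             **_metrics_row(report)}
        )
    return pd.DataFrame(rows)


def cross_species_eval(
    datasets: Mapping[str, LabeledDataset],
    hp: Optional[Hyperparameters] = None,
    seed: int = 0,
    holdout: float = 0.3,
) -> dict[str, dict[str, EvaluationReport]]:
    """Train per group and evaluate on every group (train x test grid).

    The diagonal uses a stratified held-out split of the training group;
    off-diagonal cells train on the full training group and test on the
    full other group.  Overlapping sequence ids between a train and test
    group raise (leakage guard).
    """
    grid: dict[str, dict[str, EvaluationReport]] = {}
    for train_name, train_group in datasets.items():
        grid[train_name] = {}
        full_bundle = train(train_group, hp, seed=seed)
        for test_name, test_group in datasets.items():
            if test_name == train_name:
                idx = np.arange(len(train_group))
                tr, te = train_test_split(
                    idx, test_size=holdout, stratify=train_group.y,
                    random_state=seed,
                )
                bundle = train(train_group.subset_rows(tr), hp, seed=seed)
                report = evaluate_model(bundle, train_group.subset_rows(te))
            else:
                overlap = set(train_group.ids) & set(test_group.ids)
                if overlap:
                    raise ValueError(
                        f"id overlap between train group {train_name!r} and "
                        f"test group {test_name!r}: {sorted(overlap)[:5]}"
                    )
                report = evaluate_model(full_bundle, test_group)
            grid[train_name][test_name] = report
    return grid


def cross_species_table(
    grid: Mapping[str, Mapping[str, EvaluationReport]],
    metric: str = "ACC",
) -> pd.DataFrame:
    """Flatten a cross-species grid into a train x test DataFrame."""
    return pd.DataFrame(
        {
            test: {tr: getattr(grid[tr][test], metric) for tr in grid}
            for test in next(iter(grid.values()))
        }
    )
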