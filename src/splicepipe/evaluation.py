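"""Benchmark harness: ROC/PR analysis, sensitivity at fixed specificity,
precision at fixed recall, repeated position-keyed splits, and side-by-side
comparison with external score files.

Conventions (documented because readouts depend on them): ROC AUC is the
trapezoid over the full step curve and equals the pairwise Mann–Whitney
statistic; PR AUC is step integration (average precision); fixed-specificity
sensitivity is read conservatively, at the largest threshold whose
specificity still meets the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

SPEC_GRID = (0.95, 0.96, 0.97, 0.98, 0.99)
RECALL_GRID = (0.80, 0.85, 0.90, 0.95)


class UndefinedMetricError(ValueError):
    pass


def _check_two_classes(labels):
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("both classes required")
    return labels


def roc(labels, scores) -> tuple[np.ndarray, np.ndarray, float]:
    """(fpr, tpr, auc); ties cross thresholds simultaneously."""
    labels = _check_two_classes(labels)
    fpr, tpr, _ = roc_curve(labels, scores)
    return fpr, tpr, float(roc_auc_score(labels, scores))


def pr(labels, scores) -> tuple[np.ndarray, np.ndarray, float]:
    """(precision, recall, step-integrated AUC)."""
    labels = _check_two_classes(labels)
    precision, recall, _ = precision_recall_curve(labels, scores)
    return precision, recall, float(average_precision_score(labels, scores))


def sensitivity_at_specificity(labels, scores, target: float) -> float:
    """Sensitivity at the largest threshold with specificity ≥ target (0 if
    unreachable)."""
    fpr, tpr, _ = roc(labels, scores)
    ok = (1.0 - fpr) >= target
    return float(tpr[ok].max()) if ok.any() else 0.0


def precision_at_recall(labels, scores, target: float) -> float:
    precision, recall, _ = pr(labels, scores)
    ok = recall >= target
    return float(precision[ok].max()) if ok.any() else 0.0


@dataclass
class EvalResult:
    roc_auc: float
    pr_auc: float
    sens_at_spec: dict = field(default_factory=dict)
    prec_at_recall: dict = field(default_factory=dict)
    per_region_auc: dict = field(default_factory=dict)
    iteration: int = 0
    split_seed: int = 0
    n: int = 0

    def as_dict(self) -> dict:
        d = dict(
            roc_auc=self.roc_auc, pr_auc=self.pr_auc, iteration=self.iteration, n=self.n
        )
        d.update({f"sens_at_{int(100 * s)}": v for s, v in self.sens_at_spec.items()})
        d.update({f"prec_at_{int(100 * r)}": v for r, v in self.prec_at_recall.items()})
        return d


def evaluate_scores(
    labels, scores, regions=None, iteration: int = 0, split_seed: int = 0
) -> EvalResult:
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    _, _, auc = roc(labels, scores)
    _, _, ap = pr(labels, scores)
    res = EvalResult(
        roc_auc=auc,
        pr_auc=ap,
        sens_at_spec={s: sensitivity_at_specificity(labels, scores, s) for s in SPEC_GRID},
        prec_at_recall={r: precision_at_recall(labels, scores, r) for r in RECALL_GRID},
        iteration=iteration,
        split_seed=split_seed,
        n=len(labels),
    )
    if regions is not None:
        regions = np.asarray(regions)
        for region in np.unique(regions):
            m = regions == region
            if len(np.unique(labels[m])) == 2:
                res.per_region_auc[str(region)] = float(
                    roc_auc_score(labels[m], scores[m])
                )
    return res


def positional_split(
    chroms, positions, seed: int, fraction: float = 0.5
) -> np.ndarray:
    """Boolean mask (True = training half); all variants sharing a genomic
    position land on the same side."""
    keys = pd.Series(zip(np.asarray(chroms), np.asarray(positions)))
    uniq = keys.drop_duplicates().tolist()
    if len(uniq) < 2:
        raise ValueError("need at least two distinct genomic positions to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    n_train = int(round(fraction * len(uniq)))
    train_keys = {uniq[i] for i in order[:n_train]}
    return keys.isin(train_keys).to_numpy()


def iterate_splits(
    X: np.ndarray,
    y: np.ndarray,
    chroms,
    positions,
    n_iter: int = 100,
    seed: int = 0,
    n_trees: int = 200,
    mtry: int = 3,
    target_specificity: float = 0.99,
    regions=None,
) -> tuple[list[EvalResult], pd.DataFrame]:
    """Repeat train/calibrate/evaluate over fresh position-keyed 50/50 splits.

    Returns the per-iteration results and an aggregate frame with the
    mean/min/max of each metric.  Fully reproducible from the master seed.
    """
    from .spip_model import calibrate_threshold, train_forest, vote_fraction

    results = []
    for it in range(n_iter):
        it_seed = seed * 100_003 + it
        train_mask = positional_split(chroms, positions, seed=it_seed)
        rf = train_forest(
            X[train_mask],
            y[train_mask],
            n_trees=n_trees,
            mtry=min(mtry, X.shape[1]),
            seed=it_seed % (2**31),
        )
        scores = vote_fraction(rf, X[~train_mask])
        calibrate_threshold(scores, y[~train_mask], target_specificity)
        res = evaluate_scores(
            y[~train_mask],
            scores,
            regions=None if regions is None else np.asarray(regions)[~train_mask],
            iteration=it,
            split_seed=it_seed,
        )
        results.append(res)
    frame = pd.DataFrame([r.as_dict() for r in results])
    agg = frame.drop(columns=["iteration"]).agg(["mean", "min", "max"]).T
    return results, agg


def compare_scores(
    collection: pd.DataFrame,
    score_columns: dict[str, pd.DataFrame],
) -> tuple[pd.DataFrame, dict[str, EvalResult]]:
    """Side-by-side evaluation of named external score files.

    Each score frame has columns ``variant_id`` and ``score``.  Metrics are
    computed on the intersection of variants scored by *all* tools; per-tool
    coverage on the full collection is reported alongside.
    """
    merged = collection[["variant_id", "label"]].copy()
    coverage = {}
    for name, df in score_columns.items():
        df = df.rename(columns={"score": name})[["variant_id", name]]
        merged = merged.merge(df, on="variant_id", how="left")
        coverage[name] = float(merged[name].notna().mean())
    both = merged.dropna()
    if len(both) == 0:
        raise ValueError("no variant scored by every tool")
    results = {
        name: evaluate_scores(both["label"], both[name]) for name in score_columns
    }
    summary = pd.DataFrame(
        {
            name: dict(
                coverage=coverage[name],
                n_intersection=len(both),
                roc_auc=res.roc_auc,
                pr_auc=res.pr_auc,
            )
            for name, res in results.items()
        }
    ).T
    return summary, results
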