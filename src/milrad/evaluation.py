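"""Repeated k-fold cross-validation, diagnostic metrics, and method comparison.

The evaluation protocol is 20 repetitions of 5-fold cross-validation: per
repetition the subjects are reshuffled and split into folds so that each
subject is tested exactly once; synthetic oversampling is regenerated from
each training split and never enters a test fold.  Per repetition the
confusion counts are pooled over folds; recall, accuracy, PPV, NPV and AUC
are computed per repetition and aggregated as mean +/- SEM over repetitions.
Methods run on identical splits are compared with a paired two-sided
Wilcoxon signed-rank test.

Printed-formula note: the standard definitions are used throughout
(recall = TP/(TP+FN), accuracy = (TP+TN)/(TP+TN+FP+FN), PPV = TP/(TP+FP),
NPV = TN/(TN+FN)); any 0/0 case is flagged as undefined (NaN), excluded from
aggregation with a logged warning rather than coerced to 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata, wilcoxon

from .bagging import infer_max_bag_size
from .mil_models import MILModelConfig
from .model import MILModel
from .oversampling import OversampleConfig
from .schema import Bag
from .training import TrainConfig

__all__ = [
    "ConfusionCounts",
    "CVReport",
    "compute_metrics",
    "compute_auc",
    "confusion_counts",
    "cross_validate",
    "compare_methods",
    "sweep_oversampling",
    "sweep_batch_size",
]

logger = logging.getLogger(__name__)

METRICS = ("recall", "accuracy", "ppv", "npv", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (0/0); excluded from aggregation", name)
        return float("nan")
    return num / den


def compute_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Recall, accuracy, PPV, NPV from confusion counts; 0/0 -> NaN."""
    return {
        "recall": _ratio(counts.tp, counts.tp + counts.fn, "recall"),
        "accuracy": _ratio(counts.tp + counts.tn, counts.total, "accuracy"),
        "ppv": _ratio(counts.tp, counts.tp + counts.fp, "PPV"),
        "npv": _ratio(counts.tn, counts.tn + counts.fn, "NPV"),
    }


def compute_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC via the Mann-Whitney rank statistic (ties get 0.5 credit).

    Equals the trapezoidal area under the ROC curve.  Returns NaN when the
    labels contain a single class.
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        logger.warning("AUC undefined: test labels contain a single class")
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


class CVReport:
    """Cross-validation results for one method.

    ``fold_records`` keeps the raw per-(repetition, fold) confusion counts
    for auditability; ``rep_metrics`` holds the per-repetition pooled
    metrics that the mean/SEM aggregation and paired tests operate on.
    """

    def __init__(
        self,
        method: str,
        fold_records: pd.DataFrame,
        rep_metrics: pd.DataFrame,
        split_signature: tuple,
    ):
        self.method = method
        self.fold_records = fold_records
        self.rep_metrics = rep_metrics
        self.split_signature = split_signature

    @property
    def n_repetitions(self) -> int:
        return len(self.rep_metrics)

    def values(self, metric: str) -> np.ndarray:
        if metric not in METRICS:
            raise KeyError(f"unknown metric {metric!r}; choose from {METRICS}")
        return self.rep_metrics[metric].to_numpy()

    def mean(self, metric: str) -> float:
        return float(np.nanmean(self.values(metric)))

    def sem(self, metric: str) -> float:
        """Standard error of the mean over repetition-level values."""
        v = self.values(metric)
        v = v[np.isfinite(v)]
        if len(v) < 2:
            return float("nan")
        return float(np.std(v, ddof=1) / np.sqrt(len(v)))

    def summary(self) -> str:
        lines = [
            f"Cross-validation report: {self.method}",
            f"repetitions: {self.n_repetitions}, folds per repetition: "
            f"{self.fold_records['fold'].nunique()}",
            "-" * 44,
            f"{'metric':<10}{'mean':>10}{'SEM':>10}",
        ]
        for m in METRICS:
            lines.append(f"{m:<10}{self.mean(m):>10.3f}{self.sem(m):>10.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "mean": {m: self.mean(m) for m in METRICS},
            "sem": {m: self.sem(m) for m in METRICS},
            "rep_metrics": self.rep_metrics.to_dict(orient="records"),
            "fold_records": self.fold_records.to_dict(orient="records"),
        }


def _fold_seed(seed: int, fold: int) -> int:
    # depends on the fold only: with shuffling disabled, repetitions are
    # exact replicas; with shuffling, variability comes from the resplits
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(fold,))
    return int(ss.generate_state(1)[0] % (2**31))


def cross_validate(
    bags: list[Bag],
    model_configs: MILModelConfig | dict[str, MILModelConfig],
    train_config: TrainConfig | None = None,
    oversample: OversampleConfig | None = None,
    n_repetitions: int = 20,
    n_folds: int = 5,
    seed: int = 0,
    shuffle: bool = True,
    threshold: float = 0.5,
    max_bag_size: int | None = None,
) -> CVReport | dict[str, CVReport]:
    """Repeated k-fold cross-validation over subjects.

    When ``model_configs`` is a dict of named configurations, every method is
    trained and tested on identical splits (and identical synthetic bags),
    which is what makes the paired Wilcoxon comparison valid.  Returns one
    :class:`CVReport` per method (a bare config returns a bare report).
    """
    single = isinstance(model_configs, MILModelConfig)
    configs = {"model": model_configs} if single else dict(model_configs)
    train_config = train_config or TrainConfig()
    max_bag_size = max_bag_size or infer_max_bag_size(bags)

    n_pos = sum(b.label for b in bags)
    n_neg = len(bags) - n_pos
    if min(n_pos, n_neg) < n_folds:
        logger.warning(
            "fewer than n_folds=%d bags in one class (%d pos / %d neg); "
            "folds may lack a class and AUC will be flagged undefined",
            n_folds, n_pos, n_neg,
        )
    if any(b.synthetic for b in bags):
        raise ValueError("cross_validate expects real bags only")

    fold_rows: dict[str, list] = {name: [] for name in configs}
    rep_rows: dict[str, list] = {name: [] for name in configs}
    n = len(bags)

    for rep in range(n_repetitions):
        rep_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(rep,))
        )
        order = rep_rng.permutation(n) if shuffle else np.arange(n)
        folds = np.array_split(order, n_folds)
        rep_true: dict[str, list] = {name: [] for name in configs}
        rep_prob: dict[str, list] = {name: [] for name in configs}
        rep_counts: dict[str, ConfusionCounts] = {
            name: ConfusionCounts(0, 0, 0, 0) for name in configs
        }
        for fold_i, test_idx in enumerate(folds):
            test_set = set(int(i) for i in test_idx)
            train_bags = [bags[int(i)] for i in order if int(i) not in test_set]
            test_bags = [bags[int(i)] for i in test_idx]
            # anti-leakage guards: test folds are real bags, tested once
            assert not any(b.synthetic for b in test_bags)
            fold_cfg = replace(train_config, seed=_fold_seed(seed, fold_i))
            y_true = np.array([b.label for b in test_bags])
            for name, mcfg in configs.items():
                model = MILModel(train_bags, mcfg, max_bag_size=max_bag_size)
                res = model.fit(fold_cfg, oversample=oversample)
                probs = res.predict_proba(test_bags)
                y_pred = (probs >= threshold).astype(int)
                counts = confusion_counts(y_true, y_pred)
                met = compute_metrics(counts)
                fold_rows[name].append(
                    {
                        "repetition": rep, "fold": fold_i,
                        "tp": counts.tp, "tn": counts.tn,
                        "fp": counts.fp, "fn": counts.fn,
                        **met,
                        "auc": compute_auc(y_true, probs),
                    }
                )
                rep_counts[name] = rep_counts[name] + counts
                rep_true[name].extend(y_true.tolist())
                rep_prob[name].extend(probs.tolist())
        for name in configs:
            counts = rep_counts[name]
            rep_rows[name].append(
                {
                    "repetition": rep,
                    "tp": counts.tp, "tn": counts.tn,
                    "fp": counts.fp, "fn": counts.fn,
                    **compute_metrics(counts),
                    "auc": compute_auc(
                        np.array(rep_true[name]), np.array(rep_prob[name])
                    ),
                }
            )

    signature = (seed, n_repetitions, n_folds, tuple(b.subject_id for b in bags))
    reports = {
        name: CVReport(
            method=name,
            fold_records=pd.DataFrame(fold_rows[name]),
            rep_metrics=pd.DataFrame(rep_rows[name]),
            split_signature=signature,
        )
        for name in configs
    }
    return reports["model"] if single else reports


def compare_methods(
    report_a: CVReport, report_b: CVReport, metric: str = "auc"
) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired per-repetition values.

    Zero differences are handled with the Pratt method; identical reports
    give p = 1.  Reports must come from identical splits.
    """
    if report_a.split_signature != report_b.split_signature:
        raise ValueError(
            "reports are not paired: they were produced from different "
            "cross-validation splits"
        )
    a = report_a.values(metric)
    b = report_b.values(metric)
    mask = np.isfinite(a) & np.isfinite(b)
    diff = a[mask] - b[mask]
    if len(diff) == 0 or np.all(diff == 0):
        return 1.0
    return float(wilcoxon(diff, zero_method="pratt", alternative="two-sided").pvalue)


def sweep_oversampling(
    bags: list[Bag],
    model_configs: MILModelConfig | dict[str, MILModelConfig],
    train_config: TrainConfig | None = None,
    levels: tuple[int, ...] = (0, 20, 40, 60, 80, 100),
    oversample: OversampleConfig | None = None,
    **cv_kwargs,
) -> dict[int, CVReport | dict[str, CVReport]]:
    """Sensitivity of CV performance to the number of synthetic negatives."""
    base = oversample or OversampleConfig()
    out = {}
    for level in levels:
        cfg = replace(base, n_synthetic_negative=level) if level > 0 else None
        out[level] = cross_validate(
            bags, model_configs, train_config, oversample=cfg, **cv_kwargs
        )
    return out


def sweep_batch_size(
    bags: list[Bag],
    model_configs: MILModelConfig | dict[str, MILModelConfig],
    train_config: TrainConfig | None = None,
    batch_sizes: tuple[int, ...] = (1, 2, 3, 4),
    **cv_kwargs,
) -> dict[int, CVReport | dict[str, CVReport]]:
    """Sensitivity of CV performance to the SGD batch size (bags per step)."""
    train_config = train_config or TrainConfig()
    return {
        b: cross_validate(
            bags, model_configs, replace(train_config, batch_size=b), **cv_kwargs
        )
        for b in batch_sizes
    }
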