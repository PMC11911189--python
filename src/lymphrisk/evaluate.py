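"""Evaluation protocol: stratified 7:1:2 splits with repeats, classification
metrics, contingency-table chi-square tests, and Kaplan-Meier / log-rank
survival comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.stats import chi2_contingency
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

__all__ = [
    "SplitSpec",
    "CohortSplit",
    "MetricsEntry",
    "make_splits",
    "compute_metrics",
    "aggregate_repeats",
    "chisq_test",
    "km_curve",
    "logrank_test",
    "save_splits",
    "load_splits",
]


@dataclass
class SplitSpec:
    """Stratified train/validation/test protocol (defaults 0.7/0.1/0.2 x 10)."""

    train: float = 0.7
    val: float = 0.1
    test: float = 0.2
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")


@dataclass
class CohortSplit:
    repeat: int
    train: list = field(default_factory=list)
    val: list = field(default_factory=list)
    test: list = field(default_factory=list)


def make_splits(labels, spec: SplitSpec | None = None, ids=None) -> list[CohortSplit]:
    """Stratified random partitions, one per repeat.

    Per class c: floor(n_c * val_ratio) patients go to validation,
    floor(n_c * test_ratio) to test, the remainder to training. Each repeat
    r is seeded independently with ``spec.seed + r``.
    """
    spec = spec or SplitSpec()
    labels = np.asarray(labels)
    ids = np.asarray(ids if ids is not None else np.arange(len(labels)))
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least two patients in each of two classes")
    if any(int(np.floor(c * spec.test)) == 0 for c in counts):
        raise ValueError("a class is too small for a non-empty test partition")

    splits = []
    for r in range(spec.n_repeats):
        rng = np.random.default_rng(spec.seed + r)
        part: dict[str, list] = {"train": [], "val": [], "test": []}
        for c in classes:
            members = ids[labels == c]
            order = rng.permutation(len(members))
            n_val = int(np.floor(len(members) * spec.val))
            n_test = int(np.floor(len(members) * spec.test))
            part["val"].extend(members[order[:n_val]].tolist())
            part["test"].extend(members[order[n_val : n_val + n_test]].tolist())
            part["train"].extend(members[order[n_val + n_test :]].tolist())
        splits.append(CohortSplit(repeat=r, **part))
    return splits


def save_splits(splits: list[CohortSplit], path: str) -> None:
    with open(path, "w") as f:
        json.dump(
            [
                {"repeat": s.repeat, "train": list(s.train), "val": list(s.val),
                 "test": list(s.test)}
                for s in splits
            ],
            f,
        )


def load_splits(path: str) -> list[CohortSplit]:
    with open(path) as f:
        return [CohortSplit(**d) for d in json.load(f)]


@dataclass
class MetricsEntry:
    auroc: float
    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def compute_metrics(y_true, scores, threshold: float = 0.5) -> MetricsEntry:
    """AUROC (rank statistic, tie-midranks) plus thresholded class-1 metrics."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUROC undefined: y_true contains a single class")
    pred = (scores >= threshold).astype(int)
    return MetricsEntry(
        auroc=float(roc_auc_score(y_true, scores)),
        accuracy=float(accuracy_score(y_true, pred)),
        precision=float(precision_score(y_true, pred, zero_division=0)),
        recall=float(recall_score(y_true, pred, zero_division=0)),
        f1=float(f1_score(y_true, pred, zero_division=0)),
    )


def aggregate_repeats(entries: list[MetricsEntry]) -> dict[str, tuple[float, float]]:
    """Per metric: arithmetic mean and sample SD (n-1 denominator)."""
    if not entries:
        raise ValueError("no repeats to aggregate")
    df = pd.DataFrame([e.as_dict() for e in entries])
    sd = df.std(ddof=1) if len(df) > 1 else df.iloc[0] * 0.0
    return {k: (float(df[k].mean()), float(sd[k])) for k in df.columns}


def chisq_test(table, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    The Yates continuity correction (|O-E| reduced by 0.5, floored at 0) is
    applied only when ``yates`` is set and the table is 2x2. Returns
    (statistic, degrees of freedom, two-sided p).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(obs < 0):
        raise ValueError("negative counts")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("degenerate table: a row or column margin is zero")
    correction = bool(yates) and obs.shape == (2, 2)
    stat, p, dof, _ = chi2_contingency(obs, correction=correction)
    return float(stat), int(dof), float(p)


def km_curve(time, event) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns a right-continuous step function as a DataFrame with columns
    ``time`` and ``survival``, starting at S(0) = 1.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValueError("no subjects")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float),
         "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
    )


def logrank_test(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank chi-square (df=1); returns (statistic, p)."""
    if len(np.asarray(time_a)) == 0 or len(np.asarray(time_b)) == 0:
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(time_a, time_b, event_observed_A=event_a, event_observed_B=event_b)
    return float(res.test_statistic), float(res.p_value)
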