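"""Clinical-covariate risk modelling: preprocessing, random forest, Gini
feature selection, and accuracy-driven hyperparameter search.

Preprocessing follows routine clinical-table hygiene: variables missing in
more than one-third of patients are dropped; remaining categorical gaps are
imputed by the mode (ties broken lexicographically) and continuous gaps by
the median; declared continuous-to-categorical binnings (e.g. white-cell
count into decreased/normal/increased) are applied before one-hot encoding
of multicategory variables. Outcome-like variables (treatment response and
kin) never enter the design matrix.

The classifier is a random forest; features are ranked by Gini importance
(mean decrease in node impurity, normalised to sum 1) and only features
with positive importance are retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "VariableSchema",
    "PreprocessReport",
    "RFConfig",
    "ImportanceRanking",
    "preprocess",
    "apply_report",
    "rank_features",
    "select_features",
    "tune_hyperparameters",
    "train_rf",
    "predict_proba",
    "ClinicalRandomForest",
    "ClinicalRandomForestResults",
]

MISSING_DROP_FRACTION = 1.0 / 3.0  # drop iff missing fraction strictly exceeds this


@dataclass
class VariableSchema:
    """Schema of one clinical variable.

    kind: "binary" | "multicategory" | "continuous"; ``levels`` enumerates
    the admissible categories; ``binning`` optionally turns a continuous
    variable categorical via (cutoffs, labels) before encoding;
    ``is_outcome`` flags post-treatment variables that must not be used as
    predictors.
    """

    kind: str
    levels: list | None = None
    binning: tuple[list, list] | None = None  # (cut points, len+1 labels)
    is_outcome: bool = False


@dataclass
class RFConfig:
    n_estimators: int = 100
    max_depth: int = 10
    min_samples_split: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_estimators, self.max_depth) < 1 or self.min_samples_split < 2:
            raise ValueError("invalid random-forest configuration")


@dataclass
class PreprocessReport:
    """Everything needed to replay the fitted transform on new data."""

    dropped_variables: list[str] = field(default_factory=list)
    outcome_variables: list[str] = field(default_factory=list)
    imputation_values: dict[str, object] = field(default_factory=dict)
    binning_rules: dict[str, tuple] = field(default_factory=dict)
    onehot_map: dict[str, list] = field(default_factory=dict)
    columns: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        d = asdict(self)
        d["binning_rules"] = {k: list(v) for k, v in d["binning_rules"].items()}
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PreprocessReport":
        d = json.loads(text)
        d["binning_rules"] = {k: tuple(v) for k, v in d["binning_rules"].items()}
        return cls(**d)


@dataclass
class ImportanceRanking:
    """(feature, Gini importance) pairs sorted descending; importances sum to 1."""

    pairs: list[tuple[str, float]]

    def __post_init__(self) -> None:
        self.pairs = sorted(self.pairs, key=lambda kv: (-kv[1], kv[0]))

    def features(self) -> list[str]:
        return [k for k, _ in self.pairs]

    def as_series(self) -> pd.Series:
        return pd.Series(dict(self.pairs)).sort_values(ascending=False)


def _is_missing(col: pd.Series) -> pd.Series:
    return col.isna() | (col.astype(object) == "")


def _mode_lexicographic(values: pd.Series):
    counts = values.value_counts()
    top = counts[counts == counts.max()].index
    return sorted(map(str, top))[0] if all(isinstance(v, str) for v in top) else sorted(top)[0]


def _apply_binning(col: pd.Series, cutoffs: list, labels: list) -> pd.Series:
    idx = np.searchsorted(np.asarray(cutoffs, dtype=float), col.astype(float), side="right")
    return pd.Series(np.asarray(labels, dtype=object)[idx], index=col.index)


def preprocess(
    table: pd.DataFrame,
    schema: dict[str, VariableSchema],
    label_col: str = "label",
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Build the design matrix and a replayable :class:`PreprocessReport`."""
    report = PreprocessReport()
    work: dict[str, pd.Series] = {}
    for name in table.columns:
        if name == label_col or name not in schema:
            continue
        sch = schema[name]
        if sch.is_outcome:
            report.outcome_variables.append(name)
            continue
        col = table[name]
        miss = _is_missing(col)
        if miss.mean() > MISSING_DROP_FRACTION:
            report.dropped_variables.append(name)
            continue
        observed = col[~miss]
        if sch.kind == "continuous":
            fill = float(observed.astype(float).median())
        else:
            fill = _mode_lexicographic(observed)
        report.imputation_values[name] = fill
        col = col.where(~miss, fill)
        if sch.binning is not None:
            cutoffs, labels = sch.binning
            report.binning_rules[name] = (list(cutoffs), list(labels))
            col = _apply_binning(col, cutoffs, labels)
            kind = "multicategory" if len(labels) > 2 else "binary"
        else:
            kind = sch.kind
        if kind == "multicategory":
            levels = sorted(map(str, pd.unique(col.astype(str))))
            report.onehot_map[name] = levels
            for lev in levels:
                work[f"{name}={lev}"] = (col.astype(str) == lev).astype(float)
        elif kind == "binary":
            levels = sorted(map(str, pd.unique(col.astype(str))))
            if len(levels) > 2:
                raise ValueError(f"binary variable {name!r} has levels {levels}")
            ref = levels[-1] if len(levels) == 2 else levels[0]
            report.onehot_map[name] = levels
            work[name] = (col.astype(str) == ref).astype(float)
        else:
            work[name] = col.astype(float)
    X = pd.DataFrame(work, index=table.index)
    report.columns = list(X.columns)
    return X, report


def apply_report(
    table: pd.DataFrame, schema: dict[str, VariableSchema], report: PreprocessReport
) -> pd.DataFrame:
    """Replay a stored transform on new data; identical on the fitting table."""
    work: dict[str, pd.Series] = {}
    for name, fill in report.imputation_values.items():
        sch = schema[name]
        col = table[name]
        col = col.where(~_is_missing(col), fill)
        if name in report.binning_rules:
            cutoffs, labels = report.binning_rules[name]
            col = _apply_binning(col, cutoffs, labels)
        if name in report.onehot_map:
            levels = report.onehot_map[name]
            unknown = set(map(str, pd.unique(col.astype(str)))) - set(levels)
            if unknown and f"{name}={levels[0]}" in report.columns:
                raise ValueError(
                    f"unknown categories for {name!r} at replay: {sorted(unknown)}"
                )
            if f"{name}={levels[0]}" in report.columns:  # multicategory expansion
                for lev in levels:
                    work[f"{name}={lev}"] = (col.astype(str) == lev).astype(float)
            else:  # binary indicator against stored reference level
                if unknown:
                    raise ValueError(
                        f"unknown categories for {name!r} at replay: {sorted(unknown)}"
                    )
                ref = levels[-1] if len(levels) == 2 else levels[0]
                work[name] = (col.astype(str) == ref).astype(float)
        else:
            work[name] = col.astype(float)
    X = pd.DataFrame(work, index=table.index)
    return X[report.columns]


# ---------------------------------------------------------------------------
# random forest
# ---------------------------------------------------------------------------


def train_rf(X: pd.DataFrame | np.ndarray, y, rf: RFConfig) -> RandomForestClassifier:
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels are single-class")
    model = RandomForestClassifier(
        n_estimators=rf.n_estimators,
        max_depth=rf.max_depth,
        min_samples_split=rf.min_samples_split,
        random_state=rf.seed,
    )
    model.fit(np.asarray(X, dtype=float), y)
    return model


def predict_proba(model: RandomForestClassifier, X) -> np.ndarray:
    """Class-1 probabilities."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature-count mismatch: model expects {model.n_features_in_}, got {X.shape[1]}"
        )
    return model.predict_proba(X)[:, 1]


def rank_features(X: pd.DataFrame, y, rf: RFConfig) -> ImportanceRanking:
    """Gini importances (mean decrease in impurity), normalised to sum 1."""
    model = train_rf(X, y, rf)
    imp = model.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    names = list(X.columns) if hasattr(X, "columns") else [f"x{i}" for i in range(len(imp))]
    return ImportanceRanking(list(zip(names, imp.astype(float))))


def select_features(ranking: ImportanceRanking) -> list[str]:
    """Retain features with strictly positive Gini importance."""
    selected = [k for k, v in ranking.pairs if v > 0]
    if not selected:
        raise ValueError("feature selection is empty: no feature has positive importance")
    return selected


DEFAULT_SEARCH_SPACE = {
    "n_estimators": (10, 300),
    "max_depth": (2, 20),
    "min_samples_split": (2, 20),
}


def tune_hyperparameters(
    X_train,
    y_train,
    X_val,
    y_val,
    n_trials: int = 100,
    space: dict[str, tuple[int, int]] | None = None,
    seed: int = 0,
) -> tuple[RFConfig, list[dict]]:
    """Maximise validation accuracy over seeded random samples of the space.

    The sampler is deliberately pluggable-simple: uniform integer draws per
    trial. Returns the argmax configuration (first trial wins ties) and the
    full per-trial log.
    """
    space = space or DEFAULT_SEARCH_SPACE
    if n_trials < 1 or not space:
        raise ValueError("need n_trials >= 1 and a non-empty search space")
    rng = np.random.default_rng(seed)
    y_val = np.asarray(y_val, dtype=int)
    log: list[dict] = []
    best: tuple[float, RFConfig] | None = None
    for trial in range(n_trials):
        cfg = RFConfig(
            n_estimators=int(rng.integers(*space["n_estimators"], endpoint=True)),
            max_depth=int(rng.integers(*space["max_depth"], endpoint=True)),
            min_samples_split=int(rng.integers(*space["min_samples_split"], endpoint=True)),
            seed=seed,
        )
        model = train_rf(X_train, y_train, cfg)
        acc = float((model.predict(np.asarray(X_val, dtype=float)) == y_val).mean())
        log.append({"trial": trial, "config": asdict(cfg), "val_accuracy": acc})
        if best is None or acc > best[0]:
            best = (acc, cfg)
    return best[1], log


# ---------------------------------------------------------------------------
# model / results facade
# ---------------------------------------------------------------------------


class ClinicalRandomForest:
    """Random-forest R/R risk model over a clinical table.

    Wraps preprocessing (missingness cutoff, imputation, binning, one-hot),
    Gini-importance feature selection, and the forest fit itself.
    """

    def __init__(self, table: pd.DataFrame, schema: dict[str, VariableSchema],
                 label_col: str = "label"):
        self.table = table
        self.schema = schema
        self.label_col = label_col

    @classmethod
    def from_dataframe(cls, table, schema, label_col="label"):
        return cls(table, schema, label_col)

    def fit(self, rf: RFConfig | None = None) -> "ClinicalRandomForestResults":
        rf = rf or RFConfig()
        X, report = preprocess(self.table, self.schema, self.label_col)
        y = np.asarray(self.table[self.label_col], dtype=int)
        ranking = rank_features(X, y, rf)
        selected = select_features(ranking)
        model = train_rf(X[selected], y, rf)
        return ClinicalRandomForestResults(self, rf, report, ranking, selected, model)


@dataclass
class ClinicalRandomForestResults:
    model: ClinicalRandomForest
    rf_config: RFConfig
    report: PreprocessReport
    ranking: ImportanceRanking
    selected_features: list[str]
    forest: RandomForestClassifier

    def design_matrix(self, table: pd.DataFrame) -> pd.DataFrame:
        X = apply_report(table, self.model.schema, self.report)
        return X[self.selected_features]

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        return predict_proba(self.forest, self.design_matrix(table))

    def summary(self, top: int = 10) -> str:
        lines = [
            "Clinical random-forest R/R model",
            "=" * 44,
            f"patients              {len(self.model.table)}",
            f"features selected     {len(self.selected_features)}",
            f"variables dropped     {len(self.report.dropped_variables)} "
            f"(missing > 1/3: {', '.join(self.report.dropped_variables) or 'none'})",
            f"forest                n_estimators={self.rf_config.n_estimators}, "
            f"max_depth={self.rf_config.max_depth}, "
            f"min_samples_split={self.rf_config.min_samples_split}",
            "",
            f"top {top} features by Gini importance:",
        ]
        for name, imp in self.ranking.pairs[:top]:
            lines.append(f"  {name:<32s} {imp:.4f}")
        return "\n".join(lines)
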