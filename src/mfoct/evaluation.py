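"""Classifier benchmark: stratified cross-validation of eight models over a
labelled multifractal feature table, with the full clinical metric suite.

The positive class is DR throughout.  Per fold, feature columns are
z-scored with statistics of the training split only (no leakage), the
model is fitted and the test confusion counts collected; per-model
aggregates add the fold-mean of every metric, a Student-t 95% confidence
interval of the accuracy and a one-sided t-test p-value against the 0.50
chance level.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .multifractal import FEATURE_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "POSITIVE_LABEL",
    "CSV_COLUMNS",
    "ClassifierSpec",
    "CLASSIFIER_NAMES",
    "classifier_spec",
    "ConfusionCounts",
    "EvaluationReport",
    "load_feature_table",
    "validate_feature_table",
    "normalize_features",
    "stratified_kfold",
    "train_classifier",
    "evaluate_fold",
    "compute_metrics",
    "aggregate",
    "ClassifierBenchmark",
    "BenchmarkResults",
    "run_experiment",
]

POSITIVE_LABEL = "DR"
NEGATIVE_LABEL = "Normal"
CSV_COLUMNS = ("ID", *FEATURE_NAMES, "class")
METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "specificity")

# fixed hyperparameter presets for the eight benchmarked models
_PRESETS: dict[str, dict] = {
    "logistic_regression": {"solver": "liblinear", "penalty": "l2", "C": 1.0},
    "random_forest": {"n_estimators": 100, "max_depth": 10},
    "decision_tree": {"max_depth": 5, "criterion": "entropy"},
    "svm_poly": {"kernel": "poly", "degree": 3, "C": 1.0, "probability": True},
    "gradient_boosting": {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 3},
    "xgboost_style_gbt": {
        "n_estimators": 100,
        "learning_rate": 0.1,
        "max_depth": 4,
        "eval_metric": "logloss",
    },
    "lightgbm_style_gbt": {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 5},
    "mlp": {
        "hidden_layer_sizes": (128, 64),
        "activation": "relu",
        "solver": "adam",
        "max_iter": 1000,
        "random_state": 42,
    },
}

CLASSIFIER_NAMES = tuple(_PRESETS)


@dataclass(frozen=True)
class ClassifierSpec:
    """A benchmark model: preset name plus its (overridable) hyperparameters."""

    name: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in _PRESETS:
            raise ValueError(f"unknown classifier {self.name!r}; choose from {CLASSIFIER_NAMES}")

    def resolved(self) -> dict:
        params = dict(_PRESETS[self.name])
        params.update(self.hyperparameters)
        return params

    def build(self, seed: int = 42):
        """Instantiate the underlying estimator with a fixed random state."""
        params = self.resolved()
        if self.name == "logistic_regression":
            from sklearn.linear_model import LogisticRegression

            if params.get("penalty") == "l2":  # sklearn default; kwarg deprecated
                params.pop("penalty")
            return LogisticRegression(**params)
        if self.name == "random_forest":
            from sklearn.ensemble import RandomForestClassifier

            return RandomForestClassifier(random_state=seed, **params)
        if self.name == "decision_tree":
            from sklearn.tree import DecisionTreeClassifier

            return DecisionTreeClassifier(random_state=seed, **params)
        if self.name == "svm_poly":
            from sklearn.svm import SVC

            return SVC(random_state=seed, **params)
        if self.name == "gradient_boosting":
            from sklearn.ensemble import GradientBoostingClassifier

            return GradientBoostingClassifier(random_state=seed, **params)
        if self.name == "xgboost_style_gbt":
            from xgboost import XGBClassifier

            return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0, **params)
        if self.name == "lightgbm_style_gbt":
            from lightgbm import LGBMClassifier

            return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1, **params)
        from sklearn.neural_network import MLPClassifier

        return MLPClassifier(**params)  # random_state fixed to 42 in the preset


def classifier_spec(name: str, **overrides) -> ClassifierSpec:
    return ClassifierSpec(name=name, hyperparameters=overrides)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with DR as the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


# --- feature tables -------------------------------------------------------


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema, missing values, id uniqueness and class support."""
    missing = [c for c in CSV_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    table = table.loc[:, list(CSV_COLUMNS)]
    if table.isna().any().any():
        rows = table.index[table.isna().any(axis=1)].tolist()
        raise ValueError(f"feature table has missing values in rows {rows[:5]}")
    if table.duplicated(subset=["ID", "class"]).any():
        raise ValueError("duplicate (ID, class) pairs in feature table")
    counts = table["class"].value_counts()
    for label in (POSITIVE_LABEL, NEGATIVE_LABEL):
        if counts.get(label, 0) < 2:
            raise ValueError(f"need >= 2 rows of class {label!r}, got {counts.get(label, 0)}")
    return table


def load_feature_table(path: str | Path) -> pd.DataFrame:
    try:
        table = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"cannot parse feature CSV {path}: {exc}") from exc
    return validate_feature_table(table)


def normalize_features(
    train: pd.DataFrame, test: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Z-score both splits with mean/sd fitted on the training split only.

    Zero-variance features are passed through unchanged (scale treated as
    one) with a warning; the fitted scaler parameters are returned for
    audit.
    """
    cols = list(FEATURE_NAMES)
    mean = train[cols].mean()
    sd = train[cols].std(ddof=0)
    # float roundoff can leave a ~1e-16 spread on a constant column
    tol = 1e-12 * mean.abs().clip(lower=1.0)
    constant = sd.index[sd <= tol].tolist()
    if constant:
        warnings.warn(
            f"constant feature(s) passed through unscaled: {constant}",
            RuntimeWarning,
            stacklevel=2,
        )
        sd[constant] = 1.0
    train = train.copy()
    test = test.copy()
    train[cols] = (train[cols] - mean) / sd
    test[cols] = (test[cols] - mean) / sd
    params = {"mean": mean.to_dict(), "sd": sd.to_dict(), "constant": constant}
    return train, test, params


def stratified_kfold(
    table: pd.DataFrame, k: int = 5, seed: int = 42
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold split returning (train_ids, test_ids) pairs.

    Test folds are disjoint, cover every row, and per-fold class counts
    deviate from perfect proportion by at most one.
    """
    from sklearn.model_selection import StratifiedKFold

    counts = table["class"].value_counts()
    if (counts < k).any():
        small = counts[counts < k].to_dict()
        raise ValueError(f"every class needs >= k={k} rows, got {small}")
    ids = table["ID"].to_numpy()
    return [
        (ids[train_idx].copy(), ids[test_idx].copy())
        for train_idx, test_idx in _stratified_positions(table, k, seed)
    ]


def _stratified_positions(table: pd.DataFrame, k: int, seed: int):
    from sklearn.model_selection import StratifiedKFold

    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    labels = table["class"].to_numpy()
    return list(splitter.split(np.zeros(len(table)), labels))


# --- training and metrics -------------------------------------------------


def _xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    x = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = (table["class"] == POSITIVE_LABEL).astype(int).to_numpy()
    return x, y


def train_classifier(spec: ClassifierSpec, train: pd.DataFrame, seed: int = 42):
    """Fit one benchmark model on a (normalized) training table."""
    x, y = _xy(train)
    model = spec.build(seed=seed)
    with warnings.catch_warnings():
        # the iteration cap is the stopping rule; non-convergence is acceptable
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", FutureWarning)  # upstream API deprecations
        model.fit(x, y)
    return model


def evaluate_fold(model, test: pd.DataFrame) -> ConfusionCounts:
    """Confusion counts of a fitted model on a test table (DR positive)."""
    x, y = _xy(test)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*valid feature names.*")
        pred = np.asarray(model.predict(x)).astype(int)
    return ConfusionCounts(
        TP=int(np.sum((pred == 1) & (y == 1))),
        TN=int(np.sum((pred == 0) & (y == 0))),
        FP=int(np.sum((pred == 1) & (y == 0))),
        FN=int(np.sum((pred == 0) & (y == 1))),
    )


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall/sensitivity, specificity and F1.

    A zero denominator makes the affected metric NaN (undefined) with a
    warning, never silently zero.
    """

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", RuntimeWarning, stacklevel=3)
            return float("nan")
        return num / den

    accuracy = ratio(c.TP + c.TN, c.total, "accuracy")
    precision = ratio(c.TP, c.TP + c.FP, "precision")
    recall = ratio(c.TP, c.TP + c.FN, "recall")
    specificity = ratio(c.TN, c.TN + c.FP, "specificity")
    if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
        warnings.warn("f1 undefined", RuntimeWarning, stacklevel=2)
        f1 = float("nan")
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "specificity": specificity,
    }


@dataclass
class EvaluationReport:
    """Per-fold metrics and confusion counts of one model, with aggregates."""

    model_name: str
    fold_metrics: list[dict[str, float]]
    fold_confusions: list[ConfusionCounts]
    mean_metrics: dict[str, float]
    accuracy_ci95: tuple[float, float]
    p_value_vs_chance: float

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "folds": [
                {**m, "confusion": vars(c)}
                for m, c in zip(self.fold_metrics, self.fold_confusions)
            ],
            "mean": self.mean_metrics,
            "accuracy_ci95": list(self.accuracy_ci95),
            "p_value_vs_chance": self.p_value_vs_chance,
        }


def aggregate(
    folds: list[dict[str, float]],
    confusions: list[ConfusionCounts] | None = None,
    model_name: str = "",
    chance: float = 0.5,
) -> EvaluationReport:
    """Fold means, Student-t 95% CI of accuracy, one-sided p-value vs chance."""
    if len(folds) < 2:
        raise ValueError("need >= 2 folds to aggregate")
    mean_metrics = {
        name: float(np.nanmean([f[name] for f in folds])) for name in METRIC_NAMES
    }
    acc = np.array([f["accuracy"] for f in folds], dtype=float)
    k = acc.size
    m = float(acc.mean())
    s = float(acc.std(ddof=1))
    if s == 0.0:
        ci = (m, m)
        p = 0.0 if m > chance else 1.0
    else:
        half = float(stats.t.ppf(0.975, k - 1)) * s / np.sqrt(k)
        ci = (m - half, m + half)
        p = float(stats.ttest_1samp(acc, chance, alternative="greater").pvalue)
    return EvaluationReport(
        model_name=model_name,
        fold_metrics=folds,
        fold_confusions=confusions or [],
        mean_metrics=mean_metrics,
        accuracy_ci95=ci,
        p_value_vs_chance=p,
    )


# --- the benchmark model object ------------------------------------------


class ClassifierBenchmark:
    """Stratified k-fold benchmark of the eight classifiers on a feature table.

    Parameters
    ----------
    table : DataFrame
        Labelled feature table with the canonical columns.
    models : 'all' or list of str/ClassifierSpec
        Which presets to run.
    k : int
        Number of stratified folds (default 5; test folds are 1/k of the data).
    seed : int
        Controls fold assignment and stochastic model initialization.

    Examples
    --------
    >>> from mfoct import sample_feature_table, ClassifierBenchmark
    >>> table = sample_feature_table(n_per_class=50, seed=0)
    >>> res = ClassifierBenchmark(table, models=['mlp'], seed=0).fit()
    >>> res.reports['mlp'].mean_metrics['accuracy'] > 0.9
    True
    """

    def __init__(self, table: pd.DataFrame, models="all", k: int = 5, seed: int = 42):
        self.table = validate_feature_table(table)
        if models == "all":
            specs = [ClassifierSpec(name) for name in CLASSIFIER_NAMES]
        else:
            specs = [m if isinstance(m, ClassifierSpec) else ClassifierSpec(m) for m in models]
        self.specs = specs
        self.k = int(k)
        self.seed = int(seed)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "ClassifierBenchmark":
        return cls(load_feature_table(path), **kwargs)

    def fit(self) -> "BenchmarkResults":
        counts = self.table["class"].value_counts()
        if (counts < self.k).any():
            raise ValueError(f"every class needs >= k={self.k} rows, got {counts.to_dict()}")
        positions = _stratified_positions(self.table, self.k, self.seed)
        ids = self.table["ID"].to_numpy()
        folds = [(ids[tr].copy(), ids[te].copy()) for tr, te in positions]
        reports: dict[str, EvaluationReport] = {}
        for spec in self.specs:
            fold_metrics, fold_confusions = [], []
            for train_idx, test_idx in positions:
                train = self.table.iloc[train_idx]
                test = self.table.iloc[test_idx]
                train_n, test_n, _ = normalize_features(train, test)
                model = train_classifier(spec, train_n, seed=self.seed)
                counts = evaluate_fold(model, test_n)
                fold_metrics.append(compute_metrics(counts))
                fold_confusions.append(counts)
            reports[spec.name] = aggregate(
                fold_metrics, fold_confusions, model_name=spec.name
            )
            logger.info(
                "benchmark: %s mean accuracy %.4f",
                spec.name,
                reports[spec.name].mean_metrics["accuracy"],
            )
        return BenchmarkResults(benchmark=self, folds=folds, reports=reports)


@dataclass
class BenchmarkResults:
    """Cross-validation outcome for every requested model."""

    benchmark: ClassifierBenchmark
    folds: list[tuple[np.ndarray, np.ndarray]]
    reports: dict[str, EvaluationReport]

    def fold_table(self) -> pd.DataFrame:
        """Long per-fold metric table (one row per model and fold, plus averages)."""
        rows = []
        for name, rep in self.reports.items():
            for i, m in enumerate(rep.fold_metrics, start=1):
                rows.append({"model": name, "fold": i, **m})
            rows.append({"model": name, "fold": "average", **rep.mean_metrics})
        return pd.DataFrame(rows)

    def summary_table(self) -> pd.DataFrame:
        """One row per model: mean metrics, accuracy CI and p-value vs chance."""
        rows = []
        for name, rep in self.reports.items():
            lo, hi = rep.accuracy_ci95
            rows.append(
                {
                    "model": name,
                    **rep.mean_metrics,
                    "accuracy_ci95_low": lo,
                    "accuracy_ci95_high": hi,
                    "p_value_vs_chance": rep.p_value_vs_chance,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.summary_table()
        lines = [
            "Stratified %d-fold benchmark (%d rows, seed %d)"
            % (self.benchmark.k, len(self.benchmark.table), self.benchmark.seed),
            "=" * 64,
        ]
        for _, r in df.iterrows():
            lines.append(
                f"{r['model']:<20s} acc {r['accuracy']:.4f} "
                f"[{r['accuracy_ci95_low']:.4f}, {r['accuracy_ci95_high']:.4f}]  "
                f"prec {r['precision']:.4f}  rec {r['recall']:.4f}  "
                f"spec {r['specificity']:.4f}  F1 {r['f1']:.4f}"
            )
        return "\n".join(lines)

    def confusion_dict(self) -> dict:
        return {
            name: [vars(c) for c in rep.fold_confusions]
            for name, rep in self.reports.items()
        }

    def plot_confusions(self, axes=None):
        """Grid of per-model confusion matrices summed over folds."""
        import matplotlib.pyplot as plt

        names = list(self.reports)
        if axes is None:
            ncols = min(4, len(names))
            nrows = -(-len(names) // ncols)
            _, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 3 * nrows))
        axes = np.atleast_1d(np.asarray(axes)).ravel()
        for ax, name in zip(axes, names):
            cs = self.reports[name].fold_confusions
            mat = np.array(
                [
                    [sum(c.TP for c in cs), sum(c.FN for c in cs)],
                    [sum(c.FP for c in cs), sum(c.TN for c in cs)],
                ]
            )
            ax.imshow(mat, cmap="Blues")
            for (i, j), v in np.ndenumerate(mat):
                ax.text(j, i, str(v), ha="center", va="center")
            ax.set_xticks([0, 1], ["pred DR", "pred Normal"])
            ax.set_yticks([0, 1], ["DR", "Normal"])
            ax.set_title(name, fontsize=9)
        for ax in axes[len(names):]:
            ax.axis("off")
        return axes

    def save(self, out_dir: str | Path) -> None:
        """Write report.json, table6.csv (per-fold), table7.csv (summary), confusion.json."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        payload = {name: rep.to_dict() for name, rep in self.reports.items()}
        (out_dir / "report.json").write_text(json.dumps(payload, indent=2))
        self.fold_table().to_csv(out_dir / "table6.csv", index=False)
        self.summary_table().to_csv(out_dir / "table7.csv", index=False)
        (out_dir / "confusion.json").write_text(json.dumps(self.confusion_dict(), indent=2))


def run_experiment(
    features: str | Path | pd.DataFrame,
    models="all",
    k: int = 5,
    seed: int = 42,
    out_dir: str | Path | None = None,
) -> BenchmarkResults:
    """Full benchmark over a feature CSV (or DataFrame); optionally save reports."""
    if isinstance(features, (str, Path)):
        bench = ClassifierBenchmark.from_csv(features, models=models, k=k, seed=seed)
    else:
        bench = ClassifierBenchmark(features, models=models, k=k, seed=seed)
    results = bench.fit()
    if out_dir is not None:
        results.save(out_dir)
    return results
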