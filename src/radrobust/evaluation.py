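"""Matched-fold repeated cross-validation of the six classifiers.

Thirty repetitions of stratified 5-fold cross-validation; the fold plan is
generated once per cohort and shared by every model and segmentation
method ("matched folds"), so performance differences cannot come from
different partitions.  Per repetition, test-fold predictions are pooled
into a single confusion matrix and a single AUC (from continuous scores),
giving one value of each metric per repetition; the report carries the
30-repetition means and 95% percentile bootstrap confidence intervals of
the mean (1000 resamples).

Metrics (percent): accuracy, AUC, sensitivity, specificity, precision,
fscore.  The positive class is the high grade.  Model hyperparameters are
fixed, documented defaults: LDA; RBF-SVM (C=1, gamma='scale'); KNN (k=5);
random forest (100 trees); AdaBoost (50 stumps); one-hidden-layer neural
network (16 units).  Features are z-scored inside each training fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "FoldPlan",
    "make_repeated_folds",
    "default_model_grid",
    "bootstrap_ci",
    "confusion_metrics",
    "CrossValidationExperiment",
    "CVResults",
    "METRICS",
    "MODEL_NAMES",
]

METRICS = ("accuracy", "auc", "sensitivity", "specificity", "precision", "fscore")
MODEL_NAMES = ("LDA", "SVM", "KNN", "RF", "AdaBoost", "NN")


@dataclass(frozen=True)
class FoldPlan:
    """Stratified partitions: ``folds[rep]`` is a list of (train, test) arrays."""

    folds: tuple
    n_subjects: int
    k: int
    reps: int
    seed: int

    def index_hash(self) -> str:
        """Digest of every train/test index array (matched-folds contract)."""
        import hashlib

        h = hashlib.sha256()
        for rep in self.folds:
            for train, test in rep:
                h.update(np.asarray(train, dtype=np.int64).tobytes())
                h.update(np.asarray(test, dtype=np.int64).tobytes())
        return h.hexdigest()


def make_repeated_folds(labels, k: int = 5, reps: int = 30, seed: int = 0) -> FoldPlan:
    """Repeated stratified k-fold partition plan, deterministic in ``seed``."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"class too small to stratify: {dict(zip(classes, counts))} with k={k}"
        )
    rng = np.random.default_rng(seed)
    all_reps = []
    for _ in range(reps):
        skf = StratifiedKFold(
            n_splits=k, shuffle=True, random_state=int(rng.integers(0, 2**31 - 1))
        )
        all_reps.append(tuple((tr.copy(), te.copy()) for tr, te in skf.split(np.zeros(len(y)), y)))
    return FoldPlan(tuple(all_reps), n_subjects=len(y), k=k, reps=reps, seed=seed)


def default_model_grid(seed: int = 0) -> dict:
    """The six classifiers with fixed hyperparameters and derived seeds."""
    return {
        "LDA": LinearDiscriminantAnalysis(),
        "SVM": SVC(kernel="rbf", C=1.0, gamma="scale"),
        "KNN": KNeighborsClassifier(n_neighbors=5),
        "RF": RandomForestClassifier(n_estimators=100, random_state=seed),
        "AdaBoost": AdaBoostClassifier(n_estimators=50, random_state=seed + 1),
        "NN": MLPClassifier(
            hidden_layer_sizes=(16,), max_iter=500, random_state=seed + 2
        ),
    }


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """The five confusion-matrix metrics, as percentages."""
    n = tp + fp + tn + fn
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return {
        "accuracy": 100.0 * (tp + tn) / n,
        "sensitivity": 100.0 * sens,
        "specificity": 100.0 * spec,
        "precision": 100.0 * prec,
        "fscore": 100.0 * f1,
    }


def bootstrap_ci(
    values, n_boot: int = 1000, level: float = 95.0, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap interval of the mean; deterministic in ``seed``."""
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    means = x[idx].mean(axis=1)
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(means, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def _scores(model, X) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=np.float64)
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(X)[:, 1], dtype=np.float64)
    return np.asarray(model.predict(X), dtype=np.float64)


class CrossValidationExperiment:
    """Matched-fold CV of a model grid on one feature matrix.

    Parameters
    ----------
    X : DataFrame or array (subjects x selected features)
    y : labels; ``positive`` names the positive class
    plan : shared :class:`FoldPlan`
    models : mapping name -> unfitted sklearn estimator (defaults to the
        six-model grid)
    """

    def __init__(self, X, y, plan: FoldPlan, models: dict | None = None,
                 positive: str = "high", seed: int = 0):
        self.X = np.asarray(X, dtype=np.float64)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        y = np.asarray(y)
        self.y = (y == positive).astype(int) if y.dtype.kind in "OUS" else y.astype(int)
        if len(self.y) != plan.n_subjects:
            raise ValueError("fold plan does not cover these subjects")
        if self.X.shape[1] < 1:
            raise ValueError("need at least one selected feature")
        self.plan = plan
        self.models = models if models is not None else default_model_grid(seed)
        self.seed = seed

    def fit(self) -> "CVResults":
        from sklearn.base import clone

        rows = []
        failures: dict[str, int] = {name: 0 for name in self.models}
        for name, proto in self.models.items():
            for rep_i, rep in enumerate(self.plan.folds):
                y_true = np.empty(len(self.y), dtype=int)
                y_pred = np.empty(len(self.y), dtype=int)
                y_score = np.empty(len(self.y), dtype=np.float64)
                ok = True
                for train, test in rep:
                    model = make_pipeline(StandardScaler(), clone(proto))
                    try:
                        model.fit(self.X[train], self.y[train])
                        y_pred[test] = model.predict(self.X[test])
                        y_score[test] = _scores(model, self.X[test])
                    except Exception:
                        ok = False
                        break
                    y_true[test] = self.y[test]
                if not ok:
                    failures[name] += 1
                    continue
                tp = int(((y_pred == 1) & (y_true == 1)).sum())
                fp = int(((y_pred == 1) & (y_true == 0)).sum())
                tn = int(((y_pred == 0) & (y_true == 0)).sum())
                fn = int(((y_pred == 0) & (y_true == 1)).sum())
                rec = confusion_metrics(tp, fp, tn, fn)
                rec["auc"] = 100.0 * float(roc_auc_score(y_true, y_score))
                rec.update(model=name, repetition=rep_i, tp=tp, fp=fp, tn=tn, fn=fn)
                rows.append(rec)
        per_rep = pd.DataFrame(rows)
        return CVResults(per_rep, failures=failures, plan=self.plan, seed=self.seed)


class CVResults:
    """Per-repetition metrics, aggregate means and bootstrap CIs."""

    def __init__(self, per_repetition: pd.DataFrame, failures, plan, seed: int = 0):
        self.per_repetition = per_repetition
        self.failures = failures
        self.plan = plan
        self.seed = seed

    def aggregate(self, n_boot: int = 1000) -> pd.DataFrame:
        """Mean and 95% bootstrap CI per model x metric (percent)."""
        rows = []
        for name, sub in self.per_repetition.groupby("model", sort=False):
            rec = {"model": name, "n_repetitions": len(sub), "n_failed": self.failures.get(name, 0)}
            for i, metric in enumerate(METRICS):
                vals = sub[metric].to_numpy()
                rec[metric] = float(vals.mean())
                lo, hi = bootstrap_ci(vals, n_boot=n_boot, seed=self.seed + 104729 * i)
                rec[f"{metric}_ci_low"], rec[f"{metric}_ci_high"] = lo, hi
            rows.append(rec)
        return pd.DataFrame(rows).set_index("model")

    def summary(self) -> str:
        agg = self.aggregate()
        cols = list(METRICS)
        lines = [
            f"Repeated stratified CV: {self.plan.reps} x {self.plan.k}-fold, "
            f"n = {self.plan.n_subjects} (positive class: high grade)",
            agg[cols].round(2).to_string(),
        ]
        failed = {k: v for k, v in self.failures.items() if v}
        if failed:
            lines.append(f"repetitions excluded for non-convergence: {failed}")
        return "\n".join(lines)
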