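"""Hybrid descriptive-inferential feature selection.

Features are ranked by the absolute point-biserial correlation between
feature values and the binary grade label (descriptive step).  A logistic
regression is then grown along the ranking: at iteration m it is fitted on
the top-m features and the model's p-value — the likelihood-ratio test of
the fitted model against the intercept-only model — is recorded.  The
first iteration whose p-value fails to decrease stops the process and the
previous prefix is returned (the first feature is always accepted).  On
cohorts with one dominant feature this typically returns a singleton.

Ties in the ranking are broken lexicographically by feature name and the
design matrix is z-scored before each logistic fit, so repeated runs on
identical inputs are bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = ["point_biserial", "SelectionResults", "HybridFeatureSelector"]


def point_biserial(values: np.ndarray, labels: np.ndarray) -> float:
    """Point-biserial correlation = Pearson correlation with 0/1 labels.

    Returns NaN for constant values or a single class (such features are
    dropped from the ranking).
    """
    x = np.asarray(values, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if x.std() == 0 or y.std() == 0:
        return np.nan
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))


@dataclass
class SelectionResults:
    """Ranking, p-value trace and the selected prefix."""

    scores: pd.Series              # r_pb per feature, ranking order
    pvalue_trace: list[float]      # one entry per logistic iteration
    selected: list[str]            # ordered prefix of the ranking
    stop_iteration: int            # index of the iteration that triggered the stop
    separation_stop: bool = False  # True if a perfect-separation fit froze selection
    notes: list[str] = field(default_factory=list)

    @property
    def ranking(self) -> list[str]:
        return list(self.scores.index)

    def summary(self) -> str:
        head = self.scores.head(10)
        lines = [
            "Hybrid descriptive-inferential feature selection",
            f"ranked features: {len(self.scores)}; selected: {len(self.selected)}",
            f"selected: {self.selected}",
            f"p-value trace: {[f'{p:.3g}' for p in self.pvalue_trace]}",
            "",
            "top of ranking (point-biserial r):",
            head.round(4).to_string(),
        ]
        if self.notes:
            lines += [""] + self.notes
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "ranking_head": self.ranking[:20],
            "pvalue_trace": self.pvalue_trace,
            "selected": self.selected,
            "stop_iteration": self.stop_iteration,
            "separation_stop": self.separation_stop,
        }


class HybridFeatureSelector:
    """Model-style wrapper: construct from data, ``fit()`` returns results.

    Parameters
    ----------
    table : DataFrame (subjects x features)
    labels : binary labels; the positive class is ``positive`` (default
        "high").
    """

    def __init__(self, table: pd.DataFrame, labels, positive: str = "high"):
        self.table = table
        y = pd.Series(labels, index=table.index)
        self.y = (y == positive).astype(float) if y.dtype == object else y.astype(float)
        if self.y.nunique() != 2:
            raise ValueError("labels must contain exactly two classes")
        if self.y.value_counts().min() < 2:
            raise ValueError("need at least 2 subjects per class")

    def rank(self) -> pd.Series:
        """|r_pb|-descending ranking; NaN-scored features dropped; ties by name."""
        y = self.y.to_numpy()
        scores = {
            name: point_biserial(self.table[name].to_numpy(), y)
            for name in self.table.columns
        }
        s = pd.Series(scores).dropna()
        if s.empty:
            raise ValueError("no feature with a finite point-biserial score")
        order = sorted(s.index, key=lambda n: (-abs(s[n]), n))
        return s.loc[order]

    def _model_pvalue(self, columns) -> float:
        """Likelihood-ratio p-value of logistic(top-m) vs intercept-only."""
        X = self.table[list(columns)].to_numpy(dtype=np.float64)
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        X = sm.add_constant(X, has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(self.y.to_numpy(), X).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(fit.params)):
                raise PerfectSeparationError("non-finite logistic coefficients")
            return float(fit.llr_pvalue)

    def fit(self) -> SelectionResults:
        scores = self.rank()
        ranking = list(scores.index)
        trace: list[float] = []
        notes: list[str] = []
        selected_len = 0
        separation = False
        for m in range(1, len(ranking) + 1):
            try:
                p = self._model_pvalue(ranking[:m])
            except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
                notes.append(
                    f"iteration {m}: perfect separation / singular fit; "
                    "selection frozen at previous prefix"
                )
                trace.append(np.nan)
                separation = True
                if m == 1:
                    # a perfectly separating first feature is still selected:
                    # the selected subset must be nonempty
                    selected_len = 1
                break
            trace.append(p)
            if m == 1 or p < trace[m - 2]:
                selected_len = m
            else:
                break
        return SelectionResults(
            scores=scores,
            pvalue_trace=trace,
            selected=ranking[:selected_len],
            stop_iteration=len(trace) - 1,
            separation_stop=separation,
            notes=notes,
        )
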