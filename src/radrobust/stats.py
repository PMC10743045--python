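"""Nonparametric statistical battery over ICC groupings and CV performance.

Distribution checks (Lilliefors normality per group, Levene homogeneity of
variance across groups) are followed by omnibus nonparametric tests —
Kruskal-Wallis across independent groups, Friedman across treatments within
blocks — and, when the omnibus test is significant at 0.05, Dunn-type
pairwise z-tests on mean ranks with the Dunn-Šidák familywise adjustment
p_adj = 1 - (1 - p)^m over all unordered pairs.

The per-feature ICCs fed to these tests share subjects and are therefore
correlated; the battery reproduces the conventional procedure and carries
that caveat in its reports.  p-values too small to represent are printed
as "< 2.2e-16" rather than 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

__all__ = [
    "StatReport",
    "format_p",
    "sidak_adjust",
    "distribution_checks",
    "kruskal_wallis_posthoc",
    "friedman_posthoc",
]

_ALPHA = 0.05
_P_FLOOR = 2.2e-16


def format_p(p: float) -> str:
    """Render a p-value; values below representable precision as '< 2.2e-16'."""
    if np.isnan(p):
        return "nan"
    if p < _P_FLOOR:
        return "< 2.2e-16"
    return f"{p:.4g}"


def sidak_adjust(p: float, m: int) -> float:
    """Dunn-Šidák familywise adjustment 1 - (1-p)^m, clipped to [0, 1]."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    # -expm1(m * log1p(-p)) is 1-(1-p)^m without cancellation for small p
    if p >= 1.0:
        return 1.0
    return float(min(1.0, -np.expm1(m * np.log1p(-p))))


@dataclass
class StatReport:
    """One omnibus test with optional Šidák-adjusted pairwise comparisons."""

    test: str
    description: str
    statistic: float
    pvalue: float
    m_comparisons: int = 0
    pairwise: pd.DataFrame | None = None  # columns: a, b, z, p_raw, p_adj, significant
    notes: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.pvalue < _ALPHA

    def summary(self) -> str:
        lines = [
            f"{self.test}: {self.description}",
            f"statistic = {self.statistic:.4g}, p = {format_p(self.pvalue)}"
            + (" (significant at 0.05)" if self.significant else ""),
        ]
        if self.pairwise is not None and len(self.pairwise):
            tab = self.pairwise.copy()
            tab["p_raw"] = tab["p_raw"].map(format_p)
            tab["p_adj"] = tab["p_adj"].map(format_p)
            lines += [f"post hoc ({self.m_comparisons} comparisons, Dunn-Šidák):",
                      tab.to_string(index=False)]
        lines += self.notes
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "test": self.test,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "m_comparisons": self.m_comparisons,
        }
        if self.pairwise is not None:
            out["pairwise"] = self.pairwise.to_dict(orient="records")
        return out


def distribution_checks(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Lilliefors normality per group plus one Levene test across groups.

    Returns a tidy frame with one row per group (statistic, p) and a final
    'levene(all)' row; constant groups are flagged and skipped in the
    normality test.
    """
    rows = []
    clean = {}
    for name, vals in groups.items():
        x = np.asarray(vals, dtype=np.float64)
        if len(x) < 4:
            raise ValueError(f"group {name!r} has fewer than 4 values")
        if np.ptp(x) == 0:
            rows.append({"group": name, "test": "lilliefors", "statistic": np.nan,
                         "pvalue": np.nan, "note": "constant group"})
            continue
        stat, p = _lilliefors(x, dist="norm")
        rows.append({"group": name, "test": "lilliefors", "statistic": float(stat),
                     "pvalue": float(p), "note": ""})
        clean[name] = x
    if len(clean) >= 2:
        stat, p = sps.levene(*clean.values())
        rows.append({"group": "all", "test": "levene", "statistic": float(stat),
                     "pvalue": float(p), "note": ""})
    return pd.DataFrame(rows)


def _dunn_pairs_kw(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn z-tests on mean ranks after Kruskal-Wallis, tie-corrected."""
    names = list(groups)
    sizes = {k: len(groups[k]) for k in names}
    pooled = np.concatenate([groups[k] for k in names])
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_rank = {}
    start = 0
    for k in names:
        mean_rank[k] = ranks[start:start + sizes[k]].mean()
        start += sizes[k]
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts**3 - counts)
    var_base = n_total * (n_total + 1) / 12.0 - tie / (12.0 * (n_total - 1))
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        p_adj = sidak_adjust(p_raw, m)
        rows.append({"a": a, "b": b, "z": float(z), "p_raw": float(p_raw),
                     "p_adj": p_adj, "significant": p_adj < _ALPHA})
    return pd.DataFrame(rows)


def kruskal_wallis_posthoc(groups: dict[str, np.ndarray],
                           description: str = "") -> StatReport:
    """Kruskal-Wallis omnibus over independent groups + Dunn-Šidák post hoc.

    Post hoc pairwise comparisons run only when the omnibus p < 0.05;
    otherwise the report notes that they were skipped.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(v, dtype=np.float64) for v in groups.values()]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    stat, p = sps.kruskal(*arrays)
    report = StatReport(
        test="kruskal-wallis",
        description=description or f"{len(groups)} groups",
        statistic=float(stat),
        pvalue=float(p),
    )
    if report.significant:
        report.pairwise = _dunn_pairs_kw(
            {k: np.asarray(v, dtype=np.float64) for k, v in groups.items()}
        )
        report.m_comparisons = len(report.pairwise)
    else:
        report.notes.append("omnibus not significant; post hoc skipped")
    return report


def friedman_posthoc(blocked: pd.DataFrame, description: str = "") -> StatReport:
    """Friedman omnibus over treatments (columns) within blocks (rows).

    Post hoc: pairwise z-tests on treatment mean ranks,
    z = (R̄_a - R̄_b) / sqrt(t(t+1)/(6 n_blocks)), Šidák-adjusted over all
    pairs; run only when the omnibus p < 0.05.  The matrix must be complete.
    """
    X = np.asarray(blocked, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a complete blocks x treatments matrix (>= 2 each)")
    if not np.all(np.isfinite(X)):
        raise ValueError("incomplete matrix: non-finite entries")
    n, t = X.shape
    names = list(blocked.columns) if isinstance(blocked, pd.DataFrame) else list(range(t))
    stat, p = sps.friedmanchisquare(*[X[:, j] for j in range(t)])
    report = StatReport(
        test="friedman",
        description=description or f"{t} treatments x {n} blocks",
        statistic=float(stat),
        pvalue=float(p),
    )
    if report.significant:
        within = np.apply_along_axis(sps.rankdata, 1, X)
        mean_rank = within.mean(axis=0)
        se = np.sqrt(t * (t + 1) / (6.0 * n))
        pairs = list(itertools.combinations(range(t), 2))
        m = len(pairs)
        rows = []
        for a, b in pairs:
            z = (mean_rank[a] - mean_rank[b]) / se
            p_raw = 2.0 * sps.norm.sf(abs(z))
            p_adj = sidak_adjust(float(p_raw), m)
            rows.append({"a": names[a], "b": names[b], "z": float(z),
                         "p_raw": float(p_raw), "p_adj": p_adj,
                         "significant": p_adj < _ALPHA})
        report.pairwise = pd.DataFrame(rows)
        report.m_comparisons = m
    else:
        report.notes.append("omnibus not significant; post hoc skipped")
    return report
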