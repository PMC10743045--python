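"""Per-feature reproducibility across segmentation methods via ICC(A,1).

The three segmentation methods play the role of k = 3 observers measuring
each feature on the same n subjects.  For a two-way crossed design with one
observation per cell, the single-measure absolute-agreement intraclass
correlation is

    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

with MS_R the between-subject (row) mean square, MS_C the between-method
(column) mean square and MS_E the residual mean square.  Absolute agreement
penalizes systematic offsets between methods: adding a constant to one
method's column lowers the ICC, while a global affine rescaling of the
whole matrix leaves it unchanged.

ICC values are banded with the Koo-Li convention (left-closed intervals):
poor [-inf, 0.5), moderate [0.5, 0.75), good [0.75, 0.9),
excellent [0.9, inf).  Negative estimates, which the formula can produce on
data, are reported raw and banded "poor".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureTable

__all__ = [
    "ICCResult",
    "icc_absolute_agreement",
    "icc_band",
    "BANDS",
    "ReproducibilityModel",
    "ReproducibilityResults",
]

BANDS = ("poor", "moderate", "good", "excellent")
_BAND_EDGES = (0.5, 0.75, 0.9)


def icc_band(icc: float) -> str:
    """Koo-Li reproducibility band; intervals closed on the left."""
    if np.isnan(icc):
        return "not-computable"
    if icc < _BAND_EDGES[0]:
        return "poor"
    if icc < _BAND_EDGES[1]:
        return "moderate"
    if icc < _BAND_EDGES[2]:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int
    k: int

    @property
    def band(self) -> str:
        return icc_band(self.icc)

    @property
    def computable(self) -> bool:
        return not np.isnan(self.icc)


def icc_absolute_agreement(measurements: np.ndarray) -> ICCResult:
    """Single-measure absolute-agreement ICC of an n x k matrix.

    Mean squares come from the two-way crossed ANOVA decomposition
    (subjects x methods, one observation per cell).  A matrix with zero
    total variance has an undefined ICC, returned as NaN and excluded from
    summaries downstream.
    """
    x = np.asarray(measurements, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("measurements must be a 2-D n x k matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("measurements must be finite")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = float(np.sum((x - grand) ** 2))
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = max(ss_err, 0.0) / ((n - 1) * (k - 1))

    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if ss_total == 0 or denom == 0:
        icc = np.nan
    else:
        icc = (ms_r - ms_e) / denom
    return ICCResult(icc=float(icc), ms_rows=ms_r, ms_cols=ms_c, ms_error=ms_e, n=n, k=k)


class ReproducibilityModel:
    """Feature-reproducibility analysis over method-tagged feature tables.

    Parameters
    ----------
    tables
        Mapping of segmentation method -> :class:`FeatureTable`; all tables
        must share subjects (rows) and feature columns.  The methods are
        the k observers of the ICC design.
    """

    def __init__(self, tables: dict[str, FeatureTable]):
        if len(tables) < 2:
            raise ValueError("need at least two methods")
        self.methods = tuple(tables)
        frames = [tables[m].data for m in self.methods]
        first = frames[0]
        for f in frames[1:]:
            if not f.index.equals(first.index):
                raise ValueError("subject mismatch across tables")
            if not f.columns.equals(first.columns):
                raise ValueError("feature-column mismatch across tables")
        self.tables = tables
        self._stack = np.stack([f.to_numpy() for f in frames], axis=-1)  # n x p x k
        self.descriptors = tables[self.methods[0]].descriptors

    def fit(self) -> "ReproducibilityResults":
        n, p, k = self._stack.shape
        records = []
        for j in range(p):
            r = icc_absolute_agreement(self._stack[:, j, :])
            records.append((r.icc, r.ms_rows, r.ms_cols, r.ms_error, r.band))
        per_feature = pd.DataFrame(
            records,
            index=self.descriptors.index,
            columns=["icc", "ms_rows", "ms_cols", "ms_error", "band"],
        ).join(self.descriptors)
        return ReproducibilityResults(per_feature, n=n, k=k, methods=self.methods)


class ReproducibilityResults:
    """Per-feature ICCs plus grouped summaries and band frequencies."""

    def __init__(self, per_feature: pd.DataFrame, n: int, k: int, methods):
        self.per_feature = per_feature
        self.n = n
        self.k = k
        self.methods = methods

    # -- grouped summaries ---------------------------------------------------

    def _summary(self, keys) -> pd.DataFrame:
        """Mean ICC (over computable features) + band frequencies per group."""
        df = self.per_feature
        rows = []
        for group, sub in df.groupby(keys, sort=True):
            iccs = sub["icc"].dropna()
            rec = {
                "mean_icc": float(iccs.mean()) if len(iccs) else np.nan,
                "n_features": int(len(sub)),
                "n_computable": int(len(iccs)),
            }
            counts = sub["band"].value_counts()
            for band in BANDS:
                rec[f"pct_{band}"] = 100.0 * counts.get(band, 0) / len(sub)
            if isinstance(group, tuple):
                rec.update(dict(zip(keys, group)))
            else:
                rec[keys[0] if isinstance(keys, list) else keys] = group
            rows.append(rec)
        keycols = keys if isinstance(keys, list) else [keys]
        return pd.DataFrame(rows).set_index(keycols)

    def class_summary(self) -> pd.DataFrame:
        """Mean ICC per (image kind x feature class) — the class averages."""
        return self._summary(["image_kind", "feature_class"])

    def class_overall_summary(self) -> pd.DataFrame:
        return self._summary("feature_class")

    def image_kind_summary(self) -> pd.DataFrame:
        return self._summary("image_kind")

    def subband_summary(self) -> pd.DataFrame:
        """Mean ICC per wavelet sub-band (8 groups)."""
        df = self.per_feature[self.per_feature["image_kind"] == "wavelet"]
        out = ReproducibilityResults(df, self.n, self.k, self.methods)._summary("subband")
        return out

    def band_frequencies(self, by: str = "image_kind") -> pd.DataFrame:
        """Percentage of features per reproducibility band, per grouping."""
        return self._summary(by)[[f"pct_{b}" for b in BANDS]]

    def summary(self) -> str:
        cs = self.class_summary()
        lines = [
            "Feature reproducibility across segmentation methods (ICC, absolute agreement)",
            f"subjects n = {self.n}, methods k = {self.k} ({', '.join(self.methods)})",
            f"features: {len(self.per_feature)} "
            f"({int(self.per_feature['icc'].notna().sum())} computable)",
            "",
            cs.round(3).to_string(),
        ]
        return "\n".join(lines)

    def write(self, directory) -> None:
        """Per-feature and summary CSVs."""
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.per_feature.to_csv(d / "icc_per_feature.csv")
        self.class_summary().to_csv(d / "icc_class_summary.csv")
        self.subband_summary().to_csv(d / "icc_subband_summary.csv")
        self.band_frequencies().to_csv(d / "icc_band_frequencies.csv")
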