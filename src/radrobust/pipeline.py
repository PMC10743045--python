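"""End-to-end orchestration: simulate -> segment -> extract -> robustness ->
select -> evaluate -> stats.

Each stage is a thin call into the corresponding module; the bundle
directory receives every artifact as version-stamped CSV/JSON plus the
resolved configuration, and an identical configuration reproduces the
bundle byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import CrossValidationExperiment, CVResults, make_repeated_folds
from .features import extract_feature_table
from .io import RunConfig, write_cohort, write_csv
from .phantoms import generate_cohort
from .robustness import ReproducibilityModel, ReproducibilityResults
from .segmentation import agreement_matrix, segment_cohort
from .selection import HybridFeatureSelector
from .stats import distribution_checks, friedman_posthoc, kruskal_wallis_posthoc

log = logging.getLogger("radrobust")

__all__ = ["PipelineBundle", "run_pipeline", "run_statistics"]


@dataclass
class PipelineBundle:
    """In-memory results of a full run (also written to the bundle dir)."""

    config: RunConfig
    cases: list
    segmentations: list
    agreement: object
    tables: dict
    robustness: ReproducibilityResults
    selections: dict
    cv_results: dict[str, CVResults]
    stat_reports: dict
    timings: dict = field(default_factory=dict)


def run_statistics(robustness: ReproducibilityResults, cv_results: dict) -> dict:
    """The statistical battery over ICC groupings and CV performance.

    * Kruskal-Wallis across feature classes, once per image kind;
    * Friedman across the 8 wavelet sub-bands (blocks = base features);
    * Friedman across models (blocks = segmentation x metric);
    * Friedman across segmentations (blocks = models), once per metric;
    plus Lilliefors/Levene distribution checks on the per-class ICCs.
    """
    reports: dict[str, object] = {}
    pf = robustness.per_feature

    for kind, sub in pf.groupby("image_kind"):
        groups = {
            cls: g["icc"].dropna().to_numpy()
            for cls, g in sub.groupby("feature_class")
            if g["icc"].notna().sum() >= 2
        }
        if len(groups) >= 2:
            reports[f"kw_classes_{kind}"] = kruskal_wallis_posthoc(
                groups, description=f"ICC by feature class, {kind} images"
            )
            try:
                reports[f"checks_{kind}"] = distribution_checks(
                    {k: v for k, v in groups.items() if len(v) >= 4}
                )
            except ValueError:
                pass

    wav = pf[pf["image_kind"] == "wavelet"].copy()
    if len(wav):
        wav["base"] = wav["feature_class"] + "_" + wav["feature"]
        blocked = wav.pivot_table(index="base", columns="subband", values="icc")
        blocked = blocked.dropna(axis=0)
        if blocked.shape[0] >= 2 and blocked.shape[1] >= 2:
            reports["friedman_subbands"] = friedman_posthoc(
                blocked, description="ICC by wavelet sub-band (blocks = features)"
            )

    if cv_results:
        rows = []
        for method, res in cv_results.items():
            agg = res.aggregate(n_boot=200)
            for model, rec in agg.iterrows():
                for metric in ("accuracy", "auc", "sensitivity", "specificity", "precision", "fscore"):
                    rows.append(
                        {"method": method, "model": model, "metric": metric, "value": rec[metric]}
                    )
        perf = pd.DataFrame(rows)
        by_model = perf.pivot_table(
            index=["method", "metric"], columns="model", values="value"
        ).dropna()
        if by_model.shape[0] >= 2 and by_model.shape[1] >= 2:
            reports["friedman_models"] = friedman_posthoc(
                by_model, description="performance by model (blocks = segmentation x metric)"
            )
        for metric, sub in perf.groupby("metric"):
            by_seg = sub.pivot_table(index="model", columns="method", values="value").dropna()
            if by_seg.shape[0] >= 2 and by_seg.shape[1] >= 2:
                reports[f"friedman_segmentations_{metric}"] = friedman_posthoc(
                    by_seg, description=f"{metric} by segmentation (blocks = models)"
                )
    return reports


def run_pipeline(config: RunConfig) -> PipelineBundle:
    """Execute every stage on a synthetic cohort and write the bundle."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        log.info("stage %s", name)
        timings[name] = time.perf_counter()

    def done(name):
        timings[name] = time.perf_counter() - timings[name]
        log.info("stage %s done in %.1fs", name, timings[name])

    stage("simulate")
    cohort_spec = config.cohort
    if cohort_spec.seed == 0 and config.master_seed != 0:
        from dataclasses import replace

        cohort_spec = replace(cohort_spec, seed=config.stage_seed("simulate"))
    cases = generate_cohort(cohort_spec)
    if config.write_volumes:
        write_cohort(cases, out / "cohort")
    else:
        rows = [
            {"subject_id": c.subject_id, "label": c.label,
             "spacing_x": c.spacing[0], "spacing_y": c.spacing[1], "spacing_z": c.spacing[2]}
            for c in cases
        ]
        write_csv(pd.DataFrame(rows), out / "cohort_manifest.csv")
    done("simulate")

    stage("segment")
    seg = segment_cohort(
        cases,
        seed=config.stage_seed("segment"),
        threshold_fraction=config.segmentation.threshold_fraction,
        rg_iterations=config.segmentation.rg_iterations,
        rg_smoothing=config.segmentation.rg_smoothing,
        manual_amplitude_mm=config.segmentation.manual_amplitude_mm,
    )
    agreement = agreement_matrix(seg)
    write_csv(agreement.to_dataframe(), out / "agreement_matrix.csv", index=True)
    done("segment")

    stage("extract")
    tables = extract_feature_table(cases, seg, config.extraction)
    for method, table in tables.items():
        table.write(out / f"features_{method}")
    done("extract")

    stage("robustness")
    robustness = ReproducibilityModel(tables).fit()
    robustness.write(out / "robustness")
    done("robustness")

    stage("select")
    selections = {}
    for method, table in tables.items():
        res = HybridFeatureSelector(table.data, table.labels).fit()
        selections[method] = res
        with open(out / f"selection_{method}.json", "w", encoding="utf-8") as fh:
            json.dump(res.to_dict(), fh, indent=1)
        write_csv(
            res.scores.rename("r_pb").reset_index().rename(columns={"index": "feature"}),
            out / f"selection_scores_{method}.csv",
        )
    done("select")

    stage("evaluate")
    labels = tables[next(iter(tables))].labels.to_numpy()
    plan = make_repeated_folds(
        labels, k=config.cv.k, reps=config.cv.reps, seed=config.stage_seed("evaluate")
    )
    cv_results = {}
    per_rep_frames = []
    for method, table in tables.items():
        res = selections[method]
        X = table.data[res.selected or res.ranking[:1]]
        cv = CrossValidationExperiment(
            X, labels, plan, seed=config.stage_seed(f"cv-{method}")
        ).fit()
        cv_results[method] = cv
        per_rep_frames.append(cv.per_repetition.assign(segmentation=method))
        write_csv(
            cv.aggregate(n_boot=config.cv.n_boot).reset_index(),
            out / f"cv_aggregate_{method}.csv",
        )
    write_csv(pd.concat(per_rep_frames, ignore_index=True), out / "cv_per_repetition.csv")
    done("evaluate")

    stage("stats")
    reports = run_statistics(robustness, cv_results)
    serializable = {}
    for name, rep in reports.items():
        if isinstance(rep, pd.DataFrame):
            write_csv(rep, out / f"stats_{name}.csv")
            serializable[name] = rep.to_dict(orient="records")
        else:
            serializable[name] = rep.to_dict()
    with open(out / "stats.json", "w", encoding="utf-8") as fh:
        json.dump(serializable, fh, indent=1, default=float)
    done("stats")

    config.to_yaml(out / "config.yaml")
    with open(out / "run_info.json", "w", encoding="utf-8") as fh:
        json.dump({"version": __version__, "timings_s": timings}, fh, indent=1)

    return PipelineBundle(
        config=config,
        cases=cases,
        segmentations=seg,
        agreement=agreement,
        tables=tables,
        robustness=robustness,
        selections=selections,
        cv_results=cv_results,
        stat_reports=reports,
        timings=timings,
    )
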